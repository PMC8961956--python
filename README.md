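# rumenet

Tools for asking how the *structure* of a rumen bacterial community — not
just which taxa are present — relates to growth performance in beef
cattle. The package implements the analysis arc of longitudinal 16S ASV
studies that follow calves from weaning through backgrounding (the
growing phase on dry-lot, cover-crop or pasture systems) into feedlot
finishing: diversity dynamics, indicator-taxon mining, compositionally
corrected co-abundance networks, graph-centrality traits, and their
association with average daily gain (ADG, kg/day).

It is written for microbial ecologists who have an ASV count table,
sample metadata and per-animal phenotypes, and want the whole chain —
from validated input containers to Cytoscape-loadable networks and
letters-display group contrasts — as reproducible, tested Python.

## The statistics at the core

**Diversity.** Per-sample observed richness, Shannon entropy
H = −Σ pᵢ ln pᵢ (nats) and Gini–Simpson 1 − Σ pᵢ²; Bray–Curtis
dissimilarity d(x, y) = 1 − 2 Σ min(xᵢ, yᵢ) / Σ (xᵢ + yᵢ); classical PCoA;
single-factor PERMANOVA (pseudo-F on squared distances, R²) and ANOSIM
(rank-based R) with label-permutation p-values (+1/+1 convention);
distance-to-centroid dispersion for between-animal heterogeneity.

**Indicator taxa.** Dufrêne–Legendre IndVal on the 0–1 scale:
IndValᵢ = max_g Aᵢg·Bᵢg, where Aᵢg is the group-mean-based specificity and
Bᵢg the within-group occupancy; significance by permuting group labels
(exact enumeration on small designs), BH-adjusted across taxa, optionally
combined with an FDR-adjusted Kruskal–Wallis filter.

**Co-abundance networks.** Per (group × timepoint) stratum: prevalence
filter → centered log-ratio transform (clrᵢ = ln pᵢ − mean_j ln pⱼ, the
compositional correction) → tie-corrected Spearman ρ for every taxon pair
→ keep edges with ρ > 0.7 and BH q < 0.05. Node traits (degree, neighbor
connectivity, average shortest path length, closeness, clustering,
eccentricity, radiality) and Brandes edge betweenness are computed from
first principles and verified against exhaustive brute-force oracles.

**Phenotype association.** Genus-aggregated CLR abundances and network
traits per animal vs per-phase ADG by Spearman correlation with BH
adjustment; ADG contrasts across backgrounding systems by Kruskal–Wallis
with pairwise Wilcoxon letters displays.

Because the raw sequence data such studies deposit are not needed to test
any of this, a first-class synthetic-data module generates the full
longitudinal design with *planted* truth: correlation blocks with known
membership, group-specific indicator taxa, diet-switch diversity crashes,
and an ADG signal coupled to each group's planted network connectance.

## Worked example

```python
from rumenet.synthetic import SyntheticConfig, generate
from rumenet import diversity as dv, network as nw

ds = generate(SyntheticConfig(seed=1))   # default 3-group x 5-timepoint study

alpha = dv.alpha_diversity(ds.counts)
meta = ds.frame.data
for g in ("DL", "PP"):
    t1 = alpha.loc[meta.index[(meta.group == g) & (meta.timepoint == "T1")], "shannon"].mean()
    t2 = alpha.loc[meta.index[(meta.group == g) & (meta.timepoint == "T2")], "shannon"].mean()
    print(f"Shannon {g}: weaning {t1:.2f} -> early backgrounding {t2:.2f}")

sids = ds.frame.samples_at(timepoint="T3")
d = dv.bray_curtis(ds.counts.subset_samples(sids))
res = dv.anosim(d, ds.frame.labels(sids, "group"), n_perm=999, seed=0)
print(f"ANOSIM at T3: R = {res.statistic:.3f}, p = {res.p:.4f}")

for g in ("DL", "PP"):
    sids = ds.frame.samples_at(timepoint="T3", group=g)
    filt = nw.prevalence_filter(ds.counts.subset_samples(sids), 0.3)
    corr = nw.spearman_matrix(nw.clr_transform(filt))
    net = nw.build_network(corr, rho_min=0.7, q_max=0.05, stratum=(g, "T3"))
    attrs = nw.node_attributes(net)
    print(f"{g} T3 network: {net.n_edges} edges, "
          f"mean degree {attrs['degree'].mean():.2f}, "
          f"mean path length {attrs['avg_shortest_path_length'].dropna().mean():.2f}")
```

prints

```
Shannon DL: weaning 4.10 -> early backgrounding 3.28
Shannon PP: weaning 4.02 -> early backgrounding 4.13
ANOSIM at T3: R = 0.968, p = 0.0010
DL T3 network: 78 edges, mean degree 4.73, mean path length 1.05
PP T3 network: 13 edges, mean degree 1.44, mean path length 1.13
```

Read top to bottom, that is the study's story in miniature: the
dry-lot diet switch crashes diversity while pasture animals are
unaffected; by late backgrounding each system carries a distinct
community (ANOSIM R near 1); and the dry-lot group's co-abundance
network is denser and "faster" (higher degree, shorter paths) than the
pasture group's — the planted gradient that, through the generator's
coupling, also gives those animals the highest backgrounding ADG.

The same study runs end to end from one config:

```bash
rumenet run --config study.yaml      # -> report.md, TSVs, networks, figures
rumenet simulate --seed 4 --out sim/ # just the synthetic tables
rumenet network --counts sim/counts.tsv --metadata sim/metadata.tsv --out nets/
```

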