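# Methods

This note documents the models and procedures rumenet implements, the
design choices that were genuinely open, and what the synthetic-data
generator does and does not emulate.

## Data model

All analyses start from four validated containers: a samples × ASVs
integer count table (all-zero samples dropped with a warning; proportion
tables rejected so that counts remain the single source of scale), a
positional seven-rank taxonomy (a lineage is truncated at its first
unassigned rank), per-sample design metadata (animal, backgrounding
group ∈ {CC, DL, PP}, timepoint T1–T5, study day, with days required to
be monotone along the timepoint order), and per-animal ADG (kg/day) for
the backgrounding, finishing and overall phases. TSV orientation is
detected from the header keyword (`#SampleID` ⇒ samples as rows) with an
explicit override, because both orientations occur in the wild.

## Diversity and permutation tests

Shannon entropy is reported in nats (the convention of the R community
ecology stack). No rarefaction is applied by default: per-sample
proportions are the conservative choice, and the CLR transform handles
compositionality where correlation is involved.

PERMANOVA is single-factor: pseudo-F is computed from sums of squared
distances (SS_total = Σ_{i<j} d²ᵢⱼ/n, SS_within summed per group), with
R² = SS_between/SS_total. ANOSIM ranks all n(n−1)/2 distances (midranks
on ties) and forms R = (r̄_between − r̄_within)/(M/2). Both p-values use
the +1/+1 convention — the observed statistic counts as one permutation —
so p ∈ [1/(n_perm+1), 1] and rejection at α is exact under the null with
199 permutations. Temporal or age effects are handled by running tests
within strata rather than by multi-factor partitioning, which is all the
reported contrasts require. Dispersion uses distance to the group
centroid in full PCoA space (betadisper-style) rather than mean pairwise
distance, which is the standard choice and unbiased with respect to group
size.

Post-hoc structure after a Kruskal–Wallis test is always pairwise
two-sided Wilcoxon rank-sum with Benjamini–Hochberg adjustment within the
family of pairs, rendered as a compact letters display (groups not
sharing a letter differ at α = 0.05; letters are maximal cliques of the
"not significantly different" graph).

## Indicator analysis

IndVal uses the unweighted (group-mean based) specificity, which is
robust to the 12-vs-13 animal imbalance, on the 0–1 scale. The
permutation statistic is the max-over-groups IndVal per taxon, matching
the reporting of one best group per taxon; enumeration of all distinct
relabelings replaces sampling automatically below 10⁵ arrangements. The
late-backgrounding mining profile applies the stricter filter
IndVal > 0.7 combined with the FDR-adjusted Kruskal–Wallis test; the
q < 0.05 threshold is applied to the BH-adjusted KW q (an alternative
reading would apply a raw-p cutoff to the permutation p; both filters are
exposed independently so either profile can be configured).

## Co-abundance networks

"Compositional correction" is implemented as CLR-then-Spearman: counts
plus pseudocount (default 1; pseudocount 0 is the pure-proportion mode,
invariant to per-sample sequencing-depth rescaling), log-ratio centring,
then tie-corrected Spearman correlation (Pearson on midranks) for every
taxon pair. Model-based alternatives (e.g. SparCC-style inference) were
considered and rejected because the analysis thresholds are stated as
plain correlation coefficients on corrected data. Two-sided p-values use
the t approximation with n−2 df; exact permutation enumeration replaces
it automatically for n ≤ 8 (and on request up to n = 10 — beyond that the
factorial null is not tractable pairwise). BH adjustment runs over each
stratum's upper triangle independently, since networks are inferred
independently per stratum.

Networks keep pairs with ρ > 0.7 and q < 0.05 (strict inequalities,
positive-only edges by default with an absolute-value policy available)
per group × timepoint stratum across that stratum's 12–13 animals. A
prevalence filter (≥ 30% of the stratum's samples by default) precedes
correlation: at these sample sizes rarer taxa produce unstable rank
correlations. Empty networks are legitimate output — the weaning-stage
community yields almost none.

Graph attributes follow the conventions of the desktop network tools this
kind of analysis is usually done in: closeness is the reachable-pair form
(#reachable / Σ distances, not harmonic centrality); per-node average
shortest path length averages over reachable nodes only, so disconnected
graphs are handled component-wise; radiality normalises by the node's own
component diameter and size; edge betweenness gives fractional credit
among equal-length shortest paths (Brandes accumulation over unordered
pairs). Every one of these is tested for exact equality against an
independent brute-force implementation on all connected graphs with ≤ 5
nodes and 200 random graphs with ≤ 7 nodes, and against networkx where
conventions coincide.

The cross-stratum topology ordination z-scores the pooled node ×
attribute matrix (missing path metrics imputed by the pooled median,
flagged), ordinates it by PCoA on Euclidean distances (equivalent to
PCA), and tests stratum separation by PERMANOVA on those distances.

## Phenotype association

Genus aggregation sums ASV counts per genus, pooling genus-unassigned
ASVs under `unclassified_<finest assigned label>`; totals are conserved.
Feature–ADG association is Spearman (hence invariant to monotone feature
transforms) with BH across features. Per-animal network features are the
node-attribute medians of the animal's group-stratum network — networks
exist per group, not per animal, and results record that grouping level
to prevent pseudo-replication misreads. ADG contrasts across
backgrounding systems use the per-phase Kruskal–Wallis/Wilcoxon letters
analogue of a least-squares-means table: per-phase ADG is a single number
per animal, so repeated-measures mixed-model machinery adds nothing the
package is about.

## Synthetic data: what it emulates

The generator reproduces the study design — 38 animals in three
backgrounding systems (13 DL, 13 CC, 12 PP), five sampling days (0, 28,
55, 121, 185), sequencing depth negative-binomial with mean 29,000 reads
and dispersion 17 (matching the reported mean and spread; the pipeline's
`test` profile scales the mean to 5,000 for speed) — over a Gaussian-
copula-style latent log-normal abundance model:

1. **Correlation blocks.** Per stratum, latent log-abundances are
   multivariate normal with an equicorrelated block inside each planted
   co-abundance block (shared-factor construction) and independence
   elsewhere. Block count, size and correlation accept per-group values;
   the defaults (5/5/5 blocks of size 6/5/4 at ρ 0.99/0.96/0.93 for
   DL/CC/PP) plant a DL > CC > PP connectivity gradient. The ρ gradient
   is what shapes the recovered topology: with equicorrelated blocks and
   a hard correlation threshold, recovered subgraphs are necessarily
   near-cliques (two high adjacent correlations force the third pair high
   by positive semi-definiteness, so chain-like structures cannot be
   planted at detectable strength), and path-length contrasts therefore
   arise from *recovery completeness* — DL's blocks recover essentially
   complete (path length ≈ 1) while CC/PP blocks recover partially.
   Block membership activates by timepoint (20% of blocks at weaning,
   all during backgrounding, 60% at finishing), giving the
   sparse-to-complex-to-reduced network arc.
2. **Indicator taxa.** Eight taxa per group receive +ln(5) latent-mean
   enrichment in their own group at T2–T3.
3. **Diet switch.** From T2 onward, switched groups (DL, CC) have half of
   the unreserved taxa suppressed by −4 log units and a small group-
   specific set of initially rare taxa raised to a fixed dominant latent
   level — a bloom. At finishing (T4–T5) every group receives a shared
   suppression set and a shared bloom, emulating the move to one common
   high-energy diet. Suppression draws from above-median-abundance taxa
   and the bloom creates dominance because, in a heavy-tailed community,
   evenness (Shannon) only falls visibly when either established taxa
   vanish or a few taxa take over; a diffuse suppression of random rare
   taxa is statistically invisible at n = 13. Effect sizes are chosen for
   clear recoverability of the planted signal, not calibrated to any real
   effect size (none is available), and that is their only justification.
4. **Phenotype.** Per-phase ADG = baseline (0.9 backgrounding / 1.5
   finishing kg/day) + 50 × (planted connectance of the group's strata in
   that phase) + N(0, 0.05); connectance is the planted within-block pair
   fraction of all taxon pairs — the generative quantity the simulator
   controls directly, standing in for the degree/neighbor-connectivity
   story. The overall phase is the day-weighted mean of the two.

Softmax of (latent + N(0, 0.1) sample noise) gives per-sample relative
abundances, closed to 1 before multinomial sampling at the drawn depth
(floored at 500 reads to avoid empty libraries). Block taxa receive a
higher baseline log-mean (1.5 ± 0.5 vs 0 ± 1.5) so that planted
interactors are prevalent community members — co-abundance inference on
rare taxa is excluded by the prevalence filter anyway.

**What it does not emulate.** Within-animal temporal autocorrelation
(samples are independent draws per animal-timepoint), phylogenetic
structure in the taxonomy (lineages are drawn from a small fixed
vocabulary), sequencing error and chimeras, the finishing-stage
*reversal* of the connectivity gradient the real study reports (the
planted gradient is time-constant), and per-animal network variation
(connectance is a group-level trait). Passing tests therefore demonstrate
that the estimators recover planted structure of realistic magnitude at
the study's sample sizes — not that they would behave identically on
real rumen data.

## Numerical choices and degenerate inputs

Permutation p-values can never be zero (+1/+1). BH uses the standard
step-up; q-values equal p-values scaled, never below p. Constant taxa
yield H = 0, p = 1 in Kruskal–Wallis; taxa constant after CLR have
undefined correlations and are excluded from the BH family. Isolated
nodes carry NaN path metrics with an explicit flag; clustering is 0 for
degree < 2. PCoA discards negative-eigenvalue axes and reports their
magnitude. Ties use midranks throughout. The pipeline derives one
substream per stage by hashing the stage name with the global seed, so
adding a stage never perturbs another stage's randomness.

## Problem sizes in the test suite

The default end-to-end study (190 samples × 150 taxa, 999 permutations)
runs in well under a minute; the acceptance properties use 10 simulated
datasets for edge recovery (60 samples × 100 taxa) and 1,000
exchangeable-null datasets (n = 20) for permutation-test calibration.
These sizes give the Monte-Carlo estimates comfortable margins around
their acceptance bands while keeping the whole suite fast.

## Known limitations

Single-factor PERMANOVA only; no UniFrac (no tree is modelled); no
repeated-measures phenotype model; exact Spearman permutation p is
limited to very small n; the letters display is computed from pairwise
BH-adjusted calls and, like all such displays, is not a simultaneous
inference procedure.
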