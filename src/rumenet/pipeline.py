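"""End-to-end orchestration: simulate/ingest -> diversity -> indicators ->
networks -> associations -> report.

A single :class:`PipelineConfig` (loadable from YAML) drives the run. Two
profiles exist: ``paper`` pins the printed analysis thresholds (rho > 0.7,
q < 0.05, IndVal > 0.5 with the stricter 0.7 applied at the late-
backgrounding indicator mining, 999 permutations, full sequencing depth)
and ``test`` reduces permutations and simulated depth for fast runs.

Every stochastic stage consumes a seed derived from the global seed by
hashing the stage name, so inserting a stage never perturbs the others.
The run emits TSVs per stage, Cytoscape-loadable network files, a small
figure set, a markdown report and a manifest with per-output checksums —
rerunning an identical config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, diversity, indicator, io_formats, network
from .stats import GroupComparison, derive_seed
from .synthetic import SyntheticConfig, SyntheticDataset, generate
from .tables import CountTable, PhenotypeTable, SampleFrame, TaxonomyTable

logger = logging.getLogger("rumenet")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """One config object for the whole study analogue."""

    outdir: str = "rumenet_out"
    seed: int = 0
    profile: str = "paper"  # paper | test
    # inputs: either a simulate block or paths
    simulate: SyntheticConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    phenotype_path: str | None = None
    # thresholds
    rho_min: float = 0.7
    q_max: float = 0.05
    sign: str = "positive"
    min_prevalence: float = 0.3
    indval_min: float = 0.5
    indval_q_max: float = 0.05
    indicator_timepoint: str = "T3"
    indicator_strict_min: float = 0.7  # late-BKG mining profile
    n_permutations: int = 999
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.profile not in ("paper", "test"):
            raise ValueError("profile must be 'paper' or 'test'")
        if self.profile == "test":
            self.n_permutations = min(self.n_permutations, 199)
            if self.simulate is not None and self.simulate.depth_mean > 5000:
                self.simulate = replace(self.simulate, depth_mean=5000.0)
        if not (0 < self.q_max <= 1 and 0 <= self.rho_min <= 1):
            raise ValueError("thresholds out of range")
        if self.simulate is None and (self.counts_path is None or self.metadata_path is None):
            raise ValueError("either a simulate block or counts+metadata paths are required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        sim = doc.pop("simulate", None)
        if sim is not None:
            if not isinstance(sim, dict):
                raise ValueError("simulate block must be a mapping")
            for key in ("groups", "n_animals_per_group", "timepoints", "days",
                        "n_blocks", "block_size", "block_rho", "block_activity",
                        "indicator_timepoints", "switch_groups", "adg_baseline"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(tuple(x) if isinstance(x, list) else x
                                     for x in sim[key]) if key == "adg_baseline" \
                        else tuple(sim[key])
            doc["simulate"] = SyntheticConfig(**sim)
        return cls(**doc)

    def config_hash(self) -> str:
        doc = asdict(self)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stage_seconds: dict = field(default_factory=dict)
    stage_seeds: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, stratum, cause: Exception):
        super().__init__(f"stage {stage!r} failed at stratum {stratum!r}: {cause}")
        self.stage, self.stratum = stage, stratum


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    manifest: RunManifest
    outdir: Path
    summary: dict  # in-memory summary for programmatic inspection
    dataset: SyntheticDataset | None = None


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim = replace(config.simulate, seed=derive_seed(config.seed, "simulate"))
        ds = generate(sim)
        return ds.counts, ds.frame, ds.taxonomy, ds.phenotype, ds
    counts = io_formats.read_count_table(config.counts_path)
    frame = io_formats.read_sample_frame(config.metadata_path)
    tax = io_formats.read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
    pheno = io_formats.read_phenotype(config.phenotype_path) if config.phenotype_path else None
    return counts, frame, tax, pheno, None


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full study analogue; see module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(), version=__version__, seed=config.seed
    )
    summary: dict = {}
    timers: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timers[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    raise StageFailure(name, summary.get("current_stratum"), exc)
        return _Timer()

    # ------------------------------------------------------------------ input
    with stage("input"):
        counts, frame, taxonomy, phenotype, dataset = _load_inputs(config)
        tps = [t for t in frame.timepoints if t in set(frame.data["timepoint"])]
        groups = sorted(set(frame.data["group"]))
        io_formats.write_count_table(counts, outdir / "counts.tsv")
        io_formats.write_sample_frame(frame, outdir / "metadata.tsv")
        if taxonomy is not None:
            io_formats.write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
        if phenotype is not None:
            io_formats.write_phenotype(phenotype, outdir / "phenotype.tsv")

    # ------------------------------------------------------------------ alpha
    with stage("alpha"):
        alpha = diversity.alpha_diversity(counts)
        alpha.reset_index().pipe(io_formats.write_results_table, outdir / "alpha.tsv")
        alpha_by_group = diversity.compare_alpha(alpha, frame, "timepoint", "group")
        alpha_by_time = diversity.compare_alpha(alpha, frame, "group", "timepoint")
        io_formats.write_results_table(
            [gc.to_record() for gc in alpha_by_group + alpha_by_time],
            outdir / "alpha_comparisons.tsv",
        )
        summary["alpha"] = alpha
        summary["alpha_by_group"] = alpha_by_group
        summary["alpha_by_time"] = alpha_by_time

    # ------------------------------------------------------------------- beta
    with stage("beta"):
        beta_records = []
        ordinations = {}
        for tp in tps:
            sids = frame.samples_at(timepoint=tp)
            labels = frame.labels(sids, "group")
            if len(set(labels)) < 2:
                continue
            d = diversity.bray_curtis(counts.subset_samples(sids))
            perm = diversity.permanova(
                d, labels, n_perm=config.n_permutations,
                seed=derive_seed(config.seed, f"permanova:{tp}"),
            )
            ano = diversity.anosim(
                d, labels, n_perm=config.n_permutations,
                seed=derive_seed(config.seed, f"anosim:{tp}"),
            )
            ordinations[tp] = diversity.pcoa(d)
            beta_records.append({"timepoint": tp, "test": "PERMANOVA",
                                 **perm.to_record()})
            beta_records.append({"timepoint": tp, "test": "ANOSIM",
                                 **ano.to_record()})
        io_formats.write_results_table(beta_records, outdir / "beta_tests.tsv")
        coords = []
        for tp, ordn in ordinations.items():
            c = ordn.coordinates.iloc[:, :2].copy()
            c["timepoint"] = tp
            coords.append(c.reset_index(names="sample_id"))
        if coords:
            io_formats.write_results_table(pd.concat(coords, ignore_index=True),
                                           outdir / "pcoa_coordinates.tsv")
        # interindividual dispersion along the study (age effect analogue)
        d_all = diversity.bray_curtis(counts)
        disp, disp_gc = diversity.dispersion(
            d_all, frame.labels(counts.sample_ids, "timepoint"), stratum="all"
        )
        io_formats.write_results_table(
            disp.rename("dispersion").rename_axis("sample_id").reset_index(),
            outdir / "dispersion.tsv",
        )
        summary["beta_tests"] = beta_records
        summary["dispersion_comparison"] = disp_gc
        summary["ordinations"] = ordinations

    # -------------------------------------------------------------- indicators
    with stage("indicators"):
        ind_tp = config.indicator_timepoint if config.indicator_timepoint in tps else tps[0]
        sids = frame.samples_at(timepoint=ind_tp)
        sub = counts.subset_samples(sids)
        labels = frame.labels(sids, "group")
        ind_results = indicator.indval(
            sub, labels, n_perm=config.n_permutations,
            seed=derive_seed(config.seed, "indval"), exact=False,
        )
        da_results = indicator.differential_abundance(sub, labels)
        io_formats.write_results_table(
            [r.to_record() for r in ind_results], outdir / "indval.tsv"
        )
        io_formats.write_results_table(
            [r.to_record() for r in da_results], outdir / "differential_abundance.tsv"
        )
        strict_min = (config.indval_min if config.profile == "test"
                      else config.indicator_strict_min)
        sets = indicator.select_indicators(
            ind_results, indval_min=strict_min, q_max=config.indval_q_max,
            da_results=da_results, da_q_max=config.indval_q_max,
        )
        if not any(sets.values()):
            # fall back to the default-threshold sets for trajectory plots
            sets = indicator.select_indicators(
                ind_results, indval_min=config.indval_min, q_max=config.indval_q_max
            )
        per_sample, traj, rollup = indicator.cumulative_indicator_abundance(
            counts, frame, sets, taxonomy=taxonomy
        )
        io_formats.write_results_table(per_sample, outdir / "indicator_trajectories.tsv")
        io_formats.write_results_table(traj, outdir / "indicator_trajectory_summary.tsv")
        summary["indicator_results"] = ind_results
        summary["indicator_sets"] = sets
        summary["indicator_trajectory"] = traj
        summary["indicator_timepoint"] = ind_tp

    # ---------------------------------------------------------------- networks
    with stage("networks"):
        nets: dict[tuple, network.CoabundanceNetwork] = {}
        node_tables: dict[tuple, pd.DataFrame] = {}
        edge_counts = []
        netdir = outdir / "networks"
        netdir.mkdir(exist_ok=True)
        for g in groups:
            for tp in tps:
                summary["current_stratum"] = (g, tp)
                sids = frame.samples_at(timepoint=tp, group=g)
                if len(sids) < 4:
                    logger.warning("stratum %s/%s has %d samples; skipped", g, tp, len(sids))
                    continue
                sub = counts.subset_samples(sids)
                try:
                    filtered = network.prevalence_filter(sub, config.min_prevalence)
                except ValueError as exc:
                    logger.warning("stratum %s/%s: %s", g, tp, exc)
                    continue
                clr = network.clr_transform(filtered)
                corr = network.spearman_matrix(clr, p_method="t")
                net = network.build_network(
                    corr, rho_min=config.rho_min, q_max=config.q_max,
                    sign=config.sign, stratum=(g, tp),
                )
                nets[(g, tp)] = net
                node_tables[(g, tp)] = network.node_attributes(net)
                edges_attr = network.edge_attributes(net)
                base = netdir / f"{g}_{tp}"
                io_formats.write_network(net, f"{base}.sif", "sif")
                io_formats.write_network(net, f"{base}.graphml", "graphml", taxonomy)
                io_formats.write_network(net, f"{base}_edges.tsv", "edge-tsv")
                node_tables[(g, tp)].reset_index().pipe(
                    io_formats.write_results_table, f"{base}_nodes.tsv"
                )
                io_formats.write_results_table(edges_attr, f"{base}_edge_attributes.tsv")
                edge_counts.append({"group": g, "timepoint": tp,
                                    "n_nodes": len(net.node_ids),
                                    "n_edges": net.n_edges,
                                    "n_samples": len(sids)})
        summary.pop("current_stratum", None)
        io_formats.write_results_table(edge_counts, outdir / "network_sizes.tsv")
        attr_comparisons = network.compare_network_attributes(node_tables)
        io_formats.write_results_table(
            [gc.to_record() for gc in attr_comparisons],
            outdir / "network_attribute_comparisons.tsv",
        )
        populated = {k: v for k, v in node_tables.items() if len(v.dropna(how="all")) >= 3}
        topo = None
        if len({k[0] for k in populated}) >= 2:
            topo = network.topology_ordination(
                populated, n_perm=config.n_permutations,
                seed=derive_seed(config.seed, "topology"),
            )
        summary["networks"] = nets
        summary["node_tables"] = node_tables
        summary["edge_counts"] = edge_counts
        summary["network_comparisons"] = attr_comparisons
        summary["topology"] = topo

    # ------------------------------------------------------------- association
    with stage("association"):
        assoc_records = []
        adg_comparisons: list[GroupComparison] = []
        if phenotype is not None and taxonomy is not None:
            n_tp = len(tps)
            phase_tps = {
                "backgrounding": [t for t in tps if 1 <= tps.index(t) <= min(2, n_tp - 1)],
                "finishing": [t for t in tps if tps.index(t) >= max(n_tp - 2, 1)],
            }
            for phase, ptps in phase_tps.items():
                if phase not in phenotype.phases or not ptps:
                    continue
                feats = association.animal_genus_features(
                    counts, taxonomy, frame, ptps
                )
                res = association.phenotype_correlation(feats, phenotype, phase)
                assoc_records += [{"phase": phase, "feature_kind": "genus_clr",
                                   **r.to_record()} for r in res]
                # network-trait feature: the animal's group-stratum planted
                # connectivity proxy = median node degree of its group network
                deg = {}
                for (g, tp), tab in summary["node_tables"].items():
                    if tp in ptps and len(tab):
                        deg.setdefault(g, []).append(float(tab["degree"].median()))
                groups_map = frame.animal_groups()
                feat = pd.DataFrame(
                    {"group_network_median_degree": [
                        float(np.mean(deg.get(g, [0.0]))) for g in groups_map
                    ]},
                    index=groups_map.index,
                )
                res2 = association.phenotype_correlation(feat, phenotype, phase)
                assoc_records += [{"phase": phase,
                                   "feature_kind": "network(group-level)",
                                   **r.to_record()} for r in res2]
            adg_comparisons = association.adg_group_comparison(phenotype, frame)
            io_formats.write_results_table(
                [gc.to_record() for gc in adg_comparisons], outdir / "adg_comparisons.tsv"
            )
        io_formats.write_results_table(assoc_records, outdir / "phenotype_associations.tsv")
        summary["associations"] = assoc_records
        summary["adg_comparisons"] = adg_comparisons

    # ------------------------------------------------------------------ truth
    if dataset is not None:
        with stage("truth_eval"):
            rows = []
            for (g, tp), net in summary["networks"].items():
                true = dataset.truth.true_edges.get((g, tp), set())
                found = {frozenset({e.source, e.target}) for e in net.edges.itertuples()}
                tp_hits = len(found & true)
                rows.append({
                    "group": g, "timepoint": tp,
                    "true_edges": len(true), "found_edges": len(found),
                    "precision": tp_hits / len(found) if found else np.nan,
                    "recall": tp_hits / len(true) if true else np.nan,
                })
            io_formats.write_results_table(rows, outdir / "edge_recovery.tsv")
            summary["edge_recovery"] = rows

    # ---------------------------------------------------------------- figures
    if config.make_figures:
        with stage("figures"):
            _make_figures(outdir, summary, frame)

    # ----------------------------------------------------------------- report
    with stage("report"):
        report = _render_report(config, summary, tps, groups)
        (outdir / "report.md").write_text(report, encoding="utf-8")

    manifest.stage_seconds = timers
    manifest.stage_seeds = {
        s: derive_seed(config.seed, s)
        for s in ("simulate", "indval", "topology")
    }
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.suffix in (".tsv", ".sif", ".graphml", ".md"):
            manifest.checksums[str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return PipelineResult(manifest=manifest, outdir=outdir, summary=summary,
                          dataset=dataset)


def _make_figures(outdir: Path, summary: dict, frame: SampleFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    alpha = summary["alpha"]
    meta = frame.data.loc[alpha.index]
    fig, ax = plt.subplots(figsize=(7, 4))
    tps = [t for t in frame.timepoints if t in set(meta["timepoint"])]
    groups = sorted(set(meta["group"]))
    width = 0.8 / max(len(groups), 1)
    for k, g in enumerate(groups):
        data = [alpha.loc[(meta["timepoint"] == t) & (meta["group"] == g), "shannon"]
                for t in tps]
        pos = [i + k * width for i in range(len(tps))]
        ax.boxplot(data, positions=pos, widths=width * 0.9,
                   tick_labels=[""] * len(tps))
    ax.set_xticks([i + 0.4 - width / 2 for i in range(len(tps))])
    ax.set_xticklabels(tps)
    ax.set_ylabel("Shannon (nats)")
    ax.set_title("Alpha diversity by timepoint (groups side by side)")
    fig.tight_layout()
    fig.savefig(figdir / "alpha_shannon.png", dpi=110)
    plt.close(fig)

    ordinations = summary.get("ordinations", {})
    if ordinations:
        tp0, ordn = next(iter(ordinations.items()))
        fig, ax = plt.subplots(figsize=(5, 4.5))
        c = ordn.coordinates
        if c.shape[1] >= 2:
            labels = frame.data.loc[c.index, "group"]
            for g in sorted(set(labels)):
                sel = labels == g
                ax.scatter(c.loc[sel, "PCo1"], c.loc[sel, "PCo2"], label=g, s=18)
            ax.legend()
            ax.set_xlabel("PCo1")
            ax.set_ylabel("PCo2")
            ax.set_title(f"PCoA (Bray–Curtis), {tp0}")
            fig.tight_layout()
            fig.savefig(figdir / f"pcoa_{tp0}.png", dpi=110)
        plt.close(fig)

    node_tables = summary.get("node_tables", {})
    if node_tables:
        fig, ax = plt.subplots(figsize=(7, 4))
        labels, data = [], []
        for (g, tp), tab in sorted(node_tables.items()):
            if len(tab):
                labels.append(f"{g}\n{tp}")
                data.append(tab["degree"].dropna())
        if data:
            ax.boxplot(data, tick_labels=labels)
            ax.set_ylabel("node degree")
            ax.set_title("Co-abundance network degree by stratum")
            fig.tight_layout()
            fig.savefig(figdir / "network_degree.png", dpi=110)
        plt.close(fig)


def _letters_table(comparisons: list[GroupComparison]) -> str:
    lines = []
    for gc in comparisons:
        letters = " ".join(f"{g}:{gc.letters.get(g, '')}" for g in gc.group_summary.index)
        medians = " ".join(
            f"{g}={gc.group_summary.loc[g, 'median']:.3g}" for g in gc.group_summary.index
        )
        lines.append(
            f"| {gc.stratum} | {gc.feature} | H={gc.statistic:.3g} | p={gc.p:.3g} "
            f"| {medians} | {letters} |"
        )
    return "\n".join(lines)


def _render_report(config: PipelineConfig, summary: dict, tps, groups) -> str:
    parts = ["# rumenet run report", ""]
    parts.append(f"profile: **{config.profile}**, seed: {config.seed}, "
                 f"thresholds: rho > {config.rho_min}, q < {config.q_max}, "
                 f"IndVal > {config.indval_min} (strict {config.indicator_strict_min} "
                 f"at {summary.get('indicator_timepoint')})")
    parts.append("")
    parts.append("## Alpha diversity (groups within timepoint)")
    parts.append("| stratum | metric | statistic | p | medians | letters |")
    parts.append("|---|---|---|---|---|---|")
    parts.append(_letters_table(summary.get("alpha_by_group", [])))
    parts.append("")
    parts.append("## Beta diversity tests per timepoint")
    for rec in summary.get("beta_tests", []):
        extra = f", R2={rec['R2']:.3g}" if "R2" in rec else ""
        parts.append(f"- {rec['timepoint']} {rec['test']}: "
                     f"{rec['statistic_name']}={rec['statistic']:.3g}{extra}, "
                     f"p={rec['p']:.3g}")
    parts.append("")
    parts.append("## Indicator taxa")
    sets = summary.get("indicator_sets", {})
    for g, members in sets.items():
        parts.append(f"- {g}: {len(members)} indicator ASVs")
    parts.append("")
    parts.append("## Networks (per group x timepoint)")
    parts.append("| group | timepoint | nodes | edges | samples |")
    parts.append("|---|---|---|---|---|")
    for rec in summary.get("edge_counts", []):
        parts.append(f"| {rec['group']} | {rec['timepoint']} | {rec['n_nodes']} "
                     f"| {rec['n_edges']} | {rec['n_samples']} |")
    parts.append("")
    parts.append("## Network attribute contrasts")
    parts.append("| stratum | attribute | statistic | p | medians | letters |")
    parts.append("|---|---|---|---|---|---|")
    parts.append(_letters_table(summary.get("network_comparisons", [])))
    parts.append("")
    if summary.get("adg_comparisons"):
        parts.append("## Average daily gain by backgrounding system")
        parts.append("| phase | feature | statistic | p | medians | letters |")
        parts.append("|---|---|---|---|---|---|")
        parts.append(_letters_table(summary["adg_comparisons"]))
        parts.append("")
        parts.append("(Nonparametric Kruskal–Wallis/Wilcoxon analogue of the "
                     "repeated-measures least-squares means analysis.)")
    return "\n".join(parts) + "\n"
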