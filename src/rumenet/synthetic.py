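"""Synthetic longitudinal compositional datasets with planted ground truth.

The generator emulates the study design the pipeline targets: three
backgrounding systems (DL, CC, PP) x five sampling timepoints (weaning,
twice during backgrounding, twice at finishing), 12–13 animals per group,
16S-like ASV counts. The generative model is a Gaussian-copula-style
latent log-normal chosen so that planted pairwise correlation is explicit
and recoverable:

1. per stratum (group x timepoint), latent log-abundances are multivariate
   normal with a block-diagonal correlation matrix — ``block_rho`` within
   planted co-abundance blocks, zero elsewhere — and a mean vector
   encoding indicator-taxon enrichment (own group, backgrounding
   timepoints) plus diet-switch suppression that produces the
   alpha-diversity drop;
2. per-sample relative abundances are the softmax of the animal's latent
   vector plus independent Gaussian noise;
3. counts are multinomial at a depth drawn negative-binomially;
4. per-phase average daily gain is ``baseline + adg_coupling x planted
   connectance of the animal's group-stratum + N(0, adg_noise_sd)``.

Connectance (planted within-block pair fraction of all taxon pairs) is
the network trait coupled to ADG, because it is the generative quantity
the simulator controls directly. Block size and correlation accept
per-group values; the defaults plant a DL > CC > PP connectivity gradient
(the qualitative arc the real study reports during backgrounding).
All randomness flows from ``config.seed``: identical configs yield
identical datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import (
    RANKS,
    CountTable,
    PhenotypeTable,
    SampleFrame,
    TaxonomyTable,
)

logger = logging.getLogger("rumenet")

_PHYLA = (
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Butyrivibrio"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Ruminococcus"),
    ("Proteobacteria", "Gammaproteobacteria", "Aeromonadales", "Succinivibrionaceae", "Ruminobacter"),
    ("Verrucomicrobia", "Verruco-5", "RFP12", "RFP12_f", "RFP12_g"),
    ("Tenericutes", "Mollicutes", "RF39", "RF39_f", "RF39_g"),
    ("Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", "Methanosphaera"),
    ("Spirochaetes", "Spirochaetia", "Spirochaetales", "Spirochaetaceae", "Treponema"),
)


def _per_group(value, groups: Sequence[str], what: str) -> list:
    """Broadcast a scalar or per-group sequence over groups."""
    if np.isscalar(value):
        return [value] * len(groups)
    value = list(value)
    if len(value) != len(groups):
        raise ValueError(f"{what} must be scalar or one value per group")
    return value


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of a synthetic study; a pure function input.

    Defaults are the study conditions: groups (DL, CC, PP) with 13/13/12
    animals over five timepoints at the study's sampling days, sequencing
    depth negative-binomial with mean 29,000 reads (dispersion matching
    the reported depth spread; test profiles scale the mean down for
    speed), and a planted DL > CC > PP co-abundance gradient.
    """

    groups: tuple = ("DL", "CC", "PP")
    n_animals_per_group: tuple = (13, 13, 12)
    timepoints: tuple = ("T1", "T2", "T3", "T4", "T5")
    days: tuple = (0, 28, 55, 121, 185)
    n_taxa: int = 150
    # co-abundance blocks: scalar or per-group count/size/correlation
    n_blocks: object = (5, 5, 5)
    block_size: object = (6, 5, 4)
    block_rho: object = (0.99, 0.96, 0.93)
    #: fraction of blocks active per timepoint (weaning sparse, BKG full,
    #: finishing reduced — the connectivity arc)
    block_activity: tuple = (0.2, 1.0, 1.0, 0.6, 0.6)
    # indicator taxa
    n_indicators_per_group: int = 8
    indicator_fold_change: float = 5.0
    indicator_timepoints: tuple = ("T2", "T3")
    # diet-switch suppression (alpha-diversity drops)
    switch_groups: tuple = ("DL", "CC")
    switch_fraction: float = 0.5
    switch_effect: float = -4.0  # added to latent log-mean, T2 onward
    finishing_fraction: float = 0.5
    finishing_effect: float = -4.0  # all groups, T4 onward
    #: diet-switch bloom: a few initially rare taxa surge to a fixed
    #: dominant latent level in each switched group (and in every group at
    #: finishing), crashing evenness the way the Proteobacteria bloom does
    #: in the real study
    bloom_count: int = 3
    bloom_level: float = 5.0
    # abundance model
    latent_sd: float = 1.0
    sample_noise_sd: float = 0.1
    baseline_mean_sd: float = 1.5
    block_taxa_mean: float = 1.5
    block_taxa_mean_sd: float = 0.5
    depth_mean: float = 29_000.0
    depth_dispersion: float = 17.0  # NB size; sd ~ mean/sqrt(size)
    # phenotype model
    adg_coupling: float = 50.0  # kg/day per unit connectance
    adg_noise_sd: float = 0.05
    adg_baseline: tuple = (("backgrounding", 0.9), ("finishing", 1.5))
    seed: int = 0

    def validate(self) -> None:
        sizes = _per_group(self.block_size, self.groups, "block_size")
        rhos = _per_group(self.block_rho, self.groups, "block_rho")
        counts = _per_group(self.n_blocks, self.groups, "n_blocks")
        if len(self.n_animals_per_group) != len(self.groups):
            raise ValueError("n_animals_per_group must match groups")
        if len(self.days) != len(self.timepoints):
            raise ValueError("days must match timepoints")
        if len(self.block_activity) != len(self.timepoints):
            raise ValueError("block_activity must match timepoints")
        for s in sizes:
            if s < 2:
                raise ValueError("block_size must be >= 2")
        for r in rhos:
            if not 0 <= r < 1:
                raise ValueError("block_rho must lie in [0, 1)")
        block_taxa = int(np.sum([c * s for c, s in zip(counts, sizes)]))
        n_ind = self.n_indicators_per_group * len(self.groups)
        if block_taxa + n_ind > self.n_taxa:
            raise ValueError(
                f"{block_taxa} block taxa + {n_ind} indicators exceed n_taxa={self.n_taxa}"
            )
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth — the acceptance surface.

    * ``true_edges`` — per (group, timepoint), the set of taxon pairs
      inside active planted blocks (frozensets of ASV ids);
    * ``true_indicators`` — ASV -> group for planted indicator taxa;
    * ``true_adg`` — per-animal ADG table as generated;
    * ``connectance`` — per stratum, planted within-block pair fraction of
      all taxon pairs (the trait ADG is coupled to);
    * ``latent_means`` — taxon x stratum latent log-abundance means.
    """

    true_edges: dict
    true_indicators: dict
    true_adg: pd.DataFrame
    connectance: dict
    latent_means: pd.DataFrame
    blocks: dict  # group -> list of taxon-id lists


@dataclass
class SyntheticDataset:
    counts: CountTable
    frame: SampleFrame
    taxonomy: TaxonomyTable
    phenotype: PhenotypeTable
    truth: SyntheticTruth
    config: SyntheticConfig


def _make_taxonomy(asv_ids: Sequence[str], rng: np.random.Generator) -> TaxonomyTable:
    rows = []
    for asv in asv_ids:
        ph = _PHYLA[rng.integers(len(_PHYLA))]
        lineage = ["Bacteria" if ph[0] != "Euryarchaeota" else "Archaea", *ph]
        # species mostly unassigned, genus sometimes unassigned
        depth = 6 if rng.random() < 0.7 else (5 if rng.random() < 0.7 else 4)
        lineage = lineage[:depth] + [np.nan] * (7 - depth)
        rows.append(lineage)
    return TaxonomyTable.from_frame(
        pd.DataFrame(rows, index=pd.Index(asv_ids, name="asv_id"), columns=list(RANKS))
    )


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a dataset; deterministic in ``config`` (seed included)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = list(config.groups)
    tps = list(config.timepoints)
    n_taxa = config.n_taxa
    sizes = [int(s) for s in _per_group(config.block_size, groups, "block_size")]
    rhos = [float(r) for r in _per_group(config.block_rho, groups, "block_rho")]
    n_blocks = [int(c) for c in _per_group(config.n_blocks, groups, "n_blocks")]
    asv_ids = [f"ASV{i + 1:04d}" for i in range(n_taxa)]

    # --- taxon roles: block members per group, indicators, background -----
    cursor = 0
    blocks: dict[str, list[list[str]]] = {}
    for gi, g in enumerate(groups):
        blocks[g] = []
        for _ in range(n_blocks[gi]):
            member_idx = list(range(cursor, cursor + sizes[gi]))
            blocks[g].append(member_idx)
            cursor += sizes[gi]
    indicators: dict[str, list[int]] = {}
    for g in groups:
        indicators[g] = list(range(cursor, cursor + config.n_indicators_per_group))
        cursor += config.n_indicators_per_group

    block_members = sorted({i for g in groups for b in blocks[g] for i in b})
    indicator_members = sorted({i for g in groups for i in indicators[g]})

    base_mean = rng.normal(0.0, config.baseline_mean_sd, size=n_taxa)
    base_mean[block_members] = rng.normal(
        config.block_taxa_mean, config.block_taxa_mean_sd, size=len(block_members)
    )
    base_mean[indicator_members] = rng.normal(
        0.0, config.block_taxa_mean_sd, size=len(indicator_members)
    )

    # suppression sets (shared across groups so the drop is comparable);
    # block and indicator taxa are exempt so the planted signals stay
    # orthogonal, and suppression targets established (above-median
    # baseline) community members so the diversity drop is visible against
    # the heavy-tailed abundance distribution
    non_block = [i for i in range(n_taxa)
                 if i not in set(block_members) and i not in set(indicator_members)]
    candidates = [i for i in non_block
                  if base_mean[i] >= np.median(base_mean[non_block])]
    switch_set = rng.choice(
        candidates, size=min(len(candidates),
                             int(round(config.switch_fraction * len(non_block)))),
        replace=False,
    )
    finishing_set = rng.choice(
        candidates, size=min(len(candidates),
                             int(round(config.finishing_fraction * len(non_block)))),
        replace=False,
    )
    # bloom sets drawn from initially rare community members: one per
    # switched group during backgrounding, one shared set at finishing
    # (all animals move to the same high-energy diet)
    rare = [i for i in non_block
            if base_mean[i] < np.median(base_mean[non_block])]
    rare = list(rng.permutation(rare))
    bloom_sets = {}
    for g in groups:
        take = min(config.bloom_count, len(rare))
        bloom_sets[g] = np.array(rare[:take], dtype=int)
        rare = rare[take:]
    take = min(config.bloom_count, len(rare))
    finishing_bloom = np.array(rare[:take], dtype=int)

    # --- per-stratum means, active blocks, truth ---------------------------
    t_index = {t: k for k, t in enumerate(tps)}
    n_pairs_total = n_taxa * (n_taxa - 1) // 2
    means: dict[tuple, np.ndarray] = {}
    active_blocks: dict[tuple, list[list[int]]] = {}
    true_edges: dict[tuple, set] = {}
    connectance: dict[tuple, float] = {}
    for gi, g in enumerate(groups):
        for t in tps:
            mu = base_mean.copy()
            if t in config.indicator_timepoints:
                mu[indicators[g]] += np.log(config.indicator_fold_change)
            in_finishing = t_index[t] >= len(tps) - 2 and len(tps) >= 4
            if g in config.switch_groups and t_index[t] >= 1:
                mu[switch_set] += config.switch_effect
                if not in_finishing:
                    mu[bloom_sets[g]] = config.bloom_level
            if in_finishing:
                mu[finishing_set] += config.finishing_effect
                mu[finishing_bloom] = config.bloom_level
            means[(g, t)] = mu
            n_active = int(round(config.block_activity[t_index[t]] * len(blocks[g])))
            act = blocks[g][:n_active]
            active_blocks[(g, t)] = act
            edges = set()
            for b in act:
                for i in b:
                    for j in b:
                        if i < j:
                            edges.add(frozenset({asv_ids[i], asv_ids[j]}))
            true_edges[(g, t)] = edges
            connectance[(g, t)] = len(edges) / n_pairs_total

    # --- samples ------------------------------------------------------------
    sample_rows, count_rows, sample_ids = [], [], []
    animals: dict[str, str] = {}
    for gi, g in enumerate(groups):
        rho = rhos[gi]
        for ai in range(config.n_animals_per_group[gi]):
            animal = f"{g}{ai + 1:02d}"
            animals[animal] = g
            for t in tps:
                mu = means[(g, t)]
                # equicorrelated blocks via a shared factor:
                # x_i = sqrt(rho) u_block + sqrt(1-rho) e_i has corr rho
                eps = rng.normal(0.0, 1.0, size=n_taxa)
                latent = eps.copy()
                for b in active_blocks[(g, t)]:
                    u = rng.normal()
                    latent[b] = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * eps[b]
                x = mu + config.latent_sd * latent
                x = x + rng.normal(0.0, config.sample_noise_sd, size=n_taxa)
                expx = np.exp(x - x.max())
                p = expx / expx.sum()
                depth = rng.negative_binomial(
                    config.depth_dispersion,
                    config.depth_dispersion / (config.depth_dispersion + config.depth_mean),
                )
                depth = max(int(depth), 500)  # guard against empty samples
                counts = rng.multinomial(depth, p)
                sid = f"{animal}_{t}"
                sample_ids.append(sid)
                count_rows.append(counts)
                sample_rows.append(
                    {"sample_id": sid, "animal_id": animal, "group": g,
                     "timepoint": t, "day": config.days[t_index[t]]}
                )

    counts = CountTable.from_frame(
        pd.DataFrame(np.array(count_rows), index=sample_ids, columns=asv_ids)
    )
    frame = SampleFrame.from_frame(
        pd.DataFrame(sample_rows).set_index("sample_id"),
        groups=groups,
        timepoints=tps,
    )
    taxonomy = _make_taxonomy(asv_ids, rng)

    # --- phenotype ----------------------------------------------------------
    baseline = dict(config.adg_baseline)
    n_tp = len(tps)
    bkg_tps = [t for t in tps if 1 <= t_index[t] <= min(2, n_tp - 1)] or tps[:1]
    fin_tps = [t for t in tps if t_index[t] >= max(n_tp - 2, 1)] or tps[-1:]
    adg_rows = []
    for animal, g in animals.items():
        rec = {"animal_id": animal}
        conn_bkg = float(np.mean([connectance[(g, t)] for t in bkg_tps]))
        conn_fin = float(np.mean([connectance[(g, t)] for t in fin_tps]))
        bkg = baseline.get("backgrounding", 1.0) + config.adg_coupling * conn_bkg \
            + rng.normal(0.0, config.adg_noise_sd)
        fin = baseline.get("finishing", 1.5) + config.adg_coupling * conn_fin \
            + rng.normal(0.0, config.adg_noise_sd)
        rec["backgrounding"] = bkg
        rec["finishing"] = fin
        # overall = day-weighted mean of the two phases
        bkg_days = max(config.days[min(2, n_tp - 1)] - config.days[0], 1)
        fin_days = max(config.days[-1] - config.days[min(2, n_tp - 1)], 1)
        rec["overall"] = (bkg * bkg_days + fin * fin_days) / (bkg_days + fin_days)
        adg_rows.append(rec)
    phenotype = PhenotypeTable.from_frame(pd.DataFrame(adg_rows).set_index("animal_id"))

    latent_means = pd.DataFrame(
        {f"{g}:{t}": means[(g, t)] for g in groups for t in tps},
        index=pd.Index(asv_ids, name="asv_id"),
    )
    truth = SyntheticTruth(
        true_edges=true_edges,
        true_indicators={asv_ids[i]: g for g in groups for i in indicators[g]},
        true_adg=phenotype.data.copy(),
        connectance=connectance,
        latent_means=latent_means,
        blocks={g: [[asv_ids[i] for i in b] for b in blocks[g]] for g in groups},
    )
    return SyntheticDataset(
        counts=counts, frame=frame, taxonomy=taxonomy,
        phenotype=phenotype, truth=truth, config=config,
    )


def fixture_small(seed: int = 42) -> SyntheticDataset:
    """Deterministic tiny dataset for tests: 3 groups x 4 animals x 2
    timepoints x 30 taxa. Regenerates bit-identically for a given seed."""
    cfg = SyntheticConfig(
        groups=("DL", "CC", "PP"),
        n_animals_per_group=(4, 4, 4),
        timepoints=("T2", "T3"),
        days=(28, 55),
        n_taxa=30,
        n_blocks=2,
        block_size=4,
        block_rho=0.95,
        block_activity=(1.0, 1.0),
        n_indicators_per_group=2,
        indicator_fold_change=15.0,
        indicator_timepoints=("T2", "T3"),
        switch_groups=(),
        switch_fraction=0.0,
        finishing_fraction=0.0,
        depth_mean=2000.0,
        seed=seed,
    )
    return generate(cfg)


def recovery_config(
    seed: int = 0,
    block_rho: float = 0.8,
    n_samples: int = 60,
    n_taxa: int = 100,
    block_size: int = 5,
    n_blocks: int = 8,
    depth_mean: float = 29_000.0,
) -> SyntheticConfig:
    """Single-stratum configuration for edge-recovery studies.

    One group, one timepoint, ``n_samples`` animals; planted equicorrelated
    blocks with no indicator or diet-switch effects — the conditions under
    which network edge precision/recall against planted pairs is measured.
    """
    return SyntheticConfig(
        groups=("G1",),
        n_animals_per_group=(n_samples,),
        timepoints=("T1",),
        days=(0,),
        n_taxa=n_taxa,
        n_blocks=n_blocks,
        block_size=block_size,
        block_rho=block_rho,
        block_activity=(1.0,),
        n_indicators_per_group=0,
        indicator_fold_change=1.0,
        indicator_timepoints=(),
        switch_groups=(),
        switch_fraction=0.0,
        finishing_fraction=0.0,
        depth_mean=depth_mean,
        adg_coupling=0.0,
        seed=seed,
    )
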