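"""Linking microbiome features to average daily gain (ADG).

Features are genus-level CLR abundances (ASVs summed per genus, with
unassigned-genus ASVs pooled under the nearest assigned rank) or network
traits aggregated per animal. Associations are compositionally corrected
Spearman correlations (rank-based, hence invariant to monotone feature
transforms) with BH adjustment across features; ADG itself is compared
across backgrounding systems per phase with Kruskal–Wallis + pairwise
Wilcoxon letters, the nonparametric analogue of the study's least-squares
means table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import GroupComparison, bh_adjust, compare_groups
from .tables import CountTable, PhenotypeTable, SampleFrame, TaxonomyTable, RANKS

logger = logging.getLogger("rumenet")


def aggregate_to_genus(t: CountTable, tax: TaxonomyTable) -> CountTable:
    """Sum ASV counts per genus; pool unassigned under the nearest rank.

    An ASV without a genus contributes to ``unclassified_<finest assigned
    label>`` (e.g. ``unclassified_Lachnospiraceae``), or ``unclassified``
    outright when nothing is assigned. Total reads per sample are conserved.
    """
    if not tax.covers(t.asv_ids):
        missing = [a for a in t.asv_ids if a not in tax.data.index]
        raise ValueError(f"taxonomy does not cover the table: {missing[:5]}")
    labels = {}
    genus_idx = RANKS.index("genus")
    for asv in t.asv_ids:
        lineage = tax.lineage(asv)
        if not pd.isna(lineage[genus_idx]):
            labels[asv] = str(lineage[genus_idx])
        else:
            finest = next(
                (str(v) for v in reversed(lineage[:genus_idx]) if not pd.isna(v)),
                None,
            )
            labels[asv] = f"unclassified_{finest}" if finest else "unclassified"
    grouped = t.data.T.groupby(pd.Series(labels)).sum().T
    return CountTable.from_frame(grouped)


@dataclass
class FeaturePhenotypeAssociation:
    feature: str
    rho: float
    p: float
    q_bh: float
    n: int

    def to_record(self) -> dict:
        return {"feature": self.feature, "rho": self.rho, "p": self.p,
                "q": self.q_bh, "n": self.n}


def phenotype_correlation(
    features: pd.DataFrame,
    pheno: PhenotypeTable,
    phase: str,
    min_animals: int = 5,
) -> list[FeaturePhenotypeAssociation]:
    """Spearman correlation of per-animal features against ADG for a phase.

    ``features`` is animals x features (e.g. CLR genus abundances averaged
    over the phase's samples, or a per-animal network trait). Animals
    missing either side are excluded with a log entry; BH across features.
    """
    adg = pheno.adg(phase)
    common = [a for a in features.index if a in adg.index]
    dropped = sorted(set(features.index) - set(common))
    if dropped:
        logger.warning("excluding %d animal(s) without ADG for phase %s",
                       len(dropped), phase)
    if len(common) < min_animals:
        raise ValueError(
            f"need >= {min_animals} animals with both feature and ADG, have {len(common)}"
        )
    x = features.loc[common]
    y = adg.loc[common].to_numpy()
    out = []
    for feat in x.columns:
        v = x[feat].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if ok.sum() < min_animals or np.allclose(v[ok], v[ok][0]) or np.allclose(y[ok], y[ok][0]):
            rho, p = np.nan, np.nan
        else:
            rho, p = sps.spearmanr(v[ok], y[ok])
        out.append((feat, rho, p, int(ok.sum())))
    pvals = [p for (_, _, p, _) in out]
    defined = [i for i, p in enumerate(pvals) if np.isfinite(p)]
    qvals = np.full(len(out), np.nan)
    if defined:
        qvals[defined] = bh_adjust([pvals[i] for i in defined])
    return [
        FeaturePhenotypeAssociation(feature=f, rho=float(r) if np.isfinite(r) else np.nan,
                                    p=float(p) if np.isfinite(p) else np.nan,
                                    q_bh=float(q) if np.isfinite(q) else np.nan, n=n)
        for (f, r, p, n), q in zip(out, qvals)
    ]


def animal_genus_features(
    t: CountTable,
    tax: TaxonomyTable,
    frame: SampleFrame,
    timepoints: list[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-animal CLR genus abundances averaged over the given timepoints."""
    from .network import clr_transform  # local import to avoid a cycle

    genus = aggregate_to_genus(t, tax)
    sids = [s for s in genus.sample_ids
            if frame.data.loc[s, "timepoint"] in timepoints]
    sub = genus.subset_samples(sids)
    clr = clr_transform(sub, pseudocount=pseudocount)
    animals = frame.data.loc[clr.sample_ids, "animal_id"]
    return clr.data.groupby(animals).mean()


def adg_group_comparison(
    pheno: PhenotypeTable, frame: SampleFrame
) -> list[GroupComparison]:
    """Kruskal–Wallis + pairwise Wilcoxon letters on ADG per phase."""
    groups = frame.animal_groups()
    out = []
    for phase in pheno.phases:
        adg = pheno.adg(phase)
        common = [a for a in adg.index if a in groups.index]
        gc = compare_groups(
            adg.loc[common], groups.loc[common], feature=f"ADG_{phase}", stratum=phase
        )
        if gc is not None:
            out.append(gc)
    return out
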