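"""Indicator taxon mining (Dufrêne–Legendre IndVal) and differential abundance.

IndVal for taxon *i* and group *g* multiplies

* specificity ``A_ig`` — mean relative abundance of *i* in *g* divided by
  the sum of its per-group mean abundances (group-mean based, so the
  12-vs-13 animal imbalance does not weight groups), and
* fidelity ``B_ig`` — the fraction of samples in *g* where *i* occurs,

and reports ``max_g A_ig * B_ig`` on the 0–1 scale (labdsv convention,
matching printed thresholds like "> 0.5" or "> 0.7"). Significance comes
from permuting group labels with the max-over-groups statistic; small
designs can be evaluated against the exact relabelling null.

Differential abundance is a per-taxon Kruskal–Wallis on relative
abundances with BH adjustment across taxa; the combined "indicator" call
used at late backgrounding requires both the IndVal and the KW filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust
from .tables import CountTable, SampleFrame, TaxonomyTable

logger = logging.getLogger("rumenet")


@dataclass
class IndicatorResult:
    asv_id: str
    best_group: str
    indval: float
    specificity: float
    fidelity: float
    p_perm: float
    q_bh: float

    def to_record(self) -> dict:
        return {
            "asv_id": self.asv_id,
            "best_group": self.best_group,
            "indval": self.indval,
            "specificity": self.specificity,
            "fidelity": self.fidelity,
            "p": self.p_perm,
            "q": self.q_bh,
        }


def _indval_components(
    relab: np.ndarray, codes: np.ndarray, n_groups: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group specificity A and fidelity B matrices (groups x taxa)."""
    means = np.zeros((n_groups, relab.shape[1]))
    occ = np.zeros((n_groups, relab.shape[1]))
    for g in range(n_groups):
        sub = relab[codes == g]
        means[g] = sub.mean(axis=0)
        occ[g] = (sub > 0).mean(axis=0)
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, means / denom, 0.0)
    return a, occ


def _stat_matrix(relab: np.ndarray, codes2d: np.ndarray, n_groups: int) -> np.ndarray:
    """Max-over-groups IndVal per taxon for a batch of label vectors."""
    out = np.empty((codes2d.shape[0], relab.shape[1]))
    for b in range(codes2d.shape[0]):
        a, occ = _indval_components(relab, codes2d[b], n_groups)
        out[b] = (a * occ).max(axis=0)
    return out


def _exact_label_orders(codes: np.ndarray) -> np.ndarray:
    """All distinct orderings of a label multiset (for exact permutation p)."""
    seen = sorted({p for p in permutations(codes.tolist())})
    return np.array(seen, dtype=int)


def indval(
    t: CountTable,
    labels: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool | None = None,
) -> list[IndicatorResult]:
    """Dufrêne–Legendre indicator values with permutation significance.

    ``exact=True`` enumerates every distinct relabelling (feasible for
    small designs, e.g. all C(8,4) assignments of a 2x4 toy); ``exact=None``
    auto-enables it when the number of distinct relabellings is below 10^5.
    p-values are BH-adjusted across taxa into q-values.
    """
    labels = pd.Series(list(labels), index=t.sample_ids)
    cats = sorted(pd.unique(labels))
    if len(cats) < 2:
        raise ValueError("need at least two groups")
    codes = labels.map({c: i for i, c in enumerate(cats)}).to_numpy()
    relab = t.relative_abundance().to_numpy()
    absent = relab.sum(axis=0) == 0
    if absent.any():
        logger.warning("skipping %d taxa absent from every sample", int(absent.sum()))
    keep = ~absent
    asv_ids = [a for a, k in zip(t.asv_ids, keep) if k]
    relab = relab[:, keep]

    a, occ = _indval_components(relab, codes, len(cats))
    iv = a * occ
    best = iv.argmax(axis=0)
    obs = iv.max(axis=0)

    if exact is None:
        from math import factorial
        from collections import Counter

        sizes = Counter(codes.tolist())
        n_distinct = factorial(len(codes))
        for s in sizes.values():
            n_distinct //= factorial(s)
        exact = n_distinct <= 100_000

    if exact:
        orders = _exact_label_orders(codes)
        null = _stat_matrix(relab, orders, len(cats))
        # identity relabelling is among the enumerated orders
        p = (null >= obs[None, :] - 1e-12).mean(axis=0)
        n_used = orders.shape[0]
    else:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
        null = _stat_matrix(relab, perms, len(cats))
        p = (1.0 + (null >= obs[None, :] - 1e-12).sum(axis=0)) / (1.0 + n_perm)
        n_used = n_perm
    q = bh_adjust(p)
    logger.debug("indval: %d taxa, %d relabellings (%s)", len(asv_ids), n_used,
                 "exact" if exact else "sampled")
    return [
        IndicatorResult(
            asv_id=asv_ids[j],
            best_group=cats[best[j]],
            indval=float(obs[j]),
            specificity=float(a[best[j], j]),
            fidelity=float(occ[best[j], j]),
            p_perm=float(p[j]),
            q_bh=float(q[j]),
        )
        for j in range(len(asv_ids))
    ]


@dataclass
class DifferentialAbundanceResult:
    asv_id: str
    kw_h: float
    p: float
    q_bh: float
    group_means: dict  # group -> mean relative abundance

    def to_record(self) -> dict:
        rec = {"asv_id": self.asv_id, "kw_H": self.kw_h, "p": self.p, "q": self.q_bh}
        rec.update({f"mean_{g}": v for g, v in self.group_means.items()})
        return rec


def differential_abundance(
    t: CountTable, labels: Sequence
) -> list[DifferentialAbundanceResult]:
    """Per-taxon Kruskal–Wallis on relative abundance, BH across taxa."""
    labels = pd.Series(list(labels), index=t.sample_ids)
    cats = sorted(pd.unique(labels))
    if len(cats) < 2:
        raise ValueError("need at least two groups")
    relab = t.relative_abundance()
    groups = {g: relab.loc[labels == g] for g in cats}
    stats, pvals, means = [], [], []
    for asv in t.asv_ids:
        samples = [groups[g][asv].to_numpy() for g in cats]
        pooled = np.concatenate(samples)
        if np.allclose(pooled, pooled[0]):
            h, p = 0.0, 1.0
        else:
            h, p = sps.kruskal(*samples)
        stats.append(h)
        pvals.append(p)
        means.append({g: float(groups[g][asv].mean()) for g in cats})
    qvals = bh_adjust(pvals)
    return [
        DifferentialAbundanceResult(
            asv_id=asv, kw_h=float(h), p=float(p), q_bh=float(q), group_means=m
        )
        for asv, h, p, q, m in zip(t.asv_ids, stats, pvals, qvals, means)
    ]


def select_indicators(
    results: Sequence[IndicatorResult],
    indval_min: float = 0.5,
    q_max: float = 0.05,
    da_results: Sequence[DifferentialAbundanceResult] | None = None,
    da_q_max: float | None = None,
) -> dict:
    """Filter indicator results into per-group indicator sets.

    Keeps taxa with ``indval > indval_min`` and ``q < q_max`` (strict
    inequalities, as printed). When ``da_results`` is given the taxon must
    additionally pass the FDR-adjusted Kruskal–Wallis filter at
    ``da_q_max`` — the combined criterion applied at late backgrounding.
    """
    da_q = {}
    if da_results is not None:
        if da_q_max is None:
            da_q_max = q_max
        da_q = {r.asv_id: r.q_bh for r in da_results}
    sets: dict[str, list[str]] = {}
    for r in results:
        if not (r.indval > indval_min and r.q_bh < q_max):
            continue
        if da_results is not None and not (da_q.get(r.asv_id, 1.0) < da_q_max):
            continue
        sets.setdefault(r.best_group, []).append(r.asv_id)
    return {g: sorted(v) for g, v in sorted(sets.items())}


def cumulative_indicator_abundance(
    t: CountTable,
    frame: SampleFrame,
    indicator_sets: Mapping[str, Sequence[str]],
    taxonomy: TaxonomyTable | None = None,
    rollup_rank: str = "order",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Summed relative abundance of each group's indicator set per sample.

    Returns ``(per_sample, summary, rollup)``:

    * ``per_sample`` — long table: sample, animal, group, timepoint, the
      indicator set's group, and the set's cumulative relative abundance;
    * ``summary`` — mean and sd by (indicator set, timepoint), the
      trajectory whose peak marks the timepoint the set characterises;
    * ``rollup`` — per set, cumulative abundance share by taxonomy at
      ``rollup_rank`` (empty when no taxonomy given).
    """
    relab = t.relative_abundance()
    meta = frame.data.loc[relab.index]
    rows = []
    for set_group, members in indicator_sets.items():
        present = [m for m in members if m in relab.columns]
        missing = set(members) - set(present)
        if missing:
            logger.warning(
                "indicator set %s: %d taxa missing from table, contributing 0",
                set_group, len(missing),
            )
        cum = relab[present].sum(axis=1) if present else pd.Series(0.0, index=relab.index)
        for sid in relab.index:
            rows.append(
                {
                    "sample_id": sid,
                    "animal_id": meta.loc[sid, "animal_id"],
                    "group": meta.loc[sid, "group"],
                    "timepoint": meta.loc[sid, "timepoint"],
                    "indicator_set": set_group,
                    "cumulative_abundance": float(cum.loc[sid]),
                }
            )
    columns = ["sample_id", "animal_id", "group", "timepoint",
               "indicator_set", "cumulative_abundance"]
    per_sample = pd.DataFrame(rows, columns=columns)
    summary = (
        per_sample.groupby(["indicator_set", "timepoint"])["cumulative_abundance"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    rollup: dict[str, pd.Series] = {}
    if taxonomy is not None:
        for set_group, members in indicator_sets.items():
            present = [m for m in members if m in relab.columns]
            if not present:
                rollup[set_group] = pd.Series(dtype=float)
                continue
            lineage = taxonomy.data.reindex(present)[rollup_rank]
            label = lineage.fillna(f"unclassified_{rollup_rank}")
            share = relab[present].mean(axis=0).groupby(label).sum()
            rollup[set_group] = share.sort_values(ascending=False)
    return per_sample, summary, rollup
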