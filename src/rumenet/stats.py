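"""Shared nonparametric testing utilities.

Houses the Benjamini–Hochberg wrapper, the Kruskal–Wallis + pairwise
Wilcoxon rank-sum comparison used throughout (alpha diversity, network
attributes, ADG), the compact letters display, and seed-substream
derivation so that every stochastic stage consumes an independent,
reproducible stream.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("rumenet")


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def derive_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage substream seed (< 2**31).

    Hashing the stage name means inserting a new stage never perturbs the
    randomness consumed by existing stages.
    """
    h = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _maximal_cliques(n: int, adj: np.ndarray) -> list[frozenset]:
    """All maximal cliques of a small undirected graph (Bron–Kerbosch)."""
    cliques: list[frozenset] = []

    def expand(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(frozenset(r))
            return
        for v in list(p):
            nv = {u for u in range(n) if adj[v, u]}
            expand(r | {v}, p & nv, x & nv)
            p.discard(v)
            x.add(v)

    expand(set(), set(range(n)), set())
    return cliques


def letters_display(groups: Sequence[str], significant: Mapping[frozenset, bool]) -> dict:
    """Compact letters display from pairwise significance calls.

    Groups that are *not* significantly different share a letter. Letters
    are the maximal cliques of the "not significantly different" graph, so
    a pair of groups shares at least one letter iff its pairwise test was
    not significant.
    """
    groups = list(groups)
    n = len(groups)
    adj = np.ones((n, n), dtype=bool)
    for i, j in combinations(range(n), 2):
        sig = significant.get(frozenset({groups[i], groups[j]}), False)
        adj[i, j] = adj[j, i] = not sig
    np.fill_diagonal(adj, False)
    cliques = _maximal_cliques(n, adj)
    cliques.sort(key=lambda c: (-len(c), sorted(c)))
    letters = {g: "" for g in groups}
    for k, clique in enumerate(cliques):
        ch = chr(ord("a") + k)
        for idx in sorted(clique):
            letters[groups[idx]] += ch
    return letters


@dataclass
class GroupComparison:
    """Result of a Kruskal–Wallis group contrast with post-hoc letters.

    ``pairwise`` holds one row per group pair with the two-sided Wilcoxon
    rank-sum statistic and BH-adjusted p; ``letters`` encodes the post-hoc
    pattern (groups not sharing a letter differ at ``alpha``).
    """

    stratum: str
    feature: str
    statistic_name: str
    statistic: float
    p: float
    group_summary: pd.DataFrame  # index group: n, median, q1, q3
    pairwise: pd.DataFrame  # group1, group2, statistic, p, q
    letters: dict
    q: float | None = None
    alpha: float = 0.05

    def to_record(self) -> dict:
        rec = {
            "stratum": self.stratum,
            "feature": self.feature,
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p": self.p,
            "q": self.q if self.q is not None else np.nan,
        }
        for g in self.group_summary.index:
            rec[f"median_{g}"] = self.group_summary.loc[g, "median"]
            rec[f"letters_{g}"] = self.letters.get(g, "")
        return rec


def compare_groups(
    values: pd.Series,
    labels: pd.Series,
    feature: str = "",
    stratum: str = "",
    alpha: float = 0.05,
    min_n: int = 2,
) -> GroupComparison | None:
    """Kruskal–Wallis across groups with pairwise Wilcoxon + BH post-hoc.

    Groups with fewer than ``min_n`` observations are dropped; returns
    ``None`` (with a warning) when fewer than two groups remain.
    """
    values = pd.Series(values).astype(float)
    labels = pd.Series(labels).loc[values.index]
    keep = values.notna()
    values, labels = values[keep], labels[keep]
    by_group = {g: values[labels == g].to_numpy() for g in pd.unique(labels)}
    by_group = {g: v for g, v in by_group.items() if len(v) >= min_n}
    if len(by_group) < 2:
        logger.warning(
            "skipping comparison %s/%s: fewer than two groups with >= %d samples",
            stratum, feature, min_n,
        )
        return None
    groups = sorted(by_group)
    samples = [by_group[g] for g in groups]
    pooled = np.concatenate(samples)
    if np.allclose(pooled, pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)
    rows = []
    for g1, g2 in combinations(groups, 2):
        x, y = by_group[g1], by_group[g2]
        if np.allclose(np.concatenate([x, y]), x[0] if len(x) else 0):
            u, pw = len(x) * len(y) / 2.0, 1.0
        else:
            u, pw = sps.mannwhitneyu(x, y, alternative="two-sided")
        rows.append({"group1": g1, "group2": g2, "statistic": u, "p": pw})
    pairwise = pd.DataFrame(rows)
    pairwise["q"] = bh_adjust(pairwise["p"])
    sig = {
        frozenset({r.group1, r.group2}): bool(r.q <= alpha)
        for r in pairwise.itertuples()
    }
    summary = pd.DataFrame(
        {
            "n": [len(by_group[g]) for g in groups],
            "median": [float(np.median(by_group[g])) for g in groups],
            "q1": [float(np.percentile(by_group[g], 25)) for g in groups],
            "q3": [float(np.percentile(by_group[g], 75)) for g in groups],
        },
        index=pd.Index(groups, name="group"),
    )
    return GroupComparison(
        stratum=stratum,
        feature=feature,
        statistic_name="KW-H",
        statistic=float(h),
        p=float(p),
        group_summary=summary,
        pairwise=pairwise,
        letters=letters_display(groups, sig),
        alpha=alpha,
    )
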