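"""Community diversity: alpha indices, Bray–Curtis, PCoA, permutation tests.

All quantities are computed from their definitions:

* alpha diversity per sample — observed richness, Shannon entropy in nats
  (vegan's default base) and the Gini–Simpson index ``1 - sum(p_i^2)``;
* Bray–Curtis dissimilarity ``1 - 2 * sum(min(x, y)) / sum(x + y)``;
* classical metric scaling (PCoA) via the double-centred Gower matrix;
* PERMANOVA (pseudo-F from sums of squared distances) and ANOSIM (rank
  based R) with label-permutation p-values using the +1/+1 convention so a
  p-value can never be zero;
* between-individual dispersion as distance to the group centroid in PCoA
  space (betadisper-style).

Permutations are vectorised over the permutation axis, which keeps null
calibration studies (hundreds of datasets) fast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import GroupComparison, compare_groups
from .tables import CountTable, SampleFrame

logger = logging.getLogger("rumenet")


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(t: CountTable) -> pd.DataFrame:
    """Per-sample observed richness, Shannon (nats) and Gini–Simpson index."""
    counts = t.counts.astype(float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("all-zero sample encountered (should have been dropped at io)")
    p = counts / totals[:, None]
    observed = (counts > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    simpson = 1.0 - (p**2).sum(axis=1)
    return pd.DataFrame(
        {"observed": observed, "shannon": shannon, "simpson": simpson},
        index=pd.Index(t.sample_ids, name="sample_id"),
    )


def compare_alpha(
    alpha: pd.DataFrame,
    frame: SampleFrame,
    stratify_by: str = "timepoint",
    compare_by: str = "group",
    metrics: Sequence[str] = ("observed", "shannon", "simpson"),
) -> list[GroupComparison]:
    """Kruskal–Wallis + pairwise Wilcoxon (BH) per stratum and metric."""
    out: list[GroupComparison] = []
    meta = frame.data.loc[alpha.index]
    for stratum, sub in meta.groupby(stratify_by, sort=True):
        for metric in metrics:
            gc = compare_groups(
                alpha.loc[sub.index, metric],
                sub[compare_by],
                feature=metric,
                stratum=str(stratum),
            )
            if gc is not None:
                out.append(gc)
    return out


# ---------------------------------------------------------------------------
# distances / ordination
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with zero diagonal over named samples."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.data.to_numpy()
        if v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(~np.isfinite(v)):
            raise ValueError("distance matrix contains non-finite entries")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset(self, sample_ids: Sequence[str]) -> "DistanceMatrix":
        ids = list(sample_ids)
        return DistanceMatrix(self.data.loc[ids, ids])

    def condensed(self) -> np.ndarray:
        v = self.values
        iu = np.triu_indices(len(v), k=1)
        return v[iu]


def bray_curtis(t: CountTable, proportions: bool = False) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity on counts (default) or proportions."""
    x = t.counts.astype(float)
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    if proportions:
        x = x / x.sum(axis=1, keepdims=True)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(x[i], x[i + 1:]).sum(axis=1)
        sums = x[i].sum() + x[i + 1:].sum(axis=1)
        with np.errstate(invalid="ignore"):
            dij = 1.0 - 2.0 * mins / sums
        d[i, i + 1:] = dij
        d[i + 1:, i] = dij
    return DistanceMatrix(pd.DataFrame(d, index=t.sample_ids, columns=t.sample_ids))


@dataclass
class OrdinationResult:
    """Ordination coordinates with per-axis eigenvalues.

    Axes are ordered by decreasing eigenvalue; only axes with positive
    eigenvalues are materialised. ``negative_eigenvalues`` records the
    magnitude of any negative spectrum (Bray–Curtis is non-Euclidean, so
    some is expected) for the reader to judge distortion.
    """

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric scaling (principal coordinates analysis)."""
    dm = d.values
    n = dm.shape[0]
    # Gower double-centring of -D^2/2
    a = -0.5 * dm**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    b = a - row - col + a.mean()
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-10
    pos = eigvals > tol
    neg = eigvals[eigvals < -tol]
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        logger.warning(
            "requested %d axes but only %d positive eigenvalues; truncating",
            n_axes, n_pos,
        )
        n_axes = n_pos
    lam = eigvals[:n_axes]
    coords = eigvecs[:, :n_axes] * np.sqrt(lam)
    total_pos = eigvals[pos].sum() if n_pos else 1.0
    prop = lam / total_pos if n_pos else np.zeros(0)
    cols = [f"PCo{i + 1}" for i in range(n_axes)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=d.sample_ids, columns=cols),
        eigenvalues=lam,
        proportion_explained=prop,
        negative_eigenvalues=neg,
    )


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

@dataclass
class PermTestResult:
    statistic_name: str
    statistic: float
    p: float
    n_permutations: int
    seed: int | None = None
    extras: dict | None = None

    def to_record(self) -> dict:
        rec = {
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p": self.p,
            "n_permutations": self.n_permutations,
        }
        if self.extras:
            rec.update(self.extras)
        return rec


def _label_codes(labels: Sequence) -> tuple[np.ndarray, list]:
    labels = pd.Series(list(labels))
    cats = sorted(pd.unique(labels))
    codes = labels.map({c: i for i, c in enumerate(cats)}).to_numpy()
    return codes, cats


def _check_groups(codes: np.ndarray, n_groups: int) -> None:
    if n_groups < 2:
        raise ValueError("need at least two distinct groups")
    sizes = np.bincount(codes, minlength=n_groups)
    if np.any(sizes < 2):
        raise ValueError("every group needs at least two samples")


def _permuted_codes(codes: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    perms = np.tile(codes, (n_perm, 1))
    return rng.permuted(perms, axis=1)


def _ss_within(sq: np.ndarray, codes2d: np.ndarray, n_groups: int) -> np.ndarray:
    """SS_within for a batch of label vectors (rows of codes2d)."""
    out = np.zeros(codes2d.shape[0])
    for g in range(n_groups):
        mask = (codes2d == g).astype(float)
        n_g = mask[0].sum()  # group sizes invariant under permutation
        out += np.einsum("bi,ij,bj->b", mask, sq, mask) / (2.0 * n_g)
    return out


def permanova(
    d: DistanceMatrix,
    labels: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermTestResult:
    """One-factor PERMANOVA from squared distances.

    ``pseudo-F = (SS_between / (g - 1)) / (SS_within / (n - g))`` with
    ``SS_total = sum_{i<j} d_ij^2 / n`` and ``SS_within`` summed per group;
    the p-value counts permuted F at least as large as observed, with the
    observed statistic included (+1/+1).
    """
    codes, cats = _label_codes(labels)
    g = len(cats)
    _check_groups(codes, g)
    n = len(codes)
    sq = d.values.astype(float) ** 2
    ss_total = sq[np.triu_indices(n, k=1)].sum() / n

    def f_stat(codes2d: np.ndarray) -> np.ndarray:
        ss_w = _ss_within(sq, codes2d, g)
        ss_b = ss_total - ss_w
        return (ss_b / (g - 1)) / (ss_w / (n - g))

    f_obs = float(f_stat(codes[None, :])[0])
    ss_w_obs = float(_ss_within(sq, codes[None, :], g)[0])
    r2 = (ss_total - ss_w_obs) / ss_total
    rng = np.random.default_rng(seed)
    f_perm = f_stat(_permuted_codes(codes, n_perm, rng))
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm)
    return PermTestResult(
        statistic_name="pseudo-F",
        statistic=f_obs,
        p=float(p),
        n_permutations=n_perm,
        seed=seed,
        extras={"R2": float(r2), "n": n, "n_groups": g},
    )


def anosim(
    d: DistanceMatrix,
    labels: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermTestResult:
    """ANOSIM (Clarke): R = (r_between - r_within) / (M / 2).

    r_between and r_within are mean ranks (midranks on ties) of the
    between- and within-group pairwise distances, ranked over all
    M = n(n-1)/2 pairs; R lies in [-1, 1] and is 1 when every
    between-group distance exceeds every within-group distance.
    """
    codes, cats = _label_codes(labels)
    g = len(cats)
    _check_groups(codes, g)
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    ranks_flat = sps.rankdata(d.values[iu])
    m = len(ranks_flat)
    rank_mat = np.zeros((n, n))
    rank_mat[iu] = ranks_flat
    rank_mat = rank_mat + rank_mat.T
    total_sum = ranks_flat.sum()
    sizes = np.bincount(codes, minlength=g)
    n_within = int(sum(s * (s - 1) // 2 for s in sizes))
    n_between = m - n_within
    if n_between == 0:
        raise ValueError("labels are constant; no between-group pairs")

    def r_stat(codes2d: np.ndarray) -> np.ndarray:
        s_within = np.zeros(codes2d.shape[0])
        for gi in range(g):
            mask = (codes2d == gi).astype(float)
            s_within += np.einsum("bi,ij,bj->b", mask, rank_mat, mask) / 2.0
        r_w = s_within / n_within
        r_b = (total_sum - s_within) / n_between
        return (r_b - r_w) / (m / 2.0)

    r_obs = float(r_stat(codes[None, :])[0])
    rng = np.random.default_rng(seed)
    r_perm = r_stat(_permuted_codes(codes, n_perm, rng))
    p = (1.0 + np.sum(r_perm >= r_obs)) / (1.0 + n_perm)
    return PermTestResult(
        statistic_name="ANOSIM-R",
        statistic=r_obs,
        p=float(p),
        n_permutations=n_perm,
        seed=seed,
        extras={"n": n, "n_groups": g},
    )


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def dispersion(
    d: DistanceMatrix,
    labels: Sequence,
    stratum: str = "",
) -> tuple[pd.Series, GroupComparison | None]:
    """Per-sample distance to its group centroid in full PCoA space.

    Groups are then compared by Kruskal–Wallis on these distances — the
    betadisper-style test of between-individual heterogeneity.
    """
    labels = pd.Series(list(labels), index=d.sample_ids)
    ord_res = pcoa(d)
    coords = ord_res.coordinates
    if coords.shape[1] == 0:  # all samples identical
        disp = pd.Series(0.0, index=d.sample_ids)
    else:
        disp = pd.Series(0.0, index=d.sample_ids)
        for grp, idx in labels.groupby(labels).groups.items():
            sub = coords.loc[idx]
            centroid = sub.mean(axis=0)
            disp.loc[idx] = np.sqrt(((sub - centroid) ** 2).sum(axis=1))
    gc = compare_groups(disp, labels, feature="dispersion", stratum=stratum)
    return disp, gc
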