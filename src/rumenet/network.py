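"""Co-abundance network inference and graph-centrality traits.

Pipeline per stratum (one backgrounding group at one timepoint):

1. prevalence filter (taxa present in >= 30% of the stratum's samples by
   default — correlations over 12–13 animals are unstable for rarer taxa);
2. centered log-ratio (CLR) transform with pseudocount, the compositional
   correction applied before correlating;
3. tie-corrected Spearman correlation for every taxon pair (Pearson on
   midranks), two-sided p by the t approximation with n-2 df (exact
   permutation enumeration for very small n), BH over the upper triangle;
4. an undirected simple graph keeping pairs with rho > 0.7 and q < 0.05
   (strict inequalities, positive-sign policy by default).

Node and edge attributes are computed from their definitions with
breadth-first-search distances: degree, neighbor connectivity (mean degree
of neighbors), per-node average shortest path length over reachable nodes,
closeness in the Cytoscape reachable-pair convention, local clustering
coefficient, eccentricity, radiality (normalised by the node's component
diameter), and Brandes edge betweenness with fractional credit among
equal-length shortest paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diversity import DistanceMatrix, OrdinationResult, PermTestResult, pcoa, permanova
from .stats import GroupComparison, bh_adjust, compare_groups
from .tables import CountTable

logger = logging.getLogger("rumenet")

NODE_ATTRIBUTES = (
    "degree",
    "neighbor_connectivity",
    "avg_shortest_path_length",
    "closeness",
    "clustering",
    "eccentricity",
    "radiality",
)


# ---------------------------------------------------------------------------
# filtering and compositional correction
# ---------------------------------------------------------------------------

def prevalence_filter(t: CountTable, min_prevalence: float = 0.3) -> CountTable:
    """Keep taxa present (count > 0) in at least ``min_prevalence`` of samples."""
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must lie in [0, 1]")
    prev = (t.counts > 0).mean(axis=0)
    keep = prev >= min_prevalence
    if keep.sum() < 3:
        raise ValueError(
            f"prevalence filter at {min_prevalence} leaves {int(keep.sum())} taxa; "
            "lower the threshold"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("prevalence filter removed %d/%d taxa", dropped, len(keep))
    return CountTable.from_frame(t.data.loc[:, keep])


@dataclass
class ClrMatrix:
    """Centered log-ratio transformed abundances; rows sum to zero."""

    data: pd.DataFrame  # samples x taxa
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        rowsums = self.data.to_numpy().sum(axis=1)
        if not np.allclose(rowsums, 0, atol=1e-9):
            raise ValueError("CLR rows must sum to zero")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)


def clr_transform(t: CountTable, pseudocount: float = 1.0) -> ClrMatrix:
    """CLR: ln p_i - mean_j ln p_j after adding ``pseudocount`` to counts.

    ``pseudocount=0`` is the pure-proportion mode (requires strictly
    positive counts) under which the transform is invariant to per-sample
    total-count rescaling.
    """
    x = t.counts.astype(float) + pseudocount
    if np.any(x <= 0):
        raise ValueError("zero counts present; a positive pseudocount is required")
    logp = np.log(x / x.sum(axis=1, keepdims=True))
    clr = logp - logp.mean(axis=1, keepdims=True)
    return ClrMatrix(
        pd.DataFrame(clr, index=t.sample_ids, columns=t.asv_ids),
        pseudocount=pseudocount,
    )


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rho with per-pair p and BH q over the upper triangle."""

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n_samples: int
    method: str

    @property
    def asv_ids(self) -> list[str]:
        return list(self.rho.index)


_exact_null_cache: dict = {}


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman rho (small n).

    The permutation distribution depends only on the two rank multisets, so
    nulls are cached by that key (one shared distribution when there are no
    ties).
    """
    key = (tuple(np.sort(rx)), tuple(np.sort(ry)))
    if key not in _exact_null_cache:
        sx = (rx - rx.mean()) / rx.std()
        null = []
        for perm in permutations(range(len(ry))):
            yv = ry[list(perm)]
            sy = (yv - yv.mean()) / yv.std()
            null.append(float(np.mean(sx * sy)))
        _exact_null_cache[key] = np.array(null)
    null = _exact_null_cache[key]
    return float(np.mean(np.abs(null) >= abs(rho_obs) - 1e-12))


def spearman_matrix(m: ClrMatrix, p_method: str = "auto") -> CorrelationMatrix:
    """All-pairs tie-corrected Spearman rho with p and BH-adjusted q.

    rho is Pearson on per-taxon midranks. ``p_method``: ``"t"`` uses the
    two-sided t approximation with n-2 df; ``"exact"`` enumerates rank
    permutations (n <= 10); ``"auto"`` picks exact for n <= 8. Taxa that
    are constant after CLR have undefined rho; their pairs are flagged
    (NaN) and excluded from the BH adjustment.
    """
    values = m.data.to_numpy()
    n, k = values.shape
    if n < 4:
        raise ValueError("need at least four samples to correlate")
    if p_method == "auto":
        p_method = "exact" if n <= 8 else "t"
    if p_method == "exact" and n > 10:
        raise ValueError("exact permutation p is only supported for n <= 10")

    ranks = np.apply_along_axis(sps.rankdata, 0, values)
    sd = ranks.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d taxa constant after CLR; their correlations are undefined",
            int(constant.sum()),
        )
    z = np.where(constant[None, :], 0.0, (ranks - ranks.mean(axis=0)) / np.where(sd == 0, 1, sd))
    rho = (z.T @ z) / n
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan

    p = np.full_like(rho, np.nan)
    iu = np.triu_indices(k, k=1)
    if p_method == "t":
        r = rho[iu]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
        pv = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
        pv = np.where(np.abs(r) >= 1.0, 0.0, pv)
        p[iu] = pv
    else:
        for i, j in zip(*iu):
            if constant[i] or constant[j]:
                continue
            p[i, j] = _exact_spearman_p(ranks[:, i], ranks[:, j], rho[i, j])
    p[(iu[1], iu[0])] = p[iu]
    np.fill_diagonal(p, 0.0)

    q = np.full_like(p, np.nan)
    flat_p = p[iu]
    defined = ~np.isnan(flat_p)
    qv = np.full_like(flat_p, np.nan)
    qv[defined] = bh_adjust(flat_p[defined])
    q[iu] = qv
    q[(iu[1], iu[0])] = qv
    np.fill_diagonal(q, 0.0)

    ids = m.asv_ids
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=ids, columns=ids),
        p=pd.DataFrame(p, index=ids, columns=ids),
        q=pd.DataFrame(q, index=ids, columns=ids),
        n_samples=n,
        method=p_method,
    )


# ---------------------------------------------------------------------------
# network object
# ---------------------------------------------------------------------------

@dataclass
class CoabundanceNetwork:
    """Thresholded correlation graph with edge provenance.

    ``edges`` has columns source, target, rho, p, q; nodes are the taxa
    incident to at least one retained edge plus any ``declared_nodes``
    passed at construction (kept isolated).
    """

    edges: pd.DataFrame
    rho_min: float
    q_max: float
    sign: str
    stratum: tuple | None = None
    declared_nodes: tuple = ()

    @property
    def node_ids(self) -> list[str]:
        incident = sorted(set(self.edges["source"]) | set(self.edges["target"]))
        extra = [n for n in self.declared_nodes if n not in incident]
        return incident + sorted(extra)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict:
        adj: dict[str, set] = {n: set() for n in self.node_ids}
        for e in self.edges.itertuples():
            adj[e.source].add(e.target)
            adj[e.target].add(e.source)
        return adj


def build_network(
    c: CorrelationMatrix,
    rho_min: float = 0.7,
    q_max: float = 0.05,
    sign: str = "positive",
    stratum: tuple | None = None,
    declared_nodes: Sequence[str] = (),
) -> CoabundanceNetwork:
    """Threshold a correlation matrix into a co-abundance network.

    Keeps pairs with ``rho > rho_min`` (or ``|rho| > rho_min`` under the
    absolute sign policy) and ``q < q_max`` — strict inequalities, exactly
    as the thresholds are printed. An empty graph is legitimate (the
    weaning-stage network is nearly edgeless).
    """
    if sign not in ("positive", "absolute"):
        raise ValueError("sign must be 'positive' or 'absolute'")
    ids = c.asv_ids
    rho, p, q = c.rho.to_numpy(), c.p.to_numpy(), c.q.to_numpy()
    rows = []
    for i, j in combinations(range(len(ids)), 2):
        r = rho[i, j]
        if np.isnan(r):
            continue
        mag = abs(r) if sign == "absolute" else r
        if mag > rho_min and q[i, j] < q_max:
            rows.append(
                {"source": ids[i], "target": ids[j],
                 "rho": float(r), "p": float(p[i, j]), "q": float(q[i, j])}
            )
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "p", "q"])
    return CoabundanceNetwork(
        edges=edges, rho_min=rho_min, q_max=q_max, sign=sign,
        stratum=stratum, declared_nodes=tuple(declared_nodes),
    )


# ---------------------------------------------------------------------------
# node / edge attributes
# ---------------------------------------------------------------------------

def _bfs_distances(adj: Mapping[str, set], source: str) -> dict:
    dist = {source: 0}
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def _components(adj: Mapping[str, set]) -> dict:
    comp: dict[str, int] = {}
    cid = 0
    for node in adj:
        if node in comp:
            continue
        for v in _bfs_distances(adj, node):
            comp[v] = cid
        cid += 1
    return comp


def node_attributes(net: CoabundanceNetwork) -> pd.DataFrame:
    """Per-node centrality table (see module docstring for definitions).

    Isolated nodes get NaN for every path-based attribute and are flagged
    by ``path_defined = False``; neighbor connectivity is NaN for them too.
    """
    adj = net.adjacency()
    nodes = net.node_ids
    comp = _components(adj)
    degree = {v: len(adj[v]) for v in nodes}

    dist_all = {v: _bfs_distances(adj, v) for v in nodes}
    ecc = {
        v: max((d for u, d in dist_all[v].items() if u != v), default=np.nan)
        for v in nodes
    }
    # component diameter = max eccentricity over its members (NaN-safe)
    comp_diam: dict[int, float] = {}
    comp_size: dict[int, int] = {}
    for v in nodes:
        c = comp[v]
        comp_size[c] = comp_size.get(c, 0) + 1
        e = ecc[v]
        if not np.isnan(e):
            comp_diam[c] = max(comp_diam.get(c, 0), e)

    rows = []
    for v in nodes:
        deg = degree[v]
        nc = float(np.mean([degree[u] for u in adj[v]])) if deg else np.nan
        reach = {u: d for u, d in dist_all[v].items() if u != v}
        if reach:
            dists = np.array(list(reach.values()), dtype=float)
            aspl = float(dists.mean())
            closeness = len(reach) / dists.sum()
            eccentricity = float(dists.max())
            diam = comp_diam[comp[v]]
            n_c = comp_size[comp[v]]
            radiality = float(np.sum(diam + 1.0 - dists) / (n_c - 1))
            path_defined = True
        else:
            aspl = closeness = eccentricity = radiality = np.nan
            path_defined = False
        if deg >= 2:
            nbrs = list(adj[v])
            tri = sum(
                1 for a, b in combinations(nbrs, 2) if b in adj[a]
            )
            clustering = 2.0 * tri / (deg * (deg - 1))
        else:
            clustering = 0.0
        rows.append(
            {
                "node": v,
                "degree": deg,
                "neighbor_connectivity": nc,
                "avg_shortest_path_length": aspl,
                "closeness": closeness,
                "clustering": clustering,
                "eccentricity": eccentricity,
                "radiality": radiality,
                "component_id": comp[v],
                "path_defined": path_defined,
            }
        )
    columns = ["node", "degree", "neighbor_connectivity", "avg_shortest_path_length",
               "closeness", "clustering", "eccentricity", "radiality",
               "component_id", "path_defined"]
    return pd.DataFrame(rows, columns=columns).set_index("node")


def edge_attributes(net: CoabundanceNetwork) -> pd.DataFrame:
    """Edge betweenness (Brandes accumulation over unordered pairs) + strength.

    Betweenness of edge e sums sigma_st(e)/sigma_st over unordered node
    pairs {s, t}, where sigma_st counts shortest s–t paths and sigma_st(e)
    those traversing e. Endpoints count, so in A–B–C both edges carry 2.
    """
    adj = net.adjacency()
    nodes = net.node_ids
    eb: dict[frozenset, float] = {
        frozenset({e.source, e.target}): 0.0 for e in net.edges.itertuples()
    }
    for s in nodes:
        # single-source shortest paths (BFS), Brandes sigma counts
        dist = {s: 0}
        sigma = {s: 1.0}
        preds: dict[str, list] = {s: []}
        order = [s]
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        sigma[v] = 0.0
                        preds[v] = []
                        nxt.append(v)
                        order.append(v)
                    if dist[v] == dist[u] + 1:
                        sigma[v] += sigma[u]
                        preds[v].append(u)
            frontier = nxt
        delta = {v: 0.0 for v in dist}
        for w in reversed(order):
            for u in preds[w]:
                credit = sigma[u] / sigma[w] * (1.0 + delta[w])
                eb[frozenset({u, w})] += credit
                delta[u] += credit
    rows = []
    for e in net.edges.itertuples():
        rows.append(
            {
                "source": e.source,
                "target": e.target,
                # each unordered pair was accumulated from both endpoints
                "betweenness": eb[frozenset({e.source, e.target})] / 2.0,
                "strength": e.rho,
            }
        )
    return pd.DataFrame(rows, columns=["source", "target", "betweenness", "strength"])


# ---------------------------------------------------------------------------
# cross-stratum comparison and topology ordination
# ---------------------------------------------------------------------------

def compare_network_attributes(
    tables: Mapping[tuple, pd.DataFrame],
    attributes: Sequence[str] = NODE_ATTRIBUTES,
    min_nodes: int = 3,
) -> list[GroupComparison]:
    """Compare node-attribute distributions across groups per timepoint.

    ``tables`` maps (group, timepoint) -> node attribute table. For each
    attribute and timepoint a Kruskal–Wallis test across groups is run with
    pairwise Wilcoxon + BH letters; strata with fewer than ``min_nodes``
    attributed nodes are skipped with a log entry.
    """
    timepoints = sorted({tp for (_, tp) in tables})
    out: list[GroupComparison] = []
    for tp in timepoints:
        strata = {g: df for (g, t), df in tables.items() if t == tp}
        for attr in attributes:
            values, labels = [], []
            for g, df in sorted(strata.items()):
                if attr not in df.columns:
                    continue
                v = df[attr].dropna()
                if len(v) < min_nodes:
                    logger.warning(
                        "skipping %s at %s for group %s: only %d attributed nodes",
                        attr, tp, g, len(v),
                    )
                    continue
                values.append(v)
                labels.append(pd.Series(g, index=v.index))
            if len(values) < 2:
                continue
            vals = pd.concat(values, ignore_index=True)
            labs = pd.concat(labels, ignore_index=True)
            gc = compare_groups(vals, labs, feature=attr, stratum=str(tp), min_n=min_nodes)
            if gc is not None:
                out.append(gc)
    return out


def topology_ordination(
    tables: Mapping[tuple, pd.DataFrame],
    attributes: Sequence[str] = NODE_ATTRIBUTES,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[OrdinationResult, PermTestResult, pd.DataFrame]:
    """Ordinate pooled node-attribute vectors and test stratum separation.

    Node vectors are z-scored per attribute over the pooled nodes (missing
    values imputed by the pooled median, flagged in the returned frame),
    projected by PCoA on Euclidean distances — equivalent to principal
    components — and stratum labels tested by PERMANOVA on those distances.
    """
    frames = []
    for (g, tp), df in sorted(tables.items()):
        sub = df.reindex(columns=list(attributes)).copy()
        sub["stratum"] = f"{g}:{tp}"
        sub = sub.reset_index(names="node")
        frames.append(sub)
    pooled = pd.concat(frames, ignore_index=True)
    x = pooled[list(attributes)].astype(float)
    imputed = x.isna()
    if imputed.any().any():
        logger.warning("imputing %d missing attribute values by pooled median",
                       int(imputed.to_numpy().sum()))
        x = x.fillna(x.median())
    mu, sd = x.mean(), x.std(ddof=0).replace(0, 1.0)
    z = (x - mu) / sd
    pooled["imputed"] = imputed.any(axis=1)
    ids = [f"{r.stratum}|{r.node}" for r in pooled.itertuples()]
    zz = z.to_numpy()
    sq = ((zz[:, None, :] - zz[None, :, :]) ** 2).sum(axis=2)
    dmat = DistanceMatrix(pd.DataFrame(np.sqrt(sq), index=ids, columns=ids))
    ordination = pcoa(dmat)
    ptest = permanova(dmat, pooled["stratum"], n_perm=n_perm, seed=seed)
    return ordination, ptest, pooled
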