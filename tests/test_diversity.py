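"""Alpha/beta diversity, ordination and permutation tests against closed
forms, hand computations and scikit-bio as an independent implementation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

import skbio
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova

from rumenet import diversity as dv
from rumenet.tables import CountTable


def _ct(rows, index=None, cols=None):
    rows = np.atleast_2d(rows)
    index = index or [f"s{i}" for i in range(rows.shape[0])]
    cols = cols or [f"t{i}" for i in range(rows.shape[1])]
    return CountTable.from_frame(pd.DataFrame(rows, index=index, columns=cols))


class TestAlpha:
    def test_uniform_closed_form(self):
        a = dv.alpha_diversity(_ct([[10, 10, 10, 10]]))
        assert a.loc["s0", "observed"] == 4
        assert a.loc["s0", "shannon"] == pytest.approx(np.log(4))
        assert a.loc["s0", "simpson"] == pytest.approx(0.75)

    def test_single_taxon(self):
        a = dv.alpha_diversity(_ct([[100, 0, 0]]))
        assert a.loc["s0", "observed"] == 1
        assert a.loc["s0", "shannon"] == 0
        assert a.loc["s0", "simpson"] == 0

    def test_hand_evaluated_shannon(self):
        a = dv.alpha_diversity(_ct([[5, 3, 2]]))
        expected = -(0.5 * np.log(0.5) + 0.3 * np.log(0.3) + 0.2 * np.log(0.2))
        assert a.loc["s0", "shannon"] == pytest.approx(expected)

    @given(
        counts=st.lists(st.integers(1, 200), min_size=2, max_size=12),
        n_zeros=st.integers(0, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariances(self, counts, n_zeros):
        """Shannon bounded by ln(observed); metrics unchanged by zero taxa
        and by taxon order."""
        base = dv.alpha_diversity(_ct([counts])).iloc[0]
        padded = dv.alpha_diversity(_ct([counts + [0] * n_zeros])).iloc[0]
        shuffled = dv.alpha_diversity(_ct([counts[::-1]])).iloc[0]
        for metric in ("observed", "shannon", "simpson"):
            assert padded[metric] == pytest.approx(base[metric])
            assert shuffled[metric] == pytest.approx(base[metric])
        assert 0 <= base["shannon"] <= np.log(base["observed"]) + 1e-12
        assert 0 <= base["simpson"] <= 1


class TestCompareAlpha:
    def test_identical_groups_h_zero(self, toy_frame):
        alpha = pd.DataFrame(
            {"observed": [5, 7, 5, 7], "shannon": [1, 2, 1, 2], "simpson": [0.5] * 4},
            index=["s1", "s2", "s3", "s4"],
        )
        comps = dv.compare_alpha(alpha, toy_frame, "timepoint", "group",
                                 metrics=("shannon",))
        assert len(comps) == 1
        assert comps[0].statistic == 0 and comps[0].p == 1.0
        # identical multisets share a letter
        assert comps[0].letters["CC"] == comps[0].letters["DL"]

    def test_exact_minimal_p_for_3v3(self):
        """Wilcoxon on fully separated 3v3 attains the enumeration minimum
        2/C(6,3) = 0.1 (two-sided)."""
        from rumenet.stats import compare_groups

        vals = pd.Series([1, 2, 3, 10, 11, 12], index=list("abcdef"))
        labs = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        gc = compare_groups(vals, labs)
        assert gc.pairwise.loc[0, "p"] == pytest.approx(0.1)

    def test_null_rejection_rate_calibrated(self):
        """KW at alpha=0.05 rejects ~5% under an exchangeable null."""
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 400
        from scipy.stats import kruskal

        for _ in range(n_rep):
            x = rng.normal(size=(3, 8))
            rejections += kruskal(*x)[1] <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.08


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = _ct([[4, 2, 0, 0], [4, 2, 0, 0], [0, 0, 3, 9]])
        d = dv.bray_curtis(t)
        assert d.values[0, 1] == pytest.approx(0.0)
        assert d.values[0, 2] == pytest.approx(1.0)

    def test_hand_value(self):
        d = dv.bray_curtis(_ct([[6, 0, 2], [0, 4, 2]]))
        assert d.values[0, 1] == pytest.approx(5 / 7)

    @given(
        x=st.lists(st.integers(0, 30), min_size=4, max_size=4),
        y=st.lists(st.integers(0, 30), min_size=4, max_size=4),
    )
    @settings(max_examples=60, deadline=None)
    def test_range_and_symmetry(self, x, y):
        if sum(x) == 0 or sum(y) == 0:
            return
        d = dv.bray_curtis(_ct([x, y]))
        assert -1e-12 <= d.values[0, 1] <= 1 + 1e-12
        assert d.values[0, 1] == pytest.approx(d.values[1, 0])

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 40, size=(6, 10)) + (rng.random((6, 10)) < 0.1)
        counts[:, 0] += 1
        t = _ct(counts)
        ours = dv.bray_curtis(t).values
        ref = squareform(pdist(counts.astype(float), metric="braycurtis"))
        np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestPcoa:
    def test_euclidean_line_recovered(self):
        pts = np.array([[0.0], [1.0], [3.0], [6.0]])
        d = dv.DistanceMatrix(pd.DataFrame(
            squareform(pdist(pts)), index=list("abcd"), columns=list("abcd")))
        res = dv.pcoa(d)
        axis1 = res.coordinates.iloc[:, 0].to_numpy()
        gaps = np.diff(np.sort(axis1))
        np.testing.assert_allclose(sorted(gaps), [1, 2, 3], atol=1e-9)

    def test_distances_reconstructed_for_euclidean_input(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(7, 3))
        dm = squareform(pdist(pts))
        d = dv.DistanceMatrix(pd.DataFrame(dm, index=range(7), columns=range(7)))
        res = dv.pcoa(d)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(rec, dm, atol=1e-8)

    def test_identical_samples_all_zero(self):
        d = dv.DistanceMatrix(pd.DataFrame(np.zeros((3, 3)), index=list("abc"),
                                           columns=list("abc")))
        res = dv.pcoa(d)
        assert res.coordinates.shape[1] == 0

    def test_matches_skbio(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 60, size=(8, 12))
        t = _ct(counts)
        d = dv.bray_curtis(t)
        ours = dv.pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, ids=d.sample_ids))
        k = min(3, ours.coordinates.shape[1])
        for ax in range(k):
            a = ours.coordinates.iloc[:, ax].to_numpy()
            b = ref.samples.iloc[:, ax].to_numpy()
            assert np.allclose(a, b, atol=1e-6) or np.allclose(a, -b, atol=1e-6)


def _two_clouds(seed=0, n=8, sep=10.0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(sep, 1, (n, 2))])
    ids = [f"s{i}" for i in range(2 * n)]
    d = dv.DistanceMatrix(pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids))
    labels = ["a"] * n + ["b"] * n
    return d, labels


class TestPermanova:
    def test_separation_limit(self):
        d, labels = _two_clouds(sep=50.0)
        res = dv.permanova(d, labels, n_perm=199, seed=1)
        assert res.extras["R2"] > 0.95
        assert res.p == pytest.approx(1 / 200)

    def test_f_statistic_matches_direct_two_group_computation(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 2))
        dm = squareform(pdist(pts))
        ids = list("abcdef")
        labels = ["x", "x", "x", "y", "y", "y"]
        d = dv.DistanceMatrix(pd.DataFrame(dm, index=ids, columns=ids))
        res = dv.permanova(d, labels, n_perm=9, seed=0)
        sq = dm**2
        n = 6
        ss_total = sq[np.triu_indices(n, 1)].sum() / n
        ss_w = (sq[np.ix_([0, 1, 2], [0, 1, 2])][np.triu_indices(3, 1)].sum() / 3
                + sq[np.ix_([3, 4, 5], [3, 4, 5])][np.triu_indices(3, 1)].sum() / 3)
        f_direct = ((ss_total - ss_w) / 1) / (ss_w / 4)
        assert res.statistic == pytest.approx(f_direct, rel=1e-12)

    def test_statistic_matches_skbio(self):
        d, labels = _two_clouds(seed=3, sep=2.0)
        ours = dv.permanova(d, labels, n_perm=99, seed=0)
        ref = skbio_permanova(skbio.DistanceMatrix(d.values, ids=d.sample_ids),
                              grouping=list(labels), permutations=99)
        assert ours.statistic == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_constant_labels_error(self):
        d, _ = _two_clouds()
        with pytest.raises(ValueError):
            dv.permanova(d, ["a"] * 16, n_perm=9)


class TestAnosim:
    def test_perfect_separation_r_one(self):
        d, labels = _two_clouds(sep=100.0)
        res = dv.anosim(d, labels, n_perm=199, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_hand_ranked_four_samples(self):
        """2+2 design with hand-ranked distances.

        Distances (condensed, pairs in order ab, ac, ad, bc, bd, cd):
        within = {ab: 1, cd: 2}, between = {ac: 3, ad: 4, bc: 5, bd: 6}.
        ranks are the values themselves; r_W = 1.5, r_B = 4.5, M = 6,
        R = (4.5 - 1.5) / 3 = 1.
        """
        dm = np.array(
            [
                [0, 1, 3, 4],
                [1, 0, 5, 6],
                [3, 5, 0, 2],
                [4, 6, 2, 0],
            ],
            dtype=float,
        )
        d = dv.DistanceMatrix(pd.DataFrame(dm, index=list("abcd"), columns=list("abcd")))
        res = dv.anosim(d, ["g1", "g1", "g2", "g2"], n_perm=9, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_statistic_matches_skbio(self):
        d, labels = _two_clouds(seed=9, sep=1.0)
        ours = dv.anosim(d, labels, n_perm=99, seed=0)
        ref = skbio_anosim(skbio.DistanceMatrix(d.values, ids=d.sample_ids),
                           grouping=list(labels), permutations=99)
        assert ours.statistic == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_null_expectation_near_zero(self):
        rng = np.random.default_rng(8)
        rs = []
        for k in range(100):
            pts = rng.normal(size=(12, 2))
            ids = [f"s{i}" for i in range(12)]
            d = dv.DistanceMatrix(
                pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids))
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            rs.append(dv.anosim(d, labels, n_perm=9, seed=k).statistic)
        assert abs(float(np.mean(rs))) < 0.05


class TestDispersion:
    def test_identical_samples_zero_dispersion(self):
        dm = np.zeros((4, 4))
        d = dv.DistanceMatrix(pd.DataFrame(dm, index=list("abcd"), columns=list("abcd")))
        disp, _ = dv.dispersion(d, ["g", "g", "h", "h"])
        assert np.allclose(disp, 0)

    def test_doubling_distances_doubles_dispersion(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 2))
        dm = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(8)]
        labels = ["a"] * 4 + ["b"] * 4
        d1 = dv.DistanceMatrix(pd.DataFrame(dm, index=ids, columns=ids))
        d2 = dv.DistanceMatrix(pd.DataFrame(2 * dm, index=ids, columns=ids))
        disp1, _ = dv.dispersion(d1, labels)
        disp2, _ = dv.dispersion(d2, labels)
        np.testing.assert_allclose(disp2, 2 * disp1, atol=1e-9)

    def test_detects_spread_difference(self):
        rng = np.random.default_rng(6)
        tight = rng.normal(0, 0.1, (15, 2))
        spread = rng.normal(0, 1.0, (15, 2))
        pts = np.vstack([tight, spread])
        ids = [f"s{i}" for i in range(30)]
        d = dv.DistanceMatrix(pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids))
        _, gc = dv.dispersion(d, ["tight"] * 15 + ["spread"] * 15)
        assert gc.p < 0.05
        assert (gc.group_summary.loc["spread", "median"]
                > gc.group_summary.loc["tight", "median"])
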