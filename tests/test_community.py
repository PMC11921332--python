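import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from fmtrack import (
    DistanceMatrix,
    FeatureTable,
    alpha_diversity,
    bray_curtis,
    dunn_posthoc,
    kruskal_wallis,
    pcoa,
    permanova,
    permdisp,
    rarefy,
)
from fmtrack.community import read_distance_matrix, write_distance_matrix


def make_table(counts):
    counts = np.asarray(counts)
    return FeatureTable(
        tuple(f"f{i}" for i in range(counts.shape[0])),
        tuple(f"s{j}" for j in range(counts.shape[1])),
        counts,
    )


def euclid_dm(points):
    points = np.asarray(points, dtype=float)
    return DistanceMatrix(
        tuple(f"s{i}" for i in range(len(points))), squareform(pdist(points))
    )


class TestRarefy:
    def test_exhaustive_depth_is_identity(self):
        t = make_table([[3, 5], [7, 5]])
        r = rarefy(t, 10, seed=0)
        assert np.array_equal(r.counts, t.counts)

    def test_depth_one_leaves_single_read(self):
        t = make_table([[3, 5], [7, 5]])
        r = rarefy(t, 1, seed=0)
        assert (r.counts.sum(axis=0) == 1).all()
        assert ((r.counts == 0) | (r.counts == 1)).all()

    def test_shallow_samples_dropped_with_warning(self):
        t = make_table([[3, 50], [7, 50]])
        with pytest.warns(UserWarning, match="below rarefaction depth"):
            r = rarefy(t, 20, seed=0)
        assert r.sample_ids == ("s1",)

    def test_invalid_depth(self):
        with pytest.raises(ValueError, match="depth"):
            rarefy(make_table([[5]]), 0, seed=0)

    def test_deterministic_and_hypergeometric_moments(self):
        t = make_table([[50], [30], [20]])
        r1 = rarefy(t, 50, seed=42)
        r2 = rarefy(t, 50, seed=42)
        assert np.array_equal(r1.counts, r2.counts)
        # mean over replicates matches depth * proportion within 3 SE
        reps = np.array(
            [rarefy(t, 50, seed=s).counts[:, 0] for s in range(1000)], dtype=float
        )
        n_pop, depth = 100, 50
        for i, k in enumerate((50, 30, 20)):
            expected = depth * k / n_pop
            var = (
                depth * (k / n_pop) * (1 - k / n_pop) * (n_pop - depth) / (n_pop - 1)
            )
            se = np.sqrt(var / len(reps))
            assert abs(reps[:, i].mean() - expected) < 3 * se


class TestAlphaDiversity:
    def test_uniform_closed_forms(self):
        t = make_table([[5], [5], [5], [5]])
        a = alpha_diversity(t)
        assert a.loc["s0", "observed"] == 4
        assert a.loc["s0", "shannon"] == pytest.approx(np.log(4), abs=1e-12)
        assert a.loc["s0", "simpson"] == pytest.approx(0.75, abs=1e-12)

    def test_single_feature(self):
        a = alpha_diversity(make_table([[9]]))
        assert (a.loc["s0"] == [1, 0.0, 0.0]).all()

    def test_hand_evaluated_shannon(self):
        # p = (0.5, 0.25, 0.25) -> -sum p ln p
        a = alpha_diversity(make_table([[2], [1], [1]]))
        assert a.loc["s0", "shannon"] == pytest.approx(1.5 * np.log(2), abs=1e-12)
        assert a.loc["s0", "shannon"] == pytest.approx(1.0397, abs=1e-4)

    def test_invariant_to_count_rescaling(self, rng):
        counts = rng.integers(1, 40, (12, 5))
        a1 = alpha_diversity(make_table(counts))
        a2 = alpha_diversity(make_table(counts * 7))
        assert np.allclose(a1[["shannon", "simpson"]], a2[["shannon", "simpson"]])
        assert (a1["observed"] == a2["observed"]).all()


class TestKruskalWallis:
    def test_matches_no_tie_closed_form_for_separated_groups(self):
        values = np.arange(15, dtype=float)  # all A < all B < all C, n=5 each
        groups = ["A"] * 5 + ["B"] * 5 + ["C"] * 5
        h, p = kruskal_wallis(values, groups)
        n = 15
        rbar = {g: np.mean([values[i] + 1 for i in range(n) if groups[i] == g]) for g in "ABC"}
        expected = 12 / (n * (n + 1)) * sum(5 * rbar[g] ** 2 for g in "ABC") - 3 * (n + 1)
        assert h == pytest.approx(expected, abs=1e-12)

    def test_constant_data_convention(self):
        h, p = kruskal_wallis([2.0] * 6, ["A"] * 3 + ["B"] * 3)
        assert (h, p) == (0.0, 1.0)

    def test_agrees_with_scipy_including_ties(self, rng):
        values = rng.integers(0, 6, 30).astype(float)  # heavy ties
        groups = list(np.repeat(["A", "B", "C"], 10))
        h, p = kruskal_wallis(values, groups)
        ref = stats.kruskal(values[:10], values[10:20], values[20:])
        assert h == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestDunn:
    def test_identical_groups_give_zero_z(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        out = dunn_posthoc(values, ["A"] * 3 + ["B"] * 3)
        row = out.iloc[0]
        assert row["z"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_pairwise_formula_on_fixed_dataset(self):
        values = np.array([1.0, 4.0, 2.0, 7.0, 9.0, 6.0, 3.0, 8.0, 5.0])
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        out = dunn_posthoc(values, groups)
        ranks = stats.rankdata(values)
        n = len(values)
        rbar = {g: ranks[np.array(groups) == g].mean() for g in "ABC"}
        se = np.sqrt(n * (n + 1) / 12 * (1 / 3 + 1 / 3))
        expected = (rbar["A"] - rbar["B"]) / se
        got = out[(out.group_a == "A") & (out.group_b == "B")]["z"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_bh_adjustment_never_decreases_p(self, rng):
        values = rng.normal(size=20)
        groups = list(np.repeat(["A", "B", "C", "D"], 5))
        out = dunn_posthoc(values, groups, adjust="bh")
        assert (out["q"] >= out["p"] - 1e-15).all()


class TestBrayCurtis:
    def test_identical_disjoint_and_halfway(self):
        t = make_table([[1, 0, 1], [1, 1, 1], [0, 1, 0]])
        d = bray_curtis(t)
        assert d.values[0, 2] == pytest.approx(0.0)
        assert d.values[0, 1] == pytest.approx(0.5)  # (1,1,0) vs (0,1,1)
        t2 = make_table([[2, 0], [0, 3]])
        assert bray_curtis(t2).values[0, 1] == pytest.approx(1.0)

    @given(
        arrays(
            np.int64,
            st.tuples(st.integers(1, 8), st.integers(2, 6)),
            elements=st.integers(0, 30),
        ).filter(lambda m: (m.sum(axis=0) > 0).all())
    )
    def test_bounds_symmetry_and_reference_agreement(self, counts):
        d = bray_curtis(make_table(counts))
        assert (d.values >= 0).all() and (d.values <= 1).all()
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)
        ref = squareform(pdist(counts.T.astype(float), metric="braycurtis"))
        assert np.allclose(d.values, ref, atol=1e-12)

    def test_round_trip_serialization(self, tmp_path, rng):
        d = bray_curtis(make_table(rng.integers(1, 20, (6, 4))))
        write_distance_matrix(d, tmp_path / "d.tsv")
        back = read_distance_matrix(tmp_path / "d.tsv")
        assert back.sample_ids == d.sample_ids
        assert np.allclose(back.values, d.values, atol=1e-9)


class TestPcoa:
    def test_collinear_points_have_one_positive_axis(self):
        d = euclid_dm([[0.0], [1.0], [3.0]])
        res = pcoa(d)
        assert res.n_axes == 1
        rebuilt = squareform(pdist(res.coordinates))
        assert np.allclose(rebuilt, d.values, atol=1e-9)

    def test_zero_distances_give_no_axes(self):
        d = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))
        res = pcoa(d)
        assert res.n_axes == 0

    def test_euclidean_embedding_reproduces_distances(self, rng):
        pts = rng.normal(size=(15, 4))
        res = pcoa(euclid_dm(pts))
        rebuilt = squareform(pdist(res.coordinates))
        assert np.allclose(rebuilt, squareform(pdist(pts)), atol=1e-9)

    def test_matches_reference_eigenvalues(self, rng):
        import skbio

        counts = rng.integers(0, 50, (30, 10))
        counts[0] += 1
        d = bray_curtis(make_table(counts))
        res = pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values.copy(), ids=list(d.sample_ids))
        )
        ref_pos = ref.eigvals[ref.eigvals > 1e-10].to_numpy()
        assert np.allclose(np.sort(res.eigenvalues), np.sort(ref_pos), atol=1e-8)


class TestPermanova:
    def test_two_tight_far_clusters_hit_permutation_floor(self, rng):
        pts = np.vstack([rng.normal(0, 0.01, (6, 2)), rng.normal(100, 0.01, (6, 2))])
        d = euclid_dm(pts)
        res = permanova(d, ["A"] * 6 + ["B"] * 6, n_permutations=199, seed=1)
        assert res.p == pytest.approx(1 / 200)

    def test_r_squared_invariances(self, rng):
        pts = rng.normal(size=(12, 3))
        d = euclid_dm(pts)
        groups = ["A", "B", "C"] * 4
        r1 = permanova(d, groups, n_permutations=49, seed=0).r_squared
        relabeled = [{"A": "X", "B": "Y", "C": "Z"}[g] for g in groups]
        r2 = permanova(d, relabeled, n_permutations=49, seed=0).r_squared
        scaled = DistanceMatrix(d.sample_ids, d.values * 3.7)
        r3 = permanova(scaled, groups, n_permutations=49, seed=0).r_squared
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert r1 == pytest.approx(r3, abs=1e-12)

    def test_matches_reference_f_statistic(self, rng):
        import skbio

        pts = rng.normal(size=(14, 3))
        pts[:7] += 1.0
        d = euclid_dm(pts)
        groups = ["A"] * 7 + ["B"] * 7
        res = permanova(d, groups, n_permutations=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values.copy(), ids=list(d.sample_ids)),
            grouping=groups,
            permutations=99,
        )
        assert res.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_singleton_group_rejected(self):
        d = euclid_dm(np.arange(8.0).reshape(4, 2))
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(d, ["A", "B", "B", "B"], n_permutations=9, seed=0)

    def test_exhaustive_matches_enumeration_small_n(self, rng):
        pts = rng.normal(size=(6, 2))
        pts[3:] += 2.0
        d = euclid_dm(pts)
        groups = ["A"] * 3 + ["B"] * 3
        res = permanova(d, groups, exhaustive=True)
        # brute-force oracle: F for every 3/3 split computed independently
        d2 = d.values**2
        def f_of(split):
            within = 0.0
            for g in (split, tuple(i for i in range(6) if i not in split)):
                for i, j in itertools.combinations(g, 2):
                    within += d2[i, j] / 3
            total = d2[np.triu_indices(6, 1)].sum() / 6
            between = total - within
            return between / (within / 4)
        f_all = [f_of(s) for s in itertools.combinations(range(6), 3)]
        f_obs = f_of((0, 1, 2))
        expected = np.mean([f >= f_obs - 1e-12 for f in f_all])
        assert res.p == pytest.approx(expected, abs=1e-12)
        assert res.pseudo_f == pytest.approx(f_obs, abs=1e-10)


class TestPermdisp:
    def test_mirror_groups_have_equal_dispersion(self):
        pts = np.array(
            [[0, 0], [1, 0], [0, 1], [3, 3], [10, 0], [11, 0], [10, 1], [13, 3]],
            dtype=float,
        )
        d = euclid_dm(pts)
        f, p = permdisp(d, ["A"] * 4 + ["B"] * 4, n_permutations=199, seed=0)
        assert f == pytest.approx(0.0, abs=1e-10)
        assert p > 0.9

    def test_tight_vs_diffuse_cluster_detected(self, rng):
        pts = np.vstack([rng.normal(0, 0.01, (8, 2)), rng.normal(0, 5.0, (8, 2))])
        d = euclid_dm(pts)
        f, p = permdisp(d, ["A"] * 8 + ["B"] * 8, n_permutations=199, seed=0)
        assert p == pytest.approx(1 / 200)
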