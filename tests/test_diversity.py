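from itertools import combinations
from math import comb, log

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kruskal as scipy_kruskal
from scipy.stats import rankdata

from provmark import (
    GroupLabels,
    alpha_profile,
    jaccard_matrix,
    kruskal_wallis,
    pcoa,
    upgma_cluster,
)
from provmark.diversity import DistanceMatrix

from .test_preprocess import table_from_counts


def single_sample_profile(counts):
    t = table_from_counts([[c] for c in counts])
    return alpha_profile(t).iloc[0]


class TestAlphaIndices:
    def test_uniform_counts_closed_form(self):
        row = single_sample_profile([4, 4, 4, 4])
        assert row["s_obs"] == 4
        assert row["chao1"] == 4  # F1 = F2 = 0
        assert row["shannon"] == pytest.approx(log(4), abs=1e-12)
        assert row["pielou"] == pytest.approx(1.0, abs=1e-12)

    def test_chao1_hand_computation(self):
        # F1=2, F2=0: bias-corrected Chao1 = 4 + 2*1/2 = 5
        row = single_sample_profile([5, 3, 1, 1])
        assert row["chao1"] == pytest.approx(5.0)

    def test_single_taxon_sample(self):
        row = single_sample_profile([7])
        assert row["shannon"] == 0.0
        assert np.isnan(row["pielou"])  # undefined, not 0
        assert row["chao1"] == 1.0

    def test_ace_undefined_when_all_rare_singletons(self):
        row = single_sample_profile([1, 1, 1])
        assert np.isnan(row["ace"])

    def test_chao1_equals_richness_without_singletons(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(2, 30, size=25)
        row = single_sample_profile(counts)
        assert row["chao1"] == row["s_obs"]

    def test_shannon_bounded_by_log_richness(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(0, 40, size=12)
            if (counts > 0).sum() < 2:
                continue
            row = single_sample_profile(counts)
            assert row["shannon"] <= log(row["s_obs"]) + 1e-12

    def test_matches_scikit_bio_estimators(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        rng = np.random.default_rng(2)
        for _ in range(25):
            counts = rng.integers(0, 25, size=30)
            if counts.sum() == 0:
                continue
            row = single_sample_profile(counts)
            c = counts[counts > 0]
            assert row["chao1"] == pytest.approx(
                float(skbio_alpha.chao1(c, bias_corrected=True)), rel=1e-12
            )
            assert row["shannon"] == pytest.approx(
                float(skbio_alpha.shannon(c, base=np.e)), rel=1e-12
            )
            if not np.isnan(row["ace"]):
                assert row["ace"] == pytest.approx(
                    float(skbio_alpha.ace(c, rare_threshold=10)), rel=1e-9
                )


class TestJaccard:
    def test_set_arithmetic_cases(self):
        # presence sets: s0={o0,o1,o2}, s1={o1,o2,o3}, s2={o0,o1,o2}, s3={}
        t = table_from_counts(
            [
                [5, 0, 1, 0],
                [1, 2, 3, 0],
                [4, 9, 2, 0],
                [0, 3, 0, 0],
            ]
        )
        d = jaccard_matrix(t).matrix
        assert d[0, 1] == pytest.approx(1 - 2 / 4)  # shared {o1,o2} of 4
        assert d[0, 2] == 0.0  # identical presence sets
        assert d[0, 3] == 1.0  # disjoint (s3 empty vs non-empty)

    def test_both_empty_samples_distance_zero(self):
        t = table_from_counts([[0, 0], [0, 0]])
        assert jaccard_matrix(t).matrix[0, 1] == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        t = table_from_counts(rng.integers(0, 2, size=(8, 5)))
        d = jaccard_matrix(t).matrix
        n = d.shape[0]
        for i, j, k in combinations(range(n), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestPcoa:
    def test_collinear_points_single_axis(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_equilateral_triple_splits_evenly(self):
        d = 1 - np.eye(3)
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        assert res.proportion_explained[:2] == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_zero_matrix_warns(self):
        with pytest.warns(UserWarning):
            res = pcoa(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
        assert res.coordinates.shape[1] == 0
        assert np.allclose(res.eigenvalues, 0, atol=1e-12)

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(7)], d))
        coords = res.coordinates
        rec = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(rec, d, atol=1e-9)

    def test_matches_scikit_bio(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 4))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(6)]
        ours = pcoa(DistanceMatrix(ids, d))
        theirs = skbio_ord.pcoa(skbio.DistanceMatrix(d, ids))
        n_axes = ours.coordinates.shape[1]
        theirs_prop = np.asarray(theirs.proportion_explained)[:n_axes]
        assert np.allclose(ours.proportion_explained, theirs_prop, atol=1e-9)
        # coordinates agree up to per-axis sign
        theirs_coords = theirs.samples.to_numpy()[:, :n_axes]
        for k in range(n_axes):
            a, b = ours.coordinates[:, k], theirs_coords[:, k]
            assert np.allclose(a, b, atol=1e-6) or np.allclose(a, -b, atol=1e-6)


class TestUpgma:
    def test_two_samples_single_merge(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.3], [0.3, 0]]))
        dendro = upgma_cluster(dm)
        assert dendro.merge_heights().tolist() == [0.3]

    def test_three_point_linkage_arithmetic(self):
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        dendro = upgma_cluster(DistanceMatrix(["A", "B", "C"], d))
        z = dendro.linkage_matrix
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}  # A,B merge first
        assert z[0, 2] == pytest.approx(0.1)
        assert z[1, 2] == pytest.approx(0.9)

    def test_ultrametric_input_reproduced(self):
        # heights: (a,b) at 0.2; ((a,b),c) at 0.6; all with d to e at 1.0
        d = np.array(
            [
                [0.0, 0.2, 0.6, 1.0],
                [0.2, 0.0, 0.6, 1.0],
                [0.6, 0.6, 0.0, 1.0],
                [1.0, 1.0, 1.0, 0.0],
            ]
        )
        dendro = upgma_cluster(DistanceMatrix(list("abcd"), d))
        assert dendro.merge_heights().tolist() == pytest.approx([0.2, 0.6, 1.0])
        heights = dendro.merge_heights()
        assert np.all(np.diff(heights) >= -1e-12)

    def test_newick_contains_all_leaves(self):
        d = np.array([[0, 0.5, 0.4], [0.5, 0, 0.3], [0.4, 0.3, 0]])
        nwk = upgma_cluster(DistanceMatrix(["x", "y", "z"], d)).to_newick()
        assert nwk.endswith(";")
        for leaf in ("x", "y", "z"):
            assert leaf in nwk


def labels_for(values_by_group):
    mapping = {}
    values = {}
    for g, vals in values_by_group.items():
        for i, v in enumerate(vals):
            sid = f"{g}{i}"
            mapping[sid] = g
            values[sid] = v
    return values, GroupLabels(mapping)


class TestKruskalWallis:
    def test_all_equal_full_ties(self):
        values, groups = labels_for({"a": [2, 2, 2], "b": [2, 2, 2]})
        res = kruskal_wallis(values, groups)
        assert (res.statistic, res.pvalue) == (0.0, 1.0)

    def test_hand_computed_statistic(self):
        values, groups = labels_for({"a": [1, 2, 3], "b": [4, 5, 6]})
        res = kruskal_wallis(values, groups)
        expected = 12 / (6 * 7) * (6 ** 2 / 3 + 15 ** 2 / 3) - 3 * 7
        assert res.statistic == pytest.approx(expected, abs=1e-12)
        assert res.df == 1

    def test_monotone_transform_invariance(self):
        raw = {"a": [1.2, 3.4, 0.5], "b": [9.0, 2.2, 7.7], "c": [4.4, 5.5, 6.6]}
        values, groups = labels_for(raw)
        cubed, _ = labels_for({g: [v ** 3 for v in vs] for g, vs in raw.items()})
        r1 = kruskal_wallis(values, groups)
        r2 = kruskal_wallis(cubed, groups)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.pvalue == pytest.approx(r2.pvalue, abs=1e-12)

    def test_permutation_p_matches_bruteforce_enumeration(self):
        # n=7 toy, two groups of 3 and 4: enumerate all C(7,3) assignments
        data = {"a": [1.0, 5.0, 2.5], "b": [7.0, 3.0, 8.0, 6.0]}
        values, groups = labels_for(data)
        res = kruskal_wallis(values, groups, method="permutation")
        pooled = np.array(data["a"] + data["b"])
        ranks = rankdata(pooled)
        n = 7

        def h_of(idx_a):
            idx_a = list(idx_a)
            idx_b = [i for i in range(n) if i not in idx_a]
            s = ranks[idx_a].sum() ** 2 / 3 + ranks[idx_b].sum() ** 2 / 4
            return 12 / (n * (n + 1)) * s - 3 * (n + 1)

        h_obs = h_of(range(3))
        count = sum(h_of(c) >= h_obs - 1e-12 for c in combinations(range(n), 3))
        expected = count / comb(7, 3)
        assert res.pvalue == pytest.approx(expected, abs=1e-12)
        assert res.statistic == pytest.approx(h_obs, abs=1e-12)
        # the default chi-square p approximates the same tail
        approx = kruskal_wallis(values, groups)
        assert approx.pvalue == pytest.approx(float(scipy_kruskal(
            data["a"], data["b"]).pvalue), abs=1e-12)

    def test_pairwise_two_group_use(self):
        values, groups = labels_for(
            {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        )
        res = kruskal_wallis(values, groups, use_groups=["a", "c"])
        assert res.df == 1

    def test_group_with_missing_observations_rejected(self):
        values, groups = labels_for({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        values["b0"] = float("nan")
        with pytest.raises(ValueError, match="missing"):
            kruskal_wallis(values, groups)

    def test_too_small_group_rejected(self):
        values, groups = labels_for({"a": [1, 2], "b": [3, 4]})
        del values["b1"]
        with pytest.raises(ValueError, match="fewer than 2"):
            kruskal_wallis(values, groups)
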