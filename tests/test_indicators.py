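from itertools import combinations

import numpy as np
import pytest
from scipy.stats import pointbiserialr

from provmark import (
    GroupLabels,
    chain_select,
    compact_letter_display,
    indicator_analysis,
    permutation_p,
    point_biserial,
    to_relative_abundance,
)
from provmark.indicators import IndicatorResult, assess_suitability

from .test_preprocess import table_from_counts


class TestPointBiserial:
    def test_perfect_association(self):
        res = point_biserial([3.0, 3.0, 0.0, 0.0], [1, 1, 0, 0])
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_complement_negates(self):
        a = [1.0, 4.0, 2.0, 8.0, 0.5]
        m = [1, 0, 1, 0, 0]
        mc = [0, 1, 0, 1, 1]
        assert point_biserial(a, m).r == pytest.approx(-point_biserial(a, mc).r,
                                                       abs=1e-12)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            a = rng.normal(size=n)
            m = np.zeros(n, dtype=int)
            m[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            expected = pointbiserialr(m, a).statistic
            assert point_biserial(a, m).r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_degenerate(self):
        res = point_biserial([2.0, 2.0, 2.0, 2.0], [1, 1, 0, 0])
        assert res.r == 0.0
        assert res.degenerate

    def test_single_class_membership_rejected(self):
        with pytest.raises(ValueError):
            point_biserial([1.0, 2.0], [1, 1])


class TestPermutationP:
    def test_exhaustive_unique_maximum(self):
        # observed arrangement is the unique maximum of all C(6,3) = 20
        a = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        m = np.array([1, 1, 1, 0, 0, 0])
        assert permutation_p(a, m, exact=True) == pytest.approx(1 / 20)

    def test_constant_abundance_p_one(self):
        p = permutation_p([1.0] * 6, [1, 1, 1, 0, 0, 0], n_perm=99, seed=0)
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_monte_carlo_close_to_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=8)
        m = np.zeros(8)
        m[:3] = 1
        exact = permutation_p(a, m, exact=True)
        n_perm = 999
        mc = permutation_p(a, m, n_perm=n_perm, seed=seed + 100)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(mc - exact) <= 3 * se + 2 / n_perm

    def test_bad_n_perm_rejected(self):
        with pytest.raises(ValueError):
            permutation_p([1.0, 2.0], [1, 0], n_perm=0)


def planted_cohort(seed=0, n_per_group=12, fold=8.0):
    """4-OTU, two-group proportion table; OTU 0 planted higher in 'north'."""
    rng = np.random.default_rng(seed)
    base = np.array([0.05, 0.3, 0.3, 0.35])
    north = base * np.array([fold, 1, 1, 1])
    north /= north.sum()
    counts, mapping, sids = [], {}, []
    for j in range(2 * n_per_group):
        grp = "north" if j < n_per_group else "south"
        comp = north if grp == "north" else base
        counts.append(rng.multinomial(5000, comp))
        sid = f"{grp}{j}"
        sids.append(sid)
        mapping[sid] = grp
    t = table_from_counts(np.array(counts).T)
    t.sample_ids = sids
    return to_relative_abundance(t), GroupLabels(mapping)


class TestIndicatorAnalysis:
    def test_planted_marker_assigned_to_home_group(self):
        props, groups = planted_cohort(seed=1)
        res = indicator_analysis(props, groups, n_perm=199, seed=2)
        row = res.table[res.table["otu_id"] == "O0"].iloc[0]
        assert row["group"] == "north"
        assert row["p"] <= 0.05
        assert "O0" in res.candidates["north"]

    def test_each_otu_in_at_most_one_candidate_list(self):
        props, groups = planted_cohort(seed=3)
        res = indicator_analysis(props, groups, n_perm=99, seed=4)
        seen = [o for lst in res.candidates.values() for o in lst]
        assert len(seen) == len(set(seen))

    def test_group_relabeling_invariance(self):
        props, groups = planted_cohort(seed=5)
        renamed = GroupLabels(
            {s: {"north": "X", "south": "Y"}[g] for s, g in groups.mapping.items()},
            ["X", "Y"],
        )
        r1 = indicator_analysis(props, groups, n_perm=99, seed=6)
        r2 = indicator_analysis(props, renamed, n_perm=99, seed=6)
        assert np.allclose(r1.table["r"], r2.table["r"], atol=1e-12)
        assert [len(v) for v in r1.candidates.values()] == [
            len(v) for v in r2.candidates.values()
        ]

    def test_equalized_variant_runs(self):
        props, groups = planted_cohort(seed=7, n_per_group=6)
        res = indicator_analysis(props, groups, n_perm=49, seed=8,
                                 equalize_groups=True)
        row = res.table[res.table["otu_id"] == "O0"].iloc[0]
        assert row["group"] == "north"


def _indicator_result(candidates, r=0.5, p=0.01):
    import pandas as pd

    rows = [
        {"otu_id": o, "group": g, "r": r, "p": p, "candidate": True}
        for g, otus in candidates.items()
        for o in otus
    ]
    return IndicatorResult(pd.DataFrame(rows), candidates, 0.05, 999)


class TestChainSelect:
    def test_intersection_and_rank_order(self):
        ind = _indicator_result({"A": ["o1", "o2", "o3"]})
        panel = chain_select(ind, ["o2", "o9", "o1"], k=5)
        assert panel.members["A"] == ["o2", "o1"]

    def test_fewer_than_k_survivors(self):
        ind = _indicator_result({"A": ["o1"]})
        panel = chain_select(ind, ["o1", "o2"], k=5)
        assert panel.members["A"] == ["o1"]

    def test_k_zero_empty_panels(self):
        ind = _indicator_result({"A": ["o1"], "B": ["o2"]})
        panel = chain_select(ind, ["o1", "o2"], k=0)
        assert all(v == [] for v in panel.members.values())

    def test_empty_intersection_warns(self):
        ind = _indicator_result({"A": ["o1"]})
        with pytest.warns(UserWarning, match="exclusion"):
            panel = chain_select(ind, ["o9"], k=5)
        assert panel.members["A"] == []
        assert panel.warnings

    def test_truncation_respects_k(self):
        ind = _indicator_result({"A": [f"o{i}" for i in range(10)]})
        important = [f"o{i}" for i in range(10)]
        panel = chain_select(ind, important, k=5)
        assert len(panel.members["A"]) == 5
        assert panel.members["A"] == important[:5]


class TestCompactLetterDisplay:
    def test_no_differences_single_letter(self):
        letters = compact_letter_display(["a", "b", "c"], set())
        assert len({letters[g] for g in "abc"}) == 1

    def test_all_different_distinct_letters(self):
        groups = ["a", "b", "c"]
        sig = {("a", "b"), ("a", "c"), ("b", "c")}
        letters = compact_letter_display(groups, sig)
        for x, y in sig:
            assert set(letters[x]).isdisjoint(letters[y])

    @pytest.mark.parametrize("seed", range(30))
    def test_reconstruction_property(self, seed):
        # groups share a letter iff their comparison was non-significant
        rng = np.random.default_rng(seed)
        groups = ["g1", "g2", "g3", "g4"]
        sig = {
            pair for pair in combinations(groups, 2) if rng.random() < 0.5
        }
        letters = compact_letter_display(groups, sig)
        for x, y in combinations(groups, 2):
            shared = bool(set(letters[x]) & set(letters[y]))
            assert shared == ((x, y) not in sig and (y, x) not in sig)


class TestSuitability:
    def test_identical_distributions_share_letter(self):
        t = table_from_counts([[4] * 8, [6] * 8])
        props = to_relative_abundance(t)
        groups = GroupLabels({f"s{j}": ("x" if j < 4 else "y") for j in range(8)})
        ind = _indicator_result({"x": ["O0"], "y": []})
        panel = chain_select(ind, ["O0"], k=5)
        panel = assess_suitability(props, groups, panel, alpha=0.05)
        row = panel.suitability.iloc[0]
        assert row["letters_x"] == row["letters_y"]
        assert not row["discriminating"]

    def test_planted_marker_discriminates(self):
        props, groups = planted_cohort(seed=9)
        ind = _indicator_result({"north": ["O0"], "south": []})
        panel = chain_select(ind, ["O0"], k=5)
        panel = assess_suitability(props, groups, panel, alpha=0.05)
        member = panel.suitability[panel.suitability["otu_id"] == "O0"].iloc[0]
        assert member["discriminating"]
        assert member["mean_pct_north"] > member["mean_pct_south"]

    def test_cumulative_abundance_is_exact_sum(self):
        props, groups = planted_cohort(seed=10, n_per_group=5)
        ind = _indicator_result({"north": ["O0", "O1"], "south": []})
        panel = chain_select(ind, ["O0", "O1"], k=5)
        panel = assess_suitability(props, groups, panel)
        cum = panel.suitability[panel.suitability["otu_id"] == "cumulative"].iloc[0]
        i0, i1 = props.otu_index("O0"), props.otu_index("O1")
        north_cols = [props.sample_index(s) for s in groups.samples_in("north")]
        expected = (props.counts[i0, north_cols] + props.counts[i1, north_cols]).mean()
        assert cum["mean_pct_north"] == pytest.approx(expected * 100, abs=1e-12)
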