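"""Richness, rarefaction, Hill-number evenness, overlap and group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from islesar.core import CountTable
from islesar.diversity import (
    compartment_overlap,
    evenness_vs_size,
    hill_q1,
    observed_richness,
    rarefaction_curve,
    richness_anova,
    simple_ols,
)


class TestObservedRichness:
    def test_per_sample(self):
        t = CountTable([[5, 0, 1]], ["s1"], ["a", "b", "c"])
        assert observed_richness(t).tolist() == [2]

    def test_pooling_is_union(self, tiny_islands):
        t = CountTable([[1, 0, 0], [0, 1, 0]], ["s1", "s2"], ["a", "b", "c"])
        samples = pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "island_id": ["i1", "i1"],
                "compartment": ["detritus", "detritus"],
                "locus": ["18S", "18S"],
                "replicate_index": [1, 2],
            }
        )
        pooled = observed_richness(t, samples, group_by="island_compartment")
        assert pooled.loc[("i1", "detritus")] == 2

    def test_all_zero_sample_counts_zero(self):
        t = CountTable([[0, 0]], ["s1"], ["a", "b"])
        assert observed_richness(t).tolist() == [0]


class TestRarefaction:
    def test_endpoint_equals_observed_richness(self):
        counts = [12, 7, 3, 1]
        curve = rarefaction_curve(counts, [1, 5, 23])
        assert curve.expected_richness[-1] == pytest.approx(4.0, abs=1e-10)

    def test_one_read_shows_one_species(self):
        curve = rarefaction_curve([10, 5, 5], [1])
        assert curve.expected_richness[0] == pytest.approx(1.0)

    def test_monotone_and_concave(self, rng):
        counts = rng.integers(1, 60, size=20)
        depths = np.arange(1, int(counts.sum()) + 1, 5)
        curve = rarefaction_curve(counts, depths)
        diffs = np.diff(curve.expected_richness)
        assert (diffs >= -1e-9).all()
        assert (np.diff(diffs) <= 1e-9).all()

    def test_matches_monte_carlo_subsampling(self, rng):
        counts = rng.integers(1, 40, size=20)
        total = int(counts.sum())
        m = total // 3
        curve = rarefaction_curve(counts, [m])
        reads = np.repeat(np.arange(20), counts)
        draws = np.array(
            [np.unique(rng.choice(reads, size=m, replace=False)).size for _ in range(10_000)]
        )
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert curve.expected_richness[0] == pytest.approx(draws.mean(), abs=3 * se)

    def test_no_extrapolation(self):
        with pytest.raises(ValueError, match="exceeds total"):
            rarefaction_curve([5, 5], [11])


class TestHillQ1:
    def test_uniform_community(self):
        assert hill_q1([10, 10, 10, 10]) == pytest.approx(4.0)

    def test_single_species(self):
        assert hill_q1([42]) == pytest.approx(1.0)

    def test_two_species_skewed(self):
        # exp(-(0.75 ln 0.75 + 0.25 ln 0.25)) = 1.75478...
        assert hill_q1([75, 25]) == pytest.approx(1.7548, abs=1e-4)

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(1, 500), min_size=1, max_size=12),
        st.integers(2, 9),
    )
    def test_invariant_to_count_rescaling(self, counts, k):
        a = hill_q1(counts)
        b = hill_q1([c * k for c in counts])
        assert a == pytest.approx(b, rel=1e-12)

    def test_bounded_by_richness(self, rng):
        counts = rng.integers(1, 100, size=15)
        q1 = hill_q1(counts)
        assert 1.0 <= q1 <= 15.0


class TestEvennessVsSize:
    def test_constant_evenness_zero_slope(self, tiny_islands):
        records = pd.DataFrame(
            {"island_id": ["i1", "i2", "i1"], "q1": [3.0, 3.0, 3.0]}
        )
        islands = pd.concat(
            [tiny_islands, tiny_islands.iloc[[0]].assign(island_id="i3",
                                                         detritus_weight_mg=900.0)],
            ignore_index=True,
        )
        records = pd.DataFrame({"island_id": ["i1", "i2", "i3"], "q1": [3.0, 3.0, 3.0]})
        fit = evenness_vs_size(records, islands, "detritus_weight_mg")
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_relation_r2_one(self, tiny_islands):
        islands = pd.concat(
            [tiny_islands, tiny_islands.iloc[[0]].assign(island_id="i3",
                                                         detritus_weight_mg=900.0)],
            ignore_index=True,
        )
        q1 = 1.0 + 0.5 * np.log(islands["detritus_weight_mg"])
        records = pd.DataFrame({"island_id": islands["island_id"], "q1": q1})
        fit = evenness_vs_size(records, islands, "detritus_weight_mg")
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.5)

    def test_simple_ols_matches_closed_form(self):
        # hand-computed on a 5-point toy set
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 7.8, 10.1])
        fit = simple_ols(x, y)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        resid = y - (y.mean() + slope * (x - x.mean()))
        se = np.sqrt(resid @ resid / 3 / sxx)
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.stderr == pytest.approx(se, rel=1e-12)


class TestCompartmentOverlap:
    def _samples(self, comps):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(comps))],
                "island_id": ["i1"] * len(comps),
                "compartment": comps,
                "locus": ["18S"] * len(comps),
                "replicate_index": [1] * len(comps),
            }
        )

    def test_disjoint_compartments(self):
        t = CountTable([[1, 0], [0, 1]], ["s0", "s1"], ["a", "b"])
        ov = compartment_overlap(t, self._samples(["detritus", "water"]))
        assert ov.regions[frozenset({"detritus", "water"})] == 0
        assert ov.regions[frozenset({"detritus"})] == 1

    def test_identical_compartments_only_full_intersection(self):
        t = CountTable([[1, 1], [1, 1]], ["s0", "s1"], ["a", "b"])
        ov = compartment_overlap(t, self._samples(["detritus", "water"]))
        assert ov.regions[frozenset({"detritus", "water"})] == 2
        assert ov.regions[frozenset({"detritus"})] == 0

    def test_regions_partition_the_union(self, rng):
        counts = rng.integers(0, 3, size=(6, 30))
        t = CountTable(counts, [f"s{i}" for i in range(6)], [f"a{j}" for j in range(30)])
        comps = ["detritus", "detritus", "water", "water", "invertebrate", "invertebrate"]
        ov = compartment_overlap(t, self._samples(comps))
        assert sum(ov.regions.values()) == ov.union_size()


class TestRichnessAnova:
    def test_equal_group_means_f_near_zero(self):
        vals = [10, 12, 11, 10, 12, 11]
        groups = ["a", "a", "a", "b", "b", "b"]
        res = richness_anova(vals, groups)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(10, 2, 12), rng.normal(13, 2, 15)
        res = richness_anova(np.concatenate([a, b]), ["a"] * 12 + ["b"] * 15)
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert res.f_statistic == pytest.approx(t**2, rel=1e-10)

    def test_tukey_p_monotone_in_mean_difference(self, rng):
        base = rng.normal(0, 1, 10)
        vals = np.concatenate([base, base + 0.5, base + 3.0])
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        res = richness_anova(vals, groups)
        tk = res.tukey.set_index(["group1", "group2"])
        assert tk.loc[("a", "c"), "p-adj"] <= tk.loc[("a", "b"), "p-adj"]
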