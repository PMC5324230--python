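"""Inhibition arithmetic, mixture stratification, group tests and the
three-comparison set logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylgc import (
    ValidationError,
    assign_subgroups,
    compute_inhibition,
    group_tests,
    inhibition_percent,
    magnitude_vs_pooled_reference,
    three_way_overlap,
)

from conftest import make_beta, make_sample_sheet


class TestInhibitionPercent:
    @pytest.mark.parametrize("stim, supp, expected", [
        (2.0, 0.5, 75.0),
        (1.3, 1.3, 0.0),
        (0.8, 0.0, 100.0),
    ])
    def test_arithmetic(self, stim, supp, expected):
        assert inhibition_percent(stim, supp) == pytest.approx(expected)

    def test_non_positive_stimulated_rejected(self):
        with pytest.raises(ValidationError):
            inhibition_percent(0.0, 0.1)

    @settings(max_examples=50, deadline=None)
    @given(stim=st.floats(0.01, 10), supp=st.floats(0, 10),
           c=st.floats(0.01, 100))
    def test_scale_invariance(self, stim, supp, c):
        a = inhibition_percent(stim, supp)
        b = inhibition_percent(c * stim, c * supp)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)

    def test_triplicate_means_flow_through(self):
        assay = pd.DataFrame({
            "control_od_1": [0.3], "control_od_2": [0.3],
            "control_od_3": [0.3],
            "stimulated_od_1": [2.0], "stimulated_od_2": [2.0],
            "stimulated_od_3": [2.0],
            "suppressed_od_1": [0.4], "suppressed_od_2": [0.5],
            "suppressed_od_3": [0.6],
        }, index=["s1"])
        res = compute_inhibition(assay)
        assert res.loc["s1", "inhibition_pct"] == pytest.approx(75.0)


class TestAssignSubgroups:
    def test_planted_bimodal_labels_recovered(self):
        rng = np.random.default_rng(0)
        truth = np.array(["hypersensitive"] * 14 + ["typical"] * 19)
        x = np.where(truth == "hypersensitive", rng.normal(85, 3, 33),
                     rng.normal(45, 5, 33))
        inh = pd.Series(x, index=[f"s{i}" for i in range(33)])
        model = assign_subgroups(inh, seed=1)
        assert (model.assignments.to_numpy() == truth).mean() >= 0.95
        assert model.means[1] > model.means[0]  # hypersensitive higher

    def test_identical_values_fall_back_to_all_typical(self):
        inh = pd.Series([50.0] * 8, index=[f"s{i}" for i in range(8)])
        model = assign_subgroups(inh, seed=2)
        assert model.fallback
        assert (model.assignments == "typical").all()

    def test_fixed_threshold_mode(self):
        inh = pd.Series([50.0, 70.0], index=["a", "b"])
        model = assign_subgroups(inh, method="fixed_threshold", threshold=65)
        assert model.assignments.tolist() == ["typical", "hypersensitive"]

    def test_label_invariant_under_component_relabeling(self):
        # reversing the input order must not change any assignment
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(85, 3, 10), rng.normal(45, 5, 15)])
        inh = pd.Series(x, index=[f"s{i}" for i in range(25)])
        a = assign_subgroups(inh, seed=4).assignments
        b = assign_subgroups(inh[::-1], seed=4).assignments
        assert (a == b[a.index]).all()


class TestGroupTests:
    def test_identical_toy_groups_t_zero_p_one(self):
        from methylgc.gc_assay import _welch
        t, p, note = _welch(np.array([1.0, 2.0, 3.0]),
                            np.array([1.0, 2.0, 3.0]))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_constant_groups_reported_na(self):
        from methylgc.gc_assay import _welch
        t, p, note = _welch(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        assert np.isnan(t) and "constant" in note

    def test_planted_shift_detected_with_power(self):
        # +15-point case shift at the assay sample sizes: t-test should
        # reject in nearly every replicate
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(50):
            a = rng.normal(55, 10, 33)
            b = rng.normal(40, 10, 24)
            from scipy import stats
            hits += stats.ttest_ind(a, b, equal_var=False).pvalue <= 0.05
        assert hits >= 45

    def test_full_table_on_synthetic_assay(self, small_study):
        samples = small_study["samples"]
        inh = compute_inhibition(small_study["assay"])["inhibition_pct"]
        grp = samples.df.loc[inh.index, "group"]
        model = assign_subgroups(inh[grp == "case"], seed=6)
        res = group_tests(inh, samples, model)
        tt = res["ttests"].set_index(["group1", "group2"])
        assert tt.loc[("hypersensitive", "typical"), "p"] < 0.01
        assert tt.loc[("case", "control"), "p"] < 0.05
        assert set(res["correlations"]["variable"]) >= {"pc1", "pain"}


class TestThreeWayOverlap:
    def _records(self, universe, sig):
        diff = pd.Series(0.0, index=universe)
        p = pd.Series(1.0, index=universe)
        perm = pd.Series(1.0, index=universe)
        diff[list(sig)] = 0.1
        p[list(sig)] = 0.01
        perm[list(sig)] = 0.01
        return pd.DataFrame({"beta_diff": diff, "p_wilcoxon": p,
                             "perm_p": perm})

    def test_set_algebra_example(self):
        universe = list("abcdefg")
        hvt = self._records(universe, {"a", "b", "c"})
        hvc = self._records(universe, {"b", "c", "d"})
        tvc = self._records(universe, {"c"})
        venn = three_way_overlap(hvt, hvc, tvc)
        assert venn.gc_sensitivity_loci == {"b"}
        assert venn.triple_overlap == {"c"}
        assert venn.mecfs_associated == set()
        assert venn.typical_unique == set()
        assert venn.gc_sensitivity_loci_inclusive == {"b", "c"}
        assert sum(venn.region_counts.values()) == len(
            venn.s_hvt | venn.s_hvc | venn.s_tvc)

    def test_three_empty_sets(self):
        universe = list("abc")
        empty = self._records(universe, set())
        venn = three_way_overlap(empty, empty, empty)
        assert all(v == 0 for v in venn.region_counts.values())

    def test_mismatched_universe_rejected(self):
        a = self._records(list("abc"), set())
        b = self._records(list("abd"), set())
        with pytest.raises(ValidationError):
            three_way_overlap(a, a, b)


class TestMagnitudeVsPooledReference:
    def _beta(self, h, t, c):
        vals = [[h, h, t, t, c, c]]
        return make_beta(vals, probes=["cg1"],
                         samples=["h1", "h2", "t1", "t2", "c1", "c2"])

    @pytest.mark.parametrize("h, t, c, expected", [
        (0.440, 0.318, 0.276, 14.3),   # GSTM1-like strata means
        (0.762, 0.636, 0.614, 13.7),   # MYO3B-like
        (0.5, 0.5, 0.5, 0.0),
    ])
    def test_pooled_reference_magnitudes(self, h, t, c, expected):
        beta = self._beta(h, t, c)
        got = magnitude_vs_pooled_reference(beta, ["h1", "h2"],
                                            ["t1", "t2"], ["c1", "c2"],
                                            "cg1")
        assert got == pytest.approx(expected, abs=0.05)

    def test_empty_stratum_rejected(self):
        beta = self._beta(0.5, 0.5, 0.5)
        with pytest.raises(ValidationError, match="stratum"):
            magnitude_vs_pooled_reference(beta, [], ["t1"], ["c1"], "cg1")
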