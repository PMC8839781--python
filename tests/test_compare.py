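"""Statistical comparison layer: outcomes, normality, t-matrices, DID,
centroids and distances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from erdspec.compare import (
    Centroid,
    boxplot_summary,
    centroid,
    comparison_matrix,
    did_estimate,
    distance_summary,
    distance_table,
    lilliefors_test,
    scalar_outcome,
    t_test,
)
from erdspec.io import FeatureSet
from tests.conftest import make_feature_set


class TestScalarOutcome:
    def test_vector_of_ones_gives_one(self, feature_set):
        fs = FeatureSet(np.ones((2, 8)), feature_set.labels.iloc[:2])
        np.testing.assert_allclose(scalar_outcome(fs), [1.0, 1.0])

    def test_translation_linearity(self, feature_set):
        y0 = scalar_outcome(feature_set)
        shifted = FeatureSet(feature_set.vectors + 3.5, feature_set.labels)
        np.testing.assert_allclose(scalar_outcome(shifted), y0 + 3.5, atol=1e-12)

    def test_matches_loop_oracle(self, feature_set):
        y = scalar_outcome(feature_set)
        oracle = [np.mean([v for v in row]) for row in feature_set.vectors]
        np.testing.assert_allclose(y, oracle, atol=1e-12)

    def test_alternative_methods(self, feature_set):
        ref = Centroid(C=np.zeros(feature_set.n_features))
        d = scalar_outcome(feature_set, "distance_to_centroid", reference=ref)
        np.testing.assert_allclose(d, np.linalg.norm(feature_set.vectors, axis=1))
        f0 = scalar_outcome(feature_set, "single_feature", feature_index=0)
        np.testing.assert_allclose(f0, feature_set.vectors[:, 0])
        with pytest.raises(ValueError, match="unknown outcome"):
            scalar_outcome(feature_set, "median")


class TestLilliefors:
    def test_statistic_matches_manual_ecdf_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        stat, _ = lilliefors_test(x)
        from scipy.stats import norm

        xs = np.sort(x)
        cdf = norm.cdf(xs, loc=xs.mean(), scale=xs.std(ddof=1))
        n = xs.size
        manual = max(
            max((i + 1) / n - cdf[i] for i in range(n)),
            max(cdf[i] - i / n for i in range(n)),
        )
        assert stat == pytest.approx(manual, abs=1e-10)

    def test_statistic_agrees_with_statsmodels(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        rng = np.random.default_rng(0)
        x = rng.standard_normal(40)
        stat, p = lilliefors_test(x)
        sm_stat, sm_p = sm_lilliefors(x, dist="norm")
        assert stat == pytest.approx(sm_stat, abs=1e-10)
        assert p == pytest.approx(sm_p, abs=0.05)

    def test_uniform_sample_rejected(self):
        rng = np.random.default_rng(1)
        _, p = lilliefors_test(rng.uniform(0, 1, 1000))
        assert p < 0.05

    def test_type_one_error_rate_calibrated(self):
        """Empirical rejection rate at alpha=0.05 on 1000 normal samples."""
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(1000):
            _, p = lilliefors_test(rng.standard_normal(50))
            rejections += p < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_small_sample_raises(self):
        with pytest.raises(ValueError):
            lilliefors_test([1.0, 2.0, 3.0])


class TestTTest:
    def test_identical_samples(self):
        t, p, code = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert code == "+"

    def test_separated_samples_strongly_significant(self):
        t, p, code = t_test([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert p < 1e-6 and code == "-"

    def test_swapping_flips_sign_preserves_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(10), rng.standard_normal(10) + 1
        t1, p1, _ = t_test(a, b)
        t2, p2, _ = t_test(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_equal_constants_give_p_one(self):
        t, p, code = t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p, code) == (0.0, 1.0, "+")


class TestComparisonMatrix:
    def test_within_design_emits_six_pairings(self, feature_set):
        m = comparison_matrix(feature_set, "within")
        assert len(m.table) == 6
        assert m.table["pairing"].iloc[0] == "Tinnitus S1–Control S1"
        assert set(m.table["code"]) <= {"+", "-"}

    def test_between_design_emits_five_per_subject(self, feature_set):
        m = comparison_matrix(feature_set, "between")
        subjects = feature_set.labels.query("group == 'tinnitus'")["subject"].nunique()
        assert len(m.table) == 5 * subjects

    def test_code_consistent_with_p_at_alpha(self, feature_set):
        m = comparison_matrix(feature_set, "within")
        assert ((m.table["p"] > 0.05) == (m.table["code"] == "+")).all()

    def test_shifted_tinnitus_cells_flag_differences(self):
        rng = np.random.default_rng(1)
        fs = make_feature_set(
            rng, n_per_cell=10,
            cell_means={("tinnitus", "S1"): 10.0, ("tinnitus", "S2"): 10.0},
        )
        m = comparison_matrix(fs, "within").table.set_index("pairing")
        assert m.loc["Tinnitus S1–Control S1", "code"] == "-"
        assert m.loc["Tinnitus S2–Control S2", "code"] == "-"
        assert m.loc["Control S1–Control S2", "code"] == "+"

    def test_missing_cell_raises(self):
        rng = np.random.default_rng(2)
        fs = make_feature_set(rng)
        keep = ~(
            (fs.labels["group"] == "control") & (fs.labels["session"] == "S2")
        ).to_numpy()
        partial = FeatureSet(fs.vectors[keep], fs.labels[keep])
        with pytest.raises(ValueError, match="control"):
            comparison_matrix(partial, "within")


class TestDID:
    def test_closed_form_cell_means(self):
        """Cell means (C,S1)=0, (C,S2)=0.5, (T,S1)=1, (T,S2)=2 -> betas."""
        y = np.array([0.0, 0.5, 1.0, 2.0])
        time = np.array([0, 1, 0, 1])
        group = np.array([0, 0, 1, 1])
        res = did_estimate(y, time, group)
        assert res.beta0 == pytest.approx(0.0, abs=1e-12)
        assert res.beta1 == pytest.approx(0.5, abs=1e-12)
        assert res.beta2 == pytest.approx(1.0, abs=1e-12)
        assert res.beta3 == pytest.approx(0.5, abs=1e-12)
        assert res.effect == "Positive effect"

    @pytest.mark.parametrize(
        "b3,label",
        [(0.0327, "Positive effect"), (-0.0018, "Negative effect")],
    )
    def test_effect_label_follows_sign(self, b3, label):
        y = np.array([0.0, 0.0, 0.0, b3])
        res = did_estimate(y, [0, 1, 0, 1], [0, 0, 1, 1])
        assert res.beta3 == pytest.approx(b3, abs=1e-12)
        assert res.effect == label

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_ols_equals_difference_of_cell_mean_differences(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 20))
        time = np.repeat([0, 1, 0, 1], n)
        group = np.repeat([0, 0, 1, 1], n)
        y = rng.standard_normal(4 * n) + 0.5 * time * group
        res = did_estimate(y, time, group)
        cell = lambda t, g: y[(time == t) & (group == g)].mean()
        closed = (cell(1, 1) - cell(0, 1)) - (cell(1, 0) - cell(0, 0))
        assert res.beta3 == pytest.approx(closed, abs=1e-10)

    def test_recovers_injected_effect_unbiased(self):
        """beta3 over 20 simulated cohorts is within 2 MC standard errors."""
        delta = 0.7
        est = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 30
            time = np.repeat([0, 1, 0, 1], n)
            group = np.repeat([0, 0, 1, 1], n)
            mu = 0.2 * time + 0.4 * group + delta * time * group
            y = mu + rng.standard_normal(4 * n)
            est.append(did_estimate(y, time, group).beta3)
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() - delta) < 2 * se

    def test_empty_cell_raises(self):
        with pytest.raises(ValueError, match="empty design cell"):
            did_estimate([1.0, 2.0, 3.0], [0, 1, 0], [0, 0, 1])


class TestCentroidAndDistances:
    def test_toy_centroid(self):
        c = centroid(np.array([[0.0, 0.0], [2.0, 2.0]]))
        np.testing.assert_allclose(c.C, [1.0, 1.0])
        assert c.p == 2

    def test_single_vector_is_its_own_centroid(self):
        v = np.array([3.0, -1.0, 2.0])
        np.testing.assert_allclose(centroid(v).C, v)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((100, 7))
        oracle = np.array(
            [sum(x[j, i] for j in range(100)) / 100 for i in range(7)]
        )
        np.testing.assert_allclose(centroid(x).C, oracle, atol=1e-12)

    def test_3_4_5_distance(self):
        s = distance_summary(np.array([[3.0, 4.0]]), Centroid(C=np.zeros(2)))
        assert s.distances[0] == pytest.approx(5.0, abs=1e-10)

    def test_instance_at_centroid_has_zero_distance(self):
        c = Centroid(C=np.array([1.0, 2.0]))
        s = distance_summary(np.array([[1.0, 2.0]]), c)
        assert s.distances[0] == 0.0

    def test_population_std_arithmetic(self):
        """Distances {1, 3}: mean 2, SD 1 with denominator N=2."""
        c = Centroid(C=np.zeros(1))
        s = distance_summary(np.array([[1.0], [3.0]]), c)
        assert s.mean == pytest.approx(2.0, abs=1e-12)
        assert s.std == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_translation_invariance_and_scaling(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((6, 4))
        c = centroid(x)
        base = distance_summary(x, c)
        shift = rng.standard_normal(4)
        shifted = distance_summary(x + shift, Centroid(C=c.C + shift))
        np.testing.assert_allclose(shifted.distances, base.distances, atol=1e-9)
        scaled = distance_summary(3.0 * x, Centroid(C=3.0 * c.C))
        np.testing.assert_allclose(scaled.distances, 3.0 * base.distances, atol=1e-9)

    def test_population_std_below_sample_std(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((10, 3))
        s = distance_summary(x, Centroid(C=np.zeros(3)))
        assert s.std < s.distances.std(ddof=1)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            distance_summary(np.zeros((2, 3)), Centroid(C=np.zeros(4)))


class TestDistanceTable:
    def test_has_five_rows_of_mean_and_std(self, feature_set):
        table = distance_table(feature_set)
        assert len(table) == 5
        assert {"instances", "centroid", "mean", "std"} <= set(table.columns)

    def test_point_mass_cells_give_zero_distances(self):
        labels = []
        for group in ("tinnitus", "control"):
            for session in ("S1", "S2"):
                labels += [{"subject": 0, "group": group, "session": session}] * 2
        fs = FeatureSet(np.ones((8, 4)), pd.DataFrame(labels))
        table = distance_table(fs)
        np.testing.assert_allclose(table["mean"], 0.0, atol=1e-12)

    def test_post_treatment_convergence_is_visible(self):
        """Tinnitus S2 built closer to the control centroid than tinnitus S1."""
        rng = np.random.default_rng(3)
        fs = make_feature_set(
            rng, n_per_cell=20,
            cell_means={("tinnitus", "S1"): 6.0, ("tinnitus", "S2"): 1.0},
        )
        table = distance_table(fs).set_index(["instances", "centroid"])
        assert (
            table.loc[("Tinnitus S2", "Control S1"), "mean"]
            < table.loc[("Tinnitus S1", "Control S1"), "mean"]
        )


class TestBoxplotSummary:
    def test_median_of_known_cell(self):
        labels, vecs = [], []
        for group in ("tinnitus", "control"):
            for session in ("S1", "S2"):
                for v in (1.0, 2.0, 3.0, 4.0, 5.0):
                    labels.append({"subject": 0, "group": group, "session": session})
                    vecs.append([v, v])
        fs = FeatureSet(np.array(vecs), pd.DataFrame(labels))
        box = boxplot_summary(fs).set_index("cell")
        assert box.loc["T-S1", "median"] == 3.0

    def test_degenerate_constant_cells(self):
        labels = []
        for group in ("tinnitus", "control"):
            for session in ("S1", "S2"):
                labels += [{"subject": 0, "group": group, "session": session}] * 3
        fs = FeatureSet(np.full((12, 2), 7.0), pd.DataFrame(labels))
        box = boxplot_summary(fs)
        for col in ("min", "q1", "median", "q3", "max"):
            np.testing.assert_allclose(box[col], 7.0)

    def test_quartiles_match_interpolation_oracle(self, feature_set):
        from erdspec.compare import scalar_outcome

        box = boxplot_summary(feature_set).set_index("cell")
        y = scalar_outcome(feature_set)
        m = (
            (feature_set.labels["group"] == "control")
            & (feature_set.labels["session"] == "S1")
        ).to_numpy()
        v = np.sort(y[m])
        # linear interpolation between order statistics at q = 0.25
        pos = 0.25 * (v.size - 1)
        lo, frac = int(pos), pos - int(pos)
        oracle = v[lo] + frac * (v[lo + 1] - v[lo])
        assert box.loc["C-S1", "q1"] == pytest.approx(oracle, abs=1e-12)
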