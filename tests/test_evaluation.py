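"""Discrimination, calibration, NRI and AMH stratum summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovaclock import CohortRecord, amh_summary_by_age_strata, calibration_table, compute_auc
from ovaclock.errors import UndefinedMetricError
from ovaclock.evaluation import auc_point, categorical_nri, continuous_nri, nri_point


def brute_force_auc(labels, probs):
    """All-pairs concordance count: the defining form of the AUC."""
    labels = np.asarray(labels)
    probs = np.asarray(probs)
    cases = probs[labels == 1]
    controls = probs[labels == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (cases.size * controls.size)


class TestAuc:
    @pytest.mark.parametrize(
        "labels,probs,expected",
        [
            ([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2], 0.75),
            ([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2], 1.0),
            ([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5], 0.5),
        ],
    )
    def test_examples(self, labels, probs, expected):
        assert auc_point(labels, probs) == pytest.approx(expected)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 200))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # coarse grid of scores forces plenty of ties
            probs = rng.integers(0, 8, n) / 7.0
            assert auc_point(labels, probs) == pytest.approx(brute_force_auc(labels, probs))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_invariant_under_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        probs = rng.random(n)
        transformed = 1.0 / (1.0 + np.exp(-(3.0 * probs - 1.0)))  # strictly increasing
        assert auc_point(labels, probs) == pytest.approx(auc_point(labels, transformed))

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc_point([1, 1, 1], [0.2, 0.3, 0.4])

    def test_bootstrap_ci_reproducible_and_brackets_point(self, rng):
        labels = rng.integers(0, 2, 200)
        probs = np.clip(labels * 0.4 + rng.random(200) * 0.6, 0, 1)
        a1, ci1 = compute_auc(labels, probs, n_boot=200, seed=7)
        a2, ci2 = compute_auc(labels, probs, n_boot=200, seed=7)
        assert (a1, ci1) == (a2, ci2)
        assert ci1[0] <= a1 <= ci1[1]


class TestNri:
    def test_enumeration_example(self):
        # events move (+0.1, -0.05): up minus down = 0
        # non-events move (-0.1, -0.2): down minus up = 1
        labels = [1, 1, 0, 0]
        ref = [0.5, 0.5, 0.5, 0.5]
        new = [0.6, 0.45, 0.4, 0.3]
        assert nri_point(labels, ref, new) == pytest.approx(1.0)

    def test_identical_probs_give_zero(self, rng):
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        probs = rng.random(50)
        assert nri_point(labels, probs, probs) == 0.0

    def test_maximum_is_two(self):
        labels = [1, 1, 0, 0]
        ref = [0.5, 0.5, 0.5, 0.5]
        new = [0.6, 0.7, 0.4, 0.3]
        assert nri_point(labels, ref, new) == pytest.approx(2.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a, b = rng.random(30), rng.random(30)
        assert nri_point(labels, a, b) == pytest.approx(-nri_point(labels, b, a))

    def test_bootstrap_ci_reproducible(self, rng):
        labels = rng.integers(0, 2, 120)
        labels[:2] = [0, 1]
        ref, new = rng.random(120), rng.random(120)
        r1 = continuous_nri(labels, ref, new, n_boot=100, seed=3)
        r2 = continuous_nri(labels, ref, new, n_boot=100, seed=3)
        assert r1 == r2

    def test_categorical_variant_counts_threshold_crossings(self):
        labels = [1, 0]
        ref = [0.10, 0.20]
        new = [0.20, 0.10]  # event crosses 0.15 upward, non-event downward
        assert categorical_nri(labels, ref, new, thresholds=[0.15]) == pytest.approx(2.0)


class TestCalibration:
    def test_perfect_predictions_two_bins(self):
        labels = [0] * 5 + [1] * 5
        probs = [0.0] * 5 + [1.0] * 5
        cal = calibration_table(labels, probs, n_bins=2)
        np.testing.assert_allclose(cal.table["observed"], [0.0, 1.0])
        np.testing.assert_allclose(cal.table["mean_predicted"], [0.0, 1.0])

    def test_constant_probabilities_single_bin(self):
        labels = [1, 0, 0, 0, 1, 0, 0, 0, 0, 0]
        probs = [0.2] * 10
        cal = calibration_table(labels, probs, n_bins=5)
        assert len(cal.table) == 1
        assert cal.table["observed"].iloc[0] == pytest.approx(0.2)

    def test_hand_enumerated_toy(self):
        probs = [0.05, 0.1, 0.3, 0.4, 0.6, 0.7, 0.85, 0.9]
        labels = [0, 0, 0, 1, 1, 0, 1, 1]
        cal = calibration_table(labels, probs, n_bins=4)
        np.testing.assert_allclose(cal.table["mean_predicted"], [0.075, 0.35, 0.65, 0.875])
        np.testing.assert_allclose(cal.table["observed"], [0.0, 0.5, 0.5, 1.0])
        # zoom keeps only the low-probability bin
        assert (cal.zoom["mean_predicted"] <= 0.25).all()

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 300))
        labels = rng.integers(0, 2, n)
        probs = rng.random(n)
        cal = calibration_table(labels, probs, n_bins=10)
        assert cal.table["n"].sum() == n
        events = (cal.table["n"] * cal.table["observed"]).sum()
        assert events == pytest.approx(labels.sum())

    def test_fewer_records_than_bins_reduces_with_warning(self):
        with pytest.warns(UserWarning, match="reducing"):
            cal = calibration_table([0, 1, 0], [0.1, 0.8, 0.3], n_bins=10)
        assert cal.table["n"].sum() == 3


class TestAmhStrata:
    def test_order_statistics_single_stratum(self):
        cohort = [CohortRecord(f"s{i}", 28.0, float(v)) for i, v in enumerate([1, 2, 3, 4, 5])]
        table = amh_summary_by_age_strata(cohort)
        row = table[table["stratum"] == "<=30"].iloc[0]
        assert (row["median"], row["q25"], row["q75"]) == (3.0, 2.0, 4.0)

    def test_age_exactly_30_belongs_to_youngest_stratum(self):
        cohort = [CohortRecord("a", 30.0, 3.0), CohortRecord("b", 30.5, 1.0)]
        table = amh_summary_by_age_strata(cohort)
        assert table[table["stratum"] == "<=30"]["n"].iloc[0] == 1
        assert table[table["stratum"] == ">30-<=40"]["n"].iloc[0] == 1

    def test_empty_stratum_has_nan_percentiles(self):
        cohort = [CohortRecord("a", 25.0, 3.0)]
        table = amh_summary_by_age_strata(cohort)
        old = table[table["stratum"] == ">40"].iloc[0]
        assert old["n"] == 0 and np.isnan(old["median"])
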