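"""Positive rates, Cohen's kappa, and Kaplan-Meier time-to-detection."""

import math

import numpy as np
import pandas as pd
import pytest

from sfprog.evaluation import (
    FlagTable,
    between_criterion_agreement,
    between_visit_agreement,
    cohens_kappa,
    km_time_to_detection,
    positive_rate,
    positive_rate_table,
)

from conftest import make_flag_table


def wilson_oracle(k, n, z=1.959963984540054):
    """Closed-form Wilson score interval, independent of statsmodels."""
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


class TestFlagTable:
    def test_missing_cells_rejected(self):
        flags = pd.DataFrame(
            [
                {"eye_id": "a", "series_length": 5, "criterion": "X", "flag": True},
                {"eye_id": "b", "series_length": 5, "criterion": "X", "flag": False},
                {"eye_id": "a", "series_length": 5, "criterion": "Y", "flag": True},
            ]
        )
        with pytest.raises(ValueError, match="identical eye sets"):
            FlagTable(flags)

    def test_duplicate_cells_rejected(self):
        flags = pd.DataFrame(
            [
                {"eye_id": "a", "series_length": 5, "criterion": "X", "flag": True},
                {"eye_id": "a", "series_length": 5, "criterion": "X", "flag": False},
            ]
        )
        with pytest.raises(ValueError, match="duplicate"):
            FlagTable(flags)


class TestPositiveRate:
    def test_ten_of_hundred_with_wilson_interval(self):
        by_eye = {f"e{i}": i < 10 for i in range(100)}
        table = make_flag_table({"X": {5: by_eye}})
        out = positive_rate(table, "X", 5)
        lo, hi = wilson_oracle(10, 100)
        assert out.rate == pytest.approx(10.0)
        assert out.ci_low == pytest.approx(100 * lo, abs=1e-9)
        assert out.ci_high == pytest.approx(100 * hi, abs=1e-9)
        assert (round(out.ci_low, 1), round(out.ci_high, 1)) == (5.5, 17.4)

    def test_degenerate_rates_pin_the_interval(self):
        none = positive_rate(make_flag_table({"X": {5: {f"e{i}": False for i in range(20)}}}), "X", 5)
        assert none.rate == 0.0 and none.ci_low == 0.0
        full = positive_rate(make_flag_table({"X": {5: {f"e{i}": True for i in range(20)}}}), "X", 5)
        assert full.rate == 100.0 and full.ci_high == 100.0

    def test_clopper_pearson_is_wider(self):
        table = make_flag_table({"X": {5: {f"e{i}": i < 10 for i in range(100)}}})
        wilson = positive_rate(table, "X", 5, ci_method="wilson")
        exact = positive_rate(table, "X", 5, ci_method="beta")
        assert exact.ci_low <= wilson.ci_low and exact.ci_high >= wilson.ci_high

    def test_table_covers_every_cell(self):
        by_eye = {"a": True, "b": False}
        table = make_flag_table({"X": {5: by_eye, 6: by_eye}, "Y": {5: by_eye, 6: by_eye}})
        tidy = positive_rate_table(table)
        assert len(tidy) == 4
        assert set(tidy["criterion"]) == {"X", "Y"}


class TestKappa:
    def test_identical_nonconstant_vectors(self):
        res = cohens_kappa([1, 1, 0, 0], [1, 1, 0, 0])
        assert res.kappa == pytest.approx(1.0)
        assert res.band == "almost perfect"

    def test_orthogonal_vectors_give_zero(self):
        res = cohens_kappa([1, 1, 0, 0], [1, 0, 1, 0])
        assert res.kappa == pytest.approx(0.0, abs=1e-15)

    def test_two_by_two_hand_example(self):
        # a=40 both-yes, b=9, c=6, d=45: po=0.85, pe=0.49*0.46+0.51*0.54=0.5008
        a = np.repeat([1, 1, 0, 0], [40, 9, 6, 45])
        b = np.repeat([1, 0, 1, 0], [40, 9, 6, 45])
        res = cohens_kappa(a, b)
        assert res.observed_agreement == pytest.approx(0.85)
        assert res.expected_agreement == pytest.approx(0.5008)
        assert res.kappa == pytest.approx((0.85 - 0.5008) / (1 - 0.5008), abs=1e-12)
        assert round(res.kappa, 2) == 0.70
        assert res.band == "substantial"

    def test_matches_sklearn_on_random_vectors(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            a = rng.uniform(size=50) < 0.3
            b = rng.uniform(size=50) < 0.3
            if a.all() == b.all() and a.var() == 0 and b.var() == 0:
                continue
            assert cohens_kappa(a, b).kappa == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )

    def test_symmetry(self, rng):
        a = rng.uniform(size=40) < 0.4
        b = rng.uniform(size=40) < 0.4
        assert cohens_kappa(a, b).kappa == pytest.approx(cohens_kappa(b, a).kappa)

    def test_undefined_when_both_constant_identical(self):
        res = cohens_kappa([True] * 5, [True] * 5)
        assert math.isnan(res.kappa)
        assert not res.defined

    @pytest.mark.parametrize(
        "kappa,band",
        [(0.1, "slight"), (0.3, "fair"), (0.5, "moderate"), (0.7, "substantial"),
         (0.9, "almost perfect")],
    )
    def test_qualitative_bands(self, kappa, band):
        from sfprog.evaluation import _band

        assert _band(kappa) == band


class TestBetweenVisitAgreement:
    def test_constant_flags_give_unit_kappa(self):
        by_eye = {"a": True, "b": False, "c": True}
        table = make_flag_table({"X": {k: by_eye for k in (5, 6, 7, 8, 9)}})
        out = between_visit_agreement(table, "X")
        assert len(out) == 4  # consecutive pairs 5-6 .. 8-9
        assert (out["kappa"] == 1.0).all()

    def test_independent_flags_give_near_zero_kappa(self, rng):
        n = 10_000
        flags = {
            k: {f"e{i}": bool(v) for i, v in enumerate(rng.uniform(size=n) < 0.2)}
            for k in (5, 6)
        }
        out = between_visit_agreement(make_flag_table({"X": flags}), "X")
        # kappa SE for independent raters ~ 1/sqrt(n * pe-ish); 3 SE bound
        assert abs(out["kappa"].iloc[0]) < 3 / math.sqrt(n * 0.2 * 0.8)

    def test_three_lengths_give_two_kappas(self):
        by_eye = {"a": True, "b": False}
        table = make_flag_table({"X": {5: by_eye, 6: by_eye, 7: by_eye}})
        assert len(between_visit_agreement(table, "X")) == 2


class TestBetweenCriterionAgreement:
    def test_pairwise_rows(self):
        by_eye = {"a": True, "b": False}
        table = make_flag_table({"X": {5: by_eye}, "Y": {5: by_eye}, "Z": {5: by_eye}})
        out = between_criterion_agreement(table, 5)
        assert len(out) == 3  # C(3,2)


class TestKaplanMeier:
    def test_four_eye_hand_example(self):
        # events at 24 and 30 months, censoring at 36: S = 1, .75, .50; median 30
        table = make_flag_table(
            {
                "X": {
                    5: {"a": True, "b": False, "c": False, "d": False},
                    6: {"a": True, "b": True, "c": False, "d": False},
                }
            },
            visit_months={
                "a": [0, 6, 12, 18, 24, 30],
                "b": [0, 6, 12, 18, 24, 30],
                "c": [0, 8, 15, 22, 29, 36],
                "d": [0, 8, 15, 22, 29, 36],
            },
        )
        curve = km_time_to_detection(table, "X")
        surv = dict(zip(curve.times, curve.survival))
        assert surv[0.0] == pytest.approx(1.0)
        assert surv[24.0] == pytest.approx(0.75)
        assert surv[30.0] == pytest.approx(0.50)
        assert curve.median_months == pytest.approx(30.0)
        assert curve.n_events == 2 and curve.n_censored == 2

    def test_event_is_first_flagging_length(self):
        months = {"a": [0, 5, 10, 15, 20, 25]}
        table = make_flag_table(
            {"X": {5: {"a": True}, 6: {"a": True}}}, visit_months=months
        )
        curve = km_time_to_detection(table, "X")
        assert curve.durations[0] == 20.0  # 5th visit, not the 6th

    def test_never_flagged_curve_stays_at_one(self):
        months = {"a": [0, 6, 12, 18, 24], "b": [0, 6, 12, 18, 24]}
        table = make_flag_table(
            {"X": {5: {"a": False, "b": False}}}, visit_months=months
        )
        curve = km_time_to_detection(table, "X")
        assert np.all(curve.survival == 1.0)
        assert curve.median_months is None

    def test_no_censoring_median_matches_sample_median(self):
        months = {e: [0, 6, 12, 18, 24 + 6 * i] for i, e in enumerate("abcd")}
        table = make_flag_table(
            {"X": {5: {e: True for e in "abcd"}}}, visit_months=months
        )
        curve = km_time_to_detection(table, "X")
        # event times 24, 30, 36, 42 -> first time S <= 0.5 is 30
        assert curve.median_months == pytest.approx(30.0)

    def test_missing_visit_times_is_an_error(self):
        table = make_flag_table({"X": {5: {"a": True}}})
        with pytest.raises(ValueError, match="visit times"):
            km_time_to_detection(table, "X")
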