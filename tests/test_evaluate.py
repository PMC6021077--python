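"""Discrimination, calibration and bootstrap machinery."""

import numpy as np
import pytest

from iciss import (
    DegenerateMetricError,
    auroc,
    bootstrap_ci,
    calibration_line,
    decile_table,
    evaluate_matrix,
    evaluate_performance,
)
from iciss.evaluate import PerformanceReport


def auroc_bruteforce(predictions, outcomes):
    """O(n^2) Mann–Whitney pair count with half-credit for ties."""
    pos = [p for p, y in zip(predictions, outcomes) if y == 1]
    neg = [p for p, y in zip(predictions, outcomes) if y == 0]
    total = sum(
        1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
    )
    return total / (len(pos) * len(neg))


class TestAuroc:
    @pytest.mark.parametrize(
        "p,y,expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
            ([0.2, 0.4, 0.4, 0.8], [0, 0, 1, 1], 0.875),
            ([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1], 0.5),
        ],
    )
    def test_examples(self, p, y, expected):
        assert auroc(p, y) == pytest.approx(expected)

    def test_single_class_undefined(self):
        with pytest.raises(DegenerateMetricError):
            auroc([0.1, 0.2], [1, 1])

    def test_complement_symmetry_and_monotone_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.random(80)
        y = (rng.random(80) < 0.3).astype(int)
        assert auroc(p, y) + auroc(p, 1 - y) == pytest.approx(1.0)
        assert auroc(np.exp(3 * p), y) == pytest.approx(auroc(p, y))

    def test_agrees_with_bruteforce(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(4, 120))
            p = np.round(rng.random(n), 1)  # rounding forces ties
            y = (rng.random(n) < 0.4).astype(int)
            if y.min() == y.max():
                continue
            assert auroc(p, y) == pytest.approx(auroc_bruteforce(p, y))


class TestCalibrationLine:
    def test_perfect_predictions(self):
        slope, intercept = calibration_line([0, 0, 1, 1, 0], [0, 0, 1, 1, 0])
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0)

    def test_consistency_under_correct_specification(self):
        rng = np.random.default_rng(2)
        p = np.tile(np.linspace(0.05, 0.95, 50), 400)  # 20,000 points
        y = (rng.random(p.size) < p).astype(int)
        slope, intercept = calibration_line(p, y, "probability")
        assert slope == pytest.approx(1.0, abs=0.05)
        assert intercept == pytest.approx(0.0, abs=0.03)
        dslope, dintercept = calibration_line(p, y, "decile_means")
        assert dslope == pytest.approx(1.0, abs=0.07)
        assert dintercept == pytest.approx(0.0, abs=0.04)

    def test_doubling_the_risk_halves_the_slope(self):
        rng = np.random.default_rng(3)
        true_risk = np.tile(np.linspace(0.02, 0.45, 40), 500)
        y = (rng.random(true_risk.size) < true_risk).astype(int)
        slope, _ = calibration_line(2 * true_risk, y, "probability")
        assert slope == pytest.approx(0.5, abs=0.03)

    def test_constant_predictions_degenerate(self):
        with pytest.raises(DegenerateMetricError):
            calibration_line([0.3] * 20, [0, 1] * 10)


class TestDecileTable:
    def test_even_split_with_distinct_predictions(self):
        p = np.linspace(0, 1, 100)
        y = (p > 0.5).astype(int)
        table = decile_table(p, y)
        assert list(table["n"]) == [10] * 10
        assert table["mean_predicted"].is_monotonic_increasing
        assert int(table["n"].sum()) == 100

    def test_ties_kept_together(self):
        p = np.array([0.1] * 55 + [0.9] * 45)
        y = np.zeros(100)
        table = decile_table(p, y)
        assert len(table) == 2
        assert list(table["n"]) == [55, 45]

    def test_all_tied_is_degenerate(self):
        with pytest.raises(DegenerateMetricError):
            decile_table([0.5] * 100, [0, 1] * 50)

    def test_too_few_observations(self):
        from iciss import ValidationError

        with pytest.raises(ValidationError):
            decile_table([0.1] * 5, [0] * 5)

    def test_monotone_risk_shows_monotone_mortality(self, small_synthetic):
        from iciss import complete_case_filter, score_cohort
        from iciss.simulate import titco_like_spec, true_survival_table

        spec = titco_like_spec(11, n_patients=2000)
        cohort = complete_case_filter(small_synthetic).cohort
        result = score_cohort(cohort, true_survival_table(spec))
        y = [int(r.died_30d) for r in cohort]
        table = decile_table(result.predicted_mortality(), y)
        observed = table["observed"].to_numpy()
        # non-decreasing up to binomial noise: allow small inversions
        assert np.all(np.diff(observed) > -0.08)


class TestBootstrap:
    def test_constant_metric_gives_zero_width_interval(self):
        p = [0.9, 0.8, 0.1, 0.2] * 10
        y = [1, 1, 0, 0] * 10
        ci = bootstrap_ci(auroc, p, y, n_draws=200, seed=4)
        assert ci.lower == ci.upper == ci.point == 1.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        p = rng.random(200)
        y = (rng.random(200) < p).astype(int)
        a = bootstrap_ci(auroc, p, y, n_draws=300, seed=9)
        b = bootstrap_ci(auroc, p, y, n_draws=300, seed=9)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_interval_brackets_point(self):
        rng = np.random.default_rng(6)
        p = rng.random(300)
        y = (rng.random(300) < p).astype(int)
        ci = bootstrap_ci(auroc, p, y, n_draws=300, seed=1)
        assert ci.lower <= ci.point <= ci.upper

    def test_width_shrinks_at_root_n_rate(self):
        """Percentile-interval width for the sample mean ~ 1/sqrt(n)."""
        mean_metric = lambda p, y: float(np.mean(p))
        rng = np.random.default_rng(7)
        widths = {}
        for n in (250, 1000, 4000):
            x = rng.normal(0, 1, n)
            ci = bootstrap_ci(mean_metric, x, np.zeros(n), n_draws=400, seed=2)
            widths[n] = ci.upper - ci.lower
        assert widths[250] / widths[1000] == pytest.approx(2.0, rel=0.25)
        assert widths[1000] / widths[4000] == pytest.approx(2.0, rel=0.25)

    def test_single_class_resamples_are_redrawn(self):
        # 1 death among 12: many resamples miss the death entirely
        p = [0.9] + [0.1] * 11
        y = [1] + [0] * 11
        ci = bootstrap_ci(auroc, p, y, n_draws=150, seed=3)
        assert ci.n_redraws > 0
        assert np.isfinite(ci.lower) and np.isfinite(ci.upper)


class TestReports:
    def test_full_report_and_roundtrip(self):
        rng = np.random.default_rng(8)
        p = rng.random(400)
        y = (rng.random(400) < p).astype(int)
        report = evaluate_performance(p, y, n_bootstrap=100, seed=12)
        for ci in (report.auroc, report.cal_slope, report.cal_intercept):
            assert ci.lower <= ci.point <= ci.upper
        assert int(report.decile_table["n"].sum()) == 400
        back = PerformanceReport.from_dict(report.as_dict())
        assert back.auroc.point == report.auroc.point
        assert back.decile_table.equals(
            report.decile_table.reset_index(drop=True)
        )

    def test_matrix_produces_four_distinct_reports(self):
        rng = np.random.default_rng(9)
        n = 300
        risk = rng.uniform(0.05, 0.6, n)
        y30 = (rng.random(n) < risk).astype(int)
        y24 = (y30 & (rng.random(n) < 0.3)).astype(int)
        if y24.sum() == 0:
            y24[np.argmax(risk)] = 1
        scores = {"ICISSm30d": risk, "ICISSm24h": risk * 0.3}
        outcomes = {"m30d": y30, "m24h": y24}
        grid = evaluate_matrix(scores, outcomes, n_bootstrap=60, seed=1)
        assert set(grid) == {
            ("m30d", "ICISSm30d"),
            ("m30d", "ICISSm24h"),
            ("m24h", "ICISSm24h"),
            ("m24h", "ICISSm30d"),
        }
        assert len({id(r) for r in grid.values()}) == 4
        for report in grid.values():
            assert report.auroc.point > 0.5  # risk is informative by design
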