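"""Error statistics, BHS/AAMI standards, Bland-Altman, regression."""

import numpy as np
import pytest

from ppg2bp import evaluate
from ppg2bp.evaluate import (
    aami_check,
    bhs_grade,
    bhs_grade_from_percentages,
    bland_altman,
    linear_fit,
    mae_rmse,
    waveform_r_stats,
)
from ppg2bp.signal_io import Beat


def test_mae_rmse_examples():
    assert mae_rmse([0.0, 0.0, 0.0]) == (0.0, 0.0)
    mae, rmse = mae_rmse([1.0, -1.0, 2.0])
    assert mae == pytest.approx(4.0 / 3.0)
    assert rmse == pytest.approx(np.sqrt(2.0))
    assert mae_rmse([-3.5]) == (3.5, 3.5)
    with pytest.raises(ValueError):
        mae_rmse([])


def test_rmse_dominates_mae(rng):
    """Power-mean inequality on random error vectors."""
    for _ in range(30):
        errors = rng.normal(scale=rng.uniform(0.1, 10), size=rng.integers(1, 200))
        mae, rmse = mae_rmse(errors)
        assert rmse >= mae >= 0


def test_bhs_grades_from_percentages():
    assert bhs_grade_from_percentages(80.1, 93.9, 97.6) == "A"
    assert bhs_grade_from_percentages(93.9, 98.1, 99.2) == "A"
    assert bhs_grade_from_percentages(100.0, 100.0, 100.0) == "A"
    # meets all of B's thresholds but fails A's
    assert bhs_grade_from_percentages(55.0, 80.0, 92.0) == "B"
    assert bhs_grade_from_percentages(45.0, 70.0, 86.0) == "C"
    assert bhs_grade_from_percentages(30.0, 50.0, 70.0) == "D"


def test_bhs_grade_counts_inclusive_thresholds():
    errors = np.array([5.0, -10.0, 15.0, 20.0])
    p5, p10, p15, grade = bhs_grade(errors)
    assert (p5, p10, p15) == (25.0, 50.0, 75.0)
    assert grade == "D"


def test_bhs_grade_monotone_under_error_shrinkage(rng):
    """Scaling every error toward zero never worsens the grade."""
    order = {"A": 0, "B": 1, "C": 2, "D": 3}
    for _ in range(20):
        errors = rng.normal(scale=rng.uniform(2, 12), size=100)
        g_before = bhs_grade(errors)[3]
        g_after = bhs_grade(0.5 * errors)[3]
        assert order[g_after] <= order[g_before]


def test_aami_check_on_study_scale_statistics():
    assert aami_check(3.96, 5.36, 3183)
    assert aami_check(2.39, 3.28, 3183)
    assert not aami_check(5.0, 5.0, 100)  # mean error not < 5
    assert not aami_check(4.0, 8.0, 100)  # STD not < 8
    assert not aami_check(4.0, 5.0, 85)  # needs more than 85 subjects


def test_bland_altman_unit_and_degenerate_cases():
    errors = np.array([-1.0, 1.0]) / np.std([-1.0, 1.0], ddof=1)
    mu, sigma, lo, hi = bland_altman(errors)
    assert (mu, sigma) == pytest.approx((0.0, 1.0))
    assert (lo, hi) == pytest.approx((-1.96, 1.96))
    mu, sigma, lo, hi = bland_altman([3.0, 3.0, 3.0])
    assert (mu, sigma, lo, hi) == (3.0, 0.0, 3.0, 3.0)
    with pytest.raises(ValueError):
        bland_altman([1.0])


def test_bland_altman_limit_width_identity():
    """upper = lower + 2*1.96*sigma, checked at sigma = 5.36."""
    sigma = 5.36
    errors = np.array([-sigma, sigma]) / np.sqrt(2.0) + 1.41
    _, s, lo, hi = bland_altman(errors)
    assert s == pytest.approx(sigma)
    assert hi == pytest.approx(lo + 2 * 1.96 * sigma)
    assert hi - lo == pytest.approx(2 * 1.96 * 5.36, abs=1e-9)


def test_bland_altman_gaussian_coverage():
    """The limits contain ~95% of draws from a normal distribution."""
    rng = np.random.default_rng(7)
    errors = rng.normal(loc=1.0, scale=4.0, size=100_000)
    _, _, lo, hi = bland_altman(errors)
    coverage = np.mean((errors >= lo) & (errors <= hi))
    assert coverage == pytest.approx(0.95, abs=0.02)


def test_linear_fit_identity_and_affine(rng):
    t = rng.uniform(80, 180, size=50)
    assert linear_fit(t, t) == pytest.approx((1.0, 0.0, 1.0))
    slope, intercept, r = linear_fit(t, 2.0 * t + 3.0)
    assert (slope, intercept, r) == pytest.approx((2.0, 3.0, 1.0))


def test_linear_fit_matches_normal_equations(rng):
    t = rng.uniform(80, 180, size=200)
    p = 0.9 * t + 14 + rng.normal(scale=5.0, size=200)
    slope, intercept, r = linear_fit(t, p)
    design = np.column_stack([t, np.ones_like(t)])
    beta = np.linalg.solve(design.T @ design, design.T @ p)
    assert slope == pytest.approx(beta[0], abs=1e-10)
    assert intercept == pytest.approx(beta[1], abs=1e-10)
    with pytest.raises(ValueError):
        linear_fit(np.full(10, 5.0), rng.normal(size=10))


def _beats(arrays):
    return [Beat(samples=a, fs=len(a) / 1.0) for a in arrays]


def test_waveform_r_stats_identical_and_inverted(rng):
    t = np.linspace(0, 2 * np.pi, 100)
    waves = [100 + 10 * np.sin(t + k) for k in range(4)]
    stats = waveform_r_stats(_beats(waves), _beats(waves))
    assert stats["mean"] == stats["p25"] == stats["p75"] == 1.0
    flipped = [waves[0], *waves[1:]]
    flipped[0] = 200 - waves[0]
    stats = waveform_r_stats(_beats(flipped), _beats(waves))
    assert stats["min"] == pytest.approx(-1.0)


def test_waveform_r_percentiles_match_sort_oracle(rng):
    t = np.linspace(0, 2 * np.pi, 80)
    targets = [100 + 10 * np.sin(t) + rng.normal(size=80) for _ in range(21)]
    preds = [100 + 10 * np.sin(t) + rng.normal(size=80) for _ in range(21)]
    stats = waveform_r_stats(_beats(preds), _beats(targets))
    rs = np.sort(stats["values"])
    # linear interpolation between order statistics at q in {25, 75}
    for q, key in ((25.0, "p25"), (75.0, "p75")):
        pos = q / 100.0 * (rs.size - 1)
        k = int(np.floor(pos))
        expected = rs[k] + (pos - k) * (rs[min(k + 1, rs.size - 1)] - rs[k])
        assert stats[key] == pytest.approx(expected, abs=1e-12)


def test_waveform_r_resamples_mismatched_lengths():
    t1 = np.linspace(0, 2 * np.pi, 90)
    t2 = np.linspace(0, 2 * np.pi, 110)
    stats = waveform_r_stats(
        _beats([100 + np.sin(t1)]), _beats([50 + 3 * np.sin(t2)])
    )
    assert stats["mean"] > 0.999


def test_evaluate_predictions_report_structure(small_cohort):
    beats = [p.bp for p in small_cohort.pairs[:20]]
    report = evaluate.evaluate_predictions(beats, beats)
    assert report["sbp"]["mae"] == 0.0
    assert report["dbp"]["rmse"] == 0.0
    assert report["sbp"]["bhs"]["grade"] == "A"
    assert report["waveform_r"]["mean"] == pytest.approx(1.0)
    text = evaluate.summary_text(report)
    assert "Grade" in text and "AAMI" in text
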