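"""Accuracy metrics and clinical validation standards for BP estimation.

Covers per-beat error statistics (MAE, RMSE, mean error, error STD),
the British Hypertension Society (BHS) cumulative-error grading, the
AAMI pass/fail criterion, Bland-Altman 95% limits of agreement,
ordinary-least-squares diagnostics of predictions on targets, and
summary statistics of the per-beat waveform correlation.

Conventions: errors are signed (predicted - target) in mmHg; the error
STD and Bland-Altman sigma use the sample (n-1) standard deviation; BHS
cumulative thresholds are inclusive (|error| <= 5/10/15 mmHg); percentiles
use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ppg2bp.harmonics import extract_sbp_dbp
from ppg2bp.preprocess import pearson_r
from ppg2bp.signal_io import Beat

#: BHS grade thresholds: minimum cumulative percentages within 5/10/15 mmHg
BHS_GRADES = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}

AAMI_MAX_ERROR = 5.0  # mmHg
AAMI_MAX_STD = 8.0  # mmHg
AAMI_MIN_SUBJECTS = 85


def mae_rmse(errors: np.ndarray) -> tuple[float, float]:
    """Mean absolute error and root mean square error of a signed error
    sequence."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("cannot compute MAE/RMSE of an empty error sequence")
    return float(np.mean(np.abs(errors))), float(np.sqrt(np.mean(errors**2)))


def bhs_grade_from_percentages(p5: float, p10: float, p15: float) -> str:
    """BHS grade for given cumulative error percentages.

    The best grade whose three thresholds are ALL met; "D" otherwise.
    """
    for grade, (t5, t10, t15) in BHS_GRADES.items():
        if p5 >= t5 and p10 >= t10 and p15 >= t15:
            return grade
    return "D"


def bhs_grade(errors: np.ndarray) -> tuple[float, float, float, str]:
    """Cumulative error percentages within 5/10/15 mmHg and the BHS grade."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("cannot grade an empty error sequence")
    a = np.abs(errors)
    p5, p10, p15 = (100.0 * float(np.mean(a <= t)) for t in (5.0, 10.0, 15.0))
    return p5, p10, p15, bhs_grade_from_percentages(p5, p10, p15)


def aami_check(mae: float, std: float, n_subjects: int) -> bool:
    """AAMI criterion: mean error < 5 mmHg, error STD < 8 mmHg, more than
    85 subjects."""
    return mae < AAMI_MAX_ERROR and std < AAMI_MAX_STD and n_subjects > AAMI_MIN_SUBJECTS


def bland_altman(errors: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, sample SD, and 95% limits of agreement (mu -/+ 1.96 sigma)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size < 2:
        raise ValueError("Bland-Altman needs at least 2 errors")
    mu = float(np.mean(errors))
    sigma = float(np.std(errors, ddof=1))
    return mu, sigma, mu - 1.96 * sigma, mu + 1.96 * sigma


def linear_fit(targets: np.ndarray, predictions: np.ndarray) -> tuple[float, float, float]:
    """OLS regression of predictions on targets: (slope, intercept, R).

    R is the Pearson correlation between targets and predictions.
    """
    t = np.asarray(targets, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if t.size != p.size or t.size < 3:
        raise ValueError("linear_fit needs >= 3 paired points")
    if np.ptp(t) == 0:
        raise ValueError("targets are constant; slope undefined")
    tc = t - t.mean()
    slope = float(np.dot(tc, p) / np.dot(tc, tc))
    intercept = float(p.mean() - slope * t.mean())
    return slope, intercept, pearson_r(t, p)


def _percentile(values: np.ndarray, q: float) -> float:
    return float(np.percentile(values, q, method="linear"))


def waveform_r_stats(
    pred_beats: list[Beat], target_beats: list[Beat]
) -> dict[str, float]:
    """Per-pair Pearson correlation between predicted and target waveforms.

    Each predicted beat is linearly resampled to its target's length.
    Returns mean, min, max and the 25th/75th percentiles of r.
    """
    if len(pred_beats) != len(target_beats):
        raise ValueError("prediction and target beat lists differ in length")
    if not pred_beats:
        raise ValueError("no beats to correlate")
    rs = []
    for pred, target in zip(pred_beats, target_beats):
        n = target.samples.size
        resampled = np.interp(
            np.linspace(0.0, 1.0, n),
            np.linspace(0.0, 1.0, pred.samples.size),
            pred.samples,
        )
        rs.append(pearson_r(resampled, target.samples))
    rs = np.asarray(rs)
    return {
        "mean": float(np.mean(rs)),
        "min": float(np.min(rs)),
        "max": float(np.max(rs)),
        "p25": _percentile(rs, 25.0),
        "p75": _percentile(rs, 75.0),
        "values": rs.tolist(),
    }


@dataclass
class QuantityStats:
    """Error statistics for one pressure quantity (SBP or DBP)."""

    errors: np.ndarray
    n_subjects: int
    mae: float = field(init=False)
    rmse: float = field(init=False)
    mean_error: float = field(init=False)
    std_error: float = field(init=False)

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=float)
        self.mae, self.rmse = mae_rmse(self.errors)
        self.mean_error = float(np.mean(self.errors))
        self.std_error = float(np.std(self.errors, ddof=1)) if self.errors.size > 1 else 0.0

    def to_dict(self, targets: np.ndarray | None = None, predictions: np.ndarray | None = None) -> dict:
        p5, p10, p15, grade = bhs_grade(self.errors)
        out = {
            "n": int(self.errors.size),
            "mae": self.mae,
            "rmse": self.rmse,
            "mean_error": self.mean_error,
            "std_error": self.std_error,
            "bhs": {"p5": p5, "p10": p10, "p15": p15, "grade": grade},
            "aami_pass": aami_check(self.mae, self.std_error, self.n_subjects),
        }
        if self.errors.size >= 2:
            mu, sigma, lo, hi = bland_altman(self.errors)
            out["bland_altman"] = {"mu": mu, "sigma": sigma, "lower": lo, "upper": hi}
        if targets is not None and np.ptp(targets) > 0 and targets.size >= 3:
            slope, intercept, r = linear_fit(targets, predictions)
            out["linear_fit"] = {"slope": slope, "intercept": intercept, "R": r}
        return out


def evaluate_predictions(
    pred_beats: list[Beat],
    target_beats: list[Beat],
    n_subjects: int | None = None,
) -> dict:
    """Full evaluation report for predicted vs target BP beats.

    SBP/DBP are extracted from each waveform (max/min sample); errors are
    predicted - target. ``n_subjects`` defaults to the number of distinct
    subject IDs among the target beats.
    """
    if len(pred_beats) != len(target_beats) or not pred_beats:
        raise ValueError("need equal, non-empty prediction and target lists")
    if n_subjects is None:
        n_subjects = len({b.subject_id for b in target_beats})
    sbp_p, dbp_p = zip(*(extract_sbp_dbp(b) for b in pred_beats))
    sbp_t, dbp_t = zip(*(extract_sbp_dbp(b) for b in target_beats))
    sbp_t = np.asarray(sbp_t)
    dbp_t = np.asarray(dbp_t)
    sbp_p = np.asarray(sbp_p)
    dbp_p = np.asarray(dbp_p)
    report = {
        "n_beats": len(pred_beats),
        "n_subjects": int(n_subjects),
        "sbp": QuantityStats(sbp_p - sbp_t, n_subjects).to_dict(sbp_t, sbp_p),
        "dbp": QuantityStats(dbp_p - dbp_t, n_subjects).to_dict(dbp_t, dbp_p),
        "waveform_r": waveform_r_stats(pred_beats, target_beats),
    }
    return report


def summary_text(report: dict) -> str:
    """Human-readable rendering of an evaluation report."""
    lines = [
        f"Beats evaluated : {report['n_beats']}  (subjects: {report['n_subjects']})",
        "",
        f"{'':14}{'MAE':>8}{'RMSE':>8}{'STD':>8}",
    ]
    for name in ("sbp", "dbp"):
        q = report[name]
        lines.append(
            f"{name.upper():14}{q['mae']:8.2f}{q['rmse']:8.2f}{q['std_error']:8.2f}"
        )
    lines.append("")
    lines.append(f"{'':14}{'<=5mmHg':>9}{'<=10mmHg':>10}{'<=15mmHg':>10}{'Grade':>7}")
    for name in ("sbp", "dbp"):
        b = report[name]["bhs"]
        lines.append(
            f"{name.upper():14}{b['p5']:8.1f}%{b['p10']:9.1f}%{b['p15']:9.1f}%"
            f"{b['grade']:>7}"
        )
    lines.append("")
    for name in ("sbp", "dbp"):
        q = report[name]
        verdict = "pass" if q["aami_pass"] else "fail"
        lines.append(f"AAMI ({name.upper()}): {verdict}")
        if "bland_altman" in q:
            ba = q["bland_altman"]
            lines.append(
                f"Bland-Altman ({name.upper()}): mu={ba['mu']:.2f}, "
                f"limits [{ba['lower']:.2f}, {ba['upper']:.2f}] mmHg"
            )
        if "linear_fit" in q:
            lf = q["linear_fit"]
            lines.append(
                f"Linear fit ({name.upper()}): pred = {lf['slope']:.2f}*target "
                f"+ {lf['intercept']:.2f}, R = {lf['R']:.3f}"
            )
    wr = report["waveform_r"]
    lines.append(
        f"Waveform r: mean={wr['mean']:.3f} min={wr['min']:.3f} "
        f"max={wr['max']:.3f} p25={wr['p25']:.3f} p75={wr['p75']:.3f}"
    )
    return "\n".join(lines)
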