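"""Truncated-Fourier-series codec for single-period beats.

A beat of period T is represented as

    x(t) = dc + sum_{n=1..N} A_n * cos(n*w0*t + phi_n),      w0 = 2*pi/T

The encoder fits the series by ordinary linear least squares on the
cos/sin basis {cos(n*w0*t), sin(n*w0*t)} (plus a constant when a DC term
is fitted) and converts the a/b coefficients to amplitude/phase. The
amplitude-phase parameterization is nonlinear, but the problem is exactly
linear in a/b, so the residual is the global optimum of the fit.

Conventions: N = 9 harmonics for PPG (band-passed, no DC) and N = 17 for
BP (DC = mean arterial level, in mmHg). Feature vectors flatten a code as
[A_1..A_N, phi_1..phi_N] for PPG and [dc, A_1..A_N, phi_1..phi_N] for BP,
so the default dimensionalities are 18 and 35. Phases are wrapped to
(-pi, pi] and set to 0 by convention wherever the amplitude vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ppg2bp.signal_io import Beat

N_PPG_HARMONICS = 9
N_BP_HARMONICS = 17

#: amplitudes below this are treated as zero when assigning phases
_AMP_TOL = 1e-12


def wrap_phase(phi: np.ndarray | float):
    """Wrap angle(s) to the interval (-pi, pi]."""
    return -((-np.asarray(phi) + np.pi) % (2.0 * np.pi) - np.pi)


@dataclass
class HarmonicCode:
    """Amplitude/phase representation of one beat's truncated Fourier series."""

    period_s: float
    amplitudes: np.ndarray
    phases: np.ndarray
    dc: float = 0.0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.phases = wrap_phase(np.asarray(self.phases, dtype=float))
        if self.period_s <= 0:
            raise ValueError("period must be positive")
        if self.amplitudes.ndim != 1 or self.amplitudes.size < 1:
            raise ValueError("need at least one harmonic")
        if self.amplitudes.shape != self.phases.shape:
            raise ValueError("amplitudes and phases must have equal length")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be nonnegative")

    @property
    def n_harmonics(self) -> int:
        return self.amplitudes.size

    @property
    def omega0(self) -> float:
        """Fundamental angular frequency 2*pi/T in rad/s."""
        return 2.0 * np.pi / self.period_s


def _design_matrix(t: np.ndarray, omega0: float, n_harmonics: int, fit_dc: bool) -> np.ndarray:
    cols = []
    if fit_dc:
        cols.append(np.ones_like(t))
    for n in range(1, n_harmonics + 1):
        cols.append(np.cos(n * omega0 * t))
        cols.append(np.sin(n * omega0 * t))
    return np.column_stack(cols)


def encode(beat: Beat, n_harmonics: int, fit_dc: bool = False) -> HarmonicCode:
    """Least-squares fit of a truncated Fourier series to one beat.

    The fit minimizes the sum of squared residuals between the beat's
    samples and the series evaluated on the beat's own time grid
    t_k = k / fs, with T = the beat's period. Requires at least
    2*N + 2 samples for identifiability.
    """
    m = beat.samples.size
    if m < 2 * n_harmonics + 2:
        raise ValueError(
            f"beat of {m} samples cannot identify {n_harmonics} harmonics "
            f"(need >= {2 * n_harmonics + 2})"
        )
    t = np.arange(m) / beat.fs
    omega0 = 2.0 * np.pi / beat.period_s
    design = _design_matrix(t, omega0, n_harmonics, fit_dc)
    coef, _, rank, _ = np.linalg.lstsq(design, beat.samples, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient harmonic design (duplicate time points?)")
    if fit_dc:
        dc, ab = float(coef[0]), coef[1:]
    else:
        dc, ab = 0.0, coef
    a = ab[0::2]
    b = ab[1::2]
    # a*cos(nwt) + b*sin(nwt) = A*cos(nwt + phi), A = hypot(a, b),
    # phi = atan2(-b, a); zero-amplitude phases are 0 by convention
    amplitudes = np.hypot(a, b)
    phases = np.where(amplitudes > _AMP_TOL, np.arctan2(-b, a), 0.0)
    amplitudes = np.where(amplitudes > _AMP_TOL, amplitudes, 0.0)
    return HarmonicCode(
        period_s=beat.period_s, amplitudes=amplitudes, phases=phases, dc=dc
    )


def decode(
    code: HarmonicCode,
    n_samples: int,
    subject_id: str = "",
    segment_id: str = "",
    beat_id: int = 0,
    channel: str = "PPG",
) -> Beat:
    """Sample the series at t_k = k*T/n_samples, k = 0..n_samples-1.

    The returned beat's sampling rate is n_samples/T, so its period
    equals the code's period exactly and decode(encode(x), len(x))
    reproduces x on the span of the basis.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples to decode")
    t = np.arange(n_samples) * (code.period_s / n_samples)
    n = np.arange(1, code.n_harmonics + 1)[:, None]
    series = code.dc + np.sum(
        code.amplitudes[:, None] * np.cos(n * code.omega0 * t[None, :] + code.phases[:, None]),
        axis=0,
    )
    return Beat(
        samples=series,
        fs=n_samples / code.period_s,
        subject_id=subject_id,
        segment_id=segment_id,
        beat_id=beat_id,
        channel=channel,
        filtered=(channel == "PPG"),
    )


def extract_sbp_dbp(beat: Beat) -> tuple[float, float]:
    """Systolic and diastolic pressure of a decoded BP beat.

    SBP is the maximum sample, DBP the minimum; ties resolve to the first
    occurrence.
    """
    if beat.samples.size == 0:
        raise ValueError("cannot extract pressures from an empty beat")
    return float(beat.samples[np.argmax(beat.samples)]), float(
        beat.samples[np.argmin(beat.samples)]
    )


def to_feature_vector(code: HarmonicCode, include_dc: bool) -> np.ndarray:
    """Flatten a code to [amp_1..amp_N, phase_1..phase_N], with the DC term
    prepended for BP codes."""
    parts = [code.amplitudes, code.phases]
    if include_dc:
        parts.insert(0, np.array([code.dc]))
    return np.concatenate(parts)


def from_feature_vector(
    vec: np.ndarray, period_s: float, include_dc: bool
) -> HarmonicCode:
    """Inverse of :func:`to_feature_vector` (given the beat period).

    Predicted amplitudes may carry small negative excursions (the
    regressor averages training codes); a negative amplitude is folded to
    positive with a pi phase flip, preserving the waveform.
    """
    vec = np.asarray(vec, dtype=float)
    if include_dc:
        dc, rest = float(vec[0]), vec[1:]
    else:
        dc, rest = 0.0, vec
    if rest.size % 2 != 0:
        raise ValueError("feature vector has mismatched amplitude/phase halves")
    n = rest.size // 2
    amplitudes = rest[:n].copy()
    phases = rest[n:].copy()
    negative = amplitudes < 0
    amplitudes[negative] *= -1.0
    phases[negative] += np.pi
    return HarmonicCode(
        period_s=period_s, amplitudes=amplitudes, phases=phases, dc=dc
    )


def ppg_feature_vector(code: HarmonicCode) -> np.ndarray:
    return to_feature_vector(code, include_dc=False)


def bp_feature_vector(code: HarmonicCode) -> np.ndarray:
    return to_feature_vector(code, include_dc=True)
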