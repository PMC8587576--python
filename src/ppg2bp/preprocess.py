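"""Signal conditioning and quality control for paired PPG/BP waveforms.

The chain mirrors standard cuffless-BP curation practice:

1. band-pass the PPG channel (third-order Butterworth, 0.5-8 Hz, zero-phase)
   to strip baseline wander and high-frequency noise;
2. drop beats whose systolic peak is missing or degenerate;
3. drop beat pairs whose BP extrema fall outside the physiologic admission
   window (SBP strictly inside (80, 180) mmHg, DBP strictly inside
   (60, 130) mmHg) -- applied to the *unfiltered* BP channel so absolute
   pressure is meaningful;
4. drop whole segments whose mean PPG-BP Pearson correlation is below 0.8.

Beats are extracted foot-to-foot: systolic peaks are found with an
adaptive moving-mean threshold (0.75 s window) and each foot is the local
minimum in the preceding inter-peak interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from ppg2bp.signal_io import Beat, BeatPair, WaveformRecord


@dataclass
class QCConfig:
    """Thresholds for filtering and beat-level quality control.

    Attributes
    ----------
    band_lo, band_hi : float
        Pass-band edges in Hz for the PPG band-pass filter.
    filter_order : int
        Butterworth order (applied forward-backward, so the effective
        attenuation is doubled).
    sbp_lo, sbp_hi, dbp_lo, dbp_hi : float
        Admissible open intervals for beat systolic / diastolic pressure
        in mmHg; beats on or outside the bounds are rejected.
    r_min : float
        Minimum per-segment mean Pearson correlation between paired PPG
        and BP beats. ``r_min <= 0`` disables the correlation filter.
    min_beat_s, max_beat_s : float
        Admissible single-beat durations in seconds.
    peak_window_s : float
        Moving-mean window for adaptive systolic-peak detection.
    foot_match_s : float
        Maximum PPG-to-BP foot misalignment; BP feet are located within
        this window around each PPG foot.
    """

    band_lo: float = 0.5
    band_hi: float = 8.0
    filter_order: int = 3
    sbp_lo: float = 80.0
    sbp_hi: float = 180.0
    dbp_lo: float = 60.0
    dbp_hi: float = 130.0
    r_min: float = 0.8
    min_beat_s: float = 0.3
    max_beat_s: float = 1.5
    peak_window_s: float = 0.75
    foot_match_s: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.band_lo < self.band_hi:
            raise ValueError("need 0 < band_lo < band_hi")
        if self.sbp_lo >= self.sbp_hi or self.dbp_lo >= self.dbp_hi:
            raise ValueError("BP range bounds must satisfy lo < hi")
        if self.r_min > 1:
            raise ValueError("r_min cannot exceed 1")
        if self.min_beat_s <= 0 or self.min_beat_s >= self.max_beat_s:
            raise ValueError("need 0 < min_beat_s < max_beat_s")


def bandpass(record: WaveformRecord, cfg: QCConfig | None = None) -> WaveformRecord:
    """Zero-phase Butterworth band-pass of a waveform record.

    Forward-backward application preserves foot and peak timing, which
    segmentation and the harmonic phase fit rely on. The output has the
    same length and sampling rate; its DC component is removed, so the
    result is flagged ``filtered``.
    """
    cfg = cfg or QCConfig()
    nyq = record.fs / 2.0
    if cfg.band_hi >= nyq:
        raise ValueError(
            f"upper band edge {cfg.band_hi} Hz must be below Nyquist ({nyq} Hz)"
        )
    sos = butter(
        cfg.filter_order,
        [cfg.band_lo, cfg.band_hi],
        btype="bandpass",
        fs=record.fs,
        output="sos",
    )
    # sosfiltfilt pads with 3x the section count on each side; require
    # a comfortable margin so edge transients cannot dominate
    warmup = 3 * (2 * sos.shape[0] + 1)
    if record.signal.size <= 3 * warmup:
        raise ValueError(
            f"signal of {record.signal.size} samples too short for stable "
            f"order-{cfg.filter_order} band-pass filtering"
        )
    y = sosfiltfilt(sos, record.signal)
    return WaveformRecord(
        subject_id=record.subject_id,
        signal=y,
        fs=record.fs,
        units=record.units,
        channel=record.channel,
        filtered=True,
    )


def detect_systolic_peaks(signal: np.ndarray, fs: float, cfg: QCConfig | None = None) -> np.ndarray:
    """Adaptive-threshold systolic peak detection.

    A sample run is a candidate beat region when the signal exceeds its
    moving mean (window ``peak_window_s``); the maximum of each
    sufficiently long run is a systolic peak. Peaks closer together than
    ``min_beat_s`` are merged, keeping the taller one.
    """
    cfg = cfg or QCConfig()
    x = np.asarray(signal, dtype=float)
    win = max(3, int(round(cfg.peak_window_s * fs)))
    threshold = uniform_filter1d(x, size=win, mode="nearest")
    above = x > threshold
    if not above.any():
        return np.array([], dtype=int)
    # contiguous runs of "above threshold"
    boundaries = np.flatnonzero(np.diff(above.astype(int)) != 0) + 1
    runs = np.split(np.arange(x.size), boundaries)
    min_run = max(2, int(round(0.04 * fs)))  # ignore sub-40 ms blips
    peaks = []
    for run in runs:
        if run.size >= min_run and above[run[0]]:
            peaks.append(run[0] + int(np.argmax(x[run])))
    if not peaks:
        return np.array([], dtype=int)
    # enforce refractory distance
    min_dist = int(round(cfg.min_beat_s * fs))
    kept = [peaks[0]]
    for p in peaks[1:]:
        if p - kept[-1] < min_dist:
            if x[p] > x[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    return np.asarray(kept, dtype=int)


def find_feet(signal: np.ndarray, fs: float, cfg: QCConfig | None = None) -> np.ndarray:
    """Locate beat feet: the local minimum immediately preceding each
    detected systolic peak."""
    cfg = cfg or QCConfig()
    x = np.asarray(signal, dtype=float)
    peaks = detect_systolic_peaks(x, fs, cfg)
    if peaks.size < 2:
        return np.array([], dtype=int)
    feet = []
    lookback = int(round(cfg.max_beat_s * fs))
    for i, p in enumerate(peaks):
        lo = peaks[i - 1] if i > 0 else max(0, p - lookback)
        if p - lo < 2:
            continue
        feet.append(lo + int(np.argmin(x[lo:p])))
    return np.unique(np.asarray(feet, dtype=int))


def segment_beats(record: WaveformRecord, cfg: QCConfig | None = None) -> list[Beat]:
    """Cut a quasi-periodic record into consecutive foot-to-foot beats.

    Beats with durations outside ``[min_beat_s, max_beat_s]`` are dropped.
    A record with no detectable periodicity yields an empty list (with a
    warning), never an exception.
    """
    cfg = cfg or QCConfig()
    feet = find_feet(record.signal, record.fs, cfg)
    if feet.size < 2:
        warnings.warn(
            f"no beats found in record {record.subject_id!r} (flat or aperiodic)",
            stacklevel=2,
        )
        return []
    beats = []
    for bid, (a, b) in enumerate(zip(feet[:-1], feet[1:])):
        duration = (b - a) / record.fs
        if not (cfg.min_beat_s <= duration <= cfg.max_beat_s):
            continue
        beats.append(
            Beat(
                samples=record.signal[a:b].copy(),
                fs=record.fs,
                subject_id=record.subject_id,
                segment_id=f"{record.subject_id}-seg0",
                beat_id=bid,
                channel=record.channel,
                filtered=record.filtered,
            )
        )
    return beats


def segment_pairs(
    ppg: WaveformRecord,
    bp: WaveformRecord,
    cfg: QCConfig | None = None,
    segment_id: str | None = None,
) -> list[BeatPair]:
    """Segment synchronized PPG and BP records into one-to-one beat pairs.

    Feet are detected on the PPG channel; each BP foot is the BP minimum
    within ``foot_match_s`` of the corresponding PPG foot, so the two
    channels are cut at physiologically matched onsets.
    """
    cfg = cfg or QCConfig()
    if ppg.fs != bp.fs:
        raise ValueError("PPG and BP records must share a sampling rate")
    seg = segment_id or f"{ppg.subject_id}-seg0"
    ppg_feet = find_feet(ppg.signal, ppg.fs, cfg)
    if ppg_feet.size < 2:
        warnings.warn(f"no beats found for subject {ppg.subject_id!r}", stacklevel=2)
        return []
    delta = int(round(cfg.foot_match_s * bp.fs))
    bp_feet = []
    for f in ppg_feet:
        lo = max(0, f - delta)
        hi = min(bp.signal.size, f + delta + 1)
        bp_feet.append(lo + int(np.argmin(bp.signal[lo:hi])))
    bp_feet = np.asarray(bp_feet, dtype=int)
    pairs = []
    for bid in range(ppg_feet.size - 1):
        pa, pb = ppg_feet[bid], ppg_feet[bid + 1]
        ba, bb = bp_feet[bid], bp_feet[bid + 1]
        dur_p = (pb - pa) / ppg.fs
        dur_b = (bb - ba) / bp.fs
        if not (cfg.min_beat_s <= dur_p <= cfg.max_beat_s):
            continue
        if not (cfg.min_beat_s <= dur_b <= cfg.max_beat_s):
            continue
        pairs.append(
            BeatPair(
                ppg=Beat(
                    samples=ppg.signal[pa:pb].copy(), fs=ppg.fs,
                    subject_id=ppg.subject_id, segment_id=seg, beat_id=bid,
                    channel="PPG", filtered=ppg.filtered,
                ),
                bp=Beat(
                    samples=bp.signal[ba:bb].copy(), fs=bp.fs,
                    subject_id=ppg.subject_id, segment_id=seg, beat_id=bid,
                    channel="ABP", filtered=bp.filtered,
                ),
            )
        )
    return pairs


def beat_quality_mask(beats: list[Beat]) -> np.ndarray:
    """Boolean keep-mask for systolic-peak quality control.

    Rejects beats whose sample range is degenerate, whose maximum sits on
    the beat boundary (no interior systolic peak), or whose peak-to-foot
    amplitude is below 10% of the cohort's median beat amplitude.
    Deterministic given input order.
    """
    if not beats:
        return np.array([], dtype=bool)
    amplitudes = np.array([b.samples.max() - b.samples.min() for b in beats])
    median_amp = float(np.median(amplitudes))
    keep = np.ones(len(beats), dtype=bool)
    for i, beat in enumerate(beats):
        amp = amplitudes[i]
        if amp < 1e-12:
            keep[i] = False
            continue
        peak = int(np.argmax(beat.samples))
        if peak == 0 or peak == beat.samples.size - 1:
            keep[i] = False
            continue
        if median_amp > 0 and amp < 0.1 * median_amp:
            keep[i] = False
    return keep


def beat_quality(beats: list[Beat]) -> list[Beat]:
    """Filter beats by systolic-peak quality (see :func:`beat_quality_mask`)."""
    mask = beat_quality_mask(beats)
    return [b for b, k in zip(beats, mask) if k]


def range_filter(pairs: list[BeatPair], cfg: QCConfig | None = None) -> list[BeatPair]:
    """Keep pairs whose BP beat extrema lie strictly inside the admissible
    SBP/DBP windows.

    The BP beat must carry absolute pressure (DC intact); a band-passed BP
    beat makes the rule meaningless and raises.
    """
    cfg = cfg or QCConfig()
    kept = []
    for pair in pairs:
        if pair.bp.filtered:
            raise ValueError(
                "range_filter needs absolute BP in mmHg; the BP beat is "
                "flagged as band-passed (DC removed)"
            )
        sbp = float(pair.bp.samples.max())
        dbp = float(pair.bp.samples.min())
        if cfg.sbp_lo < sbp < cfg.sbp_hi and cfg.dbp_lo < dbp < cfg.dbp_hi:
            kept.append(pair)
    return kept


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation between two equal-length sequences.

    Raises for sequences shorter than 3 or with zero variance (the
    coefficient is undefined for constant input).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson_r needs two 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError("pearson_r needs at least 3 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt(np.dot(xd, xd)))
    sy = float(np.sqrt(np.dot(yd, yd)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("Pearson correlation is undefined for constant input")
    r = float(np.dot(xd, yd) / (sx * sy))
    return max(-1.0, min(1.0, r))


def pair_pearson_r(pair: BeatPair) -> float:
    """Correlation between a pair's PPG beat (linearly resampled to the BP
    beat's length) and its BP beat."""
    n = pair.bp.samples.size
    src = pair.ppg.samples
    resampled = np.interp(
        np.linspace(0.0, 1.0, n), np.linspace(0.0, 1.0, src.size), src
    )
    return pearson_r(resampled, pair.bp.samples)


def pearson_qc(pairs: list[BeatPair], cfg: QCConfig | None = None) -> list[BeatPair]:
    """Remove whole segments whose mean PPG-BP correlation is below r_min.

    Pairs are grouped by (subject, segment); the mean of the per-pair
    correlations decides the group's fate, so a segment is kept or removed
    as a unit. ``r_min <= 0`` disables the filter.
    """
    cfg = cfg or QCConfig()
    if cfg.r_min <= 0:
        return list(pairs)
    groups: dict[tuple[str, str], list[float]] = {}
    for pair in pairs:
        groups.setdefault((pair.subject_id, pair.segment_id), []).append(
            pair_pearson_r(pair)
        )
    mean_r = {k: float(np.mean(v)) for k, v in groups.items()}
    return [p for p in pairs if mean_r[(p.subject_id, p.segment_id)] >= cfg.r_min]


def apply_qc(
    pairs: list[BeatPair], cfg: QCConfig | None = None, log: dict | None = None
) -> list[BeatPair]:
    """Run the full beat-level QC chain: peak quality, BP range, Pearson.

    ``log``, if given, collects per-rule rejection counts.
    """
    cfg = cfg or QCConfig()
    counts = {"input": len(pairs)}
    mask = beat_quality_mask([p.ppg for p in pairs])
    survivors = [p for p, k in zip(pairs, mask) if k]
    counts["peak_quality_rejected"] = len(pairs) - len(survivors)
    n = len(survivors)
    survivors = range_filter(survivors, cfg)
    counts["bp_range_rejected"] = n - len(survivors)
    n = len(survivors)
    survivors = pearson_qc(survivors, cfg)
    counts["pearson_rejected"] = n - len(survivors)
    counts["output"] = len(survivors)
    if log is not None:
        log.update(counts)
    return survivors
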