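"""Filtering, beat segmentation and quality-control rules."""

import numpy as np
import pytest
from scipy.signal import butter, sosfreqz

from ppg2bp import preprocess
from ppg2bp.harmonics import HarmonicCode, decode
from ppg2bp.preprocess import (
    QCConfig,
    apply_qc,
    bandpass,
    beat_quality,
    find_feet,
    pair_pearson_r,
    pearson_qc,
    pearson_r,
    range_filter,
    segment_beats,
    segment_pairs,
)
from ppg2bp.signal_io import Beat, BeatPair, WaveformRecord
from ppg2bp.synthetic import _foot_align

FS = 125.0


def _record(signal, channel="PPG", fs=FS, **kw):
    return WaveformRecord(subject_id="t", signal=signal, fs=fs, channel=channel, **kw)


def _filter_gain(freq, cfg=None):
    """Oracle: designed filter's zero-phase frequency response magnitude."""
    cfg = cfg or QCConfig()
    sos = butter(cfg.filter_order, [cfg.band_lo, cfg.band_hi], btype="bandpass",
                 fs=FS, output="sos")
    _, h = sosfreqz(sos, worN=[freq], fs=FS)
    return np.abs(h[0]) ** 2  # forward-backward squares the magnitude


def _steady_amplitude(signal, fs=FS):
    n = signal.size
    return np.abs(signal[n // 4 : 3 * n // 4]).max()


def test_bandpass_removes_dc():
    rec = _record(np.full(1000, 3.7))
    out = bandpass(rec)
    assert np.max(np.abs(out.signal[100:-100])) < 1e-6
    assert out.filtered and out.signal.size == 1000 and out.fs == FS


@pytest.mark.parametrize("freq, band", [(4.0, (0.95, 1.05)), (0.05, (0.0, 0.1))])
def test_bandpass_frequency_response(freq, band):
    """Steady-state amplitude of a sinusoid matches the designed filter's
    response (4 Hz is in-band; 0.05 Hz is far below the passband)."""
    t = np.arange(0, 8, 1 / FS)
    out = bandpass(_record(np.sin(2 * np.pi * freq * t)))
    amp = _steady_amplitude(out.signal)
    lo, hi = band
    assert lo <= amp <= hi
    # and agrees with the frequency-response oracle
    assert amp == pytest.approx(_filter_gain(freq), abs=0.05)


def test_bandpass_is_linear(rng):
    x = rng.normal(size=800)
    rec = _record(x)
    scaled = _record(4.2 * x)
    np.testing.assert_allclose(
        bandpass(scaled).signal, 4.2 * bandpass(rec).signal, atol=1e-9
    )


def test_bandpass_rejects_bad_band_and_short_signal():
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass(_record(np.zeros(1000), fs=10.0))
    with pytest.raises(ValueError, match="short"):
        bandpass(_record(np.zeros(20)))


def _beat_train(n_beats, period_samples=125, seed=5):
    rng = np.random.default_rng(seed)
    code = _foot_align(
        HarmonicCode(
            period_s=period_samples / FS,
            amplitudes=[1.0, 0.35, 0.12, 0.05],
            phases=rng.uniform(-np.pi, np.pi, 4),
        )
    )
    one = decode(code, period_samples).samples
    return np.tile(one, n_beats)


def test_segment_beats_recovers_known_feet():
    """Four identical 1 s beats -> 3 complete foot-to-foot beats of 125
    samples each; feet within 2 samples of the construction grid."""
    sig = _beat_train(4)
    feet = find_feet(sig, FS)
    expected = np.arange(0, 4 * 125, 125)
    matched = [np.min(np.abs(feet - e)) for e in expected[: len(feet)]]
    assert all(m <= 2 for m in matched)
    beats = segment_beats(_record(sig))
    assert len(beats) == 3
    assert all(b.samples.size == 125 for b in beats)


def test_segment_beats_constant_signal_warns_empty():
    with pytest.warns(UserWarning, match="aperiodic"):
        beats = segment_beats(_record(np.zeros(1000)))
    assert beats == []


def test_segment_beats_duration_filter():
    """A 0.2 s beat inserted between 1 s beats is dropped."""
    long_beat = _beat_train(1)
    short_beat = long_beat[::5][:25]  # same shape squeezed to 0.2 s
    sig = np.concatenate([long_beat, long_beat, short_beat, long_beat, long_beat])
    beats = segment_beats(_record(sig))
    durations = [b.period_s for b in beats]
    assert all(QCConfig().min_beat_s <= d <= QCConfig().max_beat_s for d in durations)


def test_segmentation_covers_contiguous_span():
    """Concatenating returned beats reproduces a contiguous slice of the
    input record."""
    sig = _beat_train(5)
    beats = segment_beats(_record(sig))
    joined = np.concatenate([b.samples for b in beats])
    start = int(np.flatnonzero(np.isclose(sig, joined[0]))[0])
    np.testing.assert_allclose(sig[start : start + joined.size], joined, atol=1e-12)


def test_segment_pairs_aligns_channels():
    ppg_sig = _beat_train(5)
    rng = np.random.default_rng(0)
    bp_sig = 100.0 + 15.0 * np.roll(ppg_sig, 3)  # slight lag, DC intact
    pairs = segment_pairs(_record(ppg_sig), _record(bp_sig, channel="ABP"))
    assert len(pairs) >= 3
    for p in pairs:
        assert p.ppg.subject_id == p.bp.subject_id
        assert abs(p.ppg.samples.size - p.bp.samples.size) <= 0.25 * FS
        # BP segment starts at a local BP minimum (its foot)
        assert p.bp.samples[0] <= p.bp.samples[: int(0.1 * FS)].min() + 1e-9


def test_beat_quality_rules(rng):
    nominal = decode(
        _foot_align(HarmonicCode(period_s=0.8, amplitudes=[1.0, 0.3], phases=[0.2, 1.1])),
        100,
    )
    flat = Beat(samples=np.zeros(100), fs=FS)
    tiny = Beat(samples=nominal.samples * 0.01, fs=FS)
    kept = beat_quality([nominal, flat, nominal, tiny, nominal])
    assert len(kept) == 3
    assert all(k.samples.max() > 0.1 for k in kept)


def _bp_pair(bp_samples, filtered=False):
    ppg = Beat(samples=np.sin(np.linspace(0, 2 * np.pi, 100)), fs=FS, subject_id="s")
    bp = Beat(samples=bp_samples, fs=FS, subject_id="s", channel="ABP", filtered=filtered)
    return BeatPair(ppg=ppg, bp=bp)


def test_range_filter_rules():
    t = np.linspace(0, 2 * np.pi, 100)
    shape = -np.cos(t)  # min at both ends, max mid
    keep = _bp_pair(100.0 + 20.0 * shape)  # SBP 120, DBP 80
    too_high = _bp_pair(170.0 + 20.0 * shape)  # SBP 190
    too_low = _bp_pair(79.0 + 20.0 * shape)  # DBP 59
    out = range_filter([keep, too_high, too_low])
    assert out == [keep]


def test_range_filter_boundaries_are_strict():
    t = np.linspace(0, 2 * np.pi, 101)  # grid hits pi exactly
    shape = -np.cos(t)
    on_sbp_bound = _bp_pair(130.0 + 50.0 * shape)  # SBP exactly 180
    assert range_filter([on_sbp_bound]) == []


def test_range_filter_rejects_bandpassed_bp():
    with pytest.raises(ValueError, match="band-passed"):
        range_filter([_bp_pair(np.sin(np.linspace(0, 6, 100)), filtered=True)])


def test_pearson_r_basics(rng):
    x = rng.normal(size=50)
    assert pearson_r(x, x) == pytest.approx(1.0)
    assert pearson_r(x, -x) == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="constant"):
        pearson_r(x, np.full(50, 2.0))
    with pytest.raises(ValueError):
        pearson_r(x[:3], x[:4])


def test_pearson_r_direct_summation_oracle():
    """Brute-force product-moment formula on a tiny example."""
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 2.0, 3.0, 5.0])
    n = 4
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = np.sqrt(n * np.sum(x**2) - np.sum(x) ** 2) * np.sqrt(
        n * np.sum(y**2) - np.sum(y) ** 2
    )
    assert pearson_r(x, y) == pytest.approx(num / den, abs=1e-12)


def test_pearson_qc_keeps_affine_pairs(rng):
    x = np.abs(np.sin(np.linspace(0, np.pi, 80))) + 0.1 * rng.normal(size=80)
    ppg = Beat(samples=x, fs=FS, subject_id="s", segment_id="g")
    bp = Beat(samples=100 + 12 * x, fs=FS, subject_id="s", segment_id="g", channel="ABP")
    pair = BeatPair(ppg=ppg, bp=bp)
    assert pair_pearson_r(pair) == pytest.approx(1.0)
    assert pearson_qc([pair]) == [pair]


def test_pearson_qc_removes_uncorrelated_pairs(rng):
    x = np.sin(np.linspace(0, 2 * np.pi, 125))
    noise = 100 + rng.normal(size=125)
    ppg = Beat(samples=x, fs=FS, subject_id="s", segment_id="g")
    bp = Beat(samples=noise, fs=FS, subject_id="s", segment_id="g", channel="ABP")
    pair = BeatPair(ppg=ppg, bp=bp)
    assert abs(pair_pearson_r(pair)) < 0.8
    assert pearson_qc([pair]) == []
    # r_min = 0 disables the filter
    assert pearson_qc([pair], QCConfig(r_min=0.0)) == [pair]


def test_pearson_qc_removes_whole_segment(rng):
    """The mean r over a segment decides the whole group's fate."""
    x = np.sin(np.linspace(0, 2 * np.pi, 100))
    good = BeatPair(
        ppg=Beat(samples=x, fs=FS, subject_id="s", segment_id="g"),
        bp=Beat(samples=100 + 10 * x, fs=FS, subject_id="s", segment_id="g", channel="ABP"),
    )
    bad = BeatPair(
        ppg=Beat(samples=x, fs=FS, subject_id="s", segment_id="g"),
        bp=Beat(samples=100 - 10 * x, fs=FS, subject_id="s", segment_id="g", channel="ABP"),
    )
    # mean r = (1 + -1)/2 = 0 < 0.8: both go
    assert pearson_qc([good, bad]) == []


def test_qc_chain_survivors_satisfy_all_rules(cohort_with_abnormal):
    """Post-hoc re-check: every survivor of the full chain passes the
    peak, range and correlation rules individually."""
    cfg = QCConfig()
    survivors = apply_qc(cohort_with_abnormal.pairs, cfg)
    assert survivors
    assert beat_quality([p.ppg for p in survivors]) == [p.ppg for p in survivors]
    assert range_filter(survivors, cfg) == survivors
    assert pearson_qc(survivors, cfg) == survivors
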