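"""End-to-end orchestration: QC -> harmonic encoding -> GRNN -> decoding
-> evaluation, with seeded train/validation/test splits.

The default split is 70/15/15 at the subject level (no subject appears in
two splits). A segment-level split -- which can place beats of one
subject in several splits, as a fully random division of signal groups
does -- is available via ``split_level="segment"``. The validation split
is reserved for smoothing-width sensitivity checks; the canonical model
fixes delta = 0.001 and performs no tuning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ppg2bp import evaluate, grnn, harmonics, preprocess, signal_io
from ppg2bp.preprocess import QCConfig
from ppg2bp.signal_io import Beat, BeatPair

logger = logging.getLogger("ppg2bp")


@dataclass
class PipelineConfig:
    """Configuration for the full estimation pipeline."""

    qc: QCConfig = field(default_factory=QCConfig)
    n_ppg: int = harmonics.N_PPG_HARMONICS
    n_bp: int = harmonics.N_BP_HARMONICS
    delta: float = 0.001
    standardize: bool = False
    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    split_level: str = "subject"
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(f <= 0 for f in fracs[:1]) or any(f < 0 for f in fracs[1:]):
            raise ValueError("train fraction must be positive, others nonnegative")
        total = sum(fracs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"split fractions must sum to 1, got "
                f"{self.train_frac}+{self.val_frac}+{self.test_frac}={total}"
            )
        if self.split_level not in ("subject", "segment"):
            raise ValueError("split_level must be 'subject' or 'segment'")
        if self.delta <= 0:
            raise ValueError("delta must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc = QCConfig(**raw.pop("qc", {}))
        return cls(qc=qc, **raw)


def split_pairs(
    pairs: list[BeatPair], config: PipelineConfig
) -> tuple[list[BeatPair], list[BeatPair], list[BeatPair]]:
    """Deterministic seeded split into train/validation/test.

    Splitting shuffles group labels (subjects, or subject-segment pairs)
    and assigns whole groups to splits by cumulative beat count, so no
    group is divided across splits.
    """
    if config.split_level == "subject":
        label = lambda p: p.subject_id
    else:
        label = lambda p: (p.subject_id, p.segment_id, p.key[2])
    groups: dict = {}
    for p in pairs:
        groups.setdefault(label(p), []).append(p)
    keys = sorted(groups.keys(), key=str)
    rng = np.random.default_rng(config.seed)
    rng.shuffle(keys)
    n_total = len(pairs)
    train, val, test = [], [], []
    cum = 0
    for k in keys:
        frac_before = cum / n_total
        if frac_before < config.train_frac:
            train.extend(groups[k])
        elif frac_before < config.train_frac + config.val_frac:
            val.extend(groups[k])
        else:
            test.extend(groups[k])
        cum += len(groups[k])
    return train, val, test


def encode_pairs(
    pairs: list[BeatPair], config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Harmonic-encode all pairs into GRNN input/target matrices."""
    X = np.array(
        [
            harmonics.ppg_feature_vector(
                harmonics.encode(p.ppg, config.n_ppg, fit_dc=False)
            )
            for p in pairs
        ]
    )
    Y = np.array(
        [
            harmonics.bp_feature_vector(
                harmonics.encode(p.bp, config.n_bp, fit_dc=True)
            )
            for p in pairs
        ]
    )
    return X, Y


def predict_bp_beats(
    model: grnn.GRNNRegressor, pairs: list[BeatPair], config: PipelineConfig
) -> list[Beat]:
    """Predict each pair's BP beat from its PPG beat.

    The decoded waveform's period is the input PPG beat's period (the
    channels are synchronized, so the beat periods coincide), and it is
    sampled to the PPG beat's length.
    """
    beats = []
    for pair in pairs:
        code = harmonics.encode(pair.ppg, config.n_ppg, fit_dc=False)
        x = harmonics.ppg_feature_vector(code)
        y = grnn.predict(model, x)
        bp_code = harmonics.from_feature_vector(
            y, period_s=pair.ppg.period_s, include_dc=True
        )
        beats.append(
            harmonics.decode(
                bp_code,
                pair.ppg.samples.size,
                subject_id=pair.subject_id,
                segment_id=pair.segment_id,
                beat_id=pair.key[2],
                channel="ABP",
            )
        )
    return beats


def run_pipeline(
    pairs: list[BeatPair], config: PipelineConfig | None = None
) -> tuple[dict, dict]:
    """Run QC, encoding, training, prediction and evaluation on beat pairs.

    Returns ``(report, artifacts)`` where artifacts holds the fitted
    model, the splits, predicted beats, and per-stage QC counts.
    Deterministic given the config seed.
    """
    config = config or PipelineConfig()
    counts: dict = {}
    survivors = preprocess.apply_qc(pairs, config.qc, log=counts)
    for stage, n in counts.items():
        logger.info("qc %s: %s", stage, n)
    if len(survivors) < 4:
        raise ValueError(
            f"only {len(survivors)} beats survive quality control; "
            "not enough to train and test"
        )
    train, val, test = split_pairs(survivors, config)
    if not train or not test:
        raise ValueError(
            f"empty split (train={len(train)}, test={len(test)}); "
            "adjust fractions or provide more data"
        )
    X_train, Y_train = encode_pairs(train, config)
    model = grnn.GRNNRegressor(delta=config.delta, standardize=config.standardize)
    model.fit(X_train, Y_train)
    pred_beats = predict_bp_beats(model, test, config)
    target_beats = [p.bp for p in test]
    report = evaluate.evaluate_predictions(pred_beats, target_beats)
    report["qc_counts"] = counts
    report["split_sizes"] = {
        "train": len(train), "validation": len(val), "test": len(test),
    }
    artifacts = {
        "model": model,
        "train": train,
        "validation": val,
        "test": test,
        "predicted_beats": pred_beats,
        "qc_counts": counts,
    }
    return report, artifacts


def run_from_files(
    beats_path: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """File-to-file pipeline run: reads a beat CSV, writes model,
    predictions and report into ``outdir``."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs = signal_io.read_beats(beats_path)
    report, artifacts = run_pipeline(pairs, config)
    signal_io.save_model(artifacts["model"], outdir / "model.json")
    pred_pairs = [
        BeatPair(ppg=t.ppg, bp=b)
        for t, b in zip(artifacts["test"], artifacts["predicted_beats"])
    ]
    signal_io.write_beats(pred_pairs, outdir / "predictions.csv")
    signal_io.save_report(report, outdir / "report.json")
    (outdir / "report.txt").write_text(evaluate.summary_text(report) + "\n")
    return report
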