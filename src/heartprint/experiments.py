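"""Config-driven orchestration of the three experimental phases.

Phase 1 sweeps segmentation schemes and window lengths on a single-
session population and reports mean k-fold identification accuracy per
(scheme, window).  Phase 2 evaluates the best segment (R-centered
0.5 s) in single-, mixed-, and multi-session scenarios on a two-session
population.  Phase 3 reuses the multisession predictions to derive
identification statistics (per-subject accuracies, Fisher-Z population
summary, cumulative accuracy distribution) and verification metrics
(pooled one-vs-rest FRR/FAR/TAR/TRR/HTER plus a McNemar test).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import protocol
from .fiducials import detect_p_peaks, detect_r_peaks
from .nn.smallcnn import TrainConfig, build_small_cnn, predict, train
from .records import EcgRecord, preprocess
from .scalogram import CwtParams, segments_to_images
from .segmentation import (SegmentSet, augment_to_count, blind_segments,
                           normalize_lengths, pp_segments,
                           r_centered_segments, rr_segments)
from .synth import generate_dataset

__all__ = ["ExperimentConfig", "segments_for_scheme", "build_image_dataset",
           "kfold_accuracy", "run_phase1", "run_phase2", "run_phase3"]


@dataclass
class ExperimentConfig:
    n_subjects: int = 10
    n_sessions: int = 2
    duration_s: float = 20.0
    fs: float = 500.0
    seed: int = 0
    band_hz: tuple[float, float] = (0.5, 40.0)
    schemes: dict = field(default_factory=lambda: {
        "blind": [0.5, 1.0, 1.5, 2.0, 2.5, 3.0],
        "r_centered": [0.5, 0.75, 1.0],
        "rr": [None],
        "pp": [None],
    })
    cwt: CwtParams = field(default_factory=CwtParams)
    image_size: int = 224
    augment_target: int = 100
    augment_k: int = 10
    cv_folds: int = 10
    train: TrainConfig = field(default_factory=TrainConfig)


def segments_for_scheme(records: list[EcgRecord], scheme: str,
                        window_s: float | None,
                        config: ExperimentConfig) -> SegmentSet:
    """Preprocess, detect fiducials as needed, and segment every record."""
    out = None
    for rec in records:
        pre = preprocess(rec, *config.band_hz)
        if scheme == "blind":
            segs = blind_segments(pre, window_s)
        else:
            fids = detect_r_peaks(pre)
            if fids.r_peaks.size == 0:
                continue
            if scheme == "r_centered":
                segs = r_centered_segments(pre, fids, window_s)
            elif scheme == "rr":
                segs = rr_segments(pre, fids)
            elif scheme == "pp":
                segs = pp_segments(pre, detect_p_peaks(pre, fids))
            else:
                raise ValueError(f"unknown scheme {scheme!r}")
        out = segs if out is None else out.extend(segs)
    if out is None:
        raise ValueError("no records produced segments")
    if scheme in ("rr", "pp"):
        out = normalize_lengths(out)
    return out


def build_image_dataset(segset: SegmentSet, config: ExperimentConfig,
                        augment: bool = True):
    """Augment to the per-subject target and render scalogram images.

    Returns ``(X, y, sessions)`` where X is (n, size, size, 3) float32
    in [0, 1] and y holds subject ids.
    """
    if augment:
        segset = augment_to_count(segset, config.augment_target,
                                  config.augment_k, seed=config.seed)
    x, y = segments_to_images(segset, config.cwt, size=config.image_size)
    sessions = np.array([s.session_id for s in segset], dtype=object)
    return x, y, sessions


def _fit_eval(x, y, train_idx, test_idx, config: ExperimentConfig):
    classes = sorted(set(y))
    spec = build_small_cnn(len(classes), input_size=config.image_size)
    model = train(spec, x[train_idx], y[train_idx], config.train)
    pred, _ = predict(model, x[test_idx])
    confusion = protocol.confusion_matrix(y[test_idx], pred, classes)
    counts = protocol.pooled_one_vs_rest(confusion)
    return float(np.mean(pred == y[test_idx])), confusion, counts


def kfold_accuracy(x, y, config: ExperimentConfig):
    """Mean accuracy over stratified folds (the protocol's CV estimate)."""
    folds = protocol.stratified_kfold(y, k=config.cv_folds, seed=config.seed)
    accs = []
    for tr, te in folds:
        acc, _, _ = _fit_eval(x, y, tr, te, config)
        accs.append(acc)
    return float(np.mean(accs)), accs


def run_phase1(config: ExperimentConfig,
               records: list[EcgRecord] | None = None) -> pd.DataFrame:
    """Scheme x window sweep; one row per combination with mean accuracy."""
    if records is None:
        records = generate_dataset(config.n_subjects, 1, config.duration_s,
                                   config.fs, config.seed)
    rows = []
    for scheme, windows in config.schemes.items():
        for window_s in windows:
            segs = segments_for_scheme(records, scheme, window_s, config)
            x, y, _ = build_image_dataset(segs, config)
            mean_acc, fold_accs = kfold_accuracy(x, y, config)
            rows.append({"scheme": scheme, "window_s": window_s,
                         "accuracy": mean_acc, "n_folds": len(fold_accs)})
    return pd.DataFrame(rows)


def _session_dataset(config: ExperimentConfig,
                     records: list[EcgRecord] | None,
                     scheme: str = "r_centered", window_s: float = 0.5):
    """Per-session augmented image dataset for the phase-2 scenarios."""
    if records is None:
        records = generate_dataset(config.n_subjects, config.n_sessions,
                                   config.duration_s, config.fs, config.seed)
    per_session = max(1, config.augment_target // config.n_sessions)
    xs, ys, sess = [], [], []
    sessions = sorted({r.session_id for r in records})
    for si, sid in enumerate(sessions):
        recs = [r for r in records if r.session_id == sid]
        segs = segments_for_scheme(recs, scheme, window_s, config)
        segs = augment_to_count(segs, per_session, config.augment_k,
                                seed=config.seed + 37 * (si + 1))
        x, y = segments_to_images(segs, config.cwt, size=config.image_size)
        xs.append(x)
        ys.append(y)
        sess.append(np.full(len(y), sid, dtype=object))
    return (np.concatenate(xs), np.concatenate(ys), np.concatenate(sess))


def run_phase2(config: ExperimentConfig,
               records: list[EcgRecord] | None = None):
    """Single / mixed / multisession scenario accuracies.

    Returns ``(report, multi_details)`` where ``multi_details`` carries
    the two session-fold confusion matrices and pooled verification
    counts needed by phase 3.
    """
    x, y, sessions = _session_dataset(config, records)
    first = sorted(set(sessions))[0]
    rows = []

    single = np.flatnonzero(sessions == first)
    acc_single, _ = kfold_accuracy(x[single], y[single], config)
    rows.append({"scenario": "single", "accuracy": acc_single})

    acc_mixed, _ = kfold_accuracy(x, y, config)
    rows.append({"scenario": "mixed", "accuracy": acc_mixed})

    splits = protocol.multisession_split(sessions, y, seed=config.seed)
    fold_accs, confusions, counts_list = [], [], []
    for tr, te in splits:
        acc, confusion, counts = _fit_eval(x, y, tr, te, config)
        fold_accs.append(acc)
        confusions.append(confusion)
        counts_list.append(counts)
    rows.append({"scenario": "multi", "accuracy": float(np.mean(fold_accs))})

    multi_details = {"fold_accuracies": fold_accs, "confusions": confusions,
                     "counts": counts_list, "classes": sorted(set(y))}
    return pd.DataFrame(rows), multi_details


def run_phase3(multi_details: dict) -> dict:
    """Identification and verification analysis of multisession results."""
    confusion = np.sum(multi_details["confusions"], axis=0)
    per_subject = protocol.per_subject_accuracies(confusion)
    mean_z, sd_z = protocol.fisher_z_summary(per_subject)
    thresholds, fractions = protocol.cumulative_accuracy_distribution(per_subject)

    counts = protocol.pooled_one_vs_rest(confusion)
    metrics = protocol.verification_metrics(counts)
    statistic, p = protocol.mcnemar_yates(counts.fp, counts.fn)

    return {
        "identification": {
            "accuracy": float(np.mean(multi_details["fold_accuracies"])),
            "fold_accuracies": multi_details["fold_accuracies"],
            "per_subject": per_subject,
            "fisher_z_mean": mean_z,
            "fisher_z_sd": sd_z,
            "cumulative_curve": (thresholds, fractions),
        },
        "verification": {
            "counts": counts,
            "metrics": metrics,
            "mcnemar_statistic": statistic,
            "mcnemar_p": p,
        },
    }
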