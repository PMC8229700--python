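"""Evaluation protocol: cross-validation splits, identification and
verification metrics, and population statistics.

Identification is the multiclass problem (which subject?); verification
is derived from the same classification results by collapsing the
multiclass confusion matrix one-vs-rest per target subject (genuine vs
imposter).  Verification error rates:

    FRR = FN / (FN + TP)      FAR = FP / (FP + TN)
    TAR = 1 - FRR             TRR = 1 - FAR
    HTER = (FRR + FAR) / 2

HTER stands in for the equal error rate, which cannot be computed from
hard classification decisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = ["ConfusionCounts", "VerificationMetrics", "stratified_kfold",
           "multisession_split", "accuracy", "confusion_matrix",
           "one_vs_rest_counts", "pooled_one_vs_rest", "verification_metrics",
           "hter", "mcnemar_yates", "MCNEMAR_CRITICAL_95",
           "fisher_z_summary", "per_subject_accuracies",
           "cumulative_accuracy_distribution"]

#: Chi-square critical value at the 95% level, 1 degree of freedom.
MCNEMAR_CRITICAL_95 = float(stats.chi2.ppf(0.95, df=1))


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class VerificationMetrics:
    frr: float
    far: float
    tar: float
    trr: float
    hter: float


def stratified_kfold(labels: np.ndarray, k: int = 10,
                     seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint stratified folds; returns (train_idx, test_idx) pairs."""
    labels = np.asarray(labels, dtype=object)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs >= {k} members for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    codes = np.unique(labels, return_inverse=True)[1]
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), codes)]


def multisession_split(session_ids: np.ndarray, subject_ids: np.ndarray,
                       seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Two session-swap splits: train on one session group, test on the other.

    Sessions are pooled into two groups (the first session of each
    subject vs all later ones).  A subject present in only one group has
    its segments randomly halved between the two groups (seeded).  The
    final accuracy of a multisession experiment is the mean over the two
    returned splits.
    """
    session_ids = np.asarray(session_ids, dtype=object)
    subject_ids = np.asarray(subject_ids, dtype=object)
    rng = np.random.default_rng(seed)
    group_a = np.zeros(len(session_ids), dtype=bool)
    for subj in np.unique(subject_ids):
        mask = subject_ids == subj
        sessions = np.unique(session_ids[mask])
        if len(sessions) >= 2:
            group_a[mask & (session_ids == sessions[0])] = True
        else:  # single-session subject: random 50/50 division of its segments
            idx = np.flatnonzero(mask)
            half = rng.permutation(len(idx))[: len(idx) // 2]
            group_a[idx[half]] = True
    a = np.flatnonzero(group_a)
    b = np.flatnonzero(~group_a)
    return [(a, b), (b, a)]


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / total trials."""
    if counts.total == 0:
        raise ValueError("no trials")
    return (counts.tp + counts.tn) / counts.total


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     classes: list) -> np.ndarray:
    """Square confusion matrix, rows = true class, columns = predicted."""
    index = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        m[index[t], index[p]] += 1
    return m


def one_vs_rest_counts(confusion: np.ndarray, target: int) -> ConfusionCounts:
    """Collapse a multiclass confusion matrix to genuine-vs-imposter counts."""
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    if not (0 <= target < confusion.shape[0]):
        raise ValueError(f"target {target} out of range")
    tp = int(confusion[target, target])
    fn = int(confusion[target].sum() - tp)
    fp = int(confusion[:, target].sum() - tp)
    tn = int(confusion.sum() - tp - fn - fp)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def pooled_one_vs_rest(confusion: np.ndarray) -> ConfusionCounts:
    """Aggregate one-vs-rest counts over every target class."""
    parts = [one_vs_rest_counts(confusion, t) for t in range(len(confusion))]
    return ConfusionCounts(tp=sum(p.tp for p in parts),
                           tn=sum(p.tn for p in parts),
                           fp=sum(p.fp for p in parts),
                           fn=sum(p.fn for p in parts))


def verification_metrics(counts: ConfusionCounts) -> VerificationMetrics:
    """FRR/FAR/TAR/TRR/HTER from genuine-vs-imposter counts."""
    genuine = counts.tp + counts.fn
    imposter = counts.fp + counts.tn
    if genuine == 0 or imposter == 0:
        raise ValueError("need both genuine and imposter attempts")
    frr = counts.fn / genuine
    far = counts.fp / imposter
    return VerificationMetrics(frr=frr, far=far, tar=1 - frr, trr=1 - far,
                               hter=(frr + far) / 2)


def hter(frr: float, far: float) -> float:
    """Half total error rate from the two error rates."""
    return (frr + far) / 2


def mcnemar_yates(b: int, c: int) -> tuple[float, float]:
    """McNemar test with Yates continuity correction on discordant counts.

    Returns ``(statistic, p_value)``; the statistic is
    ``(|b - c| - 1)^2 / (b + c)`` (0 when there is no discordance) and
    the p-value comes from the chi-square distribution with 1 df.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        return 0.0, 1.0
    statistic = (abs(b - c) - 1) ** 2 / (b + c)
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def fisher_z_summary(accuracies: np.ndarray,
                     eps: float = 1e-6) -> tuple[float, float]:
    """Population mean and spread of per-subject accuracies via Fisher Z.

    Values are clamped to ``[eps, 1 - eps]`` (atanh diverges at 1, and
    perfect per-subject accuracies do occur), transformed with atanh,
    summarized in z-space, and the mean mapped back with tanh.  The
    returned spread is the z-space standard deviation.
    """
    a = np.clip(np.asarray(accuracies, dtype=float), eps, 1 - eps)
    z = np.arctanh(a)
    return float(np.tanh(z.mean())), float(z.std(ddof=1)) if len(z) > 1 else 0.0


def per_subject_accuracies(confusion: np.ndarray) -> np.ndarray:
    """Diagonal recall per subject: correct / row total (NaN-free)."""
    confusion = np.asarray(confusion, dtype=float)
    totals = confusion.sum(axis=1)
    totals[totals == 0] = 1.0
    return np.diag(confusion) / totals


def cumulative_accuracy_distribution(accuracies: np.ndarray,
                                     thresholds: np.ndarray | None = None
                                     ) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of subjects with accuracy >= threshold, per threshold.

    A non-increasing step curve on [0, 1].
    """
    a = np.asarray(accuracies, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one accuracy")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    fractions = np.array([(a >= t).mean() for t in thresholds])
    return thresholds, fractions
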