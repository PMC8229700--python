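"""Fiducial landmark detection: R-peaks and P-peaks.

The R detector follows a curvature-based scheme: candidate beats are
local minima of the discrete curvature (second difference of a lightly
smoothed signal — a sharp convex apex has strongly negative second
difference), gated by an adaptive per-window threshold, then refined by
a search-back for the amplitude maximum of the preprocessed signal, with
refractory suppression of close duplicates.

The P detector searches a 245 ms window ending shortly before each R in
the envelope of the analytic (Hilbert) signal of a low-band (0.5–10 Hz)
version of the record, with the QRS region masked out so P-wave energy
dominates the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal as sps

if TYPE_CHECKING:  # pragma: no cover
    from .records import EcgRecord

__all__ = [
    "FiducialSet",
    "curvature",
    "detect_r_peaks",
    "detect_p_peaks",
    "match_events",
    "detection_scores",
    "P_SEARCH_WINDOW_S",
]

#: Width of the pre-R search window for P-peaks, seconds.
P_SEARCH_WINDOW_S = 0.245


@dataclass
class FiducialSet:
    """Strictly increasing R-peak (and optionally P-peak) sample indices."""

    r_peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    p_peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        self.p_peaks = np.asarray(self.p_peaks, dtype=int)
        for name in ("r_peaks", "p_peaks"):
            arr = getattr(self, name)
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")

    def validate(self, n_samples: int) -> None:
        for name in ("r_peaks", "p_peaks"):
            arr = getattr(self, name)
            if arr.size and (arr.min() < 0 or arr.max() >= n_samples):
                raise ValueError(f"{name} indices outside [0, {n_samples})")


def curvature(samples: np.ndarray, fs: float | None = None,
              smooth_s: float = 0.010) -> np.ndarray:
    """Discrete curvature proxy: second difference of a smoothed signal.

    A sharp convex peak maps to a strong local *minimum* of the output;
    a straight line maps to (approximately) zero.  The output has the
    same length as the input (ends padded with their nearest value).

    Parameters
    ----------
    fs : sampling rate; when given, the signal is first smoothed with a
        ``smooth_s``-second moving average to suppress sample noise.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError("curvature needs at least 3 samples")
    if fs is not None:
        w = max(1, int(round(smooth_s * fs)))
        if w > 1:
            kernel = np.ones(w) / w
            x = np.convolve(x, kernel, mode="same")
    d2 = np.empty_like(x)
    d2[1:-1] = x[2:] - 2 * x[1:-1] + x[:-2]
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    return d2


def _local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local minima."""
    idx, _ = sps.find_peaks(-x)
    return idx


def detect_r_peaks(record: "EcgRecord", window_s: float = 2.0,
                   refractory_s: float = 0.25, quantile: float = 0.98,
                   threshold_frac: float = 0.5, search_back_s: float = 0.05,
                   edge_guard_s: float = 0.1) -> FiducialSet:
    """Detect R-peaks of a preprocessed record.

    Pipeline: curvature minima below an adaptive threshold (a fraction
    of the running ``quantile`` of \\|curvature\\| over consecutive
    ``window_s`` windows) → search-back to the amplitude argmax of the
    signal within ``±search_back_s`` → refractory suppression keeping
    the larger-amplitude peak of any pair closer than ``refractory_s``.
    Detections within ``edge_guard_s`` of the record ends are discarded:
    zero-phase filtering leaves edge transients there and a clipped QRS
    cannot be localized reliably.
    """
    if not (window_s >= refractory_s > 0):
        raise ValueError("need window_s >= refractory_s > 0")
    x = record.samples
    fs = record.fs
    win = int(round(window_s * fs))
    if len(x) < win:
        warnings.warn("record shorter than one sliding window; no R-peaks detected")
        return FiducialSet()

    curv = curvature(x, fs=fs)
    minima = _local_minima(curv)

    # adaptive threshold refreshed per non-overlapping window
    candidates = []
    for start in range(0, len(x), win):
        stop = min(start + win, len(x))
        if stop - start < win // 4:  # tiny tail: reuse previous threshold
            stop = len(x)
        seg = np.abs(curv[start:stop])
        thr = threshold_frac * np.quantile(seg, quantile)
        if thr <= 0:
            continue
        in_win = minima[(minima >= start) & (minima < stop)]
        candidates.extend(in_win[curv[in_win] < -thr].tolist())
        if stop == len(x):
            break

    if not candidates:
        return FiducialSet()

    # search-back: amplitude argmax of the preprocessed signal
    sb = int(round(search_back_s * fs))
    refined = []
    for c in candidates:
        lo, hi = max(0, c - sb), min(len(x), c + sb + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    guard = int(round(edge_guard_s * fs))
    refined = sorted({r for r in refined if guard <= r < len(x) - guard})
    if not refined:
        return FiducialSet()

    # refractory suppression: keep the larger-amplitude of close pairs
    refr = int(round(refractory_s * fs))
    kept: list[int] = []
    for r in refined:
        if kept and r - kept[-1] < refr:
            if x[r] > x[kept[-1]]:
                kept[-1] = r
        else:
            kept.append(r)
    return FiducialSet(r_peaks=np.array(kept, dtype=int))


def detect_p_peaks(record: "EcgRecord", fiducials: FiducialSet,
                   guard_s: float = 0.090, qrs_mask_s: tuple[float, float] = (0.090, 0.060),
                   band_hz: tuple[float, float] = (1.0, 15.0)) -> FiducialSet:
    """Locate a P-peak before each R-peak that has full left context.

    The search window is ``[r - round(0.245*fs), r - round(guard_s*fs))``.
    P is the argmax, within that window, of the envelope of the analytic
    (Hilbert-transformed) signal of the *differentiated*, band-limited
    record with the QRS excised.  The steps, and why each is there:

    * QRS excision — samples in ``[r - mask_left, r + mask_right]`` are
      replaced by a linear bridge so QRS energy (including deep Q waves)
      cannot smear into the pre-R window through the filter;
    * band-pass ``band_hz`` — removes residual baseline and noise;
    * first derivative — suppresses the ~1 Hz heartbeat-train
      fundamental that otherwise dominates the envelope, and turns the
      P bump into a doublet whose analytic envelope peaks at the apex;
    * Hilbert envelope — a smooth, sign-free peak locator.

    R-peaks whose window would start before the record yield no P.
    """
    if fiducials.r_peaks.size == 0:
        raise ValueError("detect_p_peaks requires at least one R-peak")
    from .records import preprocess  # deferred: records imports this module

    fs = record.fs
    n = len(record.samples)
    bridged = record.samples.astype(float).copy()
    ml = int(round(qrs_mask_s[0] * fs))
    mr = int(round(qrs_mask_s[1] * fs))
    for r in fiducials.r_peaks:
        lo, hi = max(0, r - ml), min(n - 1, r + mr)
        bridged[lo:hi + 1] = np.linspace(bridged[lo], bridged[hi], hi - lo + 1)
    from dataclasses import replace as _replace
    low = preprocess(_replace(record, samples=bridged),
                     band_hz[0], band_hz[1]).samples
    envelope = np.abs(sps.hilbert(np.gradient(low)))

    mask = np.zeros(n, dtype=bool)
    for r in fiducials.r_peaks:
        mask[max(0, r - ml): min(n, r + mr + 1)] = True
    masked = np.where(mask, -np.inf, envelope)

    win = int(round(P_SEARCH_WINDOW_S * fs))
    guard = int(round(guard_s * fs))
    sb = int(round(0.025 * fs))  # search-back to the signal apex
    p_peaks = []
    for r in fiducials.r_peaks:
        lo, hi = r - win, r - guard
        if lo < 0 or hi <= lo:
            continue
        seg = masked[lo:hi]
        if np.all(np.isinf(seg)):
            continue
        cand = lo + int(np.argmax(seg))
        a, b = max(lo, cand - sb), min(hi, cand + sb + 1)
        p_peaks.append(a + int(np.argmax(bridged[a:b])))
    return FiducialSet(r_peaks=fiducials.r_peaks,
                       p_peaks=np.array(sorted(set(p_peaks)), dtype=int))


def match_events(detected: np.ndarray, truth: np.ndarray,
                 tolerance: int) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected vs truth indices.

    Returns ``(n_matched, n_missed, n_extra)``.
    """
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    used = np.zeros(len(detected), dtype=bool)
    matched = 0
    for t in truth:
        if len(detected) == 0:
            break
        dist = np.abs(detected - t)
        dist[used] = tolerance + 1
        j = int(np.argmin(dist))
        if dist[j] <= tolerance:
            used[j] = True
            matched += 1
    return matched, len(truth) - matched, int((~used).sum())


def detection_scores(detected: np.ndarray, truth: np.ndarray, fs: float,
                     tolerance_s: float = 0.010) -> dict[str, float]:
    """Sensitivity and positive predictivity at a timing tolerance."""
    tol = int(round(tolerance_s * fs))
    tp, fn, fp = match_events(detected, truth, tol)
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "n_truth": tp + fn,
        "n_detected": tp + fp,
    }


def write_fiducials(fiducials: FiducialSet, path: str | Path) -> None:
    """Serialize as two-column text: type, sample_index."""
    lines = [f"R\t{r}" for r in fiducials.r_peaks]
    lines += [f"P\t{p}" for p in fiducials.p_peaks]
    Path(path).write_text("\n".join(lines) + "\n")


def read_fiducials(path: str | Path) -> FiducialSet:
    rs, ps = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        kind, idx = line.split()
        (rs if kind == "R" else ps).append(int(idx))
    return FiducialSet(r_peaks=np.array(sorted(rs), dtype=int),
                       p_peaks=np.array(sorted(ps), dtype=int))
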