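"""Heartbeat segmentation schemes and averaging-based augmentation.

Four families of windows are cut from a preprocessed record:

* ``blind`` — consecutive fixed-duration windows ignoring fiducials;
* ``r_centered`` — a fixed window centered on each R-peak;
* ``rr`` — one segment per consecutive R–R interval (variable length);
* ``pp`` — one segment per consecutive P–P interval (variable length).

Variable-length families are linearly resampled to a common length
before imaging.  Augmentation tops each subject up to a target count by
averaging k randomly chosen same-subject segments.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fiducials import FiducialSet
from .records import EcgRecord

__all__ = ["Segment", "SegmentSet", "blind_segments", "r_centered_segments",
           "rr_segments", "pp_segments", "resample_to_length",
           "normalize_lengths", "augment_to_count", "SCHEMES"]

SCHEMES = ("blind", "r_centered", "rr", "pp")


@dataclass
class Segment:
    subject_id: str
    session_id: str
    scheme: str
    samples: np.ndarray
    window_s: float | None = None            # fixed-length schemes only
    origin: tuple[str, int] | None = None    # (record id, start index)
    sources: tuple[int, ...] | None = None   # augmentation provenance
    fs: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def __len__(self) -> int:
        return len(self.samples)


class SegmentSet:
    """A homogeneous (single-scheme) collection of segments."""

    def __init__(self, segments: list[Segment]):
        schemes = {s.scheme for s in segments}
        if len(schemes) > 1:
            raise ValueError(f"mixed schemes in one set: {schemes}")
        self.segments = list(segments)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, i) -> Segment:
        return self.segments[i]

    @property
    def scheme(self) -> str | None:
        return self.segments[0].scheme if self.segments else None

    def counts(self) -> pd.Series:
        """Per-subject segment counts."""
        return pd.Series([s.subject_id for s in self.segments],
                         dtype="object").value_counts().sort_index()

    def subjects(self) -> list[str]:
        return sorted({s.subject_id for s in self.segments})

    def extend(self, other: "SegmentSet") -> "SegmentSet":
        return SegmentSet(self.segments + other.segments)


def blind_segments(record: EcgRecord, window_s: float) -> SegmentSet:
    """Consecutive non-overlapping windows from index 0; remainder dropped."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n = int(round(window_s * record.fs))
    segs = []
    for start in range(0, len(record) - n + 1, n):
        segs.append(Segment(record.subject_id, record.session_id, "blind",
                            record.samples[start:start + n], window_s=window_s,
                            origin=(record.record_id, start), fs=record.fs))
    return SegmentSet(segs)


def r_centered_segments(record: EcgRecord, fiducials: FiducialSet,
                        window_s: float) -> SegmentSet:
    """A ``window_s`` window centered on each R-peak; boundary windows dropped."""
    if fiducials.r_peaks.size == 0:
        raise ValueError("r_centered_segments requires R-peaks")
    n = int(round(window_s * record.fs))
    segs = []
    for r in fiducials.r_peaks:
        start = int(r) - n // 2
        if start < 0 or start + n > len(record):
            continue
        segs.append(Segment(record.subject_id, record.session_id, "r_centered",
                            record.samples[start:start + n], window_s=window_s,
                            origin=(record.record_id, start), fs=record.fs))
    return SegmentSet(segs)


def _interval_segments(record: EcgRecord, marks: np.ndarray,
                       scheme: str) -> SegmentSet:
    segs = []
    for a, b in zip(marks[:-1], marks[1:]):
        segs.append(Segment(record.subject_id, record.session_id, scheme,
                            record.samples[int(a):int(b)],
                            origin=(record.record_id, int(a)), fs=record.fs))
    return SegmentSet(segs)


def rr_segments(record: EcgRecord, fiducials: FiducialSet) -> SegmentSet:
    """One segment per consecutive R–R pair, ``[r_k, r_{k+1})``."""
    return _interval_segments(record, fiducials.r_peaks, "rr")


def pp_segments(record: EcgRecord, fiducials: FiducialSet) -> SegmentSet:
    """One segment per consecutive P–P pair, ``[p_k, p_{k+1})``."""
    return _interval_segments(record, fiducials.p_peaks, "pp")


def resample_to_length(segment: Segment, n_target: int) -> Segment:
    """Linear-interpolation resample preserving the endpoint samples."""
    if len(segment) < 2 or n_target < 2:
        raise ValueError("resample_to_length needs lengths >= 2")
    if n_target == len(segment):
        return segment
    old = np.linspace(0.0, 1.0, len(segment))
    new = np.linspace(0.0, 1.0, n_target)
    return replace(segment, samples=np.interp(new, old, segment.samples))


def normalize_lengths(segset: SegmentSet, n_target: int | None = None) -> SegmentSet:
    """Resample every segment to a common length (median length by default)."""
    if len(segset) == 0:
        return segset
    if n_target is None:
        n_target = int(np.median([len(s) for s in segset]))
    return SegmentSet([resample_to_length(s, n_target) for s in segset])


def augment_to_count(segset: SegmentSet, target_count: int = 100, k: int = 10,
                     seed: int = 0) -> SegmentSet:
    """Top every subject up to ``target_count`` segments by k-averaging.

    Each synthetic segment is the element-wise mean of ``k`` segments
    drawn with replacement from the same subject's originals; source
    indices (into the subject's original list) are kept as provenance.
    Originals are never altered or discarded.  Subjects already at or
    above the target are passed through unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    lengths = {len(s) for s in segset}
    if len(lengths) > 1:
        raise ValueError("augmentation requires equal-length segments; "
                         "run normalize_lengths first")
    by_subject: dict[str, list[Segment]] = {}
    for s in segset:
        by_subject.setdefault(s.subject_id, []).append(s)

    out: list[Segment] = []
    for subject in sorted(by_subject):
        originals = by_subject[subject]
        if not originals:
            raise ValueError(f"subject {subject} has no segments")
        out.extend(originals)
        # stable per-subject stream (process-independent, unlike hash())
        rng = np.random.default_rng([seed, zlib.crc32(subject.encode())])
        for _ in range(max(0, target_count - len(originals))):
            idx = rng.integers(0, len(originals), size=k)
            mean = np.mean([originals[i].samples for i in idx], axis=0)
            proto = originals[0]
            out.append(Segment(subject, proto.session_id, proto.scheme, mean,
                               window_s=proto.window_s, origin=None,
                               sources=tuple(int(i) for i in idx), fs=proto.fs))
    return SegmentSet(out)
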