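"""Synthetic multi-subject, multi-session ECG with exact ground truth.

Each heartbeat is a sum of five Gaussian bumps (P, Q, R, S, T), one per
characteristic wave, at subject-specific amplitudes, widths, and offsets
relative to the R apex.  Beat-to-beat timing follows the subject's mean
RR interval with Gaussian jitter, and records carry additive white noise
plus a sinusoidal baseline-wander component.  Session-to-session drift
perturbs a subject's wave amplitudes and shapes multiplicatively,
emulating electrode placement and physiological changes between
recording days while preserving the subject's characteristic morphology.

The generator is fully deterministic given its parameters and a seed,
and every record carries exact R and P bump centers as ground-truth
fiducials, enabling closed-loop scoring of the detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .fiducials import FiducialSet
from .records import EcgRecord, write_csv, write_wfdb

__all__ = ["WAVES", "SubjectParams", "sample_population", "synthesize_record",
           "session_perturb", "generate_dataset", "export_dataset"]

WAVES = ("P", "Q", "R", "S", "T")

# Per-wave sampling ranges for a healthy adult resting ECG, lead i.
# amplitudes in mV, widths and offsets in seconds, offset relative to R.
_RANGES = {
    "amp": {"P": (0.05, 0.25), "Q": (-0.20, -0.05), "R": (0.8, 1.6),
            "S": (-0.35, -0.10), "T": (0.10, 0.50)},
    "width": {"P": (0.020, 0.035), "Q": (0.008, 0.016), "R": (0.009, 0.014),
              "S": (0.009, 0.018), "T": (0.045, 0.075)},
    "offset": {"P": (-0.21, -0.13), "Q": (-0.045, -0.025), "R": (0.0, 0.0),
               "S": (0.025, 0.045), "T": (0.22, 0.30)},
}
_MEAN_RR_RANGE = (0.7, 1.1)
_NOISE_SD_RANGE = (0.02, 0.05)
_WANDER_AMP_RANGE = (0.05, 0.15)
_WANDER_HZ_RANGE = (0.15, 0.40)
_RR_JITTER_SD = 0.04
_SESSION_DRIFT_SD = 0.08
_MIN_RR_FLOOR_S = 0.4  # hard floor on consecutive beat spacing
_EDGE_MARGIN_S = 0.2   # no beat center closer than this to the record end


@dataclass
class SubjectParams:
    """Morphology and rhythm parameters of one synthetic subject."""

    amp: dict[str, float]      # mV per wave
    width: dict[str, float]    # s per wave
    offset: dict[str, float]   # s relative to R (offset["R"] == 0)
    mean_rr: float             # s
    rr_jitter_sd: float = _RR_JITTER_SD
    noise_sd: float = 0.03     # mV
    wander_amp: float = 0.1    # mV
    wander_hz: float = 0.25    # Hz
    session_drift_sd: float = _SESSION_DRIFT_SD
    subject_id: str = "s0"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for w in WAVES:
            if self.width[w] <= 0:
                raise ValueError(f"width[{w}] must be positive")
        o = self.offset
        if not (o["P"] < o["Q"] < 0 == o["R"] < o["S"] < o["T"]):
            raise ValueError("wave offsets must satisfy P < Q < R=0 < S < T")
        if o["R"] - o["P"] > 0.245:
            raise ValueError("P offset outside the 245 ms pre-R search window")
        if self.mean_rr <= 2 * (o["T"] - o["P"]):
            raise ValueError("mean_rr too short: consecutive beats would overlap")


def sample_population(n_subjects: int, seed: int) -> list[SubjectParams]:
    """Draw ``n_subjects`` independent parameter sets, deterministic in seed.

    If a draw violates the beat-overlap invariant (a short RR interval
    combined with a wide P–T span), the mean RR interval is raised just
    above the overlap bound rather than altering the wave morphology.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    population = []
    for i in range(n_subjects):
        amp = {w: rng.uniform(*_RANGES["amp"][w]) for w in WAVES}
        width = {w: rng.uniform(*_RANGES["width"][w]) for w in WAVES}
        offset = {w: rng.uniform(*_RANGES["offset"][w]) for w in WAVES}
        offset["R"] = 0.0
        mean_rr = rng.uniform(*_MEAN_RR_RANGE)
        span = offset["T"] - offset["P"]
        if mean_rr <= 2 * span:
            mean_rr = 2 * span + 0.05
        population.append(SubjectParams(
            amp=amp, width=width, offset=offset, mean_rr=mean_rr,
            rr_jitter_sd=_RR_JITTER_SD,
            noise_sd=rng.uniform(*_NOISE_SD_RANGE),
            wander_amp=rng.uniform(*_WANDER_AMP_RANGE),
            wander_hz=rng.uniform(*_WANDER_HZ_RANGE),
            session_drift_sd=_SESSION_DRIFT_SD,
            subject_id=f"s{i:03d}",
        ))
    return population


def synthesize_record(params: SubjectParams, duration_s: float, fs: float,
                      session_id: str = "1", seed: int = 0) -> EcgRecord:
    """Render one record for a subject; exact fiducials in ``truth_fiducials``.

    Beat centers start at half a mean RR interval and advance by
    ``max(0.4 s, mean_rr + N(0, rr_jitter_sd))``; every beat whose R
    center falls in ``[0, duration - 0.2 s)`` contributes (the trailing
    margin keeps the final QRS complete).  R (and P, when its center
    lies inside the record) bump centers rounded to the nearest sample
    are stored as ground truth.
    """
    if duration_s <= params.mean_rr:
        raise ValueError("duration_s must exceed one mean RR interval")
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)

    beat_times = []
    tc = 0.5 * params.mean_rr
    # stop short of the record end so no beat's QRS is clipped mid-complex
    while tc < duration_s - _EDGE_MARGIN_S:
        beat_times.append(tc)
        tc += max(_MIN_RR_FLOOR_S, params.mean_rr + rng.normal(0, params.rr_jitter_sd))

    r_idx, p_idx = [], []
    for tb in beat_times:
        for w in WAVES:
            center = tb + params.offset[w]
            b = params.width[w]
            # Gaussians decay fast; only render within +-5 widths
            lo = max(0, int((center - 5 * b) * fs))
            hi = min(n, int((center + 5 * b) * fs) + 1)
            if hi <= lo:
                continue
            x[lo:hi] += params.amp[w] * np.exp(
                -((t[lo:hi] - center) ** 2) / (2 * b * b))
        ri = int(round(tb * fs))
        if 0 <= ri < n:
            r_idx.append(ri)
            pi = int(round((tb + params.offset["P"]) * fs))
            if 0 <= pi < n:
                p_idx.append(pi)

    if params.noise_sd > 0:
        x += rng.normal(0, params.noise_sd, n)
    if params.wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += params.wander_amp * np.sin(2 * np.pi * params.wander_hz * t + phase)

    fids = FiducialSet(r_peaks=np.array(r_idx, dtype=int),
                       p_peaks=np.array(p_idx, dtype=int))
    return EcgRecord(params.subject_id, session_id, "i", fs, x,
                     truth_fiducials=fids,
                     meta={"synthetic": True, "seed": seed})


def session_perturb(params: SubjectParams, seed: int) -> SubjectParams:
    """Perturb a subject's parameters to emulate a new recording session.

    Amplitudes scale by ``1 + N(0, session_drift_sd)``, widths by half
    that spread; non-R offsets get small additive jitter.  Redraws the
    jitter (up to 100 times) if a draw breaks an ordering invariant.
    """
    if params.session_drift_sd == 0:
        return params
    rng = np.random.default_rng(seed)
    sd = params.session_drift_sd
    for _ in range(100):
        amp = {w: params.amp[w] * (1 + rng.normal(0, sd)) for w in WAVES}
        width = {w: params.width[w] * max(0.2, 1 + rng.normal(0, sd / 2))
                 for w in WAVES}
        offset = {w: (0.0 if w == "R" else params.offset[w] + rng.normal(0, 0.003))
                  for w in WAVES}
        # R amplitude keeps its sign and dominance
        amp["R"] = max(0.3, amp["R"])
        candidate = replace(params, amp=amp, width=width, offset=offset)
        try:
            candidate.validate()
        except ValueError:
            continue
        return candidate
    return params  # pathological drift settings: fall back to the original


def generate_dataset(n_subjects: int, n_sessions: int, duration_s: float,
                     fs: float, seed: int) -> list[EcgRecord]:
    """A full synthetic study: one record per subject per session."""
    population = sample_population(n_subjects, seed)
    records = []
    for si, params in enumerate(population):
        for sess in range(1, n_sessions + 1):
            p = params if sess == 1 else session_perturb(
                params, seed=seed + 7919 * si + 104729 * sess)
            rec = synthesize_record(p, duration_s, fs, session_id=str(sess),
                                    seed=seed + 31 * si + 977 * sess)
            records.append(rec)
    return records


def export_dataset(records: list[EcgRecord], out_dir: str | Path,
                   fmt: str = "csv") -> Path:
    """Write records plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = []
    for rec in records:
        stem = f"{rec.subject_id}_{rec.session_id}"
        if fmt == "csv":
            write_csv(rec, out / f"{stem}.csv")
        elif fmt == "wfdb":
            write_wfdb(rec, out / stem)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        lines.append(f"{stem} {rec.subject_id} {rec.session_id}")
    manifest = out / "manifest.txt"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
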