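"""Single-lead ECG records: containers, file I/O, and signal conditioning.

An :class:`EcgRecord` holds one lead of a sampled ECG together with its
sampling rate, subject/session identity and (for synthetic or annotated
data) ground-truth fiducial landmarks.  Records are read from a minimal
WFDB subset (text ``.hea`` header plus 16-bit little-endian ``.dat``),
from single-column CSV, or produced by :mod:`heartprint.synth`.

Conventions: sample indices are 0-based, windows half-open ``[start, end)``,
amplitudes in millivolts.  Record stems of the form ``<subject>_<session>``
carry identity; a plain-text manifest can override this.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .fiducials import FiducialSet

__all__ = [
    "EcgRecord",
    "read_wfdb",
    "write_wfdb",
    "read_csv",
    "write_csv",
    "read_manifest",
    "preprocess",
    "resample_record",
]


@dataclass
class EcgRecord:
    """One lead of a sampled ECG signal.

    Parameters
    ----------
    subject_id, session_id : str
        Identity of the person and the recording session.
    lead : str
        Lead label, e.g. ``"i"``.
    fs : float
        Sampling rate in Hz, strictly positive.
    samples : numpy.ndarray
        Amplitudes in mV; finite, non-empty, 1-D.
    truth_fiducials : FiducialSet, optional
        Ground-truth landmark indices (synthetic data or annotations).
    meta : dict
        Free-form annotations.
    """

    subject_id: str
    session_id: str
    lead: str
    fs: float
    samples: np.ndarray
    truth_fiducials: FiducialSet | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.truth_fiducials is not None:
            self.truth_fiducials.validate(len(self.samples))

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def record_id(self) -> str:
        return f"{self.subject_id}_{self.session_id}"


def _parse_identity(stem: str) -> tuple[str, str]:
    """``<subject>_<session>`` stem convention; lone stems get session "1"."""
    m = re.match(r"^(.*)_([^_]+)$", stem)
    if m:
        return m.group(1), m.group(2)
    return stem, "1"


def read_manifest(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a manifest mapping file stems to (subject_id, session_id).

    Whitespace/comma separated, three columns: ``stem subject session``.
    Lines starting with ``#`` are ignored.
    """
    mapping: dict[str, tuple[str, str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[,\s]+", line)
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 'stem subject session', got {line!r}")
        mapping[parts[0]] = (parts[1], parts[2])
    return mapping


# ---------------------------------------------------------------------------
# WFDB subset I/O (text .hea header + format-16 little-endian signed .dat)
# ---------------------------------------------------------------------------

def read_wfdb(path: str | Path, lead: str | None = None,
              manifest: dict[str, tuple[str, str]] | None = None) -> EcgRecord:
    """Read one lead from a WFDB record (``path`` without extension).

    Supports the format-16 subset (16-bit little-endian, interleaved
    channels) that :func:`write_wfdb` emits and that PhysioNet uses for
    many single-file records.

    Parameters
    ----------
    path : path without the ``.hea`` suffix (a ``.hea`` suffix is stripped).
    lead : lead name to extract; default is the first channel.
    """
    path = Path(path)
    if path.suffix == ".hea":
        path = path.with_suffix("")
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")

    lines = [ln.split("#")[0].strip() for ln in hea.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise ValueError(f"corrupt WFDB header (empty): {hea}")
    head = lines[0].split()
    if len(head) < 3:
        raise ValueError(f"corrupt WFDB header line in {hea}: {lines[0]!r}")
    try:
        n_sig = int(head[1])
        fs = float(head[2].split("/")[0])
    except ValueError as exc:
        raise ValueError(f"corrupt WFDB header in {hea}: {exc}") from exc

    sig_lines = lines[1:1 + n_sig]
    if len(sig_lines) < n_sig:
        raise ValueError(f"header {hea} declares {n_sig} signals, lists {len(sig_lines)}")

    dat_names, gains, baselines, leads = [], [], [], []
    for i, ln in enumerate(sig_lines):
        f = ln.split()
        if len(f) < 2:
            raise ValueError(f"corrupt signal spec in {hea}: {ln!r}")
        dat_names.append(f[0])
        fmt = f[1]
        if fmt.split("x")[0] != "16":
            raise ValueError(f"unsupported WFDB format {fmt!r} in {hea} (only 16)")
        # gain field may look like "200", "200(0)", "200/mV"
        gain_field = f[2] if len(f) > 2 else "200"
        m = re.match(r"([0-9.eE+-]+)(?:\(([-0-9]+)\))?", gain_field)
        gains.append(float(m.group(1)) if m and m.group(1) else 200.0)
        baselines.append(int(m.group(2)) if m and m.group(2) else 0)
        leads.append(f[-1] if len(f) > 4 else f"ch{i}")

    if len(set(dat_names)) != 1:
        raise ValueError(f"{hea}: multi-file records are not supported")
    dat = path.parent / dat_names[0]
    if not dat.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat}")

    raw = np.fromfile(dat, dtype="<i2")
    if n_sig > 1:
        raw = raw[: (len(raw) // n_sig) * n_sig].reshape(-1, n_sig)
    else:
        raw = raw.reshape(-1, 1)

    if lead is None:
        ch = 0
    else:
        lower = [l.lower() for l in leads]
        if lead.lower() not in lower:
            raise ValueError(f"lead {lead!r} not in record {path.name} (has {leads})")
        ch = lower.index(lead.lower())

    samples = (raw[:, ch].astype(float) - baselines[ch]) / gains[ch]
    stem = path.name
    subject, session = (manifest.get(stem, _parse_identity(stem))
                        if manifest else _parse_identity(stem))
    return EcgRecord(subject, session, leads[ch], fs, samples)


def write_wfdb(record: EcgRecord, path: str | Path, gain: float = 1000.0) -> None:
    """Write a record as a format-16 WFDB pair (``path.hea``/``path.dat``)."""
    path = Path(path)
    ints = np.clip(np.round(record.samples * gain), -32768, 32767).astype("<i2")
    path.with_suffix(".dat").write_bytes(ints.tobytes())
    hea = (f"{path.name} 1 {record.fs:g} {len(ints)}\n"
           f"{path.name}.dat 16 {gain:g}(0) 16 0 {ints[0]} 0 0 {record.lead}\n")
    path.with_suffix(".hea").write_text(hea)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_csv(path: str | Path, fs: float, lead: str = "i", has_header: bool = False,
             manifest: dict[str, tuple[str, str]] | None = None) -> EcgRecord:
    """Read a single-column CSV of amplitudes (mV) sampled at ``fs`` Hz."""
    path = Path(path)
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    lines = path.read_text().splitlines()
    if has_header and lines:
        lines = lines[1:]
    values = []
    for ln, line in enumerate(lines, start=2 if has_header else 1):
        line = line.strip()
        if not line:
            continue
        try:
            v = float(line.split(",")[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-numeric value {line!r}") from exc
        if not np.isfinite(v):
            raise ValueError(f"{path}:{ln}: non-finite value {line!r}")
        values.append(v)
    if not values:
        raise ValueError(f"{path}: no samples")
    stem = path.stem
    subject, session = (manifest.get(stem, _parse_identity(stem))
                        if manifest else _parse_identity(stem))
    return EcgRecord(subject, session, lead, fs, np.array(values))


def write_csv(record: EcgRecord, path: str | Path) -> None:
    np.savetxt(path, record.samples, fmt="%.6f")


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------

def preprocess(record: EcgRecord, low_hz: float = 0.5, high_hz: float = 40.0,
               order: int = 4) -> EcgRecord:
    """Zero-phase Butterworth band-pass conditioning.

    Removes DC and baseline wander below ``low_hz`` and high-frequency
    noise above ``high_hz`` without shifting fiducial timing
    (forward-backward filtering).  Length and sampling rate unchanged.
    """
    nyq = record.fs / 2.0
    if not (0 <= low_hz < high_hz):
        raise ValueError(f"need 0 <= low_hz < high_hz, got {low_hz}, {high_hz}")
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=record.fs,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, record.samples)
    return replace(record, samples=filtered,
                   meta={**record.meta, "band_hz": (low_hz, high_hz)})


def resample_record(record: EcgRecord, target_fs: float) -> EcgRecord:
    """Resample to ``target_fs``, rescaling any truth fiducial indices."""
    if target_fs <= 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if target_fs == record.fs:
        return record
    from fractions import Fraction

    frac = Fraction(target_fs / record.fs).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    samples = sps.resample_poly(record.samples, up, down)
    ratio = target_fs / record.fs
    fids = None
    if record.truth_fiducials is not None:
        n = len(samples)
        scale = lambda idx: np.clip(np.round(np.asarray(idx) * ratio), 0, n - 1).astype(int)
        fids = FiducialSet(r_peaks=scale(record.truth_fiducials.r_peaks),
                           p_peaks=scale(record.truth_fiducials.p_peaks))
    return replace(record, fs=target_fs, samples=samples, truth_fiducials=fids)
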