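"""Continuous wavelet transform scalograms and their rendered images.

The scalogram is the magnitude of the CWT of a segment,

    s_cwt(a, b) = 1/sqrt(a) * integral s(t) phi((t - b)/a) dt,

evaluated on a dyadic frequency grid.  The default mother wavelet is an
analytic (complex) Morlet; the magnitude matrix is min–max normalized,
mapped through a 256-entry jet colormap, and bilinearly resized to a
fixed square RGB image for the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pywt
from matplotlib import colormaps
from PIL import Image

from .segmentation import Segment, SegmentSet

__all__ = ["CwtParams", "Scalogram", "ScalogramImage", "cwt", "to_image",
           "segments_to_images"]


@dataclass(frozen=True)
class CwtParams:
    """CWT configuration.

    ``wavelet`` is any PyWavelets continuous wavelet name (default an
    analytic Morlet, bandwidth 1.5 / center frequency 1.0).  Scales are
    laid out dyadically from ``f_min`` to ``f_max`` with
    ``voices_per_octave`` rows per octave.
    """

    wavelet: str = "cmor1.5-1.0"
    voices_per_octave: int = 12
    f_min: float = 0.5
    f_max: float = 40.0

    def __post_init__(self) -> None:
        if self.voices_per_octave < 1:
            raise ValueError("voices_per_octave must be >= 1")
        if not (0 < self.f_min < self.f_max):
            raise ValueError("need 0 < f_min < f_max")

    def frequencies(self) -> np.ndarray:
        """Dyadic frequency grid, descending (high to low)."""
        n_octaves = np.log2(self.f_max / self.f_min)
        n = int(np.floor(n_octaves * self.voices_per_octave)) + 1
        freqs = self.f_min * 2.0 ** (np.arange(n) / self.voices_per_octave)
        return freqs[::-1]


@dataclass
class Scalogram:
    """|CWT| magnitudes, rows indexed by scale (descending frequency)."""

    magnitudes: np.ndarray        # (n_scales, n_samples), >= 0
    scale_frequencies: np.ndarray  # Hz per row, descending
    fs: float

    def __post_init__(self) -> None:
        if np.any(self.magnitudes < 0):
            raise ValueError("scalogram magnitudes must be non-negative")
        if self.magnitudes.shape[0] != len(self.scale_frequencies):
            raise ValueError("one frequency per scalogram row required")


@dataclass
class ScalogramImage:
    """Fixed-size RGB rendering of a scalogram, values in [0, 255]."""

    pixels: np.ndarray                 # (H, W, 3) uint8
    source: tuple[str, str] | None = None   # (subject_id, session_id)

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("image must be square")


def cwt(segment: Segment, params: CwtParams = CwtParams()) -> Scalogram:
    """Magnitude scalogram of a segment on a dyadic frequency grid.

    The segment is symmetrically padded by its own length before the
    transform and cropped after, so cone-of-influence edge artifacts do
    not dominate short windows.
    """
    x = segment.samples
    if len(x) < 8:
        raise ValueError("segment too short for CWT (need >= 8 samples)")
    fs = segment.fs
    if fs is None:
        raise ValueError("segment carries no sampling rate")
    if params.f_max > fs / 2:
        raise ValueError(f"f_max {params.f_max} Hz exceeds Nyquist {fs / 2} Hz")

    freqs = params.frequencies()
    fc = pywt.central_frequency(params.wavelet)
    scales = fc * fs / freqs

    n = len(x)
    padded = np.concatenate([x[::-1], x, x[::-1]])
    coefs, _ = pywt.cwt(padded, scales, params.wavelet,
                        sampling_period=1.0 / fs, method="fft")
    # L1 scale normalization: equal-amplitude sinusoids get equal peak
    # magnitude at every scale, so a tone peaks at its own frequency row
    mags = np.abs(coefs[:, n:2 * n]) / np.sqrt(scales)[:, None]
    return Scalogram(magnitudes=mags, scale_frequencies=freqs, fs=fs)


_JET = (colormaps["jet"](np.linspace(0, 1, 256))[:, :3] * 255).astype(np.uint8)


def to_image(scalogram: Scalogram, size: int = 224,
             colormap: np.ndarray | None = None) -> ScalogramImage:
    """Render a scalogram as a ``size``×``size`` RGB image.

    Magnitudes are min–max normalized per image (a constant scalogram
    maps to the colormap's lowest entry), looked up in a 256-entry jet
    colormap, and bilinearly resized.  Rows keep the scalogram's
    descending-frequency order, so low frequencies sit at the bottom.
    """
    lut = _JET if colormap is None else colormap
    m = scalogram.magnitudes
    lo, hi = float(m.min()), float(m.max())
    norm = np.zeros_like(m) if hi == lo else (m - lo) / (hi - lo)
    idx = np.clip(np.round(norm * 255), 0, 255).astype(np.uint8)
    rgb = lut[idx]
    img = Image.fromarray(rgb, mode="RGB").resize((size, size), Image.BILINEAR)
    return ScalogramImage(pixels=np.asarray(img, dtype=np.uint8))


def segments_to_images(segset: SegmentSet, params: CwtParams = CwtParams(),
                       size: int = 224) -> tuple[np.ndarray, np.ndarray]:
    """Batch helper: (images float32 scaled to [0,1], subject labels).

    Returns ``(X, y)`` with ``X`` of shape (n, size, size, 3) and ``y``
    the subject-id strings, aligned.
    """
    images = np.empty((len(segset), size, size, 3), dtype=np.float32)
    labels = np.empty(len(segset), dtype=object)
    for i, seg in enumerate(segset):
        img = to_image(cwt(seg, params), size=size)
        images[i] = img.pixels.astype(np.float32) / 255.0
        labels[i] = seg.subject_id
    return images, labels


def save_png(image: ScalogramImage, path: str | Path) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(Path(path), format="PNG")
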