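"""Biometric system entropy (BSE) of a representation.

BSE quantifies how much identity information a representation carries:
it is the Kullback–Leibler divergence between the density of *genuine*
similarity scores (same-subject pairs) and *imposter* scores
(cross-subject pairs),

    BSE = integral f_G(s) log( f_G(s) / f_I(s) ) ds  >=  0.

Scores default to the Pearson correlation of flattened representations;
densities are common-grid histograms with a small floor so the
divergence is always finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ScoreSet", "DensityPair", "pairwise_scores", "estimate_densities",
           "bse"]


@dataclass
class ScoreSet:
    genuine: np.ndarray
    imposter: np.ndarray

    def __post_init__(self) -> None:
        self.genuine = np.asarray(self.genuine, dtype=float)
        self.imposter = np.asarray(self.imposter, dtype=float)
        if self.genuine.size == 0 or self.imposter.size == 0:
            raise ValueError("both score lists must be non-empty")
        if not (np.all(np.isfinite(self.genuine))
                and np.all(np.isfinite(self.imposter))):
            raise ValueError("scores must be finite")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "label": ["genuine"] * len(self.genuine) + ["imposter"] * len(self.imposter),
            "score": np.concatenate([self.genuine, self.imposter]),
        })
        df.to_csv(path, index=False)


@dataclass
class DensityPair:
    """Histogram densities of genuine/imposter scores on a shared grid."""

    grid: np.ndarray      # bin edges, length n_bins + 1
    f_g: np.ndarray       # genuine density per bin
    f_i: np.ndarray       # imposter density per bin
    epsilon: float

    def __post_init__(self) -> None:
        widths = np.diff(self.grid)
        for name, f in (("f_g", self.f_g), ("f_i", self.f_i)):
            if np.any(f < 0):
                raise ValueError(f"{name} has negative entries")
            total = float(np.sum(f * widths))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} integrates to {total}, not 1")


def pearson_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two flattened representations."""
    a = np.ravel(a).astype(float)
    b = np.ravel(b).astype(float)
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _normalized_matrix(items: list[np.ndarray]) -> np.ndarray:
    """Stack flattened, centered, unit-norm rows for fast pair correlation."""
    mat = np.stack([np.ravel(np.asarray(it, dtype=np.float64)) for it in items])
    mat -= mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return mat / norms


def pairwise_scores(items: list[np.ndarray], labels: list[str],
                    n_genuine: int, n_imposter: int, seed: int = 0) -> ScoreSet:
    """Sample genuine and imposter similarity scores without duplicate pairs.

    Genuine pairs are distinct same-subject item pairs; imposter pairs
    are cross-subject item pairs.  Similarity is the Pearson correlation
    of the flattened representations.  Deterministic under ``seed``.
    """
    if len(items) != len(labels):
        raise ValueError("items and labels must be aligned")
    labels = np.asarray(labels, dtype=object)
    subjects = sorted(set(labels))
    if len(subjects) < 2:
        raise ValueError("need at least two subjects for imposter pairs")

    by_subject = {s: np.flatnonzero(labels == s) for s in subjects}
    n_gen_avail = sum(len(ix) * (len(ix) - 1) // 2 for ix in by_subject.values())
    counts = np.array([len(by_subject[s]) for s in subjects])
    total = counts.sum()
    n_imp_avail = (total * (total - 1) // 2) - n_gen_avail
    if n_genuine > n_gen_avail:
        raise ValueError(f"requested {n_genuine} genuine pairs, only {n_gen_avail} exist")
    if n_imposter > n_imp_avail:
        raise ValueError(f"requested {n_imposter} imposter pairs, only {n_imp_avail} exist")

    rng = np.random.default_rng(seed)
    mat = _normalized_matrix(items)

    def sample_pairs(pool_pairs: int, draw, n_wanted: int) -> np.ndarray:
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < n_wanted:
            i, j = draw()
            if i == j:
                continue
            chosen.add((min(i, j), max(i, j)))
        return np.array(sorted(chosen))

    # genuine: pick a subject weighted by its pair count, then two items
    subj_pair_counts = np.array(
        [len(by_subject[s]) * (len(by_subject[s]) - 1) // 2 for s in subjects],
        dtype=float)
    p_subj = subj_pair_counts / subj_pair_counts.sum()

    def draw_genuine():
        s = subjects[rng.choice(len(subjects), p=p_subj)]
        ix = by_subject[s]
        i, j = rng.choice(len(ix), size=2, replace=False)
        return int(ix[i]), int(ix[j])

    def draw_imposter():
        i, j = rng.integers(0, total, size=2)
        if labels[i] == labels[j]:
            return i, i  # rejected by caller
        return int(i), int(j)

    gen_pairs = sample_pairs(n_gen_avail, draw_genuine, n_genuine)
    imp_pairs = sample_pairs(n_imp_avail, draw_imposter, n_imposter)

    genuine = np.einsum("ij,ij->i", mat[gen_pairs[:, 0]], mat[gen_pairs[:, 1]])
    imposter = np.einsum("ij,ij->i", mat[imp_pairs[:, 0]], mat[imp_pairs[:, 1]])
    return ScoreSet(genuine=genuine, imposter=imposter)


def estimate_densities(scores: ScoreSet, n_bins: int = 100,
                       epsilon: float = 1e-6) -> DensityPair:
    """Common-grid histogram densities with an epsilon floor.

    The grid spans the pooled score range; each density gets a floor of
    ``epsilon`` (so the divergence integrand is finite wherever the
    genuine density has mass) and is renormalized to integrate to 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    pooled = np.concatenate([scores.genuine, scores.imposter])
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi == lo:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    widths = np.diff(edges)

    def density(x: np.ndarray) -> np.ndarray:
        hist, _ = np.histogram(x, bins=edges, density=True)
        hist = np.maximum(hist, epsilon)
        return hist / np.sum(hist * widths)

    return DensityPair(grid=edges, f_g=density(scores.genuine),
                       f_i=density(scores.imposter), epsilon=epsilon)


def bse(densities: DensityPair, unit: str = "nats") -> float:
    """KL divergence of the genuine density from the imposter density.

    Non-negative; zero iff the two densities coincide.  ``unit`` may be
    ``"nats"`` (natural log, default) or ``"bits"``.
    """
    widths = np.diff(densities.grid)
    kl = float(np.sum(densities.f_g * np.log(densities.f_g / densities.f_i) * widths))
    kl = max(kl, 0.0)  # guard tiny negative rounding residue
    if unit == "bits":
        return kl / np.log(2.0)
    if unit != "nats":
        raise ValueError(f"unknown unit {unit!r}")
    return kl


def bse_of_representations(items: list[np.ndarray], labels: list[str],
                           n_genuine: int = 9900, n_imposter: int = 9900,
                           seed: int = 0, n_bins: int = 100) -> float:
    """Convenience: pair sampling + density estimation + divergence."""
    scores = pairwise_scores(items, labels, n_genuine, n_imposter, seed=seed)
    return bse(estimate_densities(scores, n_bins=n_bins))
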