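"""Hue conversion, hue histograms and PCA feature compression.

Refined ROI pixels are converted from RGB to the HSV hue angle (degrees),
summarized as normalized histograms over [0, 360), and compressed with a
principal component analysis into the model-ready feature scores.

Achromatic pixels (max channel == min channel) have an undefined hue; they
are assigned 0 degrees, flagged, and excluded from histograms.  No circular
wrap-around handling is applied beyond the binning itself: synthetic data
keeps hues inside [0, 120] degrees, away from the 0/360 seam.  Callers
feeding real photographs whose hues straddle the seam should be aware that
the first and last bins are not adjacent in feature space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EmptyRoiError",
    "RankDeficientError",
    "HueHistogram",
    "PcaModel",
    "FeatureVector",
    "rgb_to_hue",
    "hue_histogram",
    "fit_pca",
    "project",
    "transform",
]


class EmptyRoiError(ValueError):
    """Raised when no usable (unmasked, chromatic) pixel remains."""


class RankDeficientError(ValueError):
    """PCA input rank is below the requested component count.

    ``achievable`` names the largest component count the data supports.
    """

    def __init__(self, rank: int, requested: int):
        self.achievable = rank
        super().__init__(
            f"rank-deficient input: rank {rank} < K={requested}; "
            f"achievable K is {rank}"
        )


def rgb_to_hue(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert 8-bit RGB pixels to HSV hue angles in degrees [0, 360).

    Parameters
    ----------
    pixels:
        Array of shape ``(..., 3)`` with values in [0, 255].

    Returns
    -------
    hues, chromatic:
        ``hues`` has the input's leading shape, in degrees.  ``chromatic``
        is a boolean array; achromatic pixels (max == min) get hue 0 and
        ``chromatic`` False.
    """
    arr = np.asarray(pixels, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("expected RGB triples in the last axis")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB values must lie in [0, 255]")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    mx = arr.max(axis=-1)
    mn = arr.min(axis=-1)
    chroma = mx - mn
    chromatic = chroma > 0
    safe = np.where(chromatic, chroma, 1.0)
    hue = np.zeros(arr.shape[:-1], dtype=float)
    is_r = chromatic & (mx == r)
    is_g = chromatic & ~is_r & (mx == g)
    is_b = chromatic & ~is_r & ~is_g
    hue[is_r] = np.mod((g - b)[is_r] / safe[is_r], 6.0)
    hue[is_g] = (b - r)[is_g] / safe[is_g] + 2.0
    hue[is_b] = (r - g)[is_b] / safe[is_b] + 4.0
    hue *= 60.0
    return np.mod(hue, 360.0), chromatic


@dataclass
class HueHistogram:
    """Normalized hue histogram over B equal-width bins on [0, 360)."""

    bin_edges: np.ndarray  # B+1 edges in degrees
    mass: np.ndarray  # B non-negative reals summing to 1
    n_pixels: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.bin_edges.size != self.mass.size + 1:
            raise ValueError("bin_edges must have one more element than mass")
        if abs(float(self.mass.sum()) - 1.0) > 1e-9:
            raise ValueError("histogram mass must sum to 1")


def hue_histogram(
    hues: np.ndarray,
    chromatic: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
    bins: int = 36,
) -> HueHistogram:
    """Histogram the hue values of the usable ROI pixels.

    ``mask`` selects ROI pixels (same shape as ``hues``); ``chromatic``
    flags pixels with a defined hue.  Both default to all-True.

    Raises
    ------
    EmptyRoiError
        If no unmasked chromatic pixel remains.
    """
    hues = np.asarray(hues, dtype=float)
    keep = np.ones(hues.shape, dtype=bool)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    if chromatic is not None:
        keep &= np.asarray(chromatic, dtype=bool)
    selected = hues[keep]
    if selected.size == 0:
        raise EmptyRoiError("no unmasked chromatic pixels in the ROI")
    counts, edges = np.histogram(selected, bins=bins, range=(0.0, 360.0))
    return HueHistogram(
        bin_edges=edges, mass=counts / counts.sum(), n_pixels=int(selected.size)
    )


@dataclass
class PcaModel:
    """Mean vector plus the top-K orthonormal loading vectors (rows)."""

    mean_vector: np.ndarray  # length B
    components: np.ndarray  # K x B, rows orthonormal

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean_vector": self.mean_vector.tolist(),
                "components": self.components.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PcaModel":
        payload = json.loads(text)
        return cls(
            mean_vector=np.asarray(payload["mean_vector"], dtype=float),
            components=np.asarray(payload["components"], dtype=float),
        )


@dataclass
class FeatureVector:
    """Model-ready features for one image: PCA scores plus optional metadata."""

    entry_ref: tuple
    modality: str
    pca_scores: np.ndarray
    metadata_features: Optional[np.ndarray] = None

    def as_array(self) -> np.ndarray:
        if self.metadata_features is None:
            return np.asarray(self.pca_scores, dtype=float)
        return np.concatenate(
            [np.asarray(self.pca_scores, dtype=float), self.metadata_features]
        )


def fit_pca(histograms: np.ndarray, n_components: int) -> PcaModel:
    """Fit a PCA on an N x B matrix of histogram rows.

    Components are the top-K right singular vectors of the mean-centered
    matrix, ordered by singular value descending.  Sign convention: the
    largest-magnitude loading of each component is positive.

    Raises
    ------
    ValueError
        If N <= K, K < 1, or the centered matrix has rank < K (the message
        names the achievable K).
    """
    X = np.asarray(histograms, dtype=float)
    if X.ndim != 2:
        raise ValueError("histograms must be an N x B matrix")
    n, b = X.shape
    if n_components < 1:
        raise ValueError("need at least one component")
    if n <= n_components:
        raise ValueError(f"need N > K rows, got N={n}, K={n_components}")
    mean = X.mean(axis=0)
    centered = X - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = max(n, b) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if rank < n_components:
        raise RankDeficientError(rank, n_components)
    components = vt[:n_components].copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PcaModel(mean_vector=mean, components=components)


def _as_mass(histogram) -> np.ndarray:
    if isinstance(histogram, HueHistogram):
        return histogram.mass
    return np.asarray(histogram, dtype=float)


def project(
    histogram,
    model: PcaModel,
    metadata: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Project one histogram onto the PCA basis: componentsᵀ·(mass − mean).

    ``metadata`` values, when given, are appended to the score vector.
    """
    mass = _as_mass(histogram)
    if mass.shape != model.mean_vector.shape:
        raise ValueError(
            f"dimension mismatch: histogram has {mass.size} bins, "
            f"model expects {model.mean_vector.size}"
        )
    scores = model.components @ (mass - model.mean_vector)
    if metadata is not None:
        scores = np.concatenate([scores, np.asarray(metadata, dtype=float)])
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite feature values")
    return scores


def transform(histograms: np.ndarray, model: PcaModel) -> np.ndarray:
    """Vectorized :func:`project` for an N x B matrix of histogram rows."""
    X = np.asarray(histograms, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.mean_vector.size:
        raise ValueError("histogram matrix does not match the PCA model")
    return (X - model.mean_vector) @ model.components.T
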