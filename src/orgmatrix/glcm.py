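"""GLCM texture analysis: correlation-vs-offset profiles and the mean
correlation distance, plus SHG signal coverage across z-stacks.

The grey-level co-occurrence matrix (GLCM) tabulates how often pairs of grey
levels co-occur at a given pixel offset and orientation.  Its Haralick
correlation, computed for offsets 1..d_max at 0/90/180/270 degrees and
averaged over the orientations, yields a correlation-versus-distance curve
``c(d)``; a slowly decaying curve indicates a long-range organised fibre
network.  The curve is summarised by the mean correlation distance

    D = sum_i d_i * c(d_i) / sum_i c(d_i)

with negative correlations clamped to zero so D remains a weighted mean of
offsets (see :func:`mean_correlation_distance`).

Co-occurrence counting itself is delegated to
``skimage.feature.graycomatrix`` (symmetric, normalised, out-of-bounds pairs
dropped); the correlation statistic and everything above it is computed
here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.feature import graycomatrix
from skimage.filters import threshold_otsu

from .errors import InvalidInputError, UndefinedStatisticError

__all__ = [
    "quantize",
    "compute_glcm",
    "glcm_correlation",
    "CorrelationProfile",
    "correlation_profile",
    "mean_correlation_distance",
    "CoverageProfile",
    "shg_coverage",
    "ORIENTATIONS_DEG",
    "DEFAULT_LEVELS",
]

#: the four co-occurrence orientations evaluated by default
ORIENTATIONS_DEG = (0, 90, 180, 270)

#: default grey-level count after quantization
DEFAULT_LEVELS = 64

_ANGLE_RAD = {0: 0.0, 90: np.pi / 2, 180: np.pi, 270: 3 * np.pi / 2}


def quantize(image: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Linearly rescale intensities to integer grey levels 0..levels-1.

    Integer images whose values already lie in ``0..levels-1`` are passed
    through unchanged, so hand-constructed level images keep their exact
    levels.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise InvalidInputError("expected a 2-D image")
    if not np.all(np.isfinite(image)):
        raise InvalidInputError("image contains non-finite values")
    if levels < 2 or levels > 256:
        raise InvalidInputError("levels must be in 2..256")
    if np.issubdtype(image.dtype, np.integer):
        if image.min() >= 0 and image.max() < levels:
            return image.astype(np.uint8)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros(image.shape, dtype=np.uint8)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def compute_glcm(
    image: np.ndarray,
    offset_px: int,
    orientation_deg: int,
    levels: int = DEFAULT_LEVELS,
) -> np.ndarray:
    """Normalised symmetric co-occurrence table for one offset/orientation.

    Pairs are counted in both directions (symmetric) and pairs extending
    past the image border are dropped; the table entries sum to 1.
    """
    if orientation_deg not in _ANGLE_RAD:
        raise InvalidInputError(
            f"orientation must be one of {sorted(_ANGLE_RAD)}, got {orientation_deg}"
        )
    q = quantize(image, levels)
    if offset_px < 1 or offset_px >= min(q.shape):
        raise InvalidInputError(
            f"offset {offset_px} must be in 1..{min(q.shape) - 1}"
        )
    n_levels = max(int(q.max()) + 1, 2)
    p = graycomatrix(
        q,
        distances=[offset_px],
        angles=[_ANGLE_RAD[orientation_deg]],
        levels=n_levels,
        symmetric=True,
        normed=True,
    )[:, :, 0, 0]
    if p.sum() == 0:
        raise InvalidInputError("offset leaves no in-bounds pixel pairs")
    return p


def glcm_correlation(glcm: np.ndarray) -> float:
    """Haralick correlation of a normalised symmetric co-occurrence table.

    ``sum_ij (i - mu)(j - mu) p(i, j) / sigma^2`` with the marginal mean and
    variance (identical for rows and columns of a symmetric table).

    Raises :class:`UndefinedStatisticError` when the marginal variance is
    zero (constant image).
    """
    p = np.asarray(glcm, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise InvalidInputError("co-occurrence table must be square")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise InvalidInputError("co-occurrence table must be normalised")
    i = np.arange(p.shape[0], dtype=float)
    px = p.sum(axis=1)
    mu = float(i @ px)
    var = float(((i - mu) ** 2) @ px)
    if var <= 0:
        raise UndefinedStatisticError(
            "correlation undefined: zero marginal variance (constant image)"
        )
    cov = float(np.einsum("i,j,ij->", i - mu, i - mu, p))
    return cov / var


@dataclass
class CorrelationProfile:
    """Orientation-averaged GLCM correlation as a function of pixel offset."""

    offsets_px: np.ndarray
    correlation: np.ndarray
    orientations_deg: tuple

    def __post_init__(self) -> None:
        self.offsets_px = np.asarray(self.offsets_px, dtype=int)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.offsets_px.shape != self.correlation.shape:
            raise InvalidInputError("offsets and correlations differ in length")
        if np.any(np.diff(self.offsets_px) <= 0):
            raise InvalidInputError("offsets must be strictly increasing")


def correlation_profile(
    image: np.ndarray,
    d_max: int = 100,
    levels: int = DEFAULT_LEVELS,
    orientations_deg: Sequence[int] = ORIENTATIONS_DEG,
) -> CorrelationProfile:
    """GLCM correlation at offsets 1..d_max averaged over orientations.

    The default offset range (1-pixel increments up to 100 pixels) and the
    four orientations 0/90/180/270 degrees follow standard practice for SHG
    matrix-texture quantification.  Averaging happens on the correlation
    values, not on the co-occurrence tables.
    """
    q = quantize(image, levels)
    if d_max < 1 or d_max >= min(q.shape):
        raise InvalidInputError(f"d_max must be in 1..{min(q.shape) - 1}")
    bad = [o for o in orientations_deg if o not in _ANGLE_RAD]
    if bad:
        raise InvalidInputError(f"unsupported orientations: {bad}")
    n_levels = max(int(q.max()) + 1, 2)
    distances = np.arange(1, d_max + 1)
    angles = [_ANGLE_RAD[o] for o in orientations_deg]
    p = graycomatrix(
        q, distances=distances, angles=angles,
        levels=n_levels, symmetric=True, normed=True,
    )  # (levels, levels, n_d, n_a)
    i = np.arange(n_levels, dtype=float)
    px = p.sum(axis=1)  # marginals, (levels, n_d, n_a)
    mu = np.einsum("i,ida->da", i, px)
    var = np.einsum("ida,ida->da", (i[:, None, None] - mu) ** 2, px)
    if np.any(var <= 0):
        raise UndefinedStatisticError(
            "correlation undefined at some offset (zero marginal variance)"
        )
    dev = i[:, None, None] - mu  # (levels, n_d, n_a)
    cov = np.einsum("ida,jda,ijda->da", dev, dev, p)
    corr = (cov / var).mean(axis=1)  # average over orientations
    return CorrelationProfile(
        offsets_px=distances,
        correlation=corr,
        orientations_deg=tuple(orientations_deg),
    )


def mean_correlation_distance(profile: CorrelationProfile) -> float:
    """Offset-weighted mean of the (clamped) correlation profile.

    ``D = sum_i d_i c^(d_i) / sum_i c^(d_i)`` where the sum runs over the
    leading positively-correlated stretch of the profile: offsets are kept
    up to (exclusive) the first non-positive correlation, and any remaining
    negative values are clamped to zero.  Negative correlations would turn
    D into an ill-defined signed weighting, and beyond the first zero
    crossing the profile is sampling noise around zero — including it would
    let arbitrarily weak fluctuations at large offsets dominate the
    statistic.
    """
    if profile.offsets_px.size == 0:
        raise InvalidInputError("empty correlation profile")
    nonpos = np.nonzero(profile.correlation <= 0)[0]
    cut = int(nonpos[0]) if nonpos.size else profile.correlation.size
    c = np.zeros_like(profile.correlation)
    c[:cut] = np.clip(profile.correlation[:cut], 0.0, None)
    total = c.sum()
    if total <= 0:
        raise UndefinedStatisticError(
            "mean correlation distance undefined: all clamped correlations zero"
        )
    return float((profile.offsets_px * c).sum() / total)


@dataclass
class CoverageProfile:
    """Per-slice percentage coverage through a z-stack, and its peak."""

    coverage_pct: np.ndarray
    peak_coverage_pct: float
    peak_slice_index: int
    threshold: float


def shg_coverage(
    zstack: Sequence[np.ndarray] | np.ndarray,
    threshold: float | str = "otsu",
) -> CoverageProfile:
    """Percent of pixels above threshold per slice; the peak slice is the
    comparison statistic.

    ``threshold="otsu"`` derives a single Otsu threshold from the pooled
    stack; a numeric value is applied as-is (pixels strictly above count).
    """
    stack = np.asarray(zstack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None, ...]
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise InvalidInputError("expected a non-empty stack of 2-D slices")
    if threshold == "otsu":
        flat = stack.ravel()
        if np.ptp(flat) == 0:  # constant stack: nothing exceeds any threshold
            thr = float(flat[0])
        else:
            thr = float(threshold_otsu(flat))
    else:
        thr = float(threshold)
    coverage = 100.0 * (stack > thr).mean(axis=(1, 2))
    peak = int(np.argmax(coverage))
    return CoverageProfile(
        coverage_pct=coverage,
        peak_coverage_pct=float(coverage[peak]),
        peak_slice_index=peak,
        threshold=thr,
    )
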