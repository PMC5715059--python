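"""Histology quantification: picrosirius-red birefringence classification,
stain-coverage measurements and per-ROI positive-cell scoring.

Birefringence classes are defined by inclusive boxes in 8-bit
Hue-Saturation-Brightness space, exactly as used for ImageJ-style polarized
light analysis of picrosirius-red sections:

===========  =========  =========  =========
class        H          S          B
===========  =========  =========  =========
red-orange   0-29       0-255      70-255
yellow       30-44      0-255      70-255
green        45-245     0-255      70-200
total fibre  0-245      0-255      70-200
===========  =========  =========  =========

Relative class areas are reported as a percentage of the total-fibre mask.
Note the printed red-orange/yellow brightness cap (255) exceeds the
total-fibre cap (200): class pixels brighter than 200 are counted in their
class but excluded from the denominator.  The boxes are applied exactly as
printed and such pixels are flagged in the result metadata rather than
silently reassigned.

DAB immunohistochemistry coverage uses colour deconvolution: per-channel
optical density ``OD = -log10(I / 255)`` unmixed through a stain matrix
(standard haematoxylin-DAB vectors by default) followed by thresholding the
DAB channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    InvalidInputError,
    InvalidThresholdError,
    UndefinedStatisticError,
)

__all__ = [
    "ChannelRange",
    "HsbBox",
    "BirefringenceThresholds",
    "DEFAULT_BIREFRINGENCE_THRESHOLDS",
    "classify_birefringence",
    "total_fibre_mask",
    "BirefringenceResult",
    "relative_areas",
    "picrosirius_coverage",
    "dab_coverage",
    "DEFAULT_HDAB_VECTORS",
    "mix_stains",
    "unmix_stains",
    "RoiScore",
    "score_rois",
    "CLASS_CODES",
]

#: integer codes in the class map
CLASS_CODES = {"none": 0, "red_orange": 1, "yellow": 2, "green": 3}
_CODE_NAMES = {v: k for k, v in CLASS_CODES.items()}


@dataclass(frozen=True)
class HsbBox:
    """Inclusive H/S/B ranges on 0..255."""

    h: tuple
    s: tuple
    b: tuple

    def __post_init__(self) -> None:
        for name, (lo, hi) in zip("hsb", (self.h, self.s, self.b)):
            if not (0 <= lo <= hi <= 255):
                raise InvalidThresholdError(
                    f"{name} range ({lo}, {hi}) must satisfy 0 <= min <= max <= 255"
                )

    def contains(self, h: np.ndarray, s: np.ndarray, b: np.ndarray) -> np.ndarray:
        return (
            (h >= self.h[0]) & (h <= self.h[1])
            & (s >= self.s[0]) & (s <= self.s[1])
            & (b >= self.b[0]) & (b <= self.b[1])
        )


@dataclass(frozen=True)
class BirefringenceThresholds:
    """HSB boxes for the three birefringence classes and the total mask."""

    red_orange: HsbBox = field(default_factory=lambda: HsbBox((0, 29), (0, 255), (70, 255)))
    yellow: HsbBox = field(default_factory=lambda: HsbBox((30, 44), (0, 255), (70, 255)))
    green: HsbBox = field(default_factory=lambda: HsbBox((45, 245), (0, 255), (70, 200)))
    total_fibres: HsbBox = field(default_factory=lambda: HsbBox((0, 245), (0, 255), (70, 200)))


DEFAULT_BIREFRINGENCE_THRESHOLDS = BirefringenceThresholds()


def _split_hsb(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise InvalidInputError("expected an (H, W, 3) HSB image")
    if image.min() < 0 or image.max() > 255:
        raise InvalidInputError("HSB channels must lie in 0..255")
    return image[..., 0], image[..., 1], image[..., 2]


def classify_birefringence(
    image: np.ndarray,
    thresholds: BirefringenceThresholds = DEFAULT_BIREFRINGENCE_THRESHOLDS,
) -> np.ndarray:
    """Label each pixel red_orange (1), yellow (2), green (3) or none (0).

    Boxes are tested in the order red-orange, yellow, green; with the
    default thresholds the hue ranges are disjoint so the order is
    irrelevant, but it makes behaviour under pathological custom thresholds
    deterministic.
    """
    h, s, b = _split_hsb(image)
    out = np.zeros(h.shape, dtype=np.uint8)
    for name in ("red_orange", "yellow", "green"):
        box: HsbBox = getattr(thresholds, name)
        mask = box.contains(h, s, b) & (out == 0)
        out[mask] = CLASS_CODES[name]
    return out


def total_fibre_mask(
    image: np.ndarray,
    thresholds: BirefringenceThresholds = DEFAULT_BIREFRINGENCE_THRESHOLDS,
) -> np.ndarray:
    """Boolean mask of pixels inside the total-fibre box (the denominator)."""
    h, s, b = _split_hsb(image)
    return thresholds.total_fibres.contains(h, s, b)


@dataclass
class BirefringenceResult:
    """Pixel counts per class and relative areas as % of total fibres."""

    pixel_counts: dict
    total_fibre_pixels: int
    relative_area_pct: dict
    n_class_pixels_outside_total: int


def relative_areas(
    class_map: np.ndarray, total_mask: np.ndarray
) -> BirefringenceResult:
    """Relative area of each class as a percentage of the total-fibre mask.

    Numerators come from the class boxes, the denominator from the printed
    total-fibre box; class pixels falling outside the denominator are
    counted and reported (``n_class_pixels_outside_total``) so the caller
    can see when relative areas exceed the naive within-mask fractions.
    """
    class_map = np.asarray(class_map)
    total_mask = np.asarray(total_mask, dtype=bool)
    if class_map.shape != total_mask.shape:
        raise InvalidInputError("class map and total mask shapes differ")
    total = int(total_mask.sum())
    if total == 0:
        raise UndefinedStatisticError("no total-fibre pixels: relative area undefined")
    counts = {
        name: int((class_map == code).sum())
        for name, code in CLASS_CODES.items()
        if name != "none"
    }
    outside = int(((class_map != 0) & ~total_mask).sum())
    rel = {name: 100.0 * n / total for name, n in counts.items()}
    return BirefringenceResult(
        pixel_counts=counts,
        total_fibre_pixels=total,
        relative_area_pct=rel,
        n_class_pixels_outside_total=outside,
    )


def picrosirius_coverage(
    rgb: np.ndarray,
    dominance_margin: int = 20,
    min_red: int = 60,
) -> float:
    """Percent of pixels carrying picrosirius-red stain (transmitted light).

    A pixel counts as stained when its red channel dominates both green and
    blue by at least ``dominance_margin`` and exceeds ``min_red`` — a plain
    red-dominance rule appropriate for brightfield picrosirius sections
    (blank white background is never red-dominant).
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3 or rgb.size == 0:
        raise InvalidInputError("expected a non-empty (H, W, 3) RGB image")
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    stained = (r >= min_red) & (r - g >= dominance_margin) & (r - b >= dominance_margin)
    return float(100.0 * stained.mean())


# Ruifrok & Johnston unit OD vectors for haematoxylin and DAB; the third
# row is their cross product (the residual channel), renormalised.
_HEMA = np.array([0.650, 0.704, 0.286])
_DAB = np.array([0.269, 0.568, 0.776])
_RESID = np.cross(_HEMA, _DAB)
DEFAULT_HDAB_VECTORS = np.vstack(
    [
        _HEMA / np.linalg.norm(_HEMA),
        _DAB / np.linalg.norm(_DAB),
        _RESID / np.linalg.norm(_RESID),
    ]
)


def mix_stains(concentrations: np.ndarray, stain_vectors: np.ndarray) -> np.ndarray:
    """Forward model: stain concentrations -> 8-bit RGB transmitted image."""
    od = np.asarray(concentrations, dtype=float) @ np.asarray(stain_vectors, dtype=float)
    return 255.0 * np.power(10.0, -od)


def unmix_stains(rgb: np.ndarray, stain_vectors: np.ndarray) -> np.ndarray:
    """Invert Beer-Lambert mixing: RGB -> per-stain concentration maps."""
    m = np.asarray(stain_vectors, dtype=float)
    if m.shape != (3, 3):
        raise InvalidInputError("stain matrix must be 3x3")
    if abs(np.linalg.det(m)) < 1e-8:
        raise InvalidInputError("stain matrix is singular; cannot unmix")
    rgb = np.asarray(rgb, dtype=float)
    od = -np.log10(np.maximum(rgb / 255.0, 1e-6))
    return od @ np.linalg.inv(m)


def dab_coverage(
    rgb: np.ndarray,
    stain_vectors: np.ndarray = DEFAULT_HDAB_VECTORS,
    dab_threshold: float = 0.15,
) -> float:
    """Percent of pixels whose unmixed DAB optical density exceeds threshold.

    The DAB channel is assumed to be the second row of ``stain_vectors``
    (haematoxylin, DAB, residual).
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3 or rgb.size == 0:
        raise InvalidInputError("expected a non-empty (H, W, 3) RGB image")
    conc = unmix_stains(rgb, stain_vectors)
    return float(100.0 * (conc[..., 1] > dab_threshold).mean())


@dataclass
class RoiScore:
    """Positive-cell count in one square region of interest."""

    roi_id: int
    roi_size_um: float
    positive_count: int


def score_rois(
    cells: pd.DataFrame,
    roi_size_um: float = 500.0,
    n_rois: int = 10,
    um_per_px: float | None = None,
) -> list[RoiScore]:
    """Count positive cells per ROI on a regular square grid.

    ``cells`` needs columns ``x``, ``y`` and boolean ``positive``.
    Coordinates are in micrometres unless ``um_per_px`` is given, in which
    case they are pixel positions converted with that calibration; pixel
    coordinates without a calibration are an error.  ROI membership is by
    cell centroid with half-open intervals ``[x0, x0 + roi_size)`` so a
    cell on a shared edge is counted exactly once.  ROIs are numbered
    row-major over the grid and the first ``n_rois`` are returned.
    """
    required = {"x", "y", "positive"}
    if not required.issubset(cells.columns):
        raise InvalidInputError(f"cell table needs columns {sorted(required)}")
    unit = str(cells.attrs.get("coordinate_unit", "um"))
    if unit == "px" and um_per_px is None:
        raise InvalidInputError(
            "cell coordinates are in pixels; um_per_px calibration required"
        )
    scale = um_per_px if (um_per_px is not None) else 1.0
    x = cells["x"].to_numpy(dtype=float) * scale
    y = cells["y"].to_numpy(dtype=float) * scale
    if np.any(x < 0) or np.any(y < 0):
        raise InvalidInputError("cell positions must be non-negative")
    pos = cells["positive"].to_numpy(dtype=bool)
    col = np.floor(x / roi_size_um).astype(int)
    row = np.floor(y / roi_size_um).astype(int)
    n_cols = int(col.max()) + 1 if len(col) else 1
    roi_index = row * n_cols + col
    scores = []
    for rid in range(n_rois):
        inside = roi_index == rid
        scores.append(
            RoiScore(
                roi_id=rid,
                roi_size_um=roi_size_um,
                positive_count=int(np.count_nonzero(pos & inside)),
            )
        )
    return scores
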