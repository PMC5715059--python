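"""Synthetic inputs with known ground truth for every analysis module.

The generators emulate the data modalities of an organotypic collagen-matrix
study — fibre micrographs, textured SHG-like fields, AFM approach curves,
polarized-light histology scenes, invasion score sheets and qPCR Ct tables —
without attempting photorealism.  Each generator is a pure function of its
spec (including the seed), and always returns the ground truth alongside the
data so downstream recovery tests never need to re-derive it.

Conventions
-----------
Orientation angles live on the half-circle [0, 180) degrees, measured from
the image x-axis (columns) counter-clockwise as displayed, i.e. a fibre at
angle ``t`` runs along the direction ``(cos t, -sin t)`` in (column, row)
array coordinates.  The fibre-orientation module shares this convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .afm import ForceCurve, hertz_force
from .errors import InvalidSpecError

__all__ = [
    "FibreFieldSpec",
    "TextureFieldSpec",
    "ForceCurveSpec",
    "HistologySceneSpec",
    "InvasionTableSpec",
    "CtTableSpec",
    "generate_fibre_image",
    "generate_correlated_texture",
    "generate_force_curve",
    "generate_histology_scene",
    "generate_invasion_counts",
    "generate_ct_table",
    "DEPTH_BIN_COLUMNS",
    "HISTOLOGY_CLASS_NAMES",
]

DEPTH_BIN_COLUMNS = ("bin0_100", "bin100_200", "bin200_300", "bin300plus")
HISTOLOGY_CLASS_NAMES = ("red_orange", "yellow", "green", "background")


# --------------------------------------------------------------------------
# fibre micrographs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FibreFieldSpec:
    """Fibre micrograph with von Mises-distributed orientations.

    ``orientation_kappa`` is the von Mises concentration on the doubled
    angle (axial data); 0 gives isotropic fibres.  ``fibre_length_px`` of
    ``None`` defaults to 60% of the smaller image dimension.
    """

    image_height_px: int
    image_width_px: int
    n_fibres: int
    fibre_width_px: float = 4.0
    orientation_mean_deg: float = 0.0
    orientation_kappa: float = 0.0
    intensity_noise_sd: float = 0.02
    fibre_length_px: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise InvalidSpecError("image dimensions must be positive")
        if self.n_fibres < 0:
            raise InvalidSpecError("n_fibres must be non-negative")
        if self.fibre_width_px <= 0:
            raise InvalidSpecError("fibre_width_px must be positive")
        if not 0.0 <= self.orientation_mean_deg < 180.0:
            raise InvalidSpecError("orientation_mean_deg must be in [0, 180)")
        if self.orientation_kappa < 0:
            raise InvalidSpecError("orientation_kappa must be non-negative")
        if self.intensity_noise_sd < 0:
            raise InvalidSpecError("intensity_noise_sd must be non-negative")


def sample_axial_von_mises(
    rng: np.random.Generator, mean_deg: float, kappa: float, n: int
) -> np.ndarray:
    """Draw axial orientations in degrees on [0, 180).

    Uses the double-angle construction: sample von Mises on the full circle
    at 2*mean with concentration kappa, then halve.  kappa = 0 reduces to a
    uniform distribution on the half-circle.
    """
    if kappa == 0:
        return rng.uniform(0.0, 180.0, size=n)
    doubled = rng.vonmises(math.radians(2.0 * mean_deg), kappa, size=n)
    return (np.degrees(doubled) / 2.0) % 180.0


def _render_segment(
    image: np.ndarray,
    cx: float,
    cy: float,
    angle_deg: float,
    half_length: float,
    sigma: float,
) -> None:
    # Gaussian-profile anti-aliased stroke accumulated into `image` in place.
    h, w = image.shape
    t = math.radians(angle_deg)
    dx, dy = math.cos(t), -math.sin(t)  # (col, row) direction, y-up display
    x0, y0 = cx - half_length * dx, cy - half_length * dy
    x1, y1 = cx + half_length * dx, cy + half_length * dy
    pad = 3.0 * sigma + 1.0
    c_lo = max(int(math.floor(min(x0, x1) - pad)), 0)
    c_hi = min(int(math.ceil(max(x0, x1) + pad)) + 1, w)
    r_lo = max(int(math.floor(min(y0, y1) - pad)), 0)
    r_hi = min(int(math.ceil(max(y0, y1) + pad)) + 1, h)
    if c_lo >= c_hi or r_lo >= r_hi:
        return
    cols = np.arange(c_lo, c_hi, dtype=float)[None, :]
    rows = np.arange(r_lo, r_hi, dtype=float)[:, None]
    # point-to-segment distance, vectorised over the bounding box
    vx, vy = x1 - x0, y1 - y0
    seg_len2 = vx * vx + vy * vy
    if seg_len2 == 0:
        d2 = (cols - x0) ** 2 + (rows - y0) ** 2
    else:
        s = ((cols - x0) * vx + (rows - y0) * vy) / seg_len2
        s = np.clip(s, 0.0, 1.0)
        d2 = (cols - (x0 + s * vx)) ** 2 + (rows - (y0 + s * vy)) ** 2
    image[r_lo:r_hi, c_lo:c_hi] += np.exp(-d2 / (2.0 * sigma * sigma))


@dataclass
class SimulatedFibreImage:
    image: np.ndarray
    orientations_deg: np.ndarray
    spec: FibreFieldSpec


def generate_fibre_image(spec: FibreFieldSpec) -> SimulatedFibreImage:
    """Render ``n_fibres`` Gaussian-profile strokes plus intensity noise.

    Returns the image (float in [0, 1]) and the drawn orientations.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px
    image = np.zeros((h, w), dtype=float)
    orientations = sample_axial_von_mises(
        rng, spec.orientation_mean_deg, spec.orientation_kappa, spec.n_fibres
    )
    length = (
        spec.fibre_length_px
        if spec.fibre_length_px is not None
        else 0.6 * min(h, w)
    )
    sigma = spec.fibre_width_px / 2.0
    centers_x = rng.uniform(0, w, size=spec.n_fibres)
    centers_y = rng.uniform(0, h, size=spec.n_fibres)
    for cx, cy, ang in zip(centers_x, centers_y, orientations):
        _render_segment(image, cx, cy, ang, length / 2.0, sigma)
    # normalise by the max instead of hard-clipping overlaps: saturated
    # plateaus at fibre crossings distort local-orientation statistics
    peak = image.max()
    if peak > 1.0:
        image /= peak
    if spec.intensity_noise_sd > 0:
        image += rng.normal(0.0, spec.intensity_noise_sd, size=image.shape)
        np.clip(image, 0.0, 1.0, out=image)
    return SimulatedFibreImage(image=image, orientations_deg=orientations, spec=spec)


# --------------------------------------------------------------------------
# correlated random textures
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TextureFieldSpec:
    """Stationary Gaussian random field with squared-exponential correlation.

    The target autocorrelation is ``rho(d) = exp(-(d / correlation_length)^2)``,
    realised by smoothing white noise with a Gaussian kernel of
    ``sigma = correlation_length / 2`` under periodic boundary conditions.
    """

    image_height_px: int
    image_width_px: int
    correlation_length_px: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise InvalidSpecError("image dimensions must be positive")
        if self.correlation_length_px <= 0:
            raise InvalidSpecError("correlation_length_px must be positive")


def generate_correlated_texture(spec: TextureFieldSpec) -> np.ndarray:
    """Return a [0, 1]-rescaled correlated random field."""
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal((spec.image_height_px, spec.image_width_px))
    fieldv = ndimage.gaussian_filter(
        white, sigma=spec.correlation_length_px / 2.0, mode="wrap"
    )
    ptp = fieldv.max() - fieldv.min()
    if ptp < 1e-12:  # degenerate: correlation length >> image, flat field
        return np.full_like(fieldv, 0.5)
    return (fieldv - fieldv.min()) / ptp


# --------------------------------------------------------------------------
# AFM force curves
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ForceCurveSpec:
    """Hertz forward-model approach curve with optional additive noise.

    The z grid spans 0.75 * max_indentation of pre-contact travel followed
    by max_indentation of indentation, so ~43% of samples are out of
    contact (enough for baseline estimation).
    """

    true_modulus_Pa: float
    tip_radius_um: float = 0.5
    poisson_ratio: float = 0.5
    contact_z_um: float = 0.0
    max_indentation_um: float = 1.0
    n_samples: int = 400
    force_noise_sd_nN: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_modulus_Pa <= 0:
            raise InvalidSpecError("true_modulus_Pa must be positive")
        if self.tip_radius_um <= 0:
            raise InvalidSpecError("tip_radius_um must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise InvalidSpecError("poisson_ratio must be in [0, 0.5]")
        if self.max_indentation_um <= 0:
            raise InvalidSpecError("max_indentation_um must be positive")
        if self.n_samples < 20:
            raise InvalidSpecError("n_samples must be at least 20")
        if self.force_noise_sd_nN < 0:
            raise InvalidSpecError("force_noise_sd_nN must be non-negative")


def generate_force_curve(spec: ForceCurveSpec) -> ForceCurve:
    """Simulate one approach curve; truth is carried in the metadata."""
    rng = np.random.default_rng(spec.seed)
    z = np.linspace(
        spec.contact_z_um - 0.75 * spec.max_indentation_um,
        spec.contact_z_um + spec.max_indentation_um,
        spec.n_samples,
    )
    force = hertz_force(
        z - spec.contact_z_um,
        spec.true_modulus_Pa,
        spec.tip_radius_um,
        spec.poisson_ratio,
    )
    if spec.force_noise_sd_nN > 0:
        force = force + rng.normal(0.0, spec.force_noise_sd_nN, size=z.shape)
    return ForceCurve(
        z_um=z,
        force_nN=force,
        metadata={
            "true_modulus_Pa": spec.true_modulus_Pa,
            "true_contact_z_um": spec.contact_z_um,
            "tip_radius_um": spec.tip_radius_um,
            "poisson_ratio": spec.poisson_ratio,
        },
    )


# --------------------------------------------------------------------------
# polarized-light histology scenes
# --------------------------------------------------------------------------

# Inclusive HSB sampling boxes per class.  Fibre classes are sampled inside
# the intersection of their threshold box with the total-fibre box
# (brightness capped at 200) so the stated class fractions are fractions of
# the total-fibre mask; background is sampled below the brightness floor.
_SCENE_BOXES = {
    "red_orange": ((0, 29), (0, 255), (70, 200)),
    "yellow": ((30, 44), (0, 255), (70, 200)),
    "green": ((45, 245), (0, 255), (70, 200)),
    "background": ((0, 255), (0, 255), (0, 69)),
}


@dataclass(frozen=True)
class HistologySceneSpec:
    """Pixel-wise mixture of birefringence classes in HSB space."""

    class_fractions: dict
    image_height_px: int = 256
    image_width_px: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise InvalidSpecError("image dimensions must be positive")
        unknown = set(self.class_fractions) - set(HISTOLOGY_CLASS_NAMES)
        if unknown:
            raise InvalidSpecError(f"unknown class labels: {sorted(unknown)}")
        vals = [self.class_fractions.get(k, 0.0) for k in HISTOLOGY_CLASS_NAMES]
        if any(v < 0 for v in vals):
            raise InvalidSpecError("class fractions must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise InvalidSpecError("class fractions must sum to 1")


@dataclass
class SimulatedHistologyScene:
    hsb: np.ndarray  # (H, W, 3) uint8
    labels: np.ndarray  # (H, W) int index into HISTOLOGY_CLASS_NAMES
    spec: HistologySceneSpec


def generate_histology_scene(spec: HistologySceneSpec) -> SimulatedHistologyScene:
    """Assign each pixel a class and sample H, S, B inside its box."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.image_height_px, spec.image_width_px)
    probs = np.array(
        [spec.class_fractions.get(k, 0.0) for k in HISTOLOGY_CLASS_NAMES]
    )
    labels = rng.choice(len(HISTOLOGY_CLASS_NAMES), size=shape, p=probs)
    hsb = np.zeros(shape + (3,), dtype=np.uint8)
    for idx, name in enumerate(HISTOLOGY_CLASS_NAMES):
        mask = labels == idx
        n = int(mask.sum())
        if n == 0:
            continue
        for ch, (lo, hi) in enumerate(_SCENE_BOXES[name]):
            hsb[..., ch][mask] = rng.integers(lo, hi + 1, size=n, dtype=np.uint8)
    return SimulatedHistologyScene(hsb=hsb, labels=labels, spec=spec)


# --------------------------------------------------------------------------
# invasion count tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class InvasionTableSpec:
    """Scored cell-count sheets for an organotypic invasion assay.

    Per ROI: surface count ~ Poisson(surface_mean); invaded counts per depth
    bin ~ Poisson(surface_mean * fraction); marker positives ~
    Binomial(total cells, marker_positive_fraction).
    """

    conditions: tuple
    vehicle_label: str
    true_depth_fractions: dict  # condition -> 4 fractions
    replicates_per_condition: int = 3
    rois_per_replicate: int = 9
    surface_mean: float = 100.0
    marker_positive_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vehicle_label not in self.conditions:
            raise InvalidSpecError(
                f"vehicle label {self.vehicle_label!r} not among conditions"
            )
        if set(self.true_depth_fractions) != set(self.conditions):
            raise InvalidSpecError("need depth fractions for every condition")
        for cond, fr in self.true_depth_fractions.items():
            if len(fr) != 4 or any(v < 0 for v in fr):
                raise InvalidSpecError(
                    f"condition {cond!r}: need 4 non-negative depth fractions"
                )
        if self.replicates_per_condition <= 0 or self.rois_per_replicate <= 0:
            raise InvalidSpecError("replicates and ROIs must be positive")
        if self.surface_mean <= 0:
            raise InvalidSpecError("surface_mean must be positive")
        if not 0.0 <= self.marker_positive_fraction <= 1.0:
            raise InvalidSpecError("marker_positive_fraction must be in [0, 1]")


def generate_invasion_counts(spec: InvasionTableSpec) -> pd.DataFrame:
    """One row per ROI with surface, per-bin invaded and marker counts."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cond in spec.conditions:
        fracs = np.asarray(spec.true_depth_fractions[cond], dtype=float)
        for rep in range(1, spec.replicates_per_condition + 1):
            for roi in range(1, spec.rois_per_replicate + 1):
                surface = int(rng.poisson(spec.surface_mean))
                bins = rng.poisson(spec.surface_mean * fracs).astype(int)
                total = surface + int(bins.sum())
                marker_pos = (
                    int(rng.binomial(total, spec.marker_positive_fraction))
                    if total > 0
                    else 0
                )
                row = {
                    "condition": cond,
                    "replicate": rep,
                    "roi": roi,
                    "surface": surface,
                    "marker_pos": marker_pos,
                    "marker_total": total,
                }
                row.update(dict(zip(DEPTH_BIN_COLUMNS, bins.tolist())))
                rows.append(row)
    cols = ["condition", "replicate", "roi", "surface", *DEPTH_BIN_COLUMNS,
            "marker_pos", "marker_total"]
    return pd.DataFrame(rows)[cols]


# --------------------------------------------------------------------------
# qPCR Ct tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CtTableSpec:
    """Two-group Ct table with known fold changes.

    The treatment group's delta-Ct for each gene is shifted by
    ``-log2(true_fold_change)`` relative to the reference group, so the
    comparative-CT method recovers the stated fold change exactly when
    ``ct_noise_sd`` is zero.
    """

    genes: tuple
    groups: tuple  # (reference_group, treatment_group)
    true_fold_changes: dict  # gene -> positive float
    reference_gene: str = "GAPDH"
    reference_gene_ct_mean: float = 18.0
    ct_noise_sd: float = 0.0
    replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) != 2:
            raise InvalidSpecError("exactly two groups (reference first)")
        if set(self.true_fold_changes) != set(self.genes):
            raise InvalidSpecError("need a fold change for every gene")
        if any(fc <= 0 for fc in self.true_fold_changes.values()):
            raise InvalidSpecError("fold changes must be positive")
        if self.ct_noise_sd < 0:
            raise InvalidSpecError("ct_noise_sd must be non-negative")
        if self.replicates < 2 and self.ct_noise_sd > 0:
            raise InvalidSpecError(
                "need at least 2 replicates when ct_noise_sd > 0"
            )
        if self.replicates < 1:
            raise InvalidSpecError("replicates must be positive")
        if self.reference_gene in self.genes:
            raise InvalidSpecError("reference gene cannot be a target gene")


def generate_ct_table(spec: CtTableSpec) -> pd.DataFrame:
    """Long-format table (sample, group, gene, ct) incl. the reference gene."""
    rng = np.random.default_rng(spec.seed)
    ref_group, trt_group = spec.groups
    rows = []
    for group in spec.groups:
        for rep in range(1, spec.replicates + 1):
            sample = f"{group}_{rep}"
            noise = lambda: rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd else 0.0
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "gene": spec.reference_gene,
                    "ct": spec.reference_gene_ct_mean + noise(),
                }
            )
            for gi, gene in enumerate(spec.genes):
                base = spec.reference_gene_ct_mean + 2.0 + 0.5 * gi
                shift = (
                    -math.log2(spec.true_fold_changes[gene])
                    if group == trt_group
                    else 0.0
                )
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "gene": gene,
                        "ct": base + shift + noise(),
                    }
                )
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])
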