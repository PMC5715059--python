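"""Hertz spherical-indentation analysis of AFM approach force curves.

Force curves are stored as probe height ``z`` (micrometres, increasing with
indentation) against measured force (nanonewtons).  The workflow mirrors how
force-spectroscopy data on soft hydrogel-like samples are usually handled:

1. :func:`baseline_correct` removes offset and tilt estimated from the
   pre-contact segment;
2. :func:`find_contact_point` locates the contact height by exhaustive
   residual minimisation of the Hertz model over candidate contact samples;
3. :func:`fit_hertz` performs the least-squares fit of
   ``F = (4/3) * E / (1 - nu**2) * sqrt(R) * delta**1.5``
   and reports the Young's modulus ``E`` in pascals;
4. :func:`summarize_force_map` aggregates fits over the measurement grid
   (three areas per matrix, nine points per area in the motivating assay);
5. :func:`matrix_thickness` converts two probe z-positions (matrix surface
   contact and dish bottom contact) into a matrix thickness.

Unit bookkeeping: with ``z``/``delta`` in um, force in nN and tip radius R in
um, ``F_nN = (4/3) * (E_Pa / (1 - nu^2)) * sqrt(R_um * 1e-6) * delta_um**1.5``
— the 1e-9 from delta^{3/2} in metres cancels the nN scaling exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyGroupError,
    FitFailureError,
    InvalidInputError,
    NoContactError,
)

__all__ = [
    "ForceCurve",
    "HertzFit",
    "ThicknessMeasurement",
    "hertz_force",
    "baseline_correct",
    "find_contact_point",
    "fit_hertz",
    "summarize_force_map",
    "matrix_thickness",
]

#: minimum number of samples for a usable approach curve
MIN_CURVE_SAMPLES = 20


def hertz_force(
    indentation_um: np.ndarray | float,
    modulus_pa: float,
    tip_radius_um: float,
    poisson_ratio: float = 0.5,
) -> np.ndarray | float:
    """Forward Hertz model for a spherical indenter.

    Parameters
    ----------
    indentation_um
        Indentation depth(s) past contact, um. Negative values are treated
        as zero (no contact, no force).
    modulus_pa
        Young's modulus of the sample, Pa.
    tip_radius_um
        Radius of the spherical probe, um.
    poisson_ratio
        Poisson ratio of the sample (0.5 = incompressible).

    Returns
    -------
    Force in nN, same shape as ``indentation_um``.
    """
    delta = np.maximum(np.asarray(indentation_um, dtype=float), 0.0)
    coeff = (4.0 / 3.0) * (modulus_pa / (1.0 - poisson_ratio**2)) * np.sqrt(
        tip_radius_um * 1e-6
    )
    out = coeff * delta**1.5
    return out if np.ndim(indentation_um) else float(out)


@dataclass
class ForceCurve:
    """One approach force-distance record.

    ``z_um`` must be strictly monotone; curves are normalised internally to
    ascending z with indentation at the high-z end.
    """

    z_um: np.ndarray
    force_nN: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)
        if self.z_um.ndim != 1 or self.z_um.shape != self.force_nN.shape:
            raise InvalidInputError("z and force must be 1-D and equal length")
        if self.z_um.size < MIN_CURVE_SAMPLES:
            raise InvalidInputError(
                f"force curve needs >= {MIN_CURVE_SAMPLES} samples, "
                f"got {self.z_um.size}"
            )
        dz = np.diff(self.z_um)
        if np.all(dz < 0):  # stored tip-retracted-first; flip to ascending
            self.z_um = self.z_um[::-1].copy()
            self.force_nN = self.force_nN[::-1].copy()
        elif not np.all(dz > 0):
            raise InvalidInputError("z_um must be strictly monotone")
        if not (np.all(np.isfinite(self.z_um)) and np.all(np.isfinite(self.force_nN))):
            raise InvalidInputError("force curve contains non-finite values")

    def __len__(self) -> int:
        return int(self.z_um.size)


@dataclass
class HertzFit:
    """Result of a Hertz-model fit to one approach curve."""

    contact_z_um: float
    young_modulus_Pa: float
    tip_radius_um: float
    poisson_ratio: float
    residual_rms_nN: float
    n_post_contact: int
    metadata: dict = field(default_factory=dict)


@dataclass
class ThicknessMeasurement:
    """Matrix thickness from two probe z positions on the same axis."""

    z_contact_matrix_um: float
    z_dish_um: float
    thickness_um: float
    thickness_mm: float


def baseline_correct(curve: ForceCurve, pre_fraction: float = 0.3) -> ForceCurve:
    """Subtract a linear baseline fitted on the pre-contact segment.

    The first ``pre_fraction`` of samples (lowest z) is assumed to be out of
    contact; a first-degree polynomial fitted there is removed from the whole
    curve so the pre-contact force is centred on zero.
    """
    if not 0.0 < pre_fraction < 1.0:
        raise InvalidInputError("pre_fraction must be in (0, 1)")
    n_pre = max(int(round(pre_fraction * len(curve))), 3)
    coeffs = np.polyfit(curve.z_um[:n_pre], curve.force_nN[:n_pre], deg=1)
    corrected = curve.force_nN - np.polyval(coeffs, curve.z_um)
    return ForceCurve(curve.z_um.copy(), corrected, dict(curve.metadata))


def _candidate_sse(
    z: np.ndarray, f: np.ndarray, i: int
) -> tuple[float, float]:
    """Sum of squared residuals and stiffness coefficient for contact at z[i].

    The model is piecewise: F = 0 for z < z[i], F = k * (z - z[i])**1.5
    beyond, with k obtained in closed form (linear in k).
    """
    delta = z[i:] - z[i]
    basis = delta**1.5
    denom = float(basis @ basis)
    k = float(basis @ f[i:]) / denom if denom > 0 else 0.0
    k = max(k, 0.0)
    sse = float(f[:i] @ f[:i]) + float(np.sum((f[i:] - k * basis) ** 2))
    return sse, k


def find_contact_point(
    curve: ForceCurve,
    min_post_samples: int = 10,
    min_signal_to_noise: float = 5.0,
) -> float:
    """Locate the contact height by Hertz-residual minimisation.

    Every sample (except guard bands at both ends) is tried as the contact
    point; for each candidate the piecewise zero/Hertz model is fitted in
    closed form and the candidate with the smallest total squared residual
    wins.  The search is exhaustive and deterministic.

    Raises
    ------
    NoContactError
        If the fitted indentation signal (model force at full indentation)
        does not exceed ``min_signal_to_noise`` times the residual noise —
        i.e. the curve carries no contact, only baseline fluctuation.
    """
    z, f = curve.z_um, curve.force_nN
    n = len(curve)
    lo, hi = 2, n - min_post_samples
    if hi <= lo:
        raise NoContactError("curve too short to host an indentation region")
    sses = np.empty(hi - lo)
    ks = np.empty(hi - lo)
    for j, i in enumerate(range(lo, hi)):
        sses[j], ks[j] = _candidate_sse(z, f, i)
    best = int(np.argmin(sses))
    i = lo + best
    amplitude = ks[best] * (z[-1] - z[i]) ** 1.5
    noise_sd = np.sqrt(sses[best] / n)
    if ks[best] <= 0 or amplitude < min_signal_to_noise * noise_sd:
        raise NoContactError("no indentation signal above the baseline noise")
    return float(z[i])


def fit_hertz(
    curve: ForceCurve,
    tip_radius_um: float = 0.5,
    poisson_ratio: float = 0.5,
    contact_z_um: float | None = None,
) -> HertzFit:
    """Least-squares Hertz fit of one baseline-corrected approach curve.

    If ``contact_z_um`` is not given it is estimated with
    :func:`find_contact_point` first.  The modulus follows from the fitted
    stiffness coefficient ``k`` via
    ``E = 0.75 * k * (1 - nu^2) / sqrt(R * 1e-6)``.
    """
    if tip_radius_um <= 0:
        raise InvalidInputError("tip radius must be positive")
    if not 0.0 <= poisson_ratio < 1.0:
        raise InvalidInputError("poisson ratio must be in [0, 1)")
    if contact_z_um is None:
        contact_z_um = find_contact_point(curve)
    z, f = curve.z_um, curve.force_nN
    if not z[0] <= contact_z_um <= z[-1]:
        raise InvalidInputError("contact point outside the curve z range")
    i = int(np.searchsorted(z, contact_z_um))
    delta = np.maximum(z - contact_z_um, 0.0)
    if np.count_nonzero(delta) < 2:
        raise FitFailureError("no indentation signal past the contact point")
    basis = delta**1.5
    k = float(basis @ f) / float(basis @ basis)
    if k <= 0:
        raise FitFailureError("fitted stiffness is non-positive")
    modulus = 0.75 * k * (1.0 - poisson_ratio**2) / np.sqrt(tip_radius_um * 1e-6)
    resid = f - k * basis
    return HertzFit(
        contact_z_um=float(contact_z_um),
        young_modulus_Pa=float(modulus),
        tip_radius_um=float(tip_radius_um),
        poisson_ratio=float(poisson_ratio),
        residual_rms_nN=float(np.sqrt(np.mean(resid**2))),
        n_post_contact=int(len(curve) - i),
        metadata=dict(curve.metadata),
    )


def summarize_force_map(fits: Sequence[HertzFit | None]) -> dict:
    """Aggregate a grid of Hertz fits into a per-matrix stiffness summary.

    ``None`` entries stand for failed fits; they are excluded from the
    statistics and counted.  Per-area means are reported when the fits carry
    an ``"area"`` key in their metadata.
    """
    ok = [f for f in fits if f is not None]
    if not ok:
        raise EmptyGroupError("no successful fits to summarize")
    e = np.array([f.young_modulus_Pa for f in ok])
    summary = {
        "n_success": len(ok),
        "n_failed": len(fits) - len(ok),
        "modulus_mean_Pa": float(np.mean(e)),
        "modulus_median_Pa": float(np.median(e)),
        "modulus_sd_Pa": float(np.std(e, ddof=1)) if len(ok) > 1 else 0.0,
    }
    areas = [f.metadata.get("area") for f in ok]
    if all(a is not None for a in areas):
        per_area = (
            pd.DataFrame({"area": areas, "E": e})
            .groupby("area")["E"]
            .mean()
            .to_dict()
        )
        summary["per_area_mean_Pa"] = {str(k): float(v) for k, v in per_area.items()}
    return summary


def matrix_thickness(
    z_contact_matrix_um: float, z_dish_um: float
) -> ThicknessMeasurement:
    """Matrix thickness as the z separation of surface and dish contacts.

    Both z positions must come from the same calibrated piezo axis.  The
    absolute difference is used so the sign convention of the axis does not
    matter; a zero difference is flagged via the metadata-free warning in
    the returned value (thickness 0 is physically degenerate).
    """
    thickness = abs(float(z_contact_matrix_um) - float(z_dish_um))
    return ThicknessMeasurement(
        z_contact_matrix_um=float(z_contact_matrix_um),
        z_dish_um=float(z_dish_um),
        thickness_um=thickness,
        thickness_mm=thickness / 1000.0,
    )
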