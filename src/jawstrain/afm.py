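"""DMT contact-model fitting and quantitative nanomechanical mapping (QNM).

The Derjaguin–Muller–Toporov model relates indentation depth delta to force:

    F(delta) = (4/3) E* sqrt(R) delta^(3/2) - F_adh,      E* = E / (1 - nu^2)

with tip radius R and adhesion force F_adh. Locally the module works in AFM
units (nm, nN); the prefactor carries the explicit nm/nN <-> MPa conversion so
moduli are returned in MPa. The fit is linear least squares on the transformed
regressor delta^(3/2) — closed form, deterministic, and fast enough for full
65,536-pixel maps.

Absolute tip radius and spring constant are the dominant systematic unknowns in
AFM nanoindentation; the *relative method* absorbs them by calibrating the
effective sqrt(R) prefactor against reference samples of known modulus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, FitError, MapRejectedError, ValidationError

__all__ = [
    "ForceCurve",
    "DMTFit",
    "QNMMap",
    "QNMScan",
    "dmt_force",
    "fit_dmt",
    "calibrate_relative",
    "rms_mean",
    "map_scan",
]

log = logging.getLogger(__name__)

#: (4/3) * E[MPa] * sqrt(R[nm]) * delta[nm]^(3/2) is in units of this many nN.
_NN_PER_MPA_NM32 = 1e-3

#: Default Poisson ratio for the E* -> E conversion. Never measured for this
#: tissue; every report that uses it states it explicitly.
DEFAULT_NU = 0.3


def dmt_force(
    delta_nm: np.ndarray,
    e_star_mpa: float,
    r_nm: float,
    f_adh_nn: float = 0.0,
) -> np.ndarray:
    """Noiseless DMT force (nN) at the given indentation depths (nm)."""
    delta = np.asarray(delta_nm, dtype=float)
    if np.any(delta < 0):
        raise ValidationError("indentation depths must be non-negative")
    return (
        (4.0 / 3.0) * e_star_mpa * np.sqrt(r_nm) * delta**1.5 * _NN_PER_MPA_NM32
        - f_adh_nn
    )


@dataclass(frozen=True)
class ForceCurve:
    """Indentation–force samples with cantilever metadata."""

    delta: np.ndarray  # nm, non-negative, non-decreasing
    force: np.ndarray  # nN
    tip_radius: float = 5.0  # nm (nominal)
    spring_constant: float = 30.0  # N/m (metadata only; forces are calibrated)

    def __post_init__(self) -> None:
        d = np.asarray(self.delta, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if d.shape != f.shape or d.ndim != 1:
            raise ValidationError("delta and force must be 1D arrays of equal length")
        if d.size < 10:
            raise ValidationError("force curve needs at least 10 samples")
        if np.any(d < 0) or np.any(np.diff(d) < 0):
            raise ValidationError("indentation must be non-negative and non-decreasing")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(f))):
            raise ValidationError("non-finite samples in force curve")
        if self.tip_radius <= 0:
            raise ValidationError("tip radius must be positive")
        object.__setattr__(self, "delta", d)
        object.__setattr__(self, "force", f)


@dataclass(frozen=True)
class DMTFit:
    """Fitted DMT parameters for one force curve."""

    E: float            # Young's modulus, MPa
    E_star: float       # reduced modulus, MPa
    F_adh: float        # adhesion force, nN
    residual_rms: float  # nN
    nu_assumed: float
    physical: bool = True  # False when the fitted E* came out non-positive


def fit_dmt(curve: ForceCurve, nu: float = DEFAULT_NU, sqrt_r_scale: float = 1.0) -> DMTFit:
    """Least-squares DMT fit of a single force curve.

    Linear in ``(E*, F_adh)`` after the delta^(3/2) transform, so the solution
    is closed form. ``sqrt_r_scale`` is the relative-calibration correction from
    :func:`calibrate_relative` (1.0 = trust the nominal tip radius). A fitted
    ``E* <= 0`` is returned flagged non-physical rather than raised, so map
    scans can tally failures.
    """
    if not 0.0 <= nu < 0.5:
        raise ValidationError("Poisson ratio must be in [0, 0.5)")
    x = curve.delta**1.5
    if np.ptp(x) <= 0:
        raise FitError("degenerate indentation range: all depths equal")
    # regress F on [x, -1]
    A = np.column_stack([x, -np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, curve.force, rcond=None)
    slope, f_adh = float(coef[0]), float(coef[1])
    pref = (4.0 / 3.0) * np.sqrt(curve.tip_radius) * sqrt_r_scale * _NN_PER_MPA_NM32
    e_star = slope / pref
    resid = curve.force - A @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    return DMTFit(
        E=e_star * (1.0 - nu**2),
        E_star=e_star,
        F_adh=f_adh,
        residual_rms=rms,
        nu_assumed=nu,
        physical=e_star > 0 or np.allclose(slope, 0.0),
    )


def calibrate_relative(
    reference_curves: list[ForceCurve],
    known_E: float,
    nu: float = DEFAULT_NU,
    warn_spread: float = 0.10,
) -> float:
    """Effective sqrt(R) scale factor from reference samples of known modulus.

    Fits each reference with the nominal tip radius; since force scales with
    ``E* sqrt(R)``, the implied correction per curve is ``E_fit / known_E``.
    Returns the geometric mean; if the per-curve corrections disagree by more
    than ``warn_spread`` (fractional), a warning is logged and the geometric
    mean is still returned (documented contract).
    """
    if not reference_curves:
        raise CalibrationError("at least one reference curve required")
    if known_E <= 0:
        raise ValidationError("known reference modulus must be positive")
    scales = []
    for c in reference_curves:
        fit = fit_dmt(c, nu=nu)
        if fit.E <= 0:
            raise CalibrationError("non-physical modulus fitted on a reference curve")
        scales.append(fit.E / known_E)
    scales = np.asarray(scales)
    if scales.max() / scales.min() > 1.0 + warn_spread:
        log.warning(
            "reference curves imply inconsistent calibration scales "
            "(spread %.1f%%); using geometric mean",
            100 * (scales.max() / scales.min() - 1.0),
        )
    return float(np.exp(np.mean(np.log(scales))))


def rms_mean(values: np.ndarray) -> float:
    """Root-mean-square mean, the aggregate used for per-pixel modulus maps."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("rms_mean of empty collection")
    if not np.all(np.isfinite(v)):
        raise ValidationError("rms_mean requires finite values")
    return float(np.sqrt(np.mean(v**2)))


@dataclass(frozen=True)
class QNMScan:
    """A grid of force curves sharing one indentation ramp.

    ``forces`` has shape (ny, nx, n_samples); ``delta`` is the common ramp.
    The canonical acquisition is 256 x 256 curves over a 500 x 500 nm region.
    """

    delta: np.ndarray
    forces: np.ndarray
    tip_radius: float = 5.0
    scan_size_nm: float = 500.0

    def __post_init__(self) -> None:
        d = np.asarray(self.delta, dtype=float)
        f = np.asarray(self.forces, dtype=float)
        if f.ndim != 3 or f.shape[2] != d.size:
            raise ValidationError("forces must be (ny, nx, n) matching delta")
        object.__setattr__(self, "delta", d)
        object.__setattr__(self, "forces", f)


@dataclass(frozen=True)
class QNMMap:
    """Per-pixel Young's modulus map (MPa) with its RMS-mean aggregate."""

    E: np.ndarray            # (ny, nx), NaN where the pixel fit failed
    aggregate: float         # RMS mean over valid pixels, MPa
    n_failed: int
    nu_assumed: float


def map_scan(
    scan: QNMScan,
    nu: float = DEFAULT_NU,
    sqrt_r_scale: float = 1.0,
    max_fail_frac: float = 0.10,
) -> QNMMap:
    """Fit every pixel of a QNM scan and aggregate by the RMS mean.

    Pixels with non-physical fits are flagged NaN and excluded; a map with more
    than ``max_fail_frac`` failures is rejected with a diagnostic.
    """
    if not 0.0 <= nu < 0.5:
        raise ValidationError("Poisson ratio must be in [0, 0.5)")
    x = scan.delta**1.5
    if np.ptp(x) <= 0:
        raise MapRejectedError("degenerate indentation ramp: all depths equal")
    ny, nx, n = scan.forces.shape
    A = np.column_stack([x, -np.ones_like(x)])
    F = scan.forces.reshape(-1, n).T  # (n, npix)
    coef, *_ = np.linalg.lstsq(A, F, rcond=None)
    slopes = coef[0]
    pref = (4.0 / 3.0) * np.sqrt(scan.tip_radius) * sqrt_r_scale * _NN_PER_MPA_NM32
    e = (slopes / pref) * (1.0 - nu**2)
    e = e.reshape(ny, nx)
    failed = ~(e > 0)
    n_failed = int(failed.sum())
    if n_failed > max_fail_frac * e.size:
        raise MapRejectedError(
            f"{n_failed}/{e.size} pixels failed the DMT fit "
            f"(limit {max_fail_frac:.0%}); map rejected"
        )
    e_masked = e.copy()
    e_masked[failed] = np.nan
    return QNMMap(
        E=e_masked,
        aggregate=rms_mean(e_masked[~failed]),
        n_failed=n_failed,
        nu_assumed=nu,
    )
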