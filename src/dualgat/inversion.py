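"""Closed-form inversion: true IOP, corneal stiffness and Young's modulus
from two dial readings.

The forward model gives one linear equation per zone in the two unknowns
(IOPT, K):

    IOPG0 g0^2 = IOPT g0^2 + K g0^4 - p3 g0^2
    IOPG1 g0^2 = IOPT g1^2 + K g1^4 - p3 g0^2

Because the dial is calibrated on the standard zone for both readings,
this 2x2 system has the exact solution

    IOPT = IOPG0 + (IOPG0 g1^2 - IOPG1 g0^2) / (g1^4/g0^2 - g1^2)
                 + p3 (g1^2 + g0^2) / g1^2
    K    = (IOPG1 g0^2 - IOPG0 g1^2) / (g1^2 (g1^2 - g0^2)) - p3 / g1^2

from which the Young's modulus follows as E = 2 (1 - nu) a^3 K / h and
the systematic Goldmann error as ERR = IOPG0 - IOPT = K g0^2 - p3.

All estimators are affine in the readings and vectorize over them, so a
cohort inverts as two array expressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DEFAULT_P3_MMHG,
    DEFAULT_PRISM,
    MMHG_TO_PA,
    CorneaGeometry,
    InvalidGeometryError,
    PrismGeometry,
)
from .forward import DualReading

__all__ = [
    "SingularPrismError",
    "NegativeStiffnessWarning",
    "InversionResult",
    "estimate_iopt",
    "estimate_stiffness",
    "estimate_modulus",
    "estimate_error",
    "iopt_uncertainty",
    "invert_reading",
]

_K_UNIT = 1e6 / MMHG_TO_PA  # (mmHg/mm^2) per (MPa/mm^2)

#: Zones closer than this (mm) make the two equations numerically
#: indistinguishable and the system is treated as singular.
_MIN_ZONE_GAP_MM = 1e-6


class SingularPrismError(ValueError):
    """The two applanation zones coincide; the 2x2 system is singular."""


class NegativeStiffnessWarning(UserWarning):
    """Readings imply K < 0 — physically inconsistent with the shell model."""


def _readings(reading, iopg1):
    """Accept (DualReading,) or (iopg0, iopg1) scalars/arrays."""
    if isinstance(reading, DualReading):
        if iopg1 is not None:
            raise TypeError("pass either a DualReading or two readings, not both")
        return np.asarray(reading.iopg0, float), np.asarray(reading.iopg1, float)
    if iopg1 is None:
        raise TypeError("second reading iopg1 is required")
    return np.asarray(reading, float), np.asarray(iopg1, float)


def _check_prism(prism: PrismGeometry) -> tuple[float, float]:
    if prism.g1 - prism.g0 < _MIN_ZONE_GAP_MM:
        raise SingularPrismError(
            f"zone radii g0={prism.g0} and g1={prism.g1} are too close; "
            "the two-zone system is singular"
        )
    return prism.g0**2, prism.g1**2


def estimate_iopt(
    reading,
    iopg1=None,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
):
    """True intraocular pressure (mmHg) from the two zone readings.

    Exact solution of the two-zone force-balance system; affine in both
    readings. Accepts a :class:`~dualgat.forward.DualReading` or two
    scalars/arrays.
    """
    iopg0, iopg1 = _readings(reading, iopg1)
    g0s, g1s = _check_prism(prism)
    middle = (iopg0 * g1s - iopg1 * g0s) / (g1s * g1s / g0s - g1s)
    out = iopg0 + middle + p3 * (g1s + g0s) / g1s
    return float(out) if out.ndim == 0 else out


def estimate_stiffness(
    reading,
    iopg1=None,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
):
    """Composite cap stiffness K (mmHg/mm^2) from the two zone readings.

    Negative values are physically inconsistent with the shell model
    (they arise from noise or non-model readings); they are returned
    with a :class:`NegativeStiffnessWarning` rather than raised, so
    batch runs keep going.
    """
    iopg0, iopg1 = _readings(reading, iopg1)
    g0s, g1s = _check_prism(prism)
    k = (iopg1 * g0s - iopg0 * g1s) / (g1s * (g1s - g0s)) - p3 / g1s
    if np.any(k < 0.0):
        warnings.warn(
            "readings imply negative composite stiffness K; inputs are "
            "inconsistent with the shell model",
            NegativeStiffnessWarning,
            stacklevel=2,
        )
    return float(k) if k.ndim == 0 else k


def estimate_modulus(
    reading,
    iopg1=None,
    geom: CorneaGeometry | None = None,
    nu: float = 0.485,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
):
    """Corneal Young's modulus E (MPa) from readings plus thickness/curvature.

    E = 2 (1 - nu) a^3 K / h with K from :func:`estimate_stiffness` — the
    exact algebraic solution of the same linear system that yields the
    pressure estimate, so forward-simulated eyes are recovered exactly.
    The Poisson ratio is an explicit parameter (default 0.485, the
    near-incompressible tissue value); with it, 2(1 - nu) = 1.03.
    """
    if geom is None:
        raise TypeError("corneal geometry (thickness and curvature) is required")
    if geom.h <= 0.0:
        raise InvalidGeometryError(f"thickness must be > 0, got {geom.h}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NegativeStiffnessWarning)
        k = estimate_stiffness(reading, iopg1, prism=prism, p3=p3)
    e = 2.0 * (1.0 - nu) * geom.a**3 * np.asarray(k) / geom.h / _K_UNIT
    if np.any(np.asarray(e) < 0.0):
        warnings.warn(
            "estimated Young's modulus is negative; returned for diagnostics only",
            NegativeStiffnessWarning,
            stacklevel=2,
        )
    e = np.asarray(e)
    return float(e) if e.ndim == 0 else e


def estimate_error(
    reading,
    iopg1=None,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
):
    """Systematic Goldmann error ERR = IOPG0 - IOPT (mmHg).

    Algebraically identical to K g0^2 - p3 with K from
    :func:`estimate_stiffness`.
    """
    iopg0, iopg1 = _readings(reading, iopg1)
    out = iopg0 - np.asarray(estimate_iopt(iopg0, iopg1, prism=prism, p3=p3))
    return float(out) if out.ndim == 0 else out


def iopt_uncertainty(
    sigma_reading: float,
    prism: PrismGeometry = DEFAULT_PRISM,
) -> float:
    """First-order (delta-method) SD of the IOPT estimate, mmHg.

    For independent Gaussian reading errors of SD ``sigma_reading`` on
    both zones, the estimator being affine gives exactly

        sigma_IOPT = sigma * sqrt((dIOPT/dIOPG0)^2 + (dIOPT/dIOPG1)^2)

    with dIOPT/dIOPG0 = 1 + g1^2/(g1^4/g0^2 - g1^2) and
    dIOPT/dIOPG1 = -g0^2/(g1^4/g0^2 - g1^2). The default prism amplifies
    reading noise about fourfold — the price of separating pressure from
    stiffness with two nearby zones.
    """
    if sigma_reading < 0.0:
        raise ValueError(f"sigma must be >= 0, got {sigma_reading}")
    g0s, g1s = _check_prism(prism)
    denom = g1s * g1s / g0s - g1s
    d0 = 1.0 + g1s / denom
    d1 = -g0s / denom
    return sigma_reading * float(np.hypot(d0, d1))


@dataclass(frozen=True)
class InversionResult:
    """Everything the two readings determine, plus diagnostics.

    ``quality_flag`` is ``"ok"`` or ``"negative_stiffness"`` (readings
    inconsistent with the shell model; estimates returned anyway for
    inspection).
    """

    iopt: float
    k: float
    e_modulus: float
    err: float
    quality_flag: str = "ok"
    diagnostics: dict = field(default_factory=dict)


def invert_reading(
    reading,
    iopg1=None,
    geom: CorneaGeometry | None = None,
    nu: float = 0.485,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
) -> InversionResult:
    """Full single-eye inversion: IOPT, K, E and ERR from one dual reading."""
    iopg0, iopg1 = _readings(reading, iopg1)
    iopg0 = float(iopg0)
    iopg1 = float(iopg1)
    g0s, g1s = _check_prism(prism)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NegativeStiffnessWarning)
        iopt = estimate_iopt(iopg0, iopg1, prism=prism, p3=p3)
        k = estimate_stiffness(iopg0, iopg1, prism=prism, p3=p3)
        e = estimate_modulus(iopg0, iopg1, geom=geom, nu=nu, prism=prism, p3=p3)
    err = iopg0 - iopt
    middle = (iopg0 * g1s - iopg1 * g0s) / (g1s * g1s / g0s - g1s)
    flag = "ok" if k >= 0.0 else "negative_stiffness"
    if flag != "ok":
        warnings.warn(
            f"negative composite stiffness K={k:.4f} mmHg/mm^2; "
            "readings inconsistent with the shell model",
            NegativeStiffnessWarning,
            stacklevel=2,
        )
    return InversionResult(
        iopt=iopt,
        k=k,
        e_modulus=e,
        err=err,
        quality_flag=flag,
        diagnostics={
            "middle_term_mmhg": middle,
            "tear_term_mmhg": p3 * (g1s + g0s) / g1s,
            "k_mmhg_mm2": k,
        },
    )
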