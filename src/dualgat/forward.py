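"""Forward model: what the tonometer dial reads for a fully known eye.

The force balance at zone radius g, with the dial calibrated on the
standard zone area pi g0^2 and the tear adhesion entering as a constant
pressure term p3 referred to that same area, gives

    reading(g) = (IOPT g^2 + K g^4 - p3 g0^2) / g0^2

where K = E h / (2 (1 - nu) a^3) is the composite stiffness of the
flattened cap (mmHg/mm^2). At the standard zone this collapses to

    IOPG0 = IOPT + K g0^2 - p3

so the systematic Goldmann error ERR = IOPG0 - IOPT = K g0^2 - p3 is
independent of the true pressure: thicker or stiffer corneas read high,
flatter (larger-radius) corneas read low, and the reference cornea
(0.536 mm, 7.15 mm, 0.16 MPa) reads true.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    DEFAULT_P3_MMHG,
    DEFAULT_PRISM,
    MMHG_TO_PA,
    CorneaGeometry,
    CorneaMechanics,
    InvalidGeometryError,
    PrismGeometry,
    TearFilm,
)
from .forces import dial_reading, force_elastic, force_iop, force_tear

__all__ = [
    "EyeState",
    "DualReading",
    "composite_stiffness",
    "goldmann_error",
    "simulate_reading",
    "simulate_dual",
    "simulate_reading_meniscus",
]

# (mmHg/mm^2) per (MPa * mm / mm^3): 1e6 Pa/MPa / 133.322 Pa/mmHg
_K_UNIT = 1e6 / MMHG_TO_PA


@dataclass(frozen=True)
class EyeState:
    """A fully specified eye: true pressure plus corneal shell properties."""

    iopt: float
    geom: CorneaGeometry
    mech: CorneaMechanics
    tear: TearFilm = field(default_factory=TearFilm.normal)

    def __post_init__(self) -> None:
        if self.iopt < 0.0:
            raise ValueError(f"true IOP must be >= 0 mmHg, got {self.iopt}")


@dataclass(frozen=True)
class DualReading:
    """Dial readings from the inner (3.06 mm) and outer (3.60 mm) zones, mmHg."""

    iopg0: float
    iopg1: float


def composite_stiffness(mech: CorneaMechanics, geom: CorneaGeometry) -> float:
    """Composite cap stiffness K = E h / (2 (1 - nu) a^3), mmHg/mm^2.

    The single coefficient through which thickness, curvature and modulus
    enter every reading: ERR = K g0^2 - p3.
    """
    return mech.e_mpa * geom.h / (2.0 * (1.0 - mech.nu) * geom.a**3) * _K_UNIT


def goldmann_error(
    mech: CorneaMechanics,
    geom: CorneaGeometry,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
) -> float:
    """Systematic Goldmann error ERR = K g0^2 - p3, mmHg.

    Equals (standard-zone reading) - (true IOP) for every true IOP; the
    true pressure cancels out of the difference.
    """
    return composite_stiffness(mech, geom) * prism.g0**2 - p3


def simulate_reading(
    eye: EyeState,
    g: float,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
) -> float:
    """Dial reading (mmHg) when the prism flattens a disc of radius ``g`` mm."""
    if not (0.0 < g < eye.geom.a):
        raise InvalidGeometryError(
            f"require 0 < g < a, got g={g}, a={eye.geom.a}"
        )
    k = composite_stiffness(eye.mech, eye.geom)
    g0sq = prism.g0**2
    return (eye.iopt * g**2 + k * g**4 - p3 * g0sq) / g0sq


def simulate_dual(
    eye: EyeState,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
) -> DualReading:
    """Noise-free dual-zone readings (IOPG0, IOPG1) for one eye."""
    return DualReading(
        iopg0=simulate_reading(eye, prism.g0, prism, p3),
        iopg1=simulate_reading(eye, prism.g1, prism, p3),
    )


def simulate_reading_meniscus(
    eye: EyeState,
    g: float,
    prism: PrismGeometry = DEFAULT_PRISM,
) -> float:
    """Forward reading with the physical, zone-dependent meniscus force.

    Sensitivity-study variant: F3 comes from the Laplace meniscus formula
    (weakly g-dependent) instead of the constant tear pressure term the
    closed-form inversion assumes. Useful for quantifying how much that
    constant-term approximation matters; deliberately *not* the model the
    inversion equations invert.
    """
    if not (0.0 < g < eye.geom.a):
        raise InvalidGeometryError(f"require 0 < g < a, got g={g}, a={eye.geom.a}")
    f4 = (
        force_iop(eye.iopt, g)
        + force_elastic(eye.mech, eye.geom, g)
        - force_tear(eye.tear, eye.geom.a, g)
    )
    return dial_reading(f4, prism)
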