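"""The four forces of the applanation balance.

When the tonometer prism flattens a disc of radius ``g`` on the cornea,
the net thrust the examiner applies (F4, the quantity the instrument
records) balances three contributions:

* F1 — the true intraocular pressure pushing the flattened cap outward,
* F2 — the elastic reaction of the bent shell resisting flattening,
* F3 — the adhesion of the annular tear meniscus pulling the prism in,

so that F4 = F1 + F2 - F3. The dial converts force to pressure by
dividing by the *standard* 3.06 mm-zone area regardless of which zone is
being read; that single calibration convention is what makes the
two-zone inversion a linear system.

Forces are reported in mN, pressures in mmHg; lengths enter in mm and
surface tension in N/m (conveniently, mm x N/m = mN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    DEFAULT_PRISM,
    MMHG_TO_PA,
    CorneaGeometry,
    CorneaMechanics,
    InvalidGeometryError,
    PrismGeometry,
    TearFilm,
    applanated_area,
    chord_height,
)

__all__ = [
    "ForceBreakdown",
    "force_iop",
    "force_elastic",
    "force_tear",
    "tear_pressure",
    "net_applied_force",
    "dial_reading",
    "force_breakdown",
]

# mN per (mmHg x mm^2): 133.322 Pa/mmHg x 1e-6 m^2/mm^2 x 1e3 mN/N
_MN_PER_MMHG_MM2 = MMHG_TO_PA * 1e-3


def force_iop(iopt: float, g: float) -> float:
    """Thrust F1 = IOPT * pi * g^2 of the intraocular pressure, mN.

    ``iopt`` in mmHg, ``g`` in mm.
    """
    if iopt < 0.0:
        raise ValueError(f"intraocular pressure must be >= 0 mmHg, got {iopt}")
    if g <= 0.0:
        raise InvalidGeometryError(f"applanation radius must be > 0, got {g}")
    return iopt * applanated_area(g) * _MN_PER_MMHG_MM2


def force_elastic(mech: CorneaMechanics, geom: CorneaGeometry, g: float) -> float:
    """Elastic reaction F2 of the flattened cap, mN.

    Closed form of bending-dominated thin-shell theory for a clamped
    spherical cap flattened over radius ``g``:

        F2 = pi * E * h * g^4 / (2 (1 - nu) a^3)

    Scales linearly in stiffness E and thickness h, as the fourth power
    of the applanation radius, and inversely with the cube of the
    mid-surface curvature radius.
    """
    if g >= geom.a:
        raise InvalidGeometryError(
            f"applanation radius {g} must be below the shell radius {geom.a}"
        )
    # E in MPa=N/mm^2, lengths in mm -> force in N, then mN
    e_n_mm2 = mech.e_mpa
    f_n = np.pi * e_n_mm2 * geom.h * g**4 / (2.0 * (1.0 - mech.nu) * geom.a**3)
    return float(f_n * 1e3)


def force_tear(tear: TearFilm, a: float, g: float) -> float:
    """Tear-meniscus adhesion force F3 = 2 pi lambda (a + sqrt(a^2 - g^2)), mN.

    Laplace capillary pull of the annular meniscus bridging the prism rim
    and the unflattened cornea, under complete wetting (zero contact
    angle). To first order it is independent of meniscus curvature and
    tear-film thickness, and only weakly dependent on the zone radius.
    """
    if not (0.0 < g < a):
        raise InvalidGeometryError(f"require 0 < g < a, got g={g}, a={a}")
    return float(2.0 * np.pi * tear.lambda_st * (a + chord_height(a, g)))


def tear_pressure(tear: TearFilm, a: float, g: float) -> float:
    """Mean pressure equivalent of F3 over the applanated disc, mmHg."""
    return force_tear(tear, a, g) / applanated_area(g) / _MN_PER_MMHG_MM2


def net_applied_force(f1: float, f2: float, f3: float) -> float:
    """Net examiner thrust F4 = F1 + F2 - F3, mN.

    Warns (does not raise) when the tear adhesion exceeds the outward
    forces, which would mean the prism is held on by capillarity alone.
    """
    if min(f1, f2, f3) < 0.0:
        raise ValueError(f"forces must be >= 0, got {(f1, f2, f3)}")
    f4 = f1 + f2 - f3
    if f4 < 0.0:
        warnings.warn(
            f"net applied force is negative ({f4:.3f} mN): tear adhesion "
            "exceeds pressure and elastic forces",
            stacklevel=2,
        )
    return f4


def dial_reading(f4: float, prism: PrismGeometry = DEFAULT_PRISM) -> float:
    """Convert net force (mN) to the tonometer dial scale, mmHg.

    The dial is calibrated once, on the standard 3.06 mm zone: the
    reading is force / (pi g0^2) for *both* zones. Reading the outer
    zone through the same calibration is what encodes the extra
    geometric information the inversion uses.
    """
    return f4 / applanated_area(prism.g0) / _MN_PER_MMHG_MM2


@dataclass(frozen=True)
class ForceBreakdown:
    """The four forces (mN) and resulting dial reading (mmHg) for one applanation."""

    f1: float
    f2: float
    f3: float
    f4: float
    dial: float


def force_breakdown(
    iopt: float,
    mech: CorneaMechanics,
    geom: CorneaGeometry,
    tear: TearFilm,
    g: float,
    prism: PrismGeometry = DEFAULT_PRISM,
) -> ForceBreakdown:
    """Assemble the full force balance at applanation radius ``g``.

    Uses the physical meniscus formula for F3. The constant-tear-term
    variant that the closed-form inversion assumes lives in
    :mod:`dualgat.forward`.
    """
    f1 = force_iop(iopt, g)
    f2 = force_elastic(mech, geom, g)
    f3 = force_tear(tear, geom.a, g)
    f4 = net_applied_force(f1, f2, f3)
    return ForceBreakdown(f1=f1, f2=f2, f3=f3, f4=f4, dial=dial_reading(f4, prism))
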