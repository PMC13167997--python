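"""Shared primitives for the applanation model.

Domain containers (cornea geometry, shell mechanics, tear film, prism),
physical constants, unit conversions, and the geometry of flattening a
thin spherical shell against a flat prism face.

Unit conventions
----------------
All public interfaces use clinical units: mmHg for pressures, mm for
lengths, mN for forces, MPa for Young's modulus. Conversions to SI happen
internally where forces are assembled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MMHG_TO_PA",
    "DEFAULT_NU",
    "DEFAULT_P3_MMHG",
    "DEFAULT_G0_MM",
    "DEFAULT_G1_MM",
    "TEAR_PRESETS",
    "InvalidGeometryError",
    "OutOfApplanationZoneError",
    "ThinShellWarning",
    "CorneaGeometry",
    "CorneaMechanics",
    "TearFilm",
    "PrismGeometry",
    "mmhg_to_pa",
    "pa_to_mmhg",
    "mid_surface_radius",
    "chord_height",
    "radial_displacement",
    "radial_displacement_chord_form",
    "applanated_area",
]

#: Pascals per millimetre of mercury (standard definition).
MMHG_TO_PA = 133.322

#: Default Poisson ratio of the corneal shell material. Soft hydrated
#: tissue is nearly incompressible (nu -> 0.5); 0.485 is the unique value
#: for which the Goldmann error vanishes exactly at the reference cornea
#: (E = 0.16 MPa, h = 0.536 mm, a = 7.15 mm) with a 4.0 mmHg tear term.
DEFAULT_NU = 0.485

#: Default tear-film pressure correction in mmHg (physiological tear film).
DEFAULT_P3_MMHG = 4.0

#: Inner applanation radius, mm — half the standard Goldmann 3.06 mm
#: applanation diameter.
DEFAULT_G0_MM = 1.53

#: Outer applanation radius, mm — half the 3.60 mm diameter of the second
#: concentric zone of the dual prism.
DEFAULT_G1_MM = 1.80

#: Tear-film surface tension presets, N/m. ``water`` is distilled water;
#: ``normal`` the physiological tear film; ``dry`` is back-solved from the
#: dry-eye meniscus force of 4.5 mN (derived, not a measured literature
#: value).
TEAR_PRESETS: dict[str, float] = {
    "water": 0.073,
    "normal": 0.044,
    "dry": 0.0507,
}


class InvalidGeometryError(ValueError):
    """Raised for geometrically impossible inputs (inverted radii, g >= a...)."""


class OutOfApplanationZoneError(InvalidGeometryError):
    """Raised when a radial coordinate lies outside the flattened disc."""


class ThinShellWarning(UserWarning):
    """Thickness-to-radius ratio large enough to strain the thin-shell assumption."""


# ---------------------------------------------------------------------------
# unit conversions

def mmhg_to_pa(p):
    """Convert pressure from mmHg to Pa (scalar or array)."""
    return np.multiply(p, MMHG_TO_PA)


def pa_to_mmhg(p):
    """Convert pressure from Pa to mmHg (scalar or array)."""
    return np.divide(p, MMHG_TO_PA)


# ---------------------------------------------------------------------------
# geometry operations

def mid_surface_radius(r_ext: float, r_int: float) -> float:
    """Mid-surface radius of the corneal shell, mm.

    The shell is bounded by the anterior (external) surface of radius
    ``r_ext`` and the posterior (internal) surface of radius ``r_int``;
    the model works on the intermediate surface whose radius is their
    arithmetic mean.
    """
    if not (r_ext >= r_int > 0.0):
        raise InvalidGeometryError(
            f"require r_ext >= r_int > 0, got r_ext={r_ext}, r_int={r_int}"
        )
    return 0.5 * (r_ext + r_int)


def chord_height(a, g):
    """Distance sqrt(a^2 - g^2) from shell centre to the applanation plane, mm.

    ``a`` is the mid-surface radius and ``g`` the radius of the flattened
    disc; the applanation plane cuts the sphere at height sqrt(a^2 - g^2)
    above the centre.
    """
    a = np.asarray(a, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(g < 0) or np.any(g >= a):
        raise InvalidGeometryError(
            f"applanation radius must satisfy 0 <= g < a, got g={g}, a={a}"
        )
    out = np.sqrt(a * a - g * g)
    return float(out) if out.ndim == 0 else out


def radial_displacement(r, a, g):
    """Radial displacement w(r) of the flattened mid-surface, mm.

    w(r) = a * (1 - sqrt((a^2 - g^2) / (a^2 - r^2)))

    for a point at radial coordinate ``r`` inside the applanated disc of
    radius ``g`` on a shell of mid-surface radius ``a``. Vanishes at the
    rim (r = g) and is largest at the apex (r = 0), where it equals
    a - sqrt(a^2 - g^2).
    """
    r = np.asarray(r, dtype=float)
    a = np.asarray(a, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(g < 0) or np.any(g >= a):
        raise InvalidGeometryError(f"require 0 <= g < a, got g={g}, a={a}")
    if np.any(r < 0) or np.any(r > g):
        raise OutOfApplanationZoneError(
            f"radial coordinate must satisfy 0 <= r <= g, got r={r}, g={g}"
        )
    out = a * (1.0 - np.sqrt((a * a - g * g) / (a * a - r * r)))
    return float(out) if out.ndim == 0 else out


def radial_displacement_chord_form(r, a, g):
    """Alternative reading of the displacement field: a - sqrt(a^2 - g^2 + r^2).

    Agrees with :func:`radial_displacement` at both endpoints (r = 0 and
    r = g) but differs slightly in between; kept only as a documented
    comparison helper, never used by the force balance.
    """
    r = np.asarray(r, dtype=float)
    a = np.asarray(a, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(g < 0) or np.any(g >= a):
        raise InvalidGeometryError(f"require 0 <= g < a, got g={g}, a={a}")
    if np.any(r < 0) or np.any(r > g):
        raise OutOfApplanationZoneError(
            f"radial coordinate must satisfy 0 <= r <= g, got r={r}, g={g}"
        )
    out = a - np.sqrt(a * a - g * g + r * r)
    return float(out) if out.ndim == 0 else out


def applanated_area(g):
    """Area pi * g^2 of the flattened disc, mm^2."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise InvalidGeometryError(f"applanation radius must be >= 0, got {g}")
    out = np.pi * g * g
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# domain containers

@dataclass(frozen=True)
class CorneaGeometry:
    """Spherical-shell geometry of a cornea.

    Parameters
    ----------
    a : float
        Mid-surface curvature radius, mm. When built from anterior and
        posterior radii it is their arithmetic mean.
    h : float
        Central corneal thickness, mm.
    r_ext, r_int : float, optional
        Anterior (external) and posterior (internal) curvature radii, mm,
        when the geometry was specified that way.
    """

    a: float
    h: float
    r_ext: float | None = None
    r_int: float | None = None

    def __post_init__(self) -> None:
        if not (self.a > 0.0):
            raise InvalidGeometryError(f"mid-surface radius must be > 0, got {self.a}")
        if not (self.h > 0.0):
            raise InvalidGeometryError(f"thickness must be > 0, got {self.h}")
        if (self.r_ext is None) != (self.r_int is None):
            raise InvalidGeometryError("give both r_ext and r_int or neither")
        if self.r_ext is not None:
            if not (self.r_ext >= self.r_int > 0.0):
                raise InvalidGeometryError(
                    f"require r_ext >= r_int > 0, got {self.r_ext}, {self.r_int}"
                )
            if self.h >= self.r_int:
                raise InvalidGeometryError(
                    f"thickness {self.h} must be below the internal radius {self.r_int}"
                )
            expect = 0.5 * (self.r_ext + self.r_int)
            if not math.isclose(self.a, expect, rel_tol=1e-9):
                raise InvalidGeometryError(
                    f"a={self.a} inconsistent with mean of radii {expect}"
                )
        elif self.h >= self.a:
            raise InvalidGeometryError(
                f"thickness {self.h} must be below the shell radius {self.a}"
            )
        if self.h / self.a >= 0.2:
            warnings.warn(
                f"h/a = {self.h / self.a:.3f} >= 0.2: thin-shell assumption is "
                "strained; results may be unreliable",
                ThinShellWarning,
                stacklevel=2,
            )

    @classmethod
    def from_radii(cls, r_ext: float, r_int: float, h: float) -> "CorneaGeometry":
        """Build from anterior/posterior radii; ``a`` becomes their mean."""
        return cls(a=mid_surface_radius(r_ext, r_int), h=h, r_ext=r_ext, r_int=r_int)

    @classmethod
    def from_mid_surface(cls, a: float, h: float) -> "CorneaGeometry":
        """Build directly from the mid-surface radius (used by all sweeps)."""
        return cls(a=a, h=h)


@dataclass(frozen=True)
class CorneaMechanics:
    """Elastic constants of the corneal shell material.

    ``e_mpa`` is the effective Young's modulus in MPa; ``nu`` the Poisson
    ratio, near 0.5 for nearly incompressible soft tissue.
    """

    e_mpa: float
    nu: float = DEFAULT_NU

    def __post_init__(self) -> None:
        if self.e_mpa < 0.0:
            raise ValueError(f"Young's modulus must be >= 0, got {self.e_mpa}")
        if not (0.0 <= self.nu <= 0.5):
            raise ValueError(f"Poisson ratio must be in [0, 0.5], got {self.nu}")


@dataclass(frozen=True)
class TearFilm:
    """Tear-film surface tension, N/m, with named presets."""

    lambda_st: float
    preset: str = "custom"

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_st <= 0.08):
            raise ValueError(
                f"surface tension must be in (0, 0.08] N/m, got {self.lambda_st}"
            )

    @classmethod
    def from_preset(cls, name: str) -> "TearFilm":
        try:
            return cls(lambda_st=TEAR_PRESETS[name], preset=name)
        except KeyError:
            raise ValueError(
                f"unknown tear preset {name!r}; choose from {sorted(TEAR_PRESETS)}"
            ) from None

    @classmethod
    def water(cls) -> "TearFilm":
        return cls.from_preset("water")

    @classmethod
    def normal(cls) -> "TearFilm":
        return cls.from_preset("normal")

    @classmethod
    def dry(cls) -> "TearFilm":
        return cls.from_preset("dry")


@dataclass(frozen=True)
class PrismGeometry:
    """Radii (mm) of the two concentric applanation zones of the dual prism."""

    g0: float = DEFAULT_G0_MM
    g1: float = DEFAULT_G1_MM

    def __post_init__(self) -> None:
        if not (self.g1 > self.g0 > 0.0):
            raise InvalidGeometryError(
                f"require g1 > g0 > 0, got g0={self.g0}, g1={self.g1}"
            )


#: Module-wide default prism (3.06 mm inner, 3.60 mm outer diameters).
DEFAULT_PRISM = PrismGeometry()
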