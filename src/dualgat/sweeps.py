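"""Parameter sweeps, zero-error roots, and the ERR lookup table.

Reproduces the model's simulation studies: how the standard-zone reading
departs from true IOP as central corneal thickness, mid-surface
curvature radius, or Young's modulus is varied with the other two fixed;
the zero-error values at which the tonometer reads true (0.536 mm,
7.15 mm, 0.16 MPa for the reference cornea); and the full factorial
ERR(h, a, E) table usable as a clinical correction lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import (
    DEFAULT_P3_MMHG,
    DEFAULT_PRISM,
    CorneaGeometry,
    CorneaMechanics,
    PrismGeometry,
)
from .forward import EyeState, goldmann_error, simulate_reading

__all__ = [
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "zero_error_thickness",
    "zero_error_curvature",
    "zero_error_modulus",
    "zero_thickness_closed_form",
    "zero_curvature_closed_form",
    "zero_modulus_closed_form",
    "err_lookup_table",
    "write_lookup_csv",
    "slope_vs_modulus",
    "DEFAULT_H_GRID",
    "DEFAULT_A_GRID",
    "DEFAULT_E_GRID",
]

_PARAM_COLUMNS = {"thickness": "h_mm", "curvature": "a_mm", "modulus": "e_mpa"}

# Default grids spanning the physiologic ranges with margin:
# CCT 450-650 um, curvature 6.5-8.0 mm, modulus 0.10-0.35 MPa.
DEFAULT_H_GRID = np.round(np.arange(0.40, 0.70 + 1e-9, 0.01), 10)
DEFAULT_A_GRID = np.round(np.arange(6.5, 8.0 + 1e-9, 0.05), 10)
DEFAULT_E_GRID = np.round(np.arange(0.10, 0.35 + 1e-9, 0.01), 10)


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep: vary one corneal property, hold the rest.

    ``fixed`` supplies the template eye; the swept field of it is
    ignored. ``iopt_grid`` defaults to the template's true pressure.
    """

    parameter: str
    grid: np.ndarray
    fixed: EyeState
    iopt_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.parameter not in _PARAM_COLUMNS:
            raise ValueError(
                f"parameter must be one of {sorted(_PARAM_COLUMNS)}, "
                f"got {self.parameter!r}"
            )
        grid = np.asarray(self.grid, float)
        if grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be non-empty and strictly increasing")
        object.__setattr__(self, "grid", grid)


@dataclass(frozen=True)
class SweepResult:
    """Long-format sweep table plus the fixed values it was computed under."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _eye_with(template: EyeState, parameter: str, value: float, iopt: float) -> EyeState:
    geom, mech = template.geom, template.mech
    if parameter == "thickness":
        geom = CorneaGeometry.from_mid_surface(geom.a, value)
    elif parameter == "curvature":
        geom = CorneaGeometry.from_mid_surface(value, geom.h)
    else:
        mech = CorneaMechanics(e_mpa=value, nu=mech.nu)
    return EyeState(iopt=iopt, geom=geom, mech=mech, tear=template.tear)


def run_sweep(
    spec: SweepSpec,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
) -> SweepResult:
    """Evaluate the forward model over the sweep grid.

    One row per (grid value, true pressure): the standard-zone reading
    and its error IOPG0 - IOPT.
    """
    iopts = (
        np.asarray(spec.iopt_grid, float)
        if spec.iopt_grid is not None
        else np.array([spec.fixed.iopt])
    )
    col = _PARAM_COLUMNS[spec.parameter]
    rows = []
    for value in spec.grid:
        for iopt in iopts:
            eye = _eye_with(spec.fixed, spec.parameter, float(value), float(iopt))
            iopg0 = simulate_reading(eye, prism.g0, prism, p3)
            rows.append((float(value), float(iopt), iopg0, iopg0 - iopt))
    table = pd.DataFrame(rows, columns=[col, "iopt_mmhg", "iopg0_mmhg", "err_mmhg"])
    meta = {
        "parameter": spec.parameter,
        "h_mm": spec.fixed.geom.h,
        "a_mm": spec.fixed.geom.a,
        "e_mpa": spec.fixed.mech.e_mpa,
        "nu": spec.fixed.mech.nu,
        "p3_mmhg": p3,
        "g0_mm": prism.g0,
        "g1_mm": prism.g1,
    }
    return SweepResult(table=table, metadata=meta)


# ---------------------------------------------------------------------------
# zero-error roots

def _bracketed_root(
    f, lo: float, hi: float, lo_limit: float = 1e-9, hi_limit: float = np.inf
) -> float:
    """Brent root of f on [lo, hi], expanding the bracket x2 up to 8 times.

    Expansion stays inside [lo_limit, hi_limit] so it cannot leave the
    domain where ERR is defined (e.g. thickness below the shell radius).
    """
    flo, fhi = f(lo), f(hi)
    for _ in range(8):
        if flo * fhi <= 0.0:
            return brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
        width = hi - lo
        lo = max(lo - width / 2.0, lo_limit)
        hi = min(hi + width / 2.0, hi_limit)
        flo, fhi = f(lo), f(hi)
    raise ValueError(
        f"no sign change of ERR on [{lo:.4g}, {hi:.4g}] after bracket expansion"
    )


def zero_error_thickness(
    mech: CorneaMechanics,
    a: float,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
    bracket: tuple[float, float] = (0.3, 0.8),
) -> float:
    """Thickness h* (mm) at which the Goldmann error vanishes."""
    def f(h: float) -> float:
        return goldmann_error(mech, CorneaGeometry.from_mid_surface(a, h), prism, p3)

    return _bracketed_root(f, *bracket, hi_limit=a * (1.0 - 1e-9))


def zero_error_curvature(
    mech: CorneaMechanics,
    h: float,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
    bracket: tuple[float, float] = (5.0, 10.0),
) -> float:
    """Mid-surface radius a* (mm) at which the Goldmann error vanishes."""
    def f(a: float) -> float:
        return goldmann_error(mech, CorneaGeometry.from_mid_surface(a, h), prism, p3)

    return _bracketed_root(f, *bracket, lo_limit=max(h, prism.g1) * (1.0 + 1e-9))


def zero_error_modulus(
    h: float,
    a: float,
    nu: float = 0.485,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
    bracket: tuple[float, float] = (0.01, 1.0),
) -> float:
    """Young's modulus E* (MPa) at which the Goldmann error vanishes."""
    geom = CorneaGeometry.from_mid_surface(a, h)

    def f(e: float) -> float:
        return goldmann_error(CorneaMechanics(e_mpa=e, nu=nu), geom, prism, p3)

    return _bracketed_root(f, *bracket)


def zero_thickness_closed_form(
    mech: CorneaMechanics,
    a: float,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
) -> float:
    """h* = 2 (1 - nu) a^3 p3 / (E g0^2), the algebraic zero-error thickness."""
    from .forward import _K_UNIT

    return 2.0 * (1.0 - mech.nu) * a**3 * p3 / (mech.e_mpa * prism.g0**2 * _K_UNIT)


def zero_curvature_closed_form(
    mech: CorneaMechanics,
    h: float,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
) -> float:
    """a* = (E h g0^2 / (2 (1 - nu) p3))^(1/3), the zero-error curvature radius."""
    from .forward import _K_UNIT

    return (
        mech.e_mpa * h * prism.g0**2 * _K_UNIT / (2.0 * (1.0 - mech.nu) * p3)
    ) ** (1.0 / 3.0)


def zero_modulus_closed_form(
    h: float,
    a: float,
    nu: float = 0.485,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
) -> float:
    """E* = 2 (1 - nu) a^3 p3 / (h g0^2), the zero-error Young's modulus."""
    from .forward import _K_UNIT

    return 2.0 * (1.0 - nu) * a**3 * p3 / (h * prism.g0**2 * _K_UNIT)


# ---------------------------------------------------------------------------
# lookup table and slopes

def err_lookup_table(
    h_grid=DEFAULT_H_GRID,
    a_grid=DEFAULT_A_GRID,
    e_grid=DEFAULT_E_GRID,
    nu: float = 0.485,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
) -> pd.DataFrame:
    """Full factorial Goldmann-error table ERR(h, a, E), mmHg.

    Evaluated from the closed form (no root finding); one row per grid
    cell with columns ``h_mm, a_mm, e_mpa, err_mmhg``. The table is what
    a correction nomogram or software lookup would ship.
    """
    h_grid = np.asarray(h_grid, float)
    a_grid = np.asarray(a_grid, float)
    e_grid = np.asarray(e_grid, float)
    for name, grid in (("h", h_grid), ("a", a_grid), ("e", e_grid)):
        if grid.size == 0 or np.any(grid <= 0):
            raise ValueError(f"{name} grid must be non-empty and positive")
    if np.any(a_grid <= prism.g1):
        raise ValueError("every curvature radius must exceed the outer zone radius")
    h, a, e = np.meshgrid(h_grid, a_grid, e_grid, indexing="ij")
    k_unit = 1e6 / 133.322
    err = e * h / (2.0 * (1.0 - nu) * a**3) * k_unit * prism.g0**2 - p3
    return pd.DataFrame(
        {
            "h_mm": h.ravel(),
            "a_mm": a.ravel(),
            "e_mpa": e.ravel(),
            "err_mmhg": err.ravel(),
        }
    )


def write_lookup_csv(table: pd.DataFrame, path) -> None:
    """Write a lookup/sweep table to CSV, rounding ERR to 0.01 mmHg.

    Rounding happens only here, at presentation time; in-memory tables
    keep full precision.
    """
    out = table.copy()
    if "err_mmhg" in out.columns:
        out["err_mmhg"] = out["err_mmhg"].round(2)
    out.to_csv(path, index=False)


def slope_vs_modulus(
    e_values,
    geom: CorneaGeometry,
    nu: float = 0.485,
    prism: PrismGeometry = DEFAULT_PRISM,
):
    """d(IOPG0)/dh (mmHg per mm of thickness) for each modulus value.

    The reading is linear in thickness with slope E g0^2 / (2 (1 - nu) a^3)
    — stiffer corneas make the thickness artefact steeper, and the slope
    ratio between two moduli equals the modulus ratio.
    """
    e_values = np.asarray(e_values, float)
    if e_values.size < 2:
        raise ValueError("need at least two modulus values to compare slopes")
    k_unit = 1e6 / 133.322
    return e_values * prism.g0**2 * k_unit / (2.0 * (1.0 - nu) * geom.a**3)
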