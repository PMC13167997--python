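"""Synthetic cohorts, instrument noise, recovery metrics, and CSV I/O.

Generates eyes by sampling biometrics from the physiologic ranges
(CCT 450-650 um, mid-surface curvature 6.5-8.0 mm, modulus
0.10-0.35 MPa), simulates their dual-zone readings, perturbs them with
Gaussian instrument noise (optionally quantized to the 0.5 mmHg dial
step), inverts the noisy readings, and scores how well truth is
recovered. Records travel as rows of a pandas DataFrame; the CSV schema
is the frame's columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DEFAULT_NU,
    DEFAULT_P3_MMHG,
    DEFAULT_PRISM,
    CorneaGeometry,
    PrismGeometry,
)
from .inversion import estimate_error, estimate_iopt, estimate_modulus, estimate_stiffness

__all__ = [
    "CohortSpec",
    "RecoveryMetrics",
    "generate_cohort",
    "invert_cohort",
    "recovery_metrics",
    "read_patient_csv",
    "write_results_csv",
    "CsvSchemaError",
]

#: Reference cornea (thickness mm, curvature mm, modulus MPa) — the
#: truncated-normal sampling means.
_REFERENCE = {"h": 0.536, "a": 7.15, "e": 0.16}


class CsvSchemaError(ValueError):
    """A patient CSV is missing required columns or holds non-numeric cells."""


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort.

    Biometric ranges default to the physiologic study ranges; true IOP
    spans normal through ocular-hypertensive eyes. ``noise_sd`` is the
    per-reading Gaussian SD in mmHg (0.5 mmHg, typical Goldmann
    repeatability); ``quantize`` snaps noisy readings to the 0.5 mmHg
    dial step. ``distribution`` is ``"uniform"`` or ``"truncnorm"``
    (centred on the reference cornea, SD a quarter of the range width,
    truncated to the range).
    """

    n: int = 1000
    seed: int = 0
    iopt_range: tuple[float, float] = (10.0, 30.0)
    h_range: tuple[float, float] = (0.450, 0.650)
    a_range: tuple[float, float] = (6.5, 8.0)
    e_range: tuple[float, float] = (0.10, 0.35)
    noise_sd: float = 0.5
    quantize: bool = False
    distribution: str = "uniform"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        if self.noise_sd < 0.0:
            raise ValueError(f"noise SD must be >= 0, got {self.noise_sd}")
        if self.distribution not in ("uniform", "truncnorm"):
            raise ValueError(
                f"distribution must be 'uniform' or 'truncnorm', got {self.distribution!r}"
            )
        for name, (lo, hi) in (
            ("iopt", self.iopt_range),
            ("h", self.h_range),
            ("a", self.a_range),
            ("e", self.e_range),
        ):
            if not (hi > lo >= 0.0):
                raise ValueError(f"{name}_range must satisfy hi > lo >= 0, got {(lo, hi)}")
        if self.a_range[0] <= DEFAULT_PRISM.g1:
            raise ValueError(
                "curvature range must stay above the outer applanation radius"
            )


def _sample(rng, lo, hi, n, distribution, centre=None):
    if distribution == "uniform" or centre is None:
        return rng.uniform(lo, hi, n)
    scale = (hi - lo) / 4.0
    dist = stats.truncnorm((lo - centre) / scale, (hi - centre) / scale,
                           loc=centre, scale=scale)
    return dist.rvs(size=n, random_state=rng)


def generate_cohort(
    spec: CohortSpec,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
    nu: float = DEFAULT_NU,
) -> pd.DataFrame:
    """Draw a cohort and simulate its clean and noisy dual readings.

    Deterministic given ``spec.seed``. Columns: ``id``, true parameters
    (``iopt_true_mmhg, h_mm, a_mm, e_true_mpa``), noise-free readings
    (``iopg0_clean_mmhg, iopg1_clean_mmhg``) and the noisy, optionally
    dial-quantized readings (``iopg0_mmhg, iopg1_mmhg``).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    iopt = _sample(rng, *spec.iopt_range, n, "uniform")
    h = _sample(rng, *spec.h_range, n, spec.distribution, _REFERENCE["h"])
    a = _sample(rng, *spec.a_range, n, spec.distribution, _REFERENCE["a"])
    e = _sample(rng, *spec.e_range, n, spec.distribution, _REFERENCE["e"])

    # vectorized forward model (same algebra as forward.simulate_dual)
    k_unit = 1e6 / 133.322
    k = e * h / (2.0 * (1.0 - nu) * a**3) * k_unit
    g0s, g1s = prism.g0**2, prism.g1**2
    iopg0 = iopt + k * g0s - p3
    iopg1 = (iopt * g1s + k * g1s * g1s - p3 * g0s) / g0s

    noisy0 = iopg0 + rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd else iopg0.copy()
    noisy1 = iopg1 + rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd else iopg1.copy()
    if spec.quantize:
        noisy0 = np.round(noisy0 * 2.0) / 2.0
        noisy1 = np.round(noisy1 * 2.0) / 2.0

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "iopt_true_mmhg": iopt,
            "h_mm": h,
            "a_mm": a,
            "e_true_mpa": e,
            "iopg0_clean_mmhg": iopg0,
            "iopg1_clean_mmhg": iopg1,
            "iopg0_mmhg": noisy0,
            "iopg1_mmhg": noisy1,
        }
    )


def invert_cohort(
    frame: pd.DataFrame,
    nu: float = DEFAULT_NU,
    prism: PrismGeometry = DEFAULT_PRISM,
    p3: float = DEFAULT_P3_MMHG,
) -> pd.DataFrame:
    """Invert the (noisy) readings of every record.

    Adds ``iopt_mmhg, k_mmhg_mm2, e_mpa, err_mmhg, quality_flag``.
    Rows whose readings imply negative stiffness are flagged
    ``negative_stiffness`` but still carry their estimates.
    """
    import warnings as _warnings

    from .inversion import NegativeStiffnessWarning

    iopg0 = frame["iopg0_mmhg"].to_numpy(float)
    iopg1 = frame["iopg1_mmhg"].to_numpy(float)
    out = frame.copy()
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", NegativeStiffnessWarning)
        out["iopt_mmhg"] = estimate_iopt(iopg0, iopg1, prism=prism, p3=p3)
        k = estimate_stiffness(iopg0, iopg1, prism=prism, p3=p3)
        out["k_mmhg_mm2"] = k
        e = np.empty(len(out))
        for i, (h, a) in enumerate(zip(frame["h_mm"], frame["a_mm"])):
            geom = CorneaGeometry.from_mid_surface(float(a), float(h))
            e[i] = 2.0 * (1.0 - nu) * geom.a**3 * k[i] / geom.h / (1e6 / 133.322)
        out["e_mpa"] = e
        out["err_mmhg"] = estimate_error(iopg0, iopg1, prism=prism, p3=p3)
    out["quality_flag"] = np.where(np.asarray(k) < 0.0, "negative_stiffness", "ok")
    return out


@dataclass(frozen=True)
class RecoveryMetrics:
    """Bias/RMSE of the recovered pressure and modulus over a cohort.

    ``coverage_iopt`` is the fraction of unflagged records with
    |recovered - true| IOP below ``bound_mmhg``.
    """

    bias_iopt: float
    rmse_iopt: float
    bias_e: float
    rmse_e: float
    coverage_iopt: float
    bound_mmhg: float
    n_used: int
    n_flagged: int


def recovery_metrics(
    frame: pd.DataFrame,
    bound_mmhg: float = 2.0,
    include_flagged: bool = False,
) -> RecoveryMetrics:
    """Score parameter recovery on an inverted cohort frame."""
    if "iopt_mmhg" not in frame.columns:
        raise ValueError("frame has no inversion columns; run invert_cohort first")
    flagged = frame["quality_flag"] != "ok"
    used = frame if include_flagged else frame[~flagged]
    if len(used) == 0:
        raise ValueError("no unflagged records to score")
    d_iopt = (used["iopt_mmhg"] - used["iopt_true_mmhg"]).to_numpy(float)
    d_e = (used["e_mpa"] - used["e_true_mpa"]).to_numpy(float)
    return RecoveryMetrics(
        bias_iopt=float(d_iopt.mean()),
        rmse_iopt=float(np.sqrt(np.mean(d_iopt**2))),
        bias_e=float(d_e.mean()),
        rmse_e=float(np.sqrt(np.mean(d_e**2))),
        coverage_iopt=float(np.mean(np.abs(d_iopt) < bound_mmhg)),
        bound_mmhg=bound_mmhg,
        n_used=int(len(used)),
        n_flagged=int(flagged.sum()),
    )


# ---------------------------------------------------------------------------
# CSV I/O

_REQUIRED = ("id", "h_mm", "iopg0_mmhg", "iopg1_mmhg")
_NUMERIC = ("h_mm", "a_mm", "r_ext_mm", "r_int_mm", "iopg0_mmhg", "iopg1_mmhg")


def read_patient_csv(path) -> pd.DataFrame:
    """Read a patient-record CSV (comma-separated, UTF-8, header required).

    Required columns: ``id, h_mm, iopg0_mmhg, iopg1_mmhg`` plus either
    ``a_mm`` or both ``r_ext_mm`` and ``r_int_mm`` (in which case
    ``a_mm`` is derived as their mean). Unknown columns pass through
    untouched. Missing columns raise :class:`CsvSchemaError` naming the
    column; non-numeric cells raise it naming the file line.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in _REQUIRED:
        if col not in frame.columns:
            raise CsvSchemaError(f"missing required column: {col}")
    if "a_mm" not in frame.columns:
        for col in ("r_ext_mm", "r_int_mm"):
            if col not in frame.columns:
                raise CsvSchemaError(
                    f"missing required column: a_mm (or {col} to derive it)"
                )
    for col in (c for c in _NUMERIC if c in frame.columns):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise CsvSchemaError(
                f"non-numeric value {frame[col][row]!r} in column {col}, "
                f"file line {row + 2}"
            )
        frame[col] = coerced
    if "a_mm" not in frame.columns:
        frame["a_mm"] = 0.5 * (frame["r_ext_mm"] + frame["r_int_mm"])
    return frame


def write_results_csv(path, frame: pd.DataFrame) -> None:
    """Write records to CSV at full precision (repr-roundtrip floats)."""
    frame.to_csv(path, index=False)
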