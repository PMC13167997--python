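"""Optional plotting hooks for sweep results and lookup tables.

Matplotlib is imported lazily; nothing else in the package needs it.
"""

from __future__ import annotations

import pandas as pd

from .sweeps import SweepResult, _PARAM_COLUMNS

_LABELS = {
    "h_mm": "central corneal thickness h (mm)",
    "a_mm": "mid-surface curvature radius a (mm)",
    "e_mpa": "Young's modulus E (MPa)",
}


def plot_sweep(result: SweepResult, path) -> None:
    """Plot IOPG0 (and ERR) against the swept parameter; save to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    col = _PARAM_COLUMNS[result.metadata["parameter"]]
    fig, ax = plt.subplots(figsize=(6, 4))
    for iopt, sub in result.table.groupby("iopt_mmhg"):
        ax.plot(sub[col], sub["iopg0_mmhg"], label=f"IOPT = {iopt:g} mmHg")
    ax.set_xlabel(_LABELS[col])
    ax.set_ylabel("standard-zone reading IOPG0 (mmHg)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_lookup_slice(table: pd.DataFrame, a_mm: float, path) -> None:
    """Heat-map slice ERR(h, E) of the lookup table at one curvature radius."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table[abs(table["a_mm"] - a_mm) < 1e-9]
    if sub.empty:
        raise ValueError(f"a={a_mm} mm is not a grid value of this table")
    pivot = sub.pivot_table(index="h_mm", columns="e_mpa", values="err_mmhg")
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.pcolormesh(pivot.columns, pivot.index, pivot.values, shading="auto")
    fig.colorbar(im, ax=ax, label="ERR (mmHg)")
    ax.set_xlabel(_LABELS["e_mpa"])
    ax.set_ylabel(_LABELS["h_mm"])
    ax.set_title(f"Goldmann error at a = {a_mm:g} mm")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
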