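"""Optional plotting helpers: kinetics curves and dose-response overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dose_response import boltzmann


def plot_kinetics(measurements: pd.DataFrame, path: str | Path, max_wells: int = 24) -> None:
    """Projected area vs time for up to ``max_wells`` wells."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for well, grp in list(measurements.groupby("well", sort=True))[:max_wells]:
        ax.plot(grp["time_min"], grp["area_mm2"], lw=0.8, label=str(well))
    ax.set_xlabel("time (min)")
    ax.set_ylabel("projected area (mm$^2$)")
    ax.set_title("Spheroid contraction kinetics")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dose_response(
    rates: pd.DataFrame,
    report: pd.DataFrame,
    compound: str,
    path: str | Path,
    response_col: str = "normalized_rate",
) -> None:
    """Normalized endpoint vs dose with the fitted Boltzmann curve overlaid."""
    sub = rates[(rates["compound"] == compound) & (rates["role"] != "vehicle")]
    rep = report[report["compound"] == compound]
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.semilogx(sub["concentration_uM"], sub[response_col], "ko", ms=5, alpha=0.7)
    if not rep.empty and bool(rep["fit_converged"].iloc[0]):
        r = rep.iloc[0]
        xg = np.linspace(
            np.log10(sub["concentration_uM"].min()) - 1,
            np.log10(sub["concentration_uM"].max()) + 0.3,
            200,
        )
        ax.semilogx(10**xg, boltzmann(xg, r["a1"], r["a2"], r["x0"], r["dx"]), "r-")
        ax.axvline(r["ic50_uM"], color="r", ls="--", lw=0.8)
    ax.set_xlabel("concentration (μM)")
    ax.set_ylabel("normalized contraction rate")
    ax.set_title(compound)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
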