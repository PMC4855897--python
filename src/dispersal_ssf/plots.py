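"""Diagnostic plots: NSD profiles with fitted movement models, and the
binned movement-rate distribution with its segmented fit."""

from __future__ import annotations

import numpy as np

from .movement_typing import MovementModelFit, nsd_dispersal, nsd_migration


def plot_nsd(nsd_profile, fit: MovementModelFit | None = None, ax=None):
    """NSD-vs-time graph for one animal-year, optionally overlaying the
    winning movement-model curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    t = nsd_profile["elapsed_days"].to_numpy(float)
    ax.plot(t, nsd_profile["nsd_km2"], ".", ms=2, color="0.4")
    if fit is not None:
        grid = np.linspace(t.min(), t.max(), 400)
        p = fit.params
        if fit.model_name == "dispersal":
            ax.plot(grid, nsd_dispersal(grid, p["delta"], p["theta"], p["phi"]), "r-")
        elif fit.model_name == "migration":
            ax.plot(
                grid,
                nsd_migration(
                    grid, p["delta"], p["theta_depart"], p["phi_depart"], p["theta_return"], p["phi_return"]
                ),
                "r-",
            )
        elif fit.model_name == "resident":
            ax.axhline(p["c"], color="r")
        elif fit.model_name == "nomadism":
            ax.plot(grid, p["b"] * grid, "r-")
    ax.set_xlabel("elapsed days")
    ax.set_ylabel("NSD (km$^2$)")
    return ax


def plot_rate_bins(bin_table, fit=None, ax=None):
    """Log-frequency movement-rate histogram with the broken-stick fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(bin_table["bin_mid"], bin_table["log_freq"], "ko", ms=4)
    if fit is not None and fit.breakpoint_found:
        x = np.linspace(bin_table["bin_mid"].min(), bin_table["bin_mid"].max(), 200)
        y = fit.intercept + fit.slope_left * x + (fit.slope_right - fit.slope_left) * np.maximum(
            x - fit.psi, 0.0
        )
        ax.plot(x, y, "r-")
        ax.axvline(fit.psi, color="r", ls=":")
    ax.set_xlabel("movement rate (m min$^{-1}$)")
    ax.set_ylabel("log$_e$ frequency")
    return ax
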