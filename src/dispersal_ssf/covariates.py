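"""Derive analysis covariates from raster layers and attach them to points.

Covariates follow the standard elk habitat-selection set: terrain
ruggedness (TRI: mean absolute elevation difference to the 8-neighbourhood)
plus its square, monthly NDVI, distance to roads, and percent canopy cover
plus its square.  All variables are z-scaled before modelling; squared
terms are squares of the scaled linear term, themselves re-scaled, so each
column enters the collinearity screen on a comparable footing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = [
    "terrain_ruggedness",
    "attach_covariates",
    "scale_and_screen",
    "ScreenReport",
    "BASE_COVARIATES",
    "MODEL_COVARIATES",
]

#: covariates sampled from the landscape, in canonical order
BASE_COVARIATES = ["ruggedness", "ndvi", "dist_roads", "canopy"]

#: shared model structure: linear + quadratic ruggedness/canopy terms
MODEL_COVARIATES = ["ruggedness", "ruggedness_sq", "ndvi", "dist_roads", "canopy", "canopy_sq"]


def terrain_ruggedness(elevation: np.ndarray) -> np.ndarray:
    """Terrain ruggedness index: per cell, the mean |Δz| over the
    8-neighbourhood; edge cells average over their available neighbours."""
    z = np.asarray(elevation, dtype=float)
    total = np.zeros_like(z)
    count = np.zeros_like(z)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            shifted = np.full_like(z, np.nan)
            src_i = slice(max(di, 0), z.shape[0] + min(di, 0))
            dst_i = slice(max(-di, 0), z.shape[0] + min(-di, 0))
            src_j = slice(max(dj, 0), z.shape[1] + min(dj, 0))
            dst_j = slice(max(-dj, 0), z.shape[1] + min(-dj, 0))
            shifted[dst_i, dst_j] = z[src_i, src_j]
            valid = ~np.isnan(shifted)
            total[valid] += np.abs(z - shifted)[valid]
            count += valid
    return total / count


def attach_covariates(points: pd.DataFrame, landscape, month=None) -> pd.DataFrame:
    """Sample landscape covariates at point locations (nearest cell).

    Parameters
    ----------
    points : DataFrame with columns ``x``, ``y`` and, unless *month* is
        given, a datetime column ``timestamp`` from which the calendar
        month selecting the NDVI layer is taken.
    landscape : :class:`~dispersal_ssf.landscape.LandscapeStack`
    month : int or array, optional
        Calendar month (1-12) overriding the timestamp-derived month.

    Returns the input frame with raw covariate columns appended.  Points
    outside the landscape extent raise, naming the offending point.
    """
    out = points.copy()
    x = out["x"].to_numpy(float)
    y = out["y"].to_numpy(float)
    if month is None:
        month = pd.DatetimeIndex(out["timestamp"]).month.to_numpy()
    month = np.broadcast_to(np.asarray(month, int), x.shape)

    out["ruggedness"] = landscape.ruggedness.sample(x, y)
    out["dist_roads"] = landscape.dist_roads.sample(x, y)
    out["canopy"] = landscape.canopy.sample(x, y)
    ndvi = np.empty_like(x)
    for m in np.unique(month):
        sel = month == m
        ndvi[sel] = landscape.ndvi_by_month[m - 1].sample(x[sel], y[sel])
    out["ndvi"] = ndvi
    return out


@dataclass
class ScreenReport:
    """Collinearity screen: pairwise Pearson r and per-variable VIF."""

    pairwise_r: pd.DataFrame
    vif: pd.Series
    r_threshold: float = 0.3
    vif_threshold: float = 2.0
    passed_r: bool = field(init=False)
    passed_vif: bool = field(init=False)

    def __post_init__(self) -> None:
        off_diag = self.pairwise_r.where(~np.eye(len(self.pairwise_r), dtype=bool))
        self.passed_r = bool((off_diag.abs().max().max() or 0) < self.r_threshold)
        self.passed_vif = bool(self.vif.max() < self.vif_threshold)


def scale_and_screen(
    design: pd.DataFrame,
    columns: list[str] | None = None,
    *,
    stats: dict[str, tuple[float, float]] | None = None,
    add_quadratics: bool = True,
    r_threshold: float = 0.3,
    vif_threshold: float = 2.0,
) -> tuple[pd.DataFrame, ScreenReport]:
    """z-scale covariates and report the collinearity screen.

    Scaling statistics default to the analysis-set mean/SD (one model, one
    scaling); pass *stats* (``{col: (mean, sd)}``) to scale against external
    statistics, e.g. landscape-wide moments when comparing against
    generator coefficients.  Quadratic terms (``*_sq``) are squares of the
    scaled linear term, re-scaled.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    columns = list(columns) if columns is not None else list(BASE_COVARIATES)
    scaled = design.copy()
    for col in columns:
        vals = design[col].to_numpy(float)
        scaled[f"{col}_raw"] = vals
        if stats is not None and col in stats:
            mu, sd = stats[col]
        else:
            mu, sd = vals.mean(), vals.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance covariate column: {col!r}")
        scaled[col] = (vals - mu) / sd

    model_cols = list(columns)
    if add_quadratics:
        for col in ("ruggedness", "canopy"):
            if col in columns:
                sq = scaled[col].to_numpy() ** 2
                sd = sq.std(ddof=0)
                if sd == 0:
                    raise ValueError(f"zero-variance covariate column: {col}_sq")
                scaled[f"{col}_sq"] = (sq - sq.mean()) / sd
                model_cols.insert(model_cols.index(col) + 1, f"{col}_sq")

    mat = scaled[model_cols].to_numpy(float)
    r = pd.DataFrame(np.corrcoef(mat, rowvar=False), index=model_cols, columns=model_cols)
    design_const = np.column_stack([np.ones(len(mat)), mat])
    vif = pd.Series(
        [variance_inflation_factor(design_const, j + 1) for j in range(mat.shape[1])],
        index=model_cols,
        name="VIF",
    )
    report = ScreenReport(r, vif, r_threshold, vif_threshold)
    return scaled, report
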