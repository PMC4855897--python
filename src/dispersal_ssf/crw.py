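"""Broad-scale route selection against correlated-random-walk nulls.

Each observed dispersal route is compared with 10 simulated alternative
paths built from the focal individual's own long-step length and
turn-angle histograms (no cross-individual leakage), sharing the observed
start point and initial heading.  Observed endpoints versus null-path
vertices are contrasted with a per-individual binomial GLM on the scaled
covariates, coefficients averaged across individuals, and each covariate
tested against zero with an exact one-sample Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .covariates import BASE_COVARIATES, attach_covariates
from .ssf import ANGLE_BIN_DEG, LENGTH_BIN_M, EmpiricalStepKernel, _histogram_mass

__all__ = [
    "CRWNullSet",
    "individual_kernel",
    "simulate_crw",
    "compare_route",
    "BroadScaleResult",
    "aggregate_population",
]

MIN_LONG_STEPS = 5


@dataclass
class CRWNullSet:
    disperser_id: str
    observed_points: pd.DataFrame  # columns x, y, month
    null_paths: list[np.ndarray]  # each (n_steps + 1, 2)
    start_xy: tuple[float, float]
    initial_heading_deg: float


def individual_kernel(long_steps: pd.DataFrame) -> EmpiricalStepKernel:
    """Step kernel from one individual's own long steps only."""
    lengths = long_steps["length_m"].to_numpy(float)
    turns = long_steps["turn_deg"].dropna().to_numpy(float)
    length_edges = np.arange(
        np.floor(lengths.min() / LENGTH_BIN_M) * LENGTH_BIN_M,
        lengths.max() + 2 * LENGTH_BIN_M,  # at least one full bin
        LENGTH_BIN_M,
    )
    angle_edges = np.arange(-180.0, 180.0 + ANGLE_BIN_DEG, ANGLE_BIN_DEG)
    return EmpiricalStepKernel(
        length_edges=length_edges,
        length_mass=_histogram_mass(lengths, length_edges),
        angle_edges=angle_edges,
        angle_mass=_histogram_mass(turns, angle_edges),
        source_animal_ids=(str(long_steps["animal_id"].iloc[0]),),
    )


def simulate_crw(
    long_steps: pd.DataFrame,
    n_paths: int = 10,
    rng: np.random.Generator | int | None = None,
    extent: tuple[float, float, float, float] | None = None,
    max_attempts: int = 100,
) -> CRWNullSet:
    """Correlated-random-walk null paths for one disperser.

    Each path takes as many steps as the individual has observed long
    steps, with (length, turn) drawn sequentially from the individual's
    own long-step histograms (uniform within bin), heading accumulated
    from the observed initial heading.  Steps leaving *extent* are
    redrawn (bounded attempts)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if len(long_steps) < MIN_LONG_STEPS:
        raise ValueError(
            f"individual {long_steps['animal_id'].iloc[0] if len(long_steps) else '?'!r} has "
            f"{len(long_steps)} long steps (<{MIN_LONG_STEPS}); excluded from CRW analysis"
        )
    long_steps = long_steps.sort_values("t_start")
    kernel = individual_kernel(long_steps)
    start = (float(long_steps["x_start"].iloc[0]), float(long_steps["y_start"].iloc[0]))
    heading0 = float(long_steps["heading_deg"].iloc[0])
    n_steps = len(long_steps)

    paths = []
    for _ in range(n_paths):
        pts = np.empty((n_steps + 1, 2))
        pts[0] = start
        heading = heading0
        for i in range(n_steps):
            for attempt in range(max_attempts):
                length, turn = kernel.sample(1, rng)
                # first step keeps the observed initial heading
                new_heading = heading0 if i == 0 else heading + float(turn[0])
                nxt = pts[i] + float(length[0]) * np.array(
                    [np.cos(np.radians(new_heading)), np.sin(np.radians(new_heading))]
                )
                if extent is None or (
                    extent[0] <= nxt[0] < extent[2] and extent[1] <= nxt[1] < extent[3]
                ):
                    break
            else:
                raise RuntimeError("CRW step could not be placed inside the extent")
            pts[i + 1] = nxt
            heading = new_heading
        paths.append(pts)

    observed = pd.DataFrame(
        {
            "x": long_steps["x_end"].to_numpy(float),
            "y": long_steps["y_end"].to_numpy(float),
            "month": pd.DatetimeIndex(long_steps["t_end"]).month,
        }
    )
    return CRWNullSet(
        disperser_id=str(long_steps["animal_id"].iloc[0]),
        observed_points=observed,
        null_paths=paths,
        start_xy=start,
        initial_heading_deg=heading0,
    )


def compare_route(
    null_set: CRWNullSet,
    landscape,
    covariates: list[str] | None = None,
    separation_bound: float = 20.0,
) -> pd.Series:
    """Binomial GLM of point label (observed = 1 vs null = 0) on scaled
    covariates; returns the coefficient vector for one individual.
    NDVI months for null vertices track the temporally corresponding
    observed step.  Perfect separation raises a flagged error."""
    import statsmodels.api as sm

    covariates = covariates if covariates is not None else list(BASE_COVARIATES)
    months = null_set.observed_points["month"].to_numpy()
    frames = [null_set.observed_points.assign(label=1)]
    for path in null_set.null_paths:
        frames.append(
            pd.DataFrame(
                {"x": path[1:, 0], "y": path[1:, 1], "month": months, "label": 0}
            )
        )
    pts = pd.concat(frames, ignore_index=True)
    pts = attach_covariates(pts, landscape, month=pts["month"].to_numpy())
    X = pts[covariates].to_numpy(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = sm.add_constant((X - mu) / sd)
    model = sm.GLM(pts["label"].to_numpy(), Xs, family=sm.families.Binomial())
    fit = model.fit(maxiter=200)
    coefs = pd.Series(fit.params[1:], index=covariates, name=null_set.disperser_id)
    if np.any(np.abs(coefs) > separation_bound) or not np.all(np.isfinite(fit.bse)):
        raise FloatingPointError(
            f"separation in route model for individual {null_set.disperser_id}"
        )
    return coefs


@dataclass
class BroadScaleResult:
    per_individual: pd.DataFrame  # individuals x covariates
    mean_beta: pd.Series
    wilcoxon_p: pd.Series
    n_positive: pd.Series
    n_negative: pd.Series


def aggregate_population(per_individual: pd.DataFrame, min_individuals: int = 5) -> BroadScaleResult:
    """Population summary: mean coefficient per covariate, exact two-sided
    one-sample Wilcoxon signed-rank test against zero (exact for n <= 25,
    zero differences dropped), and sign counts."""
    if len(per_individual) < min_individuals:
        raise ValueError(
            f"broad-scale aggregation needs >= {min_individuals} individuals, got {len(per_individual)}"
        )
    pvals = {}
    for col in per_individual.columns:
        vals = per_individual[col].to_numpy(float)
        nonzero = vals[vals != 0]
        method = "exact" if len(nonzero) <= 25 else "auto"
        pvals[col] = float(
            wilcoxon(nonzero, alternative="two-sided", method=method).pvalue
        ) if len(nonzero) else 1.0
    return BroadScaleResult(
        per_individual=per_individual,
        mean_beta=per_individual.mean(),
        wilcoxon_p=pd.Series(pvals),
        n_positive=(per_individual > 0).sum(),
        n_negative=(per_individual < 0).sum(),
    )
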