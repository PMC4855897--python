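"""Behavioural segmentation of dispersal movement.

Two tools: a random-intercept mixed model comparing movement rates across
the before/during/after/rest-of-year periods, and a broken-stick
(segmented) regression on the log-binned movement-rate distribution whose
breakpoint psi (m/min) splits during-dispersal steps into short
(foraging/resting) and long (directed travel) behavioural classes at a
step-length threshold of psi x fix interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "binned_log_frequency",
    "SegmentedRegression",
    "fit_segmented",
    "RatePeriodModel",
    "fit_rate_period_model",
    "split_steps",
    "turn_angle_histogram",
]

PERIOD_ORDER = ["rest_of_year", "before", "during", "after"]


def binned_log_frequency(rates_m_per_min, bin_width: float = 0.5) -> pd.DataFrame:
    """Bin movement rates and return per-bin natural-log frequency
    (empty bins dropped: log undefined)."""
    rates = np.asarray(rates_m_per_min, float)
    rates = rates[np.isfinite(rates)]
    edges = np.arange(0.0, rates.max() + bin_width, bin_width)
    counts, _ = np.histogram(rates, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    return pd.DataFrame({"bin_mid": mids[keep], "count": counts[keep], "log_freq": np.log(counts[keep])})


class SegmentedRegression:
    """Two-segment continuous ("broken-stick") linear regression.

    Model: y = b0 + b1*x + b2*(x - psi)_+ with the breakpoint psi estimated
    by Muggeo's iterative linearization (a working covariate
    V = -1(x > psi) with coefficient gamma updates psi by gamma/b2), seeded
    by a coarse grid search over interior x so the iteration starts near
    the global optimum.  SE(psi) = SE(gamma)/|b2| at convergence.

    Scikit-learn style estimator: ``fit(x, y)`` sets ``psi_``,
    ``psi_se_``, ``coef_`` = (intercept, left slope, right slope),
    ``r2_``, ``r2_null_``, ``breakpoint_found_``.
    """

    def __init__(self, max_iter: int = 50, tol: float = 1e-8, grid_size: int = 40, min_improvement: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol
        self.grid_size = grid_size
        self.min_improvement = min_improvement

    def get_params(self, deep: bool = True) -> dict:
        return {
            "max_iter": self.max_iter,
            "tol": self.tol,
            "grid_size": self.grid_size,
            "min_improvement": self.min_improvement,
        }

    def set_params(self, **params) -> "SegmentedRegression":
        for key, val in params.items():
            setattr(self, key, val)
        return self

    @staticmethod
    def _rss_at(x, y, psi):
        X = np.column_stack([np.ones_like(x), x, np.maximum(x - psi, 0.0)])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ beta
        return float(np.sum((y - pred) ** 2)), beta

    def fit(self, x, y) -> "SegmentedRegression":
        x = np.asarray(x, float).ravel()
        y = np.asarray(y, float).ravel()
        if len(x) != len(y) or len(x) < 5:
            raise ValueError("need at least 5 (x, y) points")
        order = np.argsort(x)
        x, y = x[order], y[order]

        # single-line null
        Xn = np.column_stack([np.ones_like(x), x])
        beta_n, *_ = np.linalg.lstsq(Xn, y, rcond=None)
        rss_null = float(np.sum((y - Xn @ beta_n) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        self.r2_null_ = 1.0 - rss_null / tss if tss > 0 else 1.0
        self.null_coef_ = beta_n

        # admissible breakpoints keep >= 2 points strictly on each side
        lo, hi = x[1], x[-3]
        if hi <= lo:
            self._no_breakpoint()
            return self
        grid = np.linspace(lo, hi, self.grid_size)
        rss_grid = [self._rss_at(x, y, p)[0] for p in grid]
        psi = float(grid[int(np.argmin(rss_grid))])

        # Muggeo iteration from the grid winner
        for _ in range(self.max_iter):
            U = np.maximum(x - psi, 0.0)
            V = -(x > psi).astype(float)
            X = np.column_stack([np.ones_like(x), x, U, V])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            b2, gamma = beta[2], beta[3]
            if abs(b2) < 1e-12:
                break
            step = gamma / b2
            psi_new = float(np.clip(psi + step, lo, hi))
            if abs(psi_new - psi) < self.tol:
                psi = psi_new
                break
            psi = psi_new

        rss, beta = self._rss_at(x, y, psi)
        # SE from the final linearized fit
        U = np.maximum(x - psi, 0.0)
        V = -(x > psi).astype(float)
        X = np.column_stack([np.ones_like(x), x, U, V])
        n, p = X.shape
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = max(n - p, 1)
        sigma2 = float(resid @ resid) / dof
        XtX_inv = np.linalg.pinv(X.T @ X)
        se_gamma = float(np.sqrt(sigma2 * XtX_inv[3, 3]))
        b2 = coef[2] if abs(coef[2]) > 1e-12 else beta[2]

        self.psi_ = psi
        self.psi_se_ = se_gamma / abs(b2) if abs(b2) > 1e-12 else float("inf")
        self.coef_ = np.array([beta[0], beta[1], beta[1] + beta[2]])  # intercept, left, right slope
        self.rss_ = rss
        self.r2_ = 1.0 - rss / tss if tss > 0 else 1.0
        # improvement judged relative to total variation so that exactly
        # collinear inputs (null RSS ~ 0) do not report a spurious break
        denom = tss if tss > 0 else 1.0
        improves = (rss_null - rss) / denom > self.min_improvement
        self.breakpoint_found_ = bool(improves and lo <= psi <= hi)
        if not improves:
            self._no_breakpoint()
        return self

    def _no_breakpoint(self) -> None:
        """Fall back to the single-line null model."""
        self.breakpoint_found_ = False
        self.psi_ = None
        self.psi_se_ = None
        self.coef_ = np.array([self.null_coef_[0], self.null_coef_[1], self.null_coef_[1]])
        self.r2_ = self.r2_null_
        self.rss_ = None

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        b0, b_left, b_right = self.coef_
        if self.psi_ is None:
            return b0 + b_left * x
        return b0 + b_left * x + (b_right - b_left) * np.maximum(x - self.psi_, 0.0)


@dataclass
class SegmentedFit:
    psi: float | None
    psi_se: float | None
    intercept: float
    slope_left: float
    slope_right: float
    r2: float
    r2_null: float
    breakpoint_found: bool


def fit_segmented(rates_m_per_min, bin_width: float = 0.5) -> tuple[SegmentedFit, pd.DataFrame]:
    """Breakpoint analysis of the movement-rate distribution: bin, take
    log_e frequencies, fit the broken stick.  Returns the fit and the
    binned table."""
    table = binned_log_frequency(rates_m_per_min, bin_width)
    est = SegmentedRegression().fit(table["bin_mid"], table["log_freq"])
    fit = SegmentedFit(
        psi=est.psi_,
        psi_se=est.psi_se_,
        intercept=float(est.coef_[0]),
        slope_left=float(est.coef_[1]),
        slope_right=float(est.coef_[2]),
        r2=float(est.r2_),
        r2_null=float(est.r2_null_),
        breakpoint_found=est.breakpoint_found_,
    )
    return fit, table


# ---------------------------------------------------------------------------
# movement rate by period (random-intercept mixed model)

@dataclass
class RatePeriodModel:
    coefficients: pd.DataFrame  # index: period; columns beta, se, ci_lo, ci_hi, n_steps
    random_intercept_var: float
    group: str
    overlap_with_reference: dict[str, bool]


def fit_rate_period_model(steps: pd.DataFrame, group: str = "") -> RatePeriodModel:
    """Movement rate (m/hr) ~ period with a per-animal random intercept,
    fitted by REML; the rest-of-year period is the reference category
    (coefficient identically 0).  Period contrasts are judged by 95%
    CI overlap, the alpha = 0.05 rule."""
    import statsmodels.formula.api as smf

    for period in PERIOD_ORDER:
        if (steps["period"] == period).sum() == 0:
            raise ValueError(f"period {period!r} has zero steps; model refused")
    df = steps[["animal_id", "period", "rate_m_per_hr"]].copy()
    df["period"] = pd.Categorical(df["period"], categories=PERIOD_ORDER)
    model = smf.mixedlm("rate_m_per_hr ~ C(period)", df, groups=df["animal_id"])
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        fit = model.fit(reml=True)

    rows = {"rest_of_year": {"beta": 0.0, "se": 0.0, "ci_lo": 0.0, "ci_hi": 0.0}}
    for period in PERIOD_ORDER[1:]:
        name = f"C(period)[T.{period}]"
        beta = float(fit.params[name])
        se = float(fit.bse[name])
        rows[period] = {"beta": beta, "se": se, "ci_lo": beta - 1.96 * se, "ci_hi": beta + 1.96 * se}
    coefs = pd.DataFrame(rows).T
    coefs["n_steps"] = [int((df["period"] == p).sum()) for p in coefs.index]
    overlap = {
        p: bool(coefs.loc[p, "ci_lo"] <= 0.0 <= coefs.loc[p, "ci_hi"]) for p in PERIOD_ORDER[1:]
    }
    return RatePeriodModel(
        coefficients=coefs,
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        group=group,
        overlap_with_reference=overlap,
    )


# ---------------------------------------------------------------------------
# short/long behavioural split

def split_steps(
    steps: pd.DataFrame, psi_m_per_min: float, interval_min: float = 120.0
) -> tuple[dict[str, pd.DataFrame], float]:
    """Split regular steps at the rate breakpoint: the threshold is
    psi x interval (rounded to the nearest metre); steps shorter than the
    threshold are "short" (foraging/resting), steps at or above it are
    "long" (directed movement)."""
    threshold_m = round(psi_m_per_min * interval_min)
    reg = steps[steps["regular"]]
    return (
        {
            "short": reg[reg["length_m"] < threshold_m].copy(),
            "long": reg[reg["length_m"] >= threshold_m].copy(),
        },
        float(threshold_m),
    )


def turn_angle_histogram(steps: pd.DataFrame, bin_deg: float = 10.0) -> pd.DataFrame:
    """Turn-angle frequency table over (-180, 180] in fixed-width bins."""
    angles = steps["turn_deg"].dropna().to_numpy(float)
    edges = np.arange(-180.0, 180.0 + bin_deg, bin_deg)
    counts, _ = np.histogram(angles, bins=edges)
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts, "freq": counts / max(len(angles), 1)}
    )
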