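"""Fine-scale step selection functions (SSF).

Matched used/available design: each observed 2-h step is compared with 10
random steps sharing its start point and prior heading, with lengths and
turns drawn from leave-one-individual-out empirical histograms (50-m and
10-degree bins).  Selection is an exponential function of endpoint
covariates, w(x) = exp(beta . x), estimated by conditional logistic
regression (Newton iterations on the within-stratum multinomial
likelihood).  Individual fits are pooled to population level by
per-coefficient random-effects combination with the between-individual
variance estimated by REML, and models are validated by k-fold
cross-validation against a within-stratum permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import spearmanr

from .covariates import MODEL_COVARIATES, attach_covariates

__all__ = [
    "EmpiricalStepKernel",
    "build_kernels",
    "draw_random_steps",
    "build_strata",
    "ConditionalLogitSSF",
    "PooledSSF",
    "pool_two_stage",
    "ValidationResult",
    "kfold_validate",
    "run_model_suite",
    "MODEL_IDS",
]

MODEL_IDS = [
    "dispersers_before",
    "dispersers_during",
    "dispersers_after",
    "residents_before",
    "residents_during",
    "residents_after",
    "during_long",
    "during_short",
]

LENGTH_BIN_M = 50.0
ANGLE_BIN_DEG = 10.0


@dataclass
class EmpiricalStepKernel:
    """Independent step-length and turn-angle histograms as probability
    masses (each sums to 1), built excluding the focal animal."""

    length_edges: np.ndarray
    length_mass: np.ndarray
    angle_edges: np.ndarray
    angle_mass: np.ndarray
    source_animal_ids: tuple = ()

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw (lengths, turns): a bin by mass, then uniform within it."""
        li = rng.choice(len(self.length_mass), size=n, p=self.length_mass)
        lengths = rng.uniform(self.length_edges[li], self.length_edges[li + 1])
        ai = rng.choice(len(self.angle_mass), size=n, p=self.angle_mass)
        turns = rng.uniform(self.angle_edges[ai], self.angle_edges[ai + 1])
        return lengths, turns


def _histogram_mass(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(values, bins=edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("no observations fall inside the histogram support")
    return counts / total


def build_kernels(
    steps: pd.DataFrame,
    focal_animal,
    length_bin_m: float = LENGTH_BIN_M,
    angle_bin_deg: float = ANGLE_BIN_DEG,
) -> EmpiricalStepKernel:
    """Leave-one-out empirical kernel for *focal_animal* from the regular
    steps of all other animals."""
    animals = steps["animal_id"].unique()
    if len(animals) < 2:
        raise ValueError("leave-one-out kernels need at least 2 animals")
    others = steps[(steps["animal_id"] != focal_animal) & steps["regular"]]
    lengths = others["length_m"].to_numpy(float)
    turns = others["turn_deg"].dropna().to_numpy(float)
    length_edges = np.arange(0.0, lengths.max() + length_bin_m, length_bin_m)
    angle_edges = np.arange(-180.0, 180.0 + angle_bin_deg, angle_bin_deg)
    return EmpiricalStepKernel(
        length_edges=length_edges,
        length_mass=_histogram_mass(lengths, length_edges),
        angle_edges=angle_edges,
        angle_mass=_histogram_mass(turns, angle_edges),
        source_animal_ids=tuple(a for a in animals if a != focal_animal),
    )


def draw_random_steps(
    start_xy: tuple[float, float],
    prior_heading_deg: float,
    kernel: EmpiricalStepKernel,
    n: int = 10,
    rng: np.random.Generator | None = None,
    extent: tuple[float, float, float, float] | None = None,
    max_attempts: int = 100,
) -> pd.DataFrame:
    """*n* random steps from *start_xy*: heading = prior heading + drawn
    turn, endpoint by planar polar displacement.  Endpoints outside
    *extent* are redrawn (bounded attempts)."""
    rng = np.random.default_rng() if rng is None else rng
    x0, y0 = start_xy
    out_x = np.empty(n)
    out_y = np.empty(n)
    out_len = np.empty(n)
    out_turn = np.empty(n)
    todo = np.arange(n)
    for _ in range(max_attempts):
        lengths, turns = kernel.sample(len(todo), rng)
        heading = np.radians(prior_heading_deg + turns)
        xs = x0 + lengths * np.cos(heading)
        ys = y0 + lengths * np.sin(heading)
        if extent is None:
            ok = np.ones(len(todo), bool)
        else:
            xmin, ymin, xmax, ymax = extent
            ok = (xs >= xmin) & (xs < xmax) & (ys >= ymin) & (ys < ymax)
        idx = todo[ok]
        out_x[idx], out_y[idx] = xs[ok], ys[ok]
        out_len[idx], out_turn[idx] = lengths[ok], turns[ok]
        todo = todo[~ok]
        if len(todo) == 0:
            break
    else:
        raise RuntimeError(f"could not place {len(todo)} random steps inside the extent")
    return pd.DataFrame({"x": out_x, "y": out_y, "length_m": out_len, "turn_deg": out_turn})


def build_strata(
    steps: pd.DataFrame,
    kernel: EmpiricalStepKernel,
    landscape,
    n_random: int = 10,
    rng: np.random.Generator | None = None,
    stratum_offset: int = 0,
) -> pd.DataFrame:
    """Matched sets for one animal: per regular step with a defined prior
    heading, the observed endpoint plus *n_random* availability endpoints,
    with raw covariates attached at all endpoints."""
    rng = np.random.default_rng() if rng is None else rng
    usable = steps[steps["regular"] & steps["turn_deg"].notna()]
    extent = landscape.extent
    xmin, ymin, xmax, ymax = extent

    def _inside(x, y):
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    # steps touching out-of-extent positions (e.g. a residual position
    # outlier) cannot form a stratum
    ok = (
        _inside(usable["x_start"], usable["y_start"])
        & _inside(usable["x_end"], usable["y_end"])
    )
    usable = usable[ok]
    rows = []
    sid = stratum_offset
    for _, step in usable.iterrows():
        prior_heading = step["heading_deg"] - step["turn_deg"]
        rand = draw_random_steps(
            (step["x_start"], step["y_start"]), prior_heading, kernel, n_random, rng, extent
        )
        month = pd.Timestamp(step["t_end"]).month
        block = pd.DataFrame(
            {
                "stratum_id": sid,
                "step_index": step.name,
                "animal_id": step["animal_id"],
                "case": [1] + [0] * n_random,
                "x": np.concatenate([[step["x_end"]], rand["x"]]),
                "y": np.concatenate([[step["y_end"]], rand["y"]]),
                "month": month,
            }
        )
        rows.append(block)
        sid += 1
    if not rows:
        return pd.DataFrame()
    design = pd.concat(rows, ignore_index=True)
    return attach_covariates(design, landscape, month=design["month"].to_numpy())


# ---------------------------------------------------------------------------
# conditional logistic regression (Newton)

class ConditionalLogitSSF:
    """Conditional logistic regression for matched used/available strata.

    Maximizes the within-stratum multinomial log-likelihood
    ``sum_s [x_obs.beta - log sum_j exp(x_j.beta)]`` by damped Newton
    iterations with observed-information standard errors.  Complete
    separation is flagged (``separation_``) and the affected standard
    errors are reported as infinity rather than failing.

    Scikit-learn style: ``fit(X, y, groups)`` sets ``coef_``, ``se_``,
    ``cov_``, ``loglik_``, ``n_iter_``, ``converged_``.
    """

    def __init__(self, max_iter: int = 60, tol: float = 1e-10, separation_bound: float = 15.0):
        self.max_iter = max_iter
        self.tol = tol
        self.separation_bound = separation_bound

    def get_params(self, deep: bool = True) -> dict:
        return {
            "max_iter": self.max_iter,
            "tol": self.tol,
            "separation_bound": self.separation_bound,
        }

    def set_params(self, **params) -> "ConditionalLogitSSF":
        for key, val in params.items():
            setattr(self, key, val)
        return self

    @staticmethod
    def _prepare(X, y, groups):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        groups = np.asarray(groups)
        order = np.argsort(groups, kind="stable")
        X, y, groups = X[order], y[order], groups[order]
        _, seg = np.unique(groups, return_inverse=True)
        n_seg = seg.max() + 1
        if not np.allclose(np.bincount(seg, weights=y), 1.0):
            raise ValueError("each stratum must contain exactly one observed (case=1) row")
        return X, y, seg, n_seg

    def _loglik_grad_hess(self, beta, X, y, seg, n_seg):
        eta = X @ beta
        # stable within-stratum softmax
        seg_max = np.full(n_seg, -np.inf)
        np.maximum.at(seg_max, seg, eta)
        z = np.exp(eta - seg_max[seg])
        denom = np.bincount(seg, weights=z, minlength=n_seg)
        p = z / denom[seg]
        ll = float(np.sum(y * (eta - (np.log(denom) + seg_max)[seg])))
        # gradient: sum over strata of (x_obs - E_p[x])
        mean_x = np.empty((n_seg, X.shape[1]))
        for j in range(X.shape[1]):
            mean_x[:, j] = np.bincount(seg, weights=p * X[:, j], minlength=n_seg)
        grad = (y[:, None] * (X - mean_x[seg])).sum(axis=0)
        # Hessian: -sum_s (E_p[x x'] - E_p[x] E_p[x]')
        Xc = X - mean_x[seg]
        H = -(Xc * p[:, None]).T @ Xc
        return ll, grad, H

    def fit(self, X, y, groups) -> "ConditionalLogitSSF":
        X, y, seg, n_seg = self._prepare(X, y, groups)
        p = X.shape[1]
        beta = np.zeros(p)
        self.converged_ = False
        self.separation_ = False
        ll_prev = -np.inf
        for it in range(1, self.max_iter + 1):
            ll, grad, H = self._loglik_grad_hess(beta, X, y, seg, n_seg)
            try:
                delta = np.linalg.solve(H, -grad)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(H, -grad, rcond=None)[0]
            # damped step: halve until the likelihood does not decrease
            step = 1.0
            for _ in range(30):
                cand = beta + step * delta
                ll_new, *_ = self._loglik_grad_hess(cand, X, y, seg, n_seg)
                if ll_new >= ll - 1e-12:
                    break
                step /= 2.0
            beta = beta + step * delta
            if np.max(np.abs(beta)) > self.separation_bound:
                self.separation_ = True
                break
            if (
                abs(ll_new - ll_prev) < self.tol * (abs(ll_prev) + 1.0)
                and np.max(np.abs(step * delta)) < 1e-8
            ):
                self.converged_ = True
                break
            ll_prev = ll_new
        ll, grad, H = self._loglik_grad_hess(beta, X, y, seg, n_seg)
        self.coef_ = beta
        self.loglik_ = ll
        self.n_iter_ = it
        # observed-information covariance; an ill-conditioned information
        # matrix yields honest (large) SEs rather than a separation flag,
        # so weak individuals are down-weighted in pooling, not discarded
        info = -H
        cov = np.linalg.pinv(info)
        diag = np.diag(cov)
        if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
            self.separation_ = True
        # a coefficient drifting off with an exploding SE is separation
        # even before it reaches the hard bound
        if np.any(np.sqrt(np.abs(diag)) > 1e3):
            self.separation_ = True
        self.cov_ = cov
        self.se_ = np.where(diag > 0, np.sqrt(np.abs(diag)), np.inf)
        if self.separation_:
            self.se_ = np.full(p, np.inf)
        return self

    def score_steps(self, X) -> np.ndarray:
        """Selection scores w(x) = exp(beta . x)."""
        return np.exp(np.asarray(X, float) @ self.coef_)


# ---------------------------------------------------------------------------
# two-stage pooling (per-coefficient REML random-effects combination)

@dataclass
class PooledSSF:
    model_id: str
    covariates: list[str]
    beta: np.ndarray
    se: np.ndarray
    tau2: np.ndarray  # between-individual variance per coefficient
    n_individuals: int
    strong: np.ndarray = field(init=False)  # |beta| > 2 SE

    def __post_init__(self) -> None:
        self.strong = np.abs(self.beta) > 2.0 * self.se

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se, "tau2": self.tau2, "strong": self.strong},
            index=self.covariates,
        )


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """REML estimate of the between-individual variance for a one-way
    random-effects combination of estimates y with sampling variances v."""

    def neg_restricted_ll(tau2):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (
            np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
        )

    upper = max(np.var(y) * 10, 1e-6)
    res = minimize_scalar(neg_restricted_ll, bounds=(0.0, upper), method="bounded")
    return float(res.x) if res.fun < neg_restricted_ll(0.0) else 0.0


def pool_two_stage(
    fits: list[ConditionalLogitSSF],
    covariates: list[str] | None = None,
    model_id: str = "",
) -> PooledSSF:
    """Combine per-individual coefficient estimates into population-level
    estimates: per coefficient, inverse-variance weighting with REML
    between-individual variance.  Individuals flagged for separation are
    excluded (infinite-variance estimates carry no weight)."""
    usable = [f for f in fits if not getattr(f, "separation_", False)]
    if len(usable) < 2:
        raise ValueError("two-stage pooling needs at least 2 non-degenerate individual fits")
    betas = np.array([f.coef_ for f in usable])
    ses = np.array([f.se_ for f in usable])
    p = betas.shape[1]
    pooled = np.empty(p)
    pooled_se = np.empty(p)
    tau2 = np.empty(p)
    for j in range(p):
        y, v = betas[:, j], ses[:, j] ** 2
        t2 = _reml_tau2(y, v)
        w = 1.0 / (v + t2)
        pooled[j] = np.sum(w * y) / np.sum(w)
        pooled_se[j] = np.sqrt(1.0 / np.sum(w))
        tau2[j] = t2
    covariates = covariates if covariates is not None else list(MODEL_COVARIATES[: betas.shape[1]])
    return PooledSSF(model_id, covariates, pooled, pooled_se, tau2, len(usable))


# ---------------------------------------------------------------------------
# k-fold cross validation

@dataclass
class ValidationResult:
    fold_rs: np.ndarray
    mean_rs: float
    null_mean_rs: np.ndarray
    null_q95: float
    useful: bool
    threshold: float = 0.65


def _fold_bin_counts(scores, case, n_bins):
    """Quantile-bin scores; count observed steps per bin; Spearman r_S of
    bin rank vs count (ties in binning broken by score rank)."""
    order = np.argsort(np.argsort(scores, kind="stable"))
    bins = np.floor(order * n_bins / len(scores)).astype(int)
    counts = np.bincount(bins[case.astype(bool)], minlength=n_bins)
    rs = spearmanr(np.arange(1, n_bins + 1), counts).statistic
    return float(rs), bins


def kfold_validate(
    X,
    y,
    groups,
    k: int = 5,
    rng: np.random.Generator | int | None = None,
    n_permutations: int = 200,
    n_bins: int = 10,
    threshold: float = 0.65,
    estimator: ConditionalLogitSSF | None = None,
) -> ValidationResult:
    """k-fold cross-validation of an SSF.

    Strata are shuffled into k folds; each fold's strata are scored with a
    model refitted on the remaining folds; held-out step scores are cut
    into *n_bins* quantile bins and the Spearman r_S between bin rank and
    the frequency of observed steps per bin is computed.  The null
    distribution permutes which step within each stratum is "observed"
    (*n_permutations* label permutations).  A model is useful when the mean
    observed r_S exceeds *threshold* and the null's 95th percentile.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.asarray(X, float)
    y = np.asarray(y, int).ravel()
    groups = np.asarray(groups)
    strata = np.unique(groups)
    if k > len(strata):
        raise ValueError(f"k={k} exceeds the number of strata ({len(strata)})")
    perm = rng.permutation(len(strata))
    fold_of = np.empty(len(strata), int)
    fold_of[perm] = np.arange(len(strata)) % k
    stratum_fold = dict(zip(strata, fold_of))
    row_fold = np.array([stratum_fold[g] for g in groups])

    base = estimator if estimator is not None else ConditionalLogitSSF()
    fold_rs = []
    fold_perm_rs = np.zeros((n_permutations, k))
    for fold in range(k):
        held = row_fold == fold
        est = ConditionalLogitSSF(**base.get_params())
        est.fit(X[~held], y[~held], groups[~held])
        scores = X[held] @ est.coef_
        case = y[held]
        seg = groups[held]
        rs, bins = _fold_bin_counts(scores, case, n_bins)
        fold_rs.append(rs)
        # permutation null: pick a random "observed" row within each stratum
        order = np.argsort(seg, kind="stable")
        seg_sorted = seg[order]
        starts = np.flatnonzero(np.r_[True, seg_sorted[1:] != seg_sorted[:-1]])
        sizes = np.diff(np.r_[starts, len(seg_sorted)])
        bins_sorted = bins[order]
        rank_grid = np.arange(1, n_bins + 1)
        for b in range(n_permutations):
            pick = starts + rng.integers(0, sizes)
            counts = np.bincount(bins_sorted[pick], minlength=n_bins)
            fold_perm_rs[b, fold] = spearmanr(rank_grid, counts).statistic
    fold_rs = np.array(fold_rs)
    null_means = np.nanmean(fold_perm_rs, axis=1)
    mean_rs = float(np.nanmean(fold_rs))
    q95 = float(np.nanquantile(null_means, 0.95))
    return ValidationResult(
        fold_rs=fold_rs,
        mean_rs=mean_rs,
        null_mean_rs=null_means,
        null_q95=q95,
        useful=bool(mean_rs > threshold and mean_rs > q95),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# the eight-model suite

def _fit_model(design: pd.DataFrame, covariates, min_strata: int = 20):
    fits = []
    for _, sub in design.groupby("animal_id", sort=False):
        if sub["stratum_id"].nunique() < min_strata:
            continue
        est = ConditionalLogitSSF()
        est.fit(sub[covariates].to_numpy(), sub["case"].to_numpy(), sub["stratum_id"].to_numpy())
        fits.append(est)
    return fits


def run_model_suite(
    design: pd.DataFrame,
    covariates: list[str] | None = None,
    *,
    k: int = 5,
    rng: np.random.Generator | int | None = None,
    n_permutations: int = 200,
    validate: bool = True,
    min_strata_per_individual: int = 20,
) -> dict[str, dict]:
    """Fit the eight-model suite (dispersers/residents x before/during/
    after, plus the during-dispersal long/short split) with the shared
    covariate structure.

    *design* needs columns ``group`` (dispersers/residents), ``period``,
    ``step_class`` (long/short/NA, dispersers-during only), ``stratum_id``,
    ``animal_id``, ``case`` and scaled covariate columns.  Models with
    fewer than two contributing individuals are reported not-estimable and
    the suite continues.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    covariates = covariates if covariates is not None else list(MODEL_COVARIATES)
    selections = {
        f"{grp}_{per}": (design["group"] == grp) & (design["period"] == per)
        for grp in ("dispersers", "residents")
        for per in ("before", "during", "after")
    }
    during_disp = (design["group"] == "dispersers") & (design["period"] == "during")
    selections["during_long"] = during_disp & (design["step_class"] == "long")
    selections["during_short"] = during_disp & (design["step_class"] == "short")

    results: dict[str, dict] = {}
    for model_id in MODEL_IDS:
        sub = design[selections[model_id]]
        entry: dict = {"n_strata": int(sub["stratum_id"].nunique()) if len(sub) else 0}
        fits = _fit_model(sub, covariates, min_strata_per_individual) if len(sub) else []
        usable = [f for f in fits if not f.separation_]
        if len(usable) < 2:
            entry["estimable"] = False
            entry["reason"] = f"{len(usable)} usable individual fits (<2)"
            results[model_id] = entry
            continue
        entry["estimable"] = True
        entry["individual_fits"] = fits
        entry["pooled"] = pool_two_stage(fits, covariates, model_id)
        if validate and sub["stratum_id"].nunique() >= k:
            entry["validation"] = kfold_validate(
                sub[covariates].to_numpy(),
                sub["case"].to_numpy(),
                sub["stratum_id"].to_numpy(),
                k=k,
                rng=rng,
                n_permutations=n_permutations,
            )
        results[model_id] = entry
    return results


def suite_report(results: dict[str, dict], covariates: list[str] | None = None) -> pd.DataFrame:
    """Wide coefficient report: one row per model, 'beta (se)'
    cells, strong effects (|beta| > 2 SE) marked with an asterisk."""
    covariates = covariates if covariates is not None else list(MODEL_COVARIATES)
    rows = {}
    for model_id, entry in results.items():
        if not entry.get("estimable"):
            rows[model_id] = {c: "NE" for c in covariates}
            continue
        pooled: PooledSSF = entry["pooled"]
        cells = {}
        for j, c in enumerate(pooled.covariates):
            mark = "*" if pooled.strong[j] else ""
            cells[c] = f"{pooled.beta[j]:.3f}{mark} ({pooled.se[j]:.3f})"
        rows[model_id] = cells
    return pd.DataFrame(rows).T
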