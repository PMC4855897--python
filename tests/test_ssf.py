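"""Step-selection machinery: kernels, availability draws, conditional
logistic estimation, two-stage pooling, cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, spearmanr

from dispersal_ssf import (
    ConditionalLogitSSF,
    build_kernels,
    draw_random_steps,
    kfold_validate,
    pool_two_stage,
)
from dispersal_ssf.ssf import EmpiricalStepKernel, _reml_tau2


def steps_frame(animal_lengths: dict):
    rows = []
    for animal, lengths in animal_lengths.items():
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": animal,
                    "length_m": lengths,
                    "turn_deg": np.linspace(-170, 170, len(lengths)),
                    "regular": True,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestKernels:
    def test_three_lengths_three_bins_equal_mass(self):
        steps = steps_frame({"focal": [999.0], "other": [10.0, 60.0, 110.0]})
        k = build_kernels(steps, "focal")
        occupied = k.length_mass[k.length_mass > 0]
        np.testing.assert_allclose(occupied, [1 / 3, 1 / 3, 1 / 3])

    def test_focal_animal_excluded(self):
        steps = steps_frame({"focal": [5000.0], "a": [100.0] * 5, "b": [200.0] * 5})
        k = build_kernels(steps, "focal")
        # the focal animal's extreme 5-km step contributes no support
        assert k.length_edges[-1] < 5000.0

    def test_masses_sum_to_one_for_every_focal(self, rng):
        steps = steps_frame({f"a{i}": rng.gamma(1.2, 400, 30) for i in range(10)})
        for focal in steps["animal_id"].unique():
            k = build_kernels(steps, focal)
            assert k.length_mass.sum() == pytest.approx(1.0)
            assert k.angle_mass.sum() == pytest.approx(1.0)

    def test_single_animal_rejected(self):
        with pytest.raises(ValueError, match="2 animals"):
            build_kernels(steps_frame({"only": [100.0] * 5}), "only")


class TestRandomSteps:
    @staticmethod
    def degenerate_kernel():
        return EmpiricalStepKernel(
            length_edges=np.array([100.0, 150.0]),
            length_mass=np.array([1.0]),
            angle_edges=np.array([0.0, 10.0]),
            angle_mass=np.array([1.0]),
        )

    def test_degenerate_kernel_annular_sector(self, rng):
        out = draw_random_steps((0.0, 0.0), 0.0, self.degenerate_kernel(), 10, rng)
        r = np.hypot(out["x"], out["y"])
        ang = np.degrees(np.arctan2(out["y"], out["x"]))
        assert ((r >= 100) & (r < 150)).all()
        assert ((ang >= 0) & (ang < 10)).all()

    def test_same_seed_reproducible(self):
        k = self.degenerate_kernel()
        a = draw_random_steps((0, 0), 30.0, k, 10, np.random.default_rng(7))
        b = draw_random_steps((0, 0), 30.0, k, 10, np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)

    def test_sampling_matches_kernel_masses(self, rng):
        kernel = EmpiricalStepKernel(
            length_edges=np.array([0.0, 50.0, 100.0, 150.0]),
            length_mass=np.array([0.5, 0.3, 0.2]),
            angle_edges=np.array([-180.0, 0.0, 180.0]),
            angle_mass=np.array([0.25, 0.75]),
        )
        lengths, turns = kernel.sample(100_000, rng)
        counts, _ = np.histogram(lengths, bins=kernel.length_edges)
        assert chisquare(counts, kernel.length_mass * len(lengths)).pvalue > 0.01
        tcounts, _ = np.histogram(turns, bins=kernel.angle_edges)
        assert chisquare(tcounts, kernel.angle_mass * len(turns)).pvalue > 0.01

    def test_extent_redraw_exhaustion_raises(self, rng):
        k = self.degenerate_kernel()
        with pytest.raises(RuntimeError, match="random steps"):
            draw_random_steps((0.0, 0.0), 0.0, k, 5, rng, extent=(-50, -50, -10, -10), max_attempts=5)


def simulate_strata(true_beta, n_strata, n_avail=10, rng=None, n_candidates=50):
    """1-D/2-D discrete-choice strata with Gaussian covariates."""
    rng = np.random.default_rng(rng)
    p = len(true_beta)
    X, y, g = [], [], []
    for s in range(n_strata):
        cands = rng.normal(size=(n_candidates, p))
        util = cands @ np.asarray(true_beta) + rng.gumbel(size=n_candidates)
        obs = cands[np.argmax(util)]
        avail = rng.normal(size=(n_avail, p))
        X.append(np.vstack([obs, avail]))
        y.extend([1] + [0] * n_avail)
        g.extend([s] * (n_avail + 1))
    return np.vstack(X), np.array(y), np.array(g)


class TestConditionalLogit:
    def test_grid_search_oracle_small_problem(self, rng):
        X, y, g = simulate_strata([0.8], n_strata=6, rng=3)
        est = ConditionalLogitSSF().fit(X, y, g)

        def loglik(beta):
            ll = 0.0
            for s in np.unique(g):
                rows = g == s
                eta = X[rows].ravel() * beta
                ll += eta[y[rows] == 1][0] - np.log(np.exp(eta).sum())
            return ll

        grid = np.linspace(-5, 5, 20001)
        beta_oracle = grid[np.argmax([loglik(b) for b in grid])]
        assert est.coef_[0] == pytest.approx(beta_oracle, abs=1e-3)

    def test_matches_statsmodels_reference(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        X, y, g = simulate_strata([-0.5, 1.0], n_strata=150, rng=11)
        est = ConditionalLogitSSF().fit(X, y, g)
        ref = ConditionalLogit(y, X, groups=g).fit(disp=False)
        # the reference optimizer stops with a looser gradient norm, so
        # agreement is bounded by its tolerance, not ours
        np.testing.assert_allclose(est.coef_, ref.params, atol=2e-4)
        np.testing.assert_allclose(est.se_, ref.bse, rtol=1e-3)

    def test_recovery_within_2se(self):
        X, y, g = simulate_strata([-0.5, 1.0], n_strata=200, rng=5)
        est = ConditionalLogitSSF().fit(X, y, g)
        assert abs(est.coef_[0] - (-0.5)) < 2 * est.se_[0]
        assert abs(est.coef_[1] - 1.0) < 2 * est.se_[1]

    def test_complete_separation_flagged(self):
        # observed always 1, available always 0: likelihood increases in beta
        X = np.array([[1.0]] + [[0.0]] * 10)
        X = np.vstack([X] * 3)
        y = np.tile([1] + [0] * 10, 3)
        g = np.repeat([0, 1, 2], 11)
        est = ConditionalLogitSSF().fit(X, y, g)
        assert est.separation_
        assert np.isinf(est.se_).all()

    def test_stratum_without_case_rejected(self):
        X = np.zeros((22, 1))
        y = np.zeros(22)
        g = np.repeat([0, 1], 11)
        with pytest.raises(ValueError, match="exactly one observed"):
            ConditionalLogitSSF().fit(X, y, g)


class TestPooling:
    @staticmethod
    def fake_fit(coef, se):
        est = ConditionalLogitSSF()
        est.coef_ = np.atleast_1d(np.asarray(coef, float))
        est.se_ = np.atleast_1d(np.asarray(se, float))
        est.separation_ = False
        return est

    def test_identical_individuals_zero_between_variance(self):
        fits = [self.fake_fit(0.5, 0.1) for _ in range(5)]
        pooled = pool_two_stage(fits, ["x"])
        assert pooled.beta[0] == pytest.approx(0.5)
        assert pooled.tau2[0] == pytest.approx(0.0, abs=1e-8)

    def test_two_individuals_match_reml_profile_oracle(self):
        y = np.array([1.0, 3.0])
        v = np.array([0.25, 0.25])
        pooled = pool_two_stage([self.fake_fit(1.0, 0.5), self.fake_fit(3.0, 0.5)], ["x"])
        assert pooled.beta[0] == pytest.approx(2.0)

        def neg_rll(tau2):
            w = 1 / (v + tau2)
            mu = (w * y).sum() / w.sum()
            return 0.5 * (np.log(v + tau2).sum() + np.log(w.sum()) + (w * (y - mu) ** 2).sum())

        grid = np.linspace(0, 50, 200001)
        tau2_oracle = grid[np.argmin([neg_rll(t) for t in grid])]
        assert pooled.tau2[0] == pytest.approx(tau2_oracle, abs=2e-3)

    def test_population_mean_recovered(self, rng):
        true_mu, between_sd = -0.2, 0.1
        fits = [
            self.fake_fit(rng.normal(true_mu, between_sd) + rng.normal(0, 0.05), 0.05)
            for _ in range(10)
        ]
        pooled = pool_two_stage(fits, ["x"])
        assert abs(pooled.beta[0] - true_mu) < 2 * max(pooled.se[0], 0.04) + 0.1

    def test_strong_flag_rule(self):
        fits = [self.fake_fit([1.0, 0.05], [0.1, 0.1]) for _ in range(4)]
        pooled = pool_two_stage(fits, ["a", "b"])
        assert pooled.strong[0] and not pooled.strong[1]

    def test_fewer_than_two_individuals_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pool_two_stage([self.fake_fit(0.5, 0.1)], ["x"])

    def test_reml_tau2_zero_when_consistent(self):
        assert _reml_tau2(np.array([1.0, 1.01, 0.99]), np.array([0.04, 0.04, 0.04])) < 1e-4


class TestKfoldValidation:
    def test_k_exceeding_strata_rejected(self):
        X, y, g = simulate_strata([0.5], n_strata=4, rng=0)
        with pytest.raises(ValueError, match="exceeds"):
            kfold_validate(X, y, g, k=5)

    def test_degenerate_max_score_observed(self, rng):
        """When the observed step is always the top-scoring step, every
        observed step lands in the top score bin and r_S equals the value
        Spearman assigns to that single-occupied-bin count vector."""
        n_strata, n_avail = 60, 10
        X = np.vstack(
            [np.vstack([[5.0], rng.uniform(-1, 1, (n_avail, 1))]) for _ in range(n_strata)]
        )
        y = np.tile([1] + [0] * n_avail, n_strata)
        g = np.repeat(np.arange(n_strata), n_avail + 1)
        res = kfold_validate(X, y, g, k=5, rng=rng, n_permutations=20)
        counts = np.zeros(10, int)
        counts[-1] = n_strata // 5  # all held-out observed in the top decile
        expected = spearmanr(np.arange(1, 11), counts).statistic
        np.testing.assert_allclose(res.fold_rs, expected, atol=1e-12)

    def test_strata_structure_conserved(self, rng):
        X, y, g = simulate_strata([0.5, -0.5], n_strata=40, rng=2)
        frame = pd.DataFrame({"g": g, "y": y})
        sizes = frame.groupby("g")["y"].agg(["size", "sum"])
        assert (sizes["size"] == 11).all()
        assert (sizes["sum"] == 1).all()
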