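"""Spatial mixture model: density, likelihood, EM, permutation null, bootstrap."""

import math

import numpy as np
import pytest
from scipy.special import ndtr

import omtrial as ot
from omtrial.datamodel import DataValidationError, ParameterError, SmallSampleError
from omtrial.mixture import trials_to_arrays

TRUE = ot.MixtureParams(0.6, 0.25, 0.15, 40.0)


def grid_integral(params, target, nontarget, screen, n=200):
    """Midpoint-rule integral of the mixture density over the screen."""
    xs = (np.arange(n) + 0.5) * screen.width_px / n
    ys = (np.arange(n) + 0.5) * screen.height_px / n
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    from omtrial.mixture import _component_logdens

    T = np.tile(np.asarray(target, float), (len(pts), 1))
    N = np.tile(
        np.asarray(nontarget, float) if nontarget is not None else (np.nan, np.nan),
        (len(pts), 1),
    )
    lt, ln, lu = _component_logdens(pts, T, N, params.sigma_px, screen)
    dens = params.p_target * np.exp(lt) + params.p_guess * np.exp(lu)
    if params.p_misbind > 0:
        dens += params.p_misbind * np.exp(ln)
    cell = (screen.width_px / n) * (screen.height_px / n)
    return dens.sum() * cell


class TestParams:
    def test_simplex_enforced(self):
        with pytest.raises(ParameterError):
            ot.MixtureParams(0.5, 0.5, 0.5, 40.0)
        with pytest.raises(ParameterError):
            ot.MixtureParams(0.7, 0.2, 0.1, -1.0)


class TestDensity:
    def test_pure_guessing_is_uniform(self, screen):
        params = ot.MixtureParams(0.0, 0.0, 1.0, 40.0)
        d = ot.mixture_density(params, (12.0, 700.0), (500.0, 400.0), None, screen)
        assert d == pytest.approx(1.0 / screen.area)

    def test_peak_at_target_matches_closed_form(self, screen):
        target = (500.0, 400.0)
        sigma = 30.0
        params = ot.MixtureParams(1.0, 0.0, 0.0, sigma)
        zx = ndtr((screen.width_px - target[0]) / sigma) - ndtr(-target[0] / sigma)
        zy = ndtr((screen.height_px - target[1]) / sigma) - ndtr(-target[1] / sigma)
        expected = 1.0 / (2 * math.pi * sigma**2) / (zx * zy)
        assert ot.mixture_density(params, target, target, None, screen) == pytest.approx(expected)

    def test_response_outside_screen_rejected(self, screen):
        with pytest.raises(DataValidationError):
            ot.mixture_density(TRUE, (-5.0, 10.0), (500.0, 400.0),
                               [(700.0, 300.0)], screen)

    def test_misbinding_without_nontarget_rejected(self, screen):
        with pytest.raises(ParameterError):
            ot.mixture_density(TRUE, (10.0, 10.0), (500.0, 400.0), None, screen)

    def test_density_normalizes_for_random_params(self, screen):
        rng = np.random.default_rng(0)
        for _ in range(10):
            w = rng.dirichlet([2.0, 2.0, 2.0])
            params = ot.MixtureParams(w[0], w[1], w[2], rng.uniform(20, 80))
            target = (rng.uniform(100, 924), rng.uniform(100, 668))
            nontarget = (rng.uniform(100, 924), rng.uniform(100, 668))
            total = grid_integral(params, target, nontarget, screen)
            assert total == pytest.approx(1.0, abs=1e-3)


class TestLogLikelihood:
    def test_pure_guessing_on_unit_area_screen(self):
        unit = ot.ScreenGeometry(width_px=2.0, height_px=0.5, margin_px=0.0)
        params = ot.MixtureParams(0.0, 0.0, 1.0, 0.1)
        X = np.array([[0.5, 0.2], [1.5, 0.4]])
        T = np.array([[1.0, 0.25], [1.0, 0.25]])
        N = np.full((2, 2), np.nan)
        assert ot.log_likelihood(params, (X, T, N), unit) == pytest.approx(0.0)

    def test_matches_per_trial_loop_oracle(self, screen, two_item_data):
        X, T, N = two_item_data(11, 40, TRUE, screen)
        total = ot.log_likelihood(TRUE, (X, T, N), screen)
        oracle = sum(
            math.log(ot.mixture_density(TRUE, x, t, [n], screen))
            for x, t, n in zip(X, T, N)
        )
        assert total == pytest.approx(oracle, abs=1e-10)

    def test_sigma_profile_decreases_past_optimum(self, screen):
        # tightly clustered on-target data: widening sigma only loses likelihood
        rng = np.random.default_rng(4)
        T = np.column_stack([rng.uniform(200, 800, 60), rng.uniform(200, 600, 60)])
        X = T + rng.normal(0, 10.0, T.shape)
        N = np.full_like(T, np.nan)
        lls = [
            ot.log_likelihood(ot.MixtureParams(0.95, 0.0, 0.05, s), (X, T, N), screen)
            for s in (10.0, 20.0, 40.0, 80.0, 160.0)
        ]
        assert all(a > b for a, b in zip(lls, lls[1:]))


class TestFitEM:
    def test_parameter_recovery_moderate_n(self, screen, two_item_data):
        fit = ot.fit_em(two_item_data(21, 800, TRUE, screen), screen, seed=0)
        assert fit.converged
        assert fit.params.p_target == pytest.approx(0.6, abs=0.05)
        assert fit.params.p_misbind == pytest.approx(0.25, abs=0.05)
        assert fit.params.p_guess == pytest.approx(0.15, abs=0.05)
        assert fit.params.sigma_px == pytest.approx(40.0, rel=0.10)

    def test_recovery_across_parameter_grid(self, screen, two_item_data):
        # median absolute weight error < 0.05 at n=1000 over a grid of
        # target-detection levels and imprecision widths
        errors = {"p_target": [], "p_misbind": [], "p_guess": []}
        for i, p_t in enumerate((0.4, 0.65, 0.9)):
            for j, sigma in enumerate((20.0, 50.0, 80.0)):
                p_n = 0.6 * (1.0 - p_t)
                true = ot.MixtureParams(p_t, p_n, 1.0 - p_t - p_n, sigma)
                fit = ot.fit_em(two_item_data(100 + 10 * i + j, 1000, true, screen),
                                screen, n_restarts=2, seed=0)
                errors["p_target"].append(abs(fit.params.p_target - p_t))
                errors["p_misbind"].append(abs(fit.params.p_misbind - p_n))
                errors["p_guess"].append(abs(fit.params.p_guess - true.p_guess))
        for name, errs in errors.items():
            assert np.median(errs) < 0.05, name

    def test_loglik_monotone_over_iterations(self, screen, two_item_data):
        fit = ot.fit_em(two_item_data(22, 300, TRUE, screen), screen, seed=0)
        diffs = np.diff(fit.ll_history)
        assert np.all(diffs >= -1e-8)

    def test_all_on_target_degenerates_to_floor(self, screen):
        rng = np.random.default_rng(1)
        T = np.column_stack([rng.uniform(200, 800, 50), rng.uniform(200, 600, 50)])
        N = np.column_stack([rng.uniform(200, 800, 50), rng.uniform(200, 600, 50)])
        fit = ot.fit_em((T.copy(), T, N), screen, seed=0)
        assert fit.params.p_target > 0.99
        assert fit.params.sigma_px == pytest.approx(1.0, abs=1e-6)  # the floor

    def test_small_sample_refused(self, screen, two_item_data):
        X, T, N = two_item_data(23, 9, TRUE, screen)
        with pytest.raises(SmallSampleError):
            ot.fit_em((X, T, N), screen)

    def test_em_at_least_as_good_as_grid_search(self, screen, two_item_data):
        arrs = two_item_data(3, 50, TRUE, screen)
        fit = ot.fit_em(arrs, screen, seed=0)
        best = -np.inf
        weights = np.linspace(0.0, 1.0, 20)
        sigmas = np.linspace(5.0, 120.0, 20)
        for pt in weights:
            for pn in weights:
                if pt + pn > 1.0:
                    continue
                for s in sigmas:
                    ll = ot.log_likelihood(
                        ot.MixtureParams(pt, pn, 1.0 - pt - pn, s), arrs, screen
                    )
                    best = max(best, ll)
        assert fit.log_likelihood >= best - 1e-9

    def test_one_item_fit_equals_two_component_fit(self, screen):
        rng = np.random.default_rng(9)
        n = 200
        T = np.column_stack([rng.uniform(150, 900, n), rng.uniform(150, 600, n)])
        X = np.where(rng.random((n, 1)) < 0.7,
                     T + rng.normal(0, 30, (n, 2)),
                     np.column_stack([rng.uniform(0, 1024, n), rng.uniform(0, 768, n)]))
        X = np.clip(X, 0, [1024, 768])
        N = np.full((n, 2), np.nan)
        fit = ot.fit_em((X, T, N), screen, seed=0)
        assert fit.params.p_misbind == 0.0
        assert fit.params.p_target + fit.params.p_guess == pytest.approx(1.0)

    def test_accepts_trial_records(self, cohort, screen):
        sel = ot.select_mixture_trials(cohort.dataset.trials)
        fit = ot.fit_em(sel, screen, seed=0)
        assert fit.n_trials == sum(
            1 for t in cohort.dataset.trials if t.condition == 2 and t.identified_correct
        )
        X, T, N = trials_to_arrays(sel)
        assert np.isnan(N).sum() == 0


class TestPermutationNull:
    def test_detects_genuine_misbinding(self, screen, two_item_data):
        hits = 0
        for rep in range(5):
            arrs = two_item_data(400 + rep, 500, ot.MixtureParams(0.5, 0.3, 0.2, 40.0), screen)
            res = ot.permutation_misbinding_null(arrs, screen, n_permutations=99, seed=rep)
            hits += res.p_value <= 0.05
            assert res.corrected_p_misbind > 0.15
        assert hits == 5

    def test_same_seed_reproduces_null_list(self, screen, two_item_data):
        arrs = two_item_data(31, 120, TRUE, screen)
        a = ot.permutation_misbinding_null(arrs, screen, n_permutations=25, seed=5)
        b = ot.permutation_misbinding_null(arrs, screen, n_permutations=25, seed=5)
        assert a.null_p_misbind == b.null_p_misbind
        assert a.p_value == b.p_value

    def test_too_few_permutations_rejected(self, screen, two_item_data):
        arrs = two_item_data(32, 60, TRUE, screen)
        with pytest.raises(ParameterError):
            ot.permutation_misbinding_null(arrs, screen, n_permutations=18)


class TestBootstrap:
    def test_zero_boot_means_absent_not_zero(self, screen, two_item_data):
        assert ot.bootstrap_se(two_item_data(41, 100, TRUE, screen), screen, n_boot=0) is None

    def test_se_shrinks_like_root_n(self, screen, two_item_data):
        se_small = ot.bootstrap_se(two_item_data(5, 250, TRUE, screen), screen,
                                   n_boot=120, seed=2)
        se_big = ot.bootstrap_se(two_item_data(6, 1000, TRUE, screen), screen,
                                 n_boot=120, seed=2)
        ratios = [se_small[k] / se_big[k]
                  for k in ("p_target", "p_misbind", "p_guess", "sigma_px")]
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.25)

    def test_se_matches_sampling_spread(self, screen, two_item_data):
        # compare one bootstrap SE against the SD over 200 independent samples
        ests = np.array([
            ot.fit_em(two_item_data(10_000 + s, 400, TRUE, screen), screen,
                      n_restarts=1).params.p_target
            for s in range(200)
        ])
        se = ot.bootstrap_se(two_item_data(999, 400, TRUE, screen), screen,
                             n_boot=150, seed=1)
        assert se["p_target"] == pytest.approx(ests.std(ddof=1), rel=0.30)
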