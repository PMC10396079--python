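import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from critnc import (
    FixedNuisance,
    ModelSpec,
    PosteriorDraws,
    check_convergence,
    coefficient_of_variation,
    log_posterior,
    sample_posterior,
    summarize_posterior,
)
from critnc.bayes import (
    GridResolutionError,
    grid_posterior_oracle,
    log_posterior_batch,
)
from critnc.io import DateGroup

from conftest import SMALL_MCMC


def toy_group(date_index=1, W=(2.0, 3.5, 4.0), N=(1.5, 2.5, 3.5)):
    return DateGroup(date_index=date_index, basis="shoot", W=np.array(W), N=np.array(N))


@pytest.fixture
def toy_spec():
    return ModelSpec(groups=[toy_group(1), toy_group(2, W=(4.0, 5.5, 6.0))])


def brute_force_log_posterior(theta, spec):
    """Direct-sum duplicate of the model density, written independently.

    Loops observation by observation with scipy's normal logpdf; shares no
    code with the vectorized implementation it checks.
    """
    a1, a2 = theta[0], theta[1]
    G = len(spec.groups)
    bmax = theta[2 : 2 + G]
    beta = theta[2 + G : 2 + 2 * G]
    sigma = theta[-1]
    if not (0 <= a1 <= 12 and 0 <= a2 <= 5 and 0 < sigma <= 0.5):
        return -math.inf
    total = 0.0
    for k, g in enumerate(spec.groups):
        if not (0 < bmax[k] <= 2 * g.W.max() and 0 < beta[k] <= 5):
            return -math.inf
        nc = a1 * bmax[k] ** (-a2)
        for w, n in zip(g.W, g.N):
            mu = bmax[k] * (1 - beta[k] * max(nc - n, 0.0))
            mu = max(mu, 0.0)
            total += stats.norm.logpdf(w, loc=mu, scale=sigma * bmax[k])
    return total


class TestLogPosterior:
    def test_outside_prior_support_is_minus_inf(self, toy_spec):
        theta = np.array([13.0, 0.3, 3.0, 5.0, 0.5, 0.5, 0.1])
        assert log_posterior(theta, toy_spec) == -np.inf
        theta = np.array([3.0, 5.5, 3.0, 5.0, 0.5, 0.5, 0.1])
        assert log_posterior(theta, toy_spec) == -np.inf

    def test_wrong_length_is_contract_error(self, toy_spec):
        with pytest.raises(ValueError, match="length"):
            log_posterior(np.array([3.0, 0.3]), toy_spec)

    def test_plateau_observation_closed_form(self):
        # every observation on the plateau: residual w - bmax, gaussian density
        g = toy_group(W=(4.0, 4.0, 4.0), N=(3.0, 3.5, 4.0))
        spec = ModelSpec(groups=[g])
        theta = np.array([1.0, 0.1, 4.0, 0.5, 0.05])
        expected = 3 * stats.norm.logpdf(0.0, scale=0.05 * 4.0)
        assert log_posterior(theta, spec) == pytest.approx(expected, abs=1e-10)

    def test_matches_independent_direct_sum_oracle(self, toy_spec):
        t1 = np.array([3.5, 0.35, 3.9, 5.9, 0.6, 0.5, 0.08])
        t2 = np.array([2.8, 0.20, 4.1, 6.1, 0.4, 0.7, 0.12])
        for t in (t1, t2):
            assert log_posterior(t, toy_spec) == pytest.approx(
                brute_force_log_posterior(t, toy_spec), abs=1e-10
            )
        # differences match as well (likelihood-ratio consistency)
        d_impl = log_posterior(t1, toy_spec) - log_posterior(t2, toy_spec)
        d_oracle = brute_force_log_posterior(t1, toy_spec) - brute_force_log_posterior(
            t2, toy_spec
        )
        assert d_impl == pytest.approx(d_oracle, abs=1e-10)

    def test_batch_agrees_with_scalar(self, toy_spec):
        rng = np.random.default_rng(0)
        thetas = np.column_stack(
            [
                rng.uniform(0, 12, 20),
                rng.uniform(0, 5, 20),
                rng.uniform(0.1, 7, 20),
                rng.uniform(0.1, 11, 20),
                rng.uniform(0.1, 5, 20),
                rng.uniform(0.1, 5, 20),
                rng.uniform(0.01, 0.5, 20),
            ]
        )
        batch = log_posterior_batch(thetas, toy_spec)
        singles = np.array([log_posterior(t, toy_spec) for t in thetas])
        np.testing.assert_allclose(batch, singles, rtol=1e-12)


class TestSampler:
    def test_same_seed_identical_draws(self, toy_spec):
        fx = FixedNuisance(bmax=(4.0, 6.0), beta=(0.5, 0.5), sigma=0.05)
        spec = ModelSpec(groups=toy_spec.groups, fixed=fx)
        d1 = sample_posterior(spec, n_chains=2, n_burn=500, n_keep=500, seed=7)
        d2 = sample_posterior(spec, n_chains=2, n_burn=500, n_keep=500, seed=7)
        np.testing.assert_array_equal(d1.draws, d2.draws)

    def test_draws_respect_prior_support(self, shoot_groups):
        spec = ModelSpec(groups=shoot_groups)
        draws = sample_posterior(spec, seed=1, **SMALL_MCMC)
        a1, a2 = draws.flat("A1"), draws.flat("A2")
        assert a1.min() >= 0 and a1.max() <= 12
        assert a2.min() >= 0 and a2.max() <= 5

    def test_weak_design_widens_a2_interval(self, noisy_trial):
        from critnc import SimConfig, default_truth, filter_low_biomass
        from critnc import make_date_groups, simulate_experiment

        truth2 = default_truth(n_dates=2)
        ds2, _ = simulate_experiment(truth2, SimConfig(seed=3, n_dates=2))
        g2 = make_date_groups(filter_low_biomass(ds2), "shoot")
        d2 = sample_posterior(ModelSpec(groups=g2), seed=1, **SMALL_MCMC)

        ds8, _ = noisy_trial
        g8 = make_date_groups(filter_low_biomass(ds8), "shoot")
        d8 = sample_posterior(ModelSpec(groups=g8), seed=1, **SMALL_MCMC)

        def width(d):
            lo, hi = np.quantile(d.flat("A2"), [0.025, 0.975])
            return hi - lo

        assert width(d2) > width(d8)


class TestConvergence:
    def _draws(self, chains):
        return PosteriorDraws(
            draws=np.stack(chains)[:, :, None],
            param_names=["A1"],
            n_burn=0,
            n_keep=chains[0].size,
        )

    def test_same_distribution_converges(self):
        rng = np.random.default_rng(1)
        draws = self._draws([rng.normal(3, 0.2, 2000) for _ in range(2)])
        report = check_convergence(draws, params=("A1",))
        assert report.converged
        assert report.rhat["A1"] < 1.05

    def test_offset_chains_fail(self):
        rng = np.random.default_rng(1)
        draws = self._draws(
            [rng.normal(3, 0.2, 2000), rng.normal(8, 0.2, 2000)]
        )
        report = check_convergence(draws, params=("A1",))
        assert not report.converged
        assert report.rhat["A1"] > 1.1

    def test_single_chain_rejected(self):
        rng = np.random.default_rng(1)
        draws = self._draws([rng.normal(3, 0.2, 100)])
        with pytest.raises(ValueError, match="2 chains"):
            check_convergence(draws, params=("A1",))


class TestSummaries:
    def _draws_for(self, values):
        arr = np.asarray(values, float)[None, :, None]
        return PosteriorDraws(arr, ["A1"], n_burn=0, n_keep=arr.shape[1])

    def test_point_mass(self):
        s = summarize_posterior(self._draws_for([2.5] * 10))
        assert s.loc["A1", "median"] == 2.5
        assert s.loc["A1", "q025"] == 2.5
        assert s.loc["A1", "q975"] == 2.5
        assert s.loc["A1", "cv_pct"] == 0.0

    def test_median_of_small_sample(self):
        s = summarize_posterior(self._draws_for([1.0, 2.0, 3.0, 4.0]))
        assert s.loc["A1", "median"] == 2.5

    def test_quantiles_match_sorted_array_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(3, 1, 30000)
        s = summarize_posterior(self._draws_for(x))
        xs = np.sort(x)

        def manual_quantile(q):  # linear interpolation on sorted order stats
            h = (xs.size - 1) * q
            lo = int(np.floor(h))
            return xs[lo] + (h - lo) * (xs[min(lo + 1, xs.size - 1)] - xs[lo])

        assert s.loc["A1", "median"] == pytest.approx(manual_quantile(0.5), abs=1e-9)
        assert s.loc["A1", "q025"] == pytest.approx(manual_quantile(0.025), abs=1e-9)
        assert s.loc["A1", "q975"] == pytest.approx(manual_quantile(0.975), abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.1, 100.0), min_size=2, max_size=40),
    )
    def test_cv_matches_direct_formula(self, values):
        x = np.asarray(values)
        expected = np.std(x, ddof=1) / np.mean(x) * 100.0
        assert coefficient_of_variation(x) == pytest.approx(expected, abs=1e-12)


class TestGridOracle:
    def test_flat_likelihood_recovers_uniform_prior(self):
        # beta fixed at ~0: predicted W is Bmax regardless of (A1, A2)
        g = toy_group(W=(4.0, 4.0, 4.0), N=(2.0, 3.0, 4.0))
        spec = ModelSpec(
            groups=[g], fixed=FixedNuisance(bmax=(4.0,), beta=(0.0,), sigma=0.05)
        )
        gp = grid_posterior_oracle(spec, n_grid=50)
        assert gp.pmf.max() == pytest.approx(gp.pmf.min(), rel=1e-9)
        assert gp.quantile("A1", 0.5) == pytest.approx(6.0, rel=0.02)

    def test_requires_fixed_nuisances(self, toy_spec):
        with pytest.raises(ValueError, match="fixed"):
            grid_posterior_oracle(toy_spec)

    def test_mode_on_boundary_raises(self):
        # data lying on a line whose critical point sits at Nc = 14 with
        # Bmax = 1: the best A1 is 14, beyond the prior's upper edge of 12,
        # so the posterior mode pins against the boundary of the grid
        g = toy_group(1, W=(0.5, 0.6, 0.7), N=(4.0, 6.0, 8.0))
        spec = ModelSpec(
            groups=[g],
            fixed=FixedNuisance(bmax=(1.0,), beta=(0.05,), sigma=0.01),
        )
        with pytest.raises(GridResolutionError):
            grid_posterior_oracle(spec, n_grid=60)

    def test_resolution_convergence(self):
        from critnc import SimConfig, default_truth, filter_low_biomass
        from critnc import make_date_groups, simulate_experiment

        truth = default_truth(n_dates=4, noise_frac=0.05)
        ds, tr = simulate_experiment(truth, SimConfig(seed=11, n_dates=4, n_rates=5, replicates=2))
        groups = make_date_groups(filter_low_biomass(ds, 0.0), "shoot")
        spec = ModelSpec(
            groups=groups,
            fixed=FixedNuisance(bmax=tr.Bmax, beta=tr.beta, sigma=tr.noise_frac),
        )
        coarse = grid_posterior_oracle(spec, n_grid=300)
        fine = grid_posterior_oracle(spec, n_grid=600)
        for p in ("A1", "A2"):
            m1, m2 = coarse.quantile(p, 0.5), fine.quantile(p, 0.5)
            assert abs(m2 - m1) / m1 < 0.005
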