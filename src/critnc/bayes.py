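"""Hierarchical Bayesian estimation of critical-N dilution curve parameters.

Model.  For one basis of one experiment, each sampling date i contributes a
group of (W, N%) pairs.  Within a group the biomass (or LAI) response to N
concentration is linear-plus-plateau with plateau Bmax_i, slope parameter
beta_i, and change point at the date's critical concentration.  The critical
concentrations of all dates are tied to the shared dilution-curve parameters
through

    Nc_i = A1 * Bmax_i^(-A2),

which makes the model hierarchical: (A1, A2) are shared across dates while
(Bmax_i, beta_i) are per-date nuisances.  Observation error is Gaussian on
W with standard deviation sigma * Bmax_i: biomass measurement error scales
with crop size, so a single relative noise parameter serves every date
without letting late-season scatter swamp the early dates.

Priors are uniform: A1 on [0, 12] and A2 on [0, 5] (weakly restrictive
ranges that comfortably contain published wheat curves), Bmax_i on
(0, 2 x max observed W in group i), beta_i on (0, 5), and the relative
noise sigma on (0, 0.5).

Sampling uses the affine-invariant ensemble sampler (emcee).  A "chain" here
is one independently seeded and initialized ensemble; n_burn and n_keep
count flattened draws per chain.  Convergence is screened with split-R-hat
and effective sample size on A1 and A2 (via arviz); non-convergent fits are
flagged and excluded downstream.

A brute-force 2-D grid posterior over (A1, A2) with nuisances fixed serves
as an independent oracle for testing the sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import arviz as az
import emcee
import numpy as np
import pandas as pd

from .io import DateGroup

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class FixedNuisance:
    """Per-date nuisances pinned at known values (reduced 2-parameter model).

    ``sigma`` is the relative observation noise (fraction of the date's
    plateau Bmax_i), matching the full model's error parameterization.
    """

    bmax: tuple[float, ...]
    beta: tuple[float, ...]
    sigma: float

    def __post_init__(self):
        object.__setattr__(self, "bmax", tuple(float(b) for b in self.bmax))
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        if len(self.bmax) != len(self.beta):
            raise ValueError("bmax and beta must have equal length")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class ModelSpec:
    """Data plus priors for one curve fit."""

    groups: list[DateGroup]
    a1_bounds: tuple[float, float] = (0.0, 12.0)
    a2_bounds: tuple[float, float] = (0.0, 5.0)
    beta_upper: float = 5.0
    fixed: FixedNuisance | None = None

    def __post_init__(self):
        if not self.groups:
            raise ValueError("ModelSpec requires at least one date group")
        for g in self.groups:
            if g.n < 3:
                raise ValueError(
                    f"group date_index={g.date_index} has {g.n} pairs (< 3)"
                )
        if self.fixed is not None and len(self.fixed.bmax) != len(self.groups):
            raise ValueError("fixed nuisances must match the number of groups")
        self.W = np.concatenate([g.W for g in self.groups])
        self.N = np.concatenate([g.N for g in self.groups])
        self.gidx = np.concatenate(
            [np.full(g.n, k, dtype=int) for k, g in enumerate(self.groups)]
        )
        self.bmax_upper = np.array([2.0 * g.W.max() for g in self.groups])
        self.sigma_upper = 0.5  # relative noise: sd as a fraction of Bmax_i

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def ndim(self) -> int:
        return 2 if self.fixed is not None else 3 + 2 * self.n_groups

    @property
    def param_names(self) -> list[str]:
        if self.fixed is not None:
            return ["A1", "A2"]
        G = self.n_groups
        return (
            ["A1", "A2"]
            + [f"Bmax_{g.date_index}" for g in self.groups]
            + [f"beta_{g.date_index}" for g in self.groups]
            + ["sigma"]
        )


def _unpack(theta: np.ndarray, spec: ModelSpec):
    """Split a (P, ndim) batch into A1, A2, Bmax (P,G), beta (P,G), sigma."""
    G = spec.n_groups
    a1, a2 = theta[:, 0], theta[:, 1]
    if spec.fixed is not None:
        P = theta.shape[0]
        bmax = np.broadcast_to(np.asarray(spec.fixed.bmax), (P, G))
        beta = np.broadcast_to(np.asarray(spec.fixed.beta), (P, G))
        sigma = np.full(P, spec.fixed.sigma)
    else:
        bmax = theta[:, 2 : 2 + G]
        beta = theta[:, 2 + G : 2 + 2 * G]
        sigma = theta[:, -1]
    return a1, a2, bmax, beta, sigma


def log_posterior_batch(theta: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Vectorized unnormalized log posterior for a (P, ndim) batch."""
    theta = np.atleast_2d(np.asarray(theta, float))
    if theta.shape[1] != spec.ndim:
        raise ValueError(
            f"parameter vector length {theta.shape[1]} != model dimension {spec.ndim}"
        )
    a1, a2, bmax, beta, sigma = _unpack(theta, spec)
    ok = (
        (a1 >= spec.a1_bounds[0]) & (a1 <= spec.a1_bounds[1])
        & (a2 >= spec.a2_bounds[0]) & (a2 <= spec.a2_bounds[1])
    )
    if spec.fixed is None:
        ok &= (bmax > 0).all(axis=1) & (bmax <= spec.bmax_upper).all(axis=1)
        ok &= (beta > 0).all(axis=1) & (beta <= spec.beta_upper).all(axis=1)
        ok &= (sigma > 0) & (sigma <= spec.sigma_upper)
    out = np.full(theta.shape[0], -np.inf)
    if not ok.any():
        return out
    a1, a2 = a1[ok], a2[ok]
    bmax, beta, sigma = bmax[ok], beta[ok], sigma[ok]
    nc = a1[:, None] * np.power(bmax, -a2[:, None])  # (P, G)
    ncg = nc[:, spec.gidx]
    bmaxg = bmax[:, spec.gidx]
    betag = beta[:, spec.gidx]
    deficit = np.maximum(ncg - spec.N[None, :], 0.0)
    mu = np.clip(bmaxg * (1.0 - betag * deficit), 0.0, None)
    resid = spec.W[None, :] - mu
    n = spec.W.size
    scale = sigma[:, None] * bmaxg  # noise sd proportional to the date's plateau
    loglik = (
        -0.5 * n * _LOG2PI
        - np.log(scale).sum(axis=1)
        - 0.5 * ((resid / scale) ** 2).sum(axis=1)
    )
    out[ok] = loglik  # flat priors contribute a constant inside the support
    return out


def log_posterior(theta, spec: ModelSpec) -> float:
    """Unnormalized log posterior density at one parameter vector.

    Returns -inf outside the prior support.
    """
    theta = np.asarray(theta, float)
    if theta.ndim != 1 or theta.size != spec.ndim:
        raise ValueError(
            f"expected parameter vector of length {spec.ndim}, got shape {theta.shape}"
        )
    return float(log_posterior_batch(theta[None, :], spec)[0])


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, shaped (n_chains, n_draws_per_chain, ndim)."""

    draws: np.ndarray
    param_names: list[str]
    n_burn: int
    n_keep: int

    def __post_init__(self):
        self.draws = np.asarray(self.draws, float)
        if self.draws.ndim != 3:
            raise ValueError("draws must be 3-D (chain, draw, parameter)")
        if self.draws.shape[2] != len(self.param_names):
            raise ValueError("parameter-name count mismatch")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def get(self, name: str) -> np.ndarray:
        """Draws for one parameter, shaped (chain, draw)."""
        return self.draws[:, :, self.param_names.index(name)]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)


def _initial_center(spec: ModelSpec) -> np.ndarray:
    """Data-driven starting point: crude per-group plateau and change point."""
    bmax0 = np.array([g.W.max() for g in spec.groups])
    nc0 = np.empty(spec.n_groups)
    for k, g in enumerate(spec.groups):
        near = g.N[g.W >= 0.9 * g.W.max()]
        nc0[k] = near.min() if near.size else g.N.max()
    # log-log regression of crude critical points on plateaus gives (A1, A2)
    X = np.column_stack([np.ones(spec.n_groups), -np.log(bmax0)])
    coef, *_ = np.linalg.lstsq(X, np.log(np.maximum(nc0, 1e-3)), rcond=None)
    a1 = float(np.clip(np.exp(coef[0]), spec.a1_bounds[0] + 0.1, spec.a1_bounds[1] - 0.1))
    a2 = float(np.clip(coef[1], spec.a2_bounds[0] + 0.01, spec.a2_bounds[1] - 0.1))
    if spec.fixed is not None:
        return np.array([a1, a2])
    beta0 = np.full(spec.n_groups, 0.5)
    sigma0 = 0.05  # relative noise starting point
    return np.concatenate([[a1, a2], 0.95 * spec.bmax_upper / 2.0, beta0, [sigma0]])


def _init_walkers(spec: ModelSpec, nwalkers: int, rng: np.random.Generator) -> np.ndarray:
    center = _initial_center(spec)
    lower = np.full(spec.ndim, 1e-6)
    if spec.fixed is not None:
        upper = np.array([spec.a1_bounds[1], spec.a2_bounds[1]]) - 1e-6
    else:
        upper = np.concatenate(
            [
                [spec.a1_bounds[1], spec.a2_bounds[1]],
                spec.bmax_upper,
                np.full(spec.n_groups, spec.beta_upper),
                [spec.sigma_upper],
            ]
        ) - 1e-6
    scale = 0.1 * np.maximum(np.abs(center), 0.05)
    p0 = center[None, :] + scale[None, :] * rng.standard_normal((nwalkers, spec.ndim))
    return np.clip(p0, lower, upper)


def sample_posterior(
    spec: ModelSpec,
    n_chains: int = 4,
    n_burn: int = 5000,
    n_keep: int = 3000,
    seed: int = 0,
    thin: int = 10,
) -> PosteriorDraws:
    """Draw from the posterior with independently seeded ensembles.

    ``n_burn`` and ``n_keep`` are totals per chain (flattened over the
    ensemble's walkers); the ensemble runs ``thin`` steps per retained step
    so the kept draws carry little walker autocorrelation.  Deterministic
    given ``seed``.  Defaults are the test scale; the large-sample
    configuration (100,000 burn-in, 30,000 retained) is reached by passing
    those counts explicitly.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if n_burn <= 0 or n_keep <= 0:
        raise ValueError("n_burn and n_keep must be positive")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    ndim = spec.ndim
    nwalkers = max(2 * ndim + 2, 32)
    nwalkers += nwalkers % 2
    # ensemble mixing time grows with dimension: never burn fewer than
    # ~30 steps per parameter regardless of the requested draw budget
    steps_burn = max(math.ceil(n_burn * thin / nwalkers), 30 * ndim, 2)
    steps_keep = max(math.ceil(n_keep * thin / nwalkers), thin)

    chains = []
    for c in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), c]))
        p0 = _init_walkers(spec, nwalkers, rng)
        # differential-evolution moves mix far better than the stretch move
        # once the per-date nuisances push the dimension past ~20
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, log_posterior_batch, args=(spec,), vectorize=True,
            moves=[
                (emcee.moves.DEMove(), 0.8),
                (emcee.moves.DESnookerMove(), 0.2),
            ],
        )
        sampler.random_state = np.random.RandomState(
            int(rng.integers(0, 2**31 - 1))
        ).get_state()
        state = sampler.run_mcmc(p0, steps_burn, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, steps_keep, progress=False)
        flat = sampler.get_chain(flat=True, thin=thin)
        if not np.isfinite(log_posterior_batch(flat[-1][None, :], spec)[0]):
            raise RuntimeError(
                "sampler finished at a non-finite posterior density; "
                "check the data groups for degeneracy"
            )
        chains.append(flat[:n_keep])
    draws = np.stack(chains, axis=0)
    return PosteriorDraws(
        draws=draws, param_names=spec.param_names, n_burn=n_burn, n_keep=n_keep
    )


@dataclass(frozen=True)
class ConvergenceReport:
    converged: bool
    rhat: dict
    ess: dict
    rhat_threshold: float
    ess_floor: float


def check_convergence(
    draws: PosteriorDraws,
    rhat_threshold: float = 1.1,
    ess_floor: float = 400.0,
    params: tuple[str, ...] = ("A1", "A2"),
) -> ConvergenceReport:
    """Screen a fit: split-R-hat below threshold and ESS above floor.

    Operates on the curve parameters (A1, A2) whose convergence gates all
    downstream use; requires at least two chains.
    """
    if draws.n_chains < 2:
        raise ValueError("convergence diagnostics require >= 2 chains")
    data = {p: draws.get(p) for p in params}
    idata = az.from_dict(posterior=data)
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {p: float(rhat_ds[p].values) for p in params}
    ess = {p: float(ess_ds[p].values) for p in params}
    converged = all(r < rhat_threshold for r in rhat.values()) and all(
        e >= ess_floor for e in ess.values()
    )
    return ConvergenceReport(
        converged=bool(converged),
        rhat=rhat,
        ess=ess,
        rhat_threshold=rhat_threshold,
        ess_floor=ess_floor,
    )


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """CV = SD / mean x 100 (%), with sample SD by default."""
    values = np.asarray(values, float)
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=ddof) / mean * 100.0)


def summarize_posterior(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-parameter posterior summary: median, 95% credible interval, CV.

    The credible interval is the central (2.5%, 97.5%) quantile pair; the CV
    is the posterior coefficient of variation (SD/mean x 100).
    """
    rows = []
    for name in draws.param_names:
        x = draws.flat(name)
        q025, med, q975 = np.quantile(x, [0.025, 0.5, 0.975])
        rows.append(
            {
                "parameter": name,
                "median": med,
                "q025": q025,
                "q975": q975,
                "mean": x.mean(),
                "sd": x.std(ddof=1) if x.size > 1 else 0.0,
                "cv_pct": (x.std(ddof=1) / x.mean() * 100.0)
                if x.size > 1 and x.mean() != 0
                else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


@dataclass
class CurveFit:
    """A fitted dilution curve for one experiment and basis."""

    experiment_id: str
    basis: str
    draws: PosteriorDraws
    summary: pd.DataFrame
    converged: bool
    diagnostics: ConvergenceReport

    @property
    def a1_median(self) -> float:
        return float(self.summary.loc["A1", "median"])

    @property
    def a2_median(self) -> float:
        return float(self.summary.loc["A2", "median"])

    def to_dict(self, draw_subsample: int = 1000) -> dict:
        """JSON-serializable summary with a deterministic draw subsample."""
        flat_a1 = self.draws.flat("A1")
        step = max(1, flat_a1.size // draw_subsample)
        return {
            "experiment_id": self.experiment_id,
            "basis": self.basis,
            "converged": self.converged,
            "rhat": self.diagnostics.rhat,
            "ess": self.diagnostics.ess,
            "summary": self.summary.reset_index().to_dict("records"),
            "draws_subsample": {
                "A1": self.draws.flat("A1")[::step].tolist(),
                "A2": self.draws.flat("A2")[::step].tolist(),
            },
        }


def fit_curve(
    groups: list[DateGroup],
    experiment_id: str = "",
    basis: str = "",
    n_chains: int = 4,
    n_burn: int = 5000,
    n_keep: int = 3000,
    seed: int = 0,
    rhat_threshold: float = 1.1,
    ess_floor: float = 400.0,
) -> CurveFit:
    """End-to-end fit of one basis: sample, diagnose, summarize."""
    spec = ModelSpec(groups=groups)
    draws = sample_posterior(
        spec, n_chains=n_chains, n_burn=n_burn, n_keep=n_keep, seed=seed
    )
    report = check_convergence(
        draws, rhat_threshold=rhat_threshold, ess_floor=ess_floor
    )
    if basis == "" and groups:
        basis = groups[0].basis
    if experiment_id == "" and groups:
        experiment_id = groups[0].experiment_id
    return CurveFit(
        experiment_id=experiment_id,
        basis=basis,
        draws=draws,
        summary=summarize_posterior(draws),
        converged=report.converged,
        diagnostics=report,
    )


@dataclass
class GridPosterior:
    """Brute-force posterior over (A1, A2) on a regular grid."""

    a1_grid: np.ndarray
    a2_grid: np.ndarray
    pmf: np.ndarray  # (len(a1_grid), len(a2_grid)), sums to 1

    def marginal(self, param: str) -> tuple[np.ndarray, np.ndarray]:
        if param == "A1":
            return self.a1_grid, self.pmf.sum(axis=1)
        if param == "A2":
            return self.a2_grid, self.pmf.sum(axis=0)
        raise KeyError(param)

    def quantile(self, param: str, q) -> np.ndarray:
        grid, pm = self.marginal(param)
        pm = pm / pm.sum()
        # cumulative mass evaluated at cell centers (half-cell correction),
        # so a uniform pmf yields exact quantiles of the continuous uniform
        cdf_mid = np.cumsum(pm) - pm / 2.0
        return np.interp(np.asarray(q, float), cdf_mid, grid)

    def summary(self) -> pd.DataFrame:
        rows = []
        for p in ("A1", "A2"):
            q025, med, q975 = self.quantile(p, [0.025, 0.5, 0.975])
            rows.append({"parameter": p, "median": med, "q025": q025, "q975": q975})
        return pd.DataFrame(rows).set_index("parameter")


class GridResolutionError(ValueError):
    """The grid is too coarse: the posterior mode sits on a boundary cell."""


def grid_posterior_oracle(spec: ModelSpec, n_grid: int = 200) -> GridPosterior:
    """Exhaustive 2-D posterior over (A1, A2) with nuisances fixed.

    Cell centers cover the full prior box; probabilities are normalized by
    direct summation.  Serves as the independent oracle against which the
    MCMC sampler is certified.
    """
    if spec.fixed is None:
        raise ValueError("grid oracle requires a spec with fixed nuisances")
    a1_lo, a1_hi = spec.a1_bounds
    a2_lo, a2_hi = spec.a2_bounds
    da1 = (a1_hi - a1_lo) / n_grid
    da2 = (a2_hi - a2_lo) / n_grid
    a1_grid = a1_lo + (np.arange(n_grid) + 0.5) * da1
    a2_grid = a2_lo + (np.arange(n_grid) + 0.5) * da2
    A1, A2 = np.meshgrid(a1_grid, a2_grid, indexing="ij")
    theta = np.column_stack([A1.ravel(), A2.ravel()])
    # evaluate in chunks to bound peak memory on fine grids
    logp = np.concatenate(
        [log_posterior_batch(chunk, spec) for chunk in np.array_split(theta, max(1, theta.shape[0] // 50000))]
    ).reshape(n_grid, n_grid)
    logp -= logp.max()
    pmf = np.exp(logp)
    total = pmf.sum()
    if not np.isfinite(total) or total <= 0:
        raise RuntimeError("grid posterior is degenerate")
    pmf /= total
    i, j = np.unravel_index(np.argmax(pmf), pmf.shape)
    flatness = pmf.max() - pmf.min() < 1e-15  # flat posterior has no mode to bracket
    if not flatness and (i in (0, n_grid - 1) or j in (0, n_grid - 1)):
        raise GridResolutionError(
            "posterior mode lies on a boundary grid cell; increase n_grid"
        )
    return GridPosterior(a1_grid=a1_grid, a2_grid=a2_grid, pmf=pmf)
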