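"""Synthetic G x E x M wheat N-trial generator with known dilution curves.

Every downstream stage (fitting, NNI, driver correlation) is exercised on
simulated trials whose ground truth is known exactly.  A trial is defined by
a ground-truth shoot dilution curve Nc = A1 * W^-A2, a per-date trajectory of
maximal shoot biomass Bmax_i, and a per-date linear-plus-plateau slope
beta_i: at each sampling date the shoot biomass response to shoot N
concentration rises linearly below the date's critical concentration
Nc_i = A1 * Bmax_i^-A2 and plateaus at Bmax_i above it.

Treatments place the achieved N concentration at fixed multiples of Nc_i
spanning deficient to luxury supply, so both limbs of the change-point
response are populated at every date.  Observation noise is additive
Gaussian on biomass with a standard deviation proportional to Bmax_i.

The shoot is split into leaf and stem with a leaf fraction that declines
over the season (stem dominates late).  Leaf N sits a fixed offset above
shoot N and stem N is solved so that the biomass-weighted mean of organ N
concentrations reproduces the shoot N concentration exactly.  LAI is leaf
biomass times a specific leaf area.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import ExperimentDataset, ExperimentMeta, dataset_from_frame
from .drivers import WeatherSeries


class DegenerateDesignError(ValueError):
    """The simulation design yields no positive expected biomass."""


def linear_plus_plateau(N, Bmax, beta, Nc):
    """Expected biomass under the linear-plus-plateau response.

    Below the critical concentration ``Nc`` the biomass falls linearly with
    the N deficit, ``Bmax * (1 - beta * (Nc - N))``; at or above ``Nc`` it
    plateaus at ``Bmax``.  The result is clipped below at zero.  Vectorized
    over any argument.
    """
    N, Bmax, beta, Nc = np.broadcast_arrays(
        np.asarray(N, float), np.asarray(Bmax, float),
        np.asarray(beta, float), np.asarray(Nc, float),
    )
    deficit = np.maximum(Nc - N, 0.0)
    out = np.clip(Bmax * (1.0 - beta * deficit), 0.0, None)
    return out if out.shape else float(out)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated trial (shoot basis).

    ``A1`` is the critical N concentration (% dry mass) at W = 1 t/ha;
    ``A2`` the dimensionless dilution exponent.  ``Bmax`` (t/ha) must be
    strictly increasing over sampling dates; ``beta`` (per % N) is the
    relative biomass loss per unit N deficit at each date.
    """

    A1: float
    A2: float
    Bmax: tuple[float, ...]
    beta: tuple[float, ...]
    noise_frac: float = 0.05  # sigma_obs as a fraction of Bmax_i

    def __post_init__(self):
        object.__setattr__(self, "Bmax", tuple(float(b) for b in self.Bmax))
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        if not (0 < self.A1 < 12):
            raise ValueError("A1 must lie in (0, 12)")
        if not (0 <= self.A2 < 5):
            raise ValueError("A2 must lie in [0, 5)")
        if len(self.Bmax) != len(self.beta):
            raise ValueError("Bmax and beta must have the same length")
        if any(b <= 0 for b in self.Bmax) or any(b <= 0 for b in self.beta):
            raise ValueError("Bmax and beta must be positive")
        if any(b2 <= b1 for b1, b2 in zip(self.Bmax, self.Bmax[1:])):
            raise ValueError("Bmax must be strictly increasing over dates")
        if not (0 <= self.noise_frac < 1):
            raise ValueError("noise_frac must lie in [0, 1)")

    @property
    def n_dates(self) -> int:
        return len(self.Bmax)

    def nc(self, date_index: int) -> float:
        """Critical shoot N concentration at one sampling date (1-based)."""
        return self.A1 * self.Bmax[date_index - 1] ** (-self.A2)

    def to_dict(self) -> dict:
        return {
            "A1": self.A1, "A2": self.A2,
            "Bmax": list(self.Bmax), "beta": list(self.beta),
            "noise_frac": self.noise_frac,
        }


@dataclass(frozen=True)
class SimConfig:
    """Design of one simulated trial.

    ``n_quantiles`` are the achieved-N multiples of the per-date critical
    concentration; by default six treatments at (0.6, 0.8, 0.95, 1.05, 1.2,
    1.4) x Nc, spanning deficient to luxury supply.  Organ accounting uses a
    leaf fraction declining linearly from ``leaf_frac_start`` to
    ``leaf_frac_end`` over dates, a fixed ``leaf_n_offset`` (% N) of leaf
    above shoot N, and ``specific_leaf_area`` (LAI units per t/ha leaf
    biomass).
    """

    experiment_id: str = "SIM-01"
    site: str = "SimSite"
    year: int = 2013
    genotype: str = "SimWheat"
    sowing_density: float = 240.0
    n_dates: int = 7
    n_rates: int = 6
    replicates: int = 3
    n_quantiles: tuple[float, ...] | None = None
    leaf_frac_start: float = 0.55
    leaf_frac_end: float = 0.30
    leaf_n_offset: float = 0.5
    specific_leaf_area: float = 2.0
    sowing_date: str = ""  # ISO date; default Oct 15 of year-1
    flowering_date: str = ""  # ISO date; default Apr 20 of year
    weather_mean_tmax: float = 14.0
    weather_mean_tmin: float = 4.0
    weather_rain_prob: float = 0.25
    weather_rain_mm: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.n_dates < 2:
            raise ValueError("n_dates must be >= 2")
        if self.n_rates < 3:
            raise ValueError("n_rates must be >= 3")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def quantiles(self) -> np.ndarray:
        if self.n_quantiles is not None:
            q = np.asarray(self.n_quantiles, float)
            if len(q) != self.n_rates:
                raise ValueError("n_quantiles length must equal n_rates")
            return q
        if self.n_rates == 6:
            return np.array([0.6, 0.8, 0.95, 1.05, 1.2, 1.4])
        return np.linspace(0.6, 1.4, self.n_rates)

    @property
    def sowing(self) -> dt.date:
        if self.sowing_date:
            return dt.date.fromisoformat(self.sowing_date)
        return dt.date(self.year - 1, 10, 15)

    @property
    def flowering(self) -> dt.date:
        if self.flowering_date:
            return dt.date.fromisoformat(self.flowering_date)
        return dt.date(self.year, 4, 20)


def default_truth(
    n_dates: int = 7,
    A1: float = 3.5,
    A2: float = 0.35,
    bmax_start: float = 1.5,
    bmax_end: float = 12.0,
    beta_level: float = 0.45,
    noise_frac: float = 0.05,
) -> TruthRecord:
    """A realistic wheat shoot truth: Bmax grows geometrically over dates."""
    bmax = np.geomspace(bmax_start, bmax_end, n_dates)
    beta = np.full(n_dates, beta_level)
    return TruthRecord(A1=A1, A2=A2, Bmax=tuple(bmax), beta=tuple(beta),
                       noise_frac=noise_frac)


def _simulate_weather(rng: np.random.Generator, cfg: SimConfig) -> WeatherSeries:
    """Daily Tmax/Tmin/rain over sowing -> flowering with a winter dip."""
    days = pd.date_range(cfg.sowing, cfg.flowering, freq="D")
    t = np.arange(len(days))
    # seasonal course: mild at sowing, cold mid-winter, warming to flowering
    phase = np.cos(2 * np.pi * (t - 0.45 * len(t)) / 365.0)
    tmean = (cfg.weather_mean_tmax + cfg.weather_mean_tmin) / 2.0 - 8.0 * phase
    spread = (cfg.weather_mean_tmax - cfg.weather_mean_tmin) / 2.0
    tmax = tmean + spread + rng.normal(0, 1.2, len(t))
    tmin = tmean - spread + rng.normal(0, 1.2, len(t))
    tmin = np.minimum(tmin, tmax)  # guarantee Tmax >= Tmin daily
    wet = rng.random(len(t)) < cfg.weather_rain_prob
    rain = np.where(wet, rng.gamma(1.3, cfg.weather_rain_mm, len(t)), 0.0)
    return WeatherSeries(
        pd.DataFrame(
            {
                "date": days.date.astype(str),
                "tmax_c": np.round(tmax, 2),
                "tmin_c": np.round(tmin, 2),
                "rain_mm": np.round(rain, 2),
            }
        )
    )


def simulate_experiment(truth: TruthRecord, cfg: SimConfig) -> tuple[ExperimentDataset, TruthRecord]:
    """Simulate one trial; returns the validated dataset and its truth.

    Deterministic given (truth, cfg): all randomness flows from
    ``cfg.seed``.  Emits leaf, stem and shoot rows with exact
    shoot = leaf + stem accounting and an LAI proportional to leaf biomass.
    """
    if truth.n_dates != cfg.n_dates:
        raise ValueError("truth.n_dates must equal cfg.n_dates")
    rng = np.random.default_rng(cfg.seed)
    quants = cfg.quantiles

    vpd_days = (cfg.flowering - cfg.sowing).days
    offsets = np.linspace(0.35 * vpd_days, vpd_days - 10, cfg.n_dates)
    dates = [cfg.sowing + dt.timedelta(days=int(round(o))) for o in offsets]
    leaf_frac = np.linspace(cfg.leaf_frac_start, cfg.leaf_frac_end, cfg.n_dates)
    n_rates_kg = tuple(np.round(np.linspace(0, 300, cfg.n_rates), 1))

    rows = []
    any_positive = False
    for i in range(cfg.n_dates):
        bmax_i, beta_i = truth.Bmax[i], truth.beta[i]
        nc_i = truth.A1 * bmax_i ** (-truth.A2)
        for j, q in enumerate(quants):
            n_shoot = q * nc_i
            expected = linear_plus_plateau(n_shoot, bmax_i, beta_i, nc_i)
            if expected > 0:
                any_positive = True
            for rep in range(1, cfg.replicates + 1):
                w_shoot = expected + rng.normal(0, truth.noise_frac * bmax_i)
                w_shoot = max(w_shoot, 0.02 * bmax_i)
                fl = leaf_frac[i]
                w_leaf, w_stem = fl * w_shoot, (1 - fl) * w_shoot
                n_leaf = n_shoot + cfg.leaf_n_offset
                # stem N solved so the biomass-weighted organ mean is n_shoot
                n_stem = (n_shoot - fl * n_leaf) / (1 - fl)
                lai = cfg.specific_leaf_area * w_leaf
                common = {
                    "experiment_id": cfg.experiment_id,
                    "date": dates[i].isoformat(),
                    "treatment_id": f"N{j}",
                    "replicate": rep,
                    "lai": lai,
                    "shoot_biomass_t_ha": w_shoot,
                    "shoot_n_conc_pct": n_shoot,
                }
                rows.append({**common, "organ": "leaf",
                             "biomass_t_ha": w_leaf, "n_conc_pct": n_leaf})
                rows.append({**common, "organ": "stem",
                             "biomass_t_ha": w_stem, "n_conc_pct": n_stem})
                rows.append({**common, "organ": "shoot",
                             "biomass_t_ha": w_shoot, "n_conc_pct": n_shoot})
    if not any_positive:
        raise DegenerateDesignError(
            "simulation design produced non-positive expected biomass for every treatment"
        )

    meta = ExperimentMeta(
        experiment_id=cfg.experiment_id,
        site=cfg.site,
        year=cfg.year,
        genotype=cfg.genotype,
        sowing_density=cfg.sowing_density,
        sowing_date=cfg.sowing,
        flowering_date=cfg.flowering,
        n_rates=n_rates_kg,
    )
    weather = _simulate_weather(rng, cfg)
    ds = dataset_from_frame(meta, pd.DataFrame(rows), weather=weather)
    return ds, truth


def subseed(master_seed: int, *labels) -> int:
    """Stable sub-seed below 2^31 keyed by the master seed and text labels."""
    key = f"{master_seed}|" + "|".join(str(x) for x in labels)
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def simulate_gem_suite(
    truths: list[TruthRecord], cfgs: list[SimConfig], master_seed: int | None = None
) -> list[tuple[ExperimentDataset, TruthRecord]]:
    """Simulate a suite of independent G x E x M trials.

    Each trial's seed is derived from ``master_seed`` (or the config's own
    seed if ``master_seed`` is None) keyed by experiment_id, so reordering
    the list never perturbs an individual experiment's output.
    """
    if not truths or len(truths) != len(cfgs):
        raise ValueError("truths and cfgs must be non-empty and of equal length")
    ids = [c.experiment_id for c in cfgs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate experiment_id in suite: {ids}")
    out = []
    for truth, cfg in zip(truths, cfgs):
        if master_seed is not None:
            cfg = replace(cfg, seed=subseed(master_seed, cfg.experiment_id))
        out.append(simulate_experiment(truth, cfg))
    return out


def default_gem_suite(
    n_experiments: int = 14,
    master_seed: int = 0,
    shared_truth: TruthRecord | None = None,
    density_a1_rho: float | None = None,
) -> tuple[list[TruthRecord], list[SimConfig]]:
    """Draw a realistic suite of G x E x M designs and truths.

    Designs vary site, year, genotype, sowing density (150-400 plants/m2),
    number of sampling dates (5-8) and N rates (4-8).  Truths vary
    A1 in [2.8, 4.6] and A2 in [0.25, 0.45] unless ``shared_truth`` pins a
    single curve for every condition.  With ``density_a1_rho`` set, true A1
    is constructed affine in sowing density with the requested correlation
    (for driver-recovery studies).
    """
    sites = ["Yizheng", "Rugao", "Xinxiang", "Xuzhou", "Sihong"]
    genotypes = ["JM22", "XM30", "NM13", "AK58", "YM16"]
    truths, cfgs = [], []
    densities, zs = [], []
    rng_master = np.random.default_rng(subseed(master_seed, "suite"))
    for k in range(n_experiments):
        exp_id = f"SIM-{k + 1:02d}"
        rng = np.random.default_rng(subseed(master_seed, "design", exp_id))
        density = float(rng.uniform(150, 400))
        densities.append(density)
        zs.append(float(rng.standard_normal()))
        cfgs.append(
            SimConfig(
                experiment_id=exp_id,
                site=sites[k % len(sites)],
                year=2010 + (k % 6),
                genotype=genotypes[(k // len(sites)) % len(genotypes)],
                sowing_density=round(density, 1),
                n_dates=int(rng.integers(5, 9)),
                n_rates=int(rng.integers(4, 9)),
                replicates=3,
                seed=subseed(master_seed, exp_id),
            )
        )
    dens = np.asarray(densities)
    z_dens = (dens - dens.mean()) / dens.std()
    for k in range(n_experiments):
        rng = np.random.default_rng(subseed(master_seed, "truth", cfgs[k].experiment_id))
        if shared_truth is not None:
            a1, a2 = shared_truth.A1, shared_truth.A2
            noise_frac = shared_truth.noise_frac
        elif density_a1_rho is not None:
            rho = density_a1_rho
            a1 = 3.7 + 0.5 * (rho * z_dens[k] + np.sqrt(1 - rho**2) * zs[k])
            a1 = float(np.clip(a1, 2.5, 5.0))
            a2 = float(rng.uniform(0.25, 0.45))
            noise_frac = 0.05
        else:
            a1 = float(rng.uniform(2.8, 4.6))
            a2 = float(rng.uniform(0.25, 0.45))
            noise_frac = 0.05
        truths.append(
            default_truth(
                n_dates=cfgs[k].n_dates,
                A1=a1,
                A2=a2,
                bmax_start=float(rng.uniform(1.2, 2.0)),
                bmax_end=float(rng.uniform(9.0, 14.0)),
                beta_level=float(rng.uniform(0.35, 0.6)),
                noise_frac=noise_frac,
            )
        )
    return truths, cfgs
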