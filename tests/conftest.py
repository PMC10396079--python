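import warnings

import numpy as np
import pandas as pd
import pytest

from critnc import (
    NcCurve,
    SimConfig,
    default_truth,
    filter_low_biomass,
    make_date_groups,
    simulate_experiment,
)

# suppress the arviz refactor notice so test output stays readable
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

#: MCMC settings small enough for unit tests, large enough to converge.
SMALL_MCMC = {"n_chains": 2, "n_burn": 2000, "n_keep": 1500}


def observation_rows(
    n_dates=2,
    n_treatments=2,
    experiment_id="E1",
    start="2013-03-01",
):
    """Well-formed long-format observation rows (one organ row per record)."""
    rows = []
    dates = pd.date_range(start, periods=n_dates, freq="14D")
    for d_i, date in enumerate(dates):
        for t in range(n_treatments):
            shoot_w = 2.0 + d_i + 0.5 * t
            shoot_n = 2.5 - 0.2 * d_i + 0.3 * t
            for organ, w, n in [
                ("leaf", 0.5 * shoot_w, shoot_n + 0.5),
                ("stem", 0.5 * shoot_w, shoot_n - 0.5),
                ("shoot", shoot_w, shoot_n),
            ]:
                rows.append(
                    {
                        "experiment_id": experiment_id,
                        "date": date.date().isoformat(),
                        "treatment_id": f"N{t}",
                        "organ": organ,
                        "biomass_t_ha": w,
                        "lai": 1.0 * shoot_w,
                        "n_conc_pct": n,
                        "shoot_biomass_t_ha": shoot_w,
                        "shoot_n_conc_pct": shoot_n,
                        "replicate": 1,
                    }
                )
    return rows


@pytest.fixture
def meta_dict():
    return {
        "experiment_id": "E1",
        "site": "Rugao",
        "year": 2013,
        "genotype": "AK58",
        "density_plants_m2": 240.0,
        "sowing_date": "2012-10-25",
        "flowering_date": "2013-04-20",
        "n_rates_kg_ha": "0;120;240",
    }


@pytest.fixture(scope="session")
def noise_free_trial():
    """Deterministic noise-free simulated trial (7 dates, 6 rates, 1 rep)."""
    truth = default_truth(n_dates=7, noise_frac=0.0)
    ds, tr = simulate_experiment(truth, SimConfig(seed=2, replicates=1))
    return ds, tr


@pytest.fixture(scope="session")
def noisy_trial():
    """Default-noise simulated trial used across fitting tests."""
    truth = default_truth(n_dates=8)
    ds, tr = simulate_experiment(
        truth, SimConfig(seed=3, n_dates=8, n_rates=6, replicates=3)
    )
    return ds, tr


@pytest.fixture(scope="session")
def shoot_groups(noisy_trial):
    ds, _ = noisy_trial
    return make_date_groups(filter_low_biomass(ds), "shoot")


def reconstruct_curve(ds, basis) -> NcCurve:
    """Noise-free oracle: per-date critical points by line-plateau intersection.

    For each date the plateau is the maximum observed W and the critical
    point is where the line through the two most-deficient treatments meets
    the plateau; (A1, A2) follow from a log-log regression.  Independent of
    the Bayesian machinery.
    """
    obs = ds.observations(basis)
    pts = []
    for _, sub in obs.groupby("date_index"):
        sub = sub.drop_duplicates(subset="treatment_id").sort_values("N_conc")
        W, N = sub["W"].to_numpy(), sub["N_conc"].to_numpy()
        bmax = W.max()
        below = W < bmax * (1 - 1e-9)
        if below.sum() < 2:
            continue
        (n1, w1), (n2, w2) = (N[below][0], W[below][0]), (N[below][1], W[below][1])
        slope = (w2 - w1) / (n2 - n1)
        pts.append((bmax, n1 + (bmax - w1) / slope))
    pts = np.asarray(pts)
    X = np.column_stack([np.ones(len(pts)), -np.log(pts[:, 0])])
    coef, *_ = np.linalg.lstsq(X, np.log(pts[:, 1]), rcond=None)
    return NcCurve(
        A1=float(np.exp(coef[0])), A2=float(coef[1]), basis=basis, provenance="truth"
    )
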