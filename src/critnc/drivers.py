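"""Per-experiment G x E x M covariates and driver-parameter correlations.

Covariates summarize one trial's genotype, environment and management:
maximum shoot biomass (DMmax, t/ha) and maximum shoot N concentration
(Nmax, % N) over the vegetative period, vegetative period duration
(VPD, days, sowing to flowering), accumulated growing degree days
(AGDD, degC day, base 0 degC), mean daily GDD, total rainfall (mm), and
sowing density (plants/m2).  Fitted curve parameters (posterior medians of
A1 and A2, one value per experiment) are then correlated with these drivers
using Pearson's r with two-sided t-test p-values, flagged at the
0.1 / 0.05 / 0.01 / 0.001 significance tiers.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class CoverageError(ValueError):
    """The weather series does not cover the requested date range."""


def _to_date(value) -> dt.date:
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    return pd.Timestamp(value).date()


@dataclass
class WeatherSeries:
    """Daily weather: date, Tmax (degC), Tmin (degC), rainfall (mm)."""

    df: pd.DataFrame

    def __post_init__(self):
        required = ["date", "tmax_c", "tmin_c", "rain_mm"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"weather table missing column(s): {missing}")
        df = self.df.copy()
        df["date"] = pd.to_datetime(df["date"]).dt.date
        df = df.sort_values("date").reset_index(drop=True)
        if (df["tmax_c"] < df["tmin_c"]).any():
            bad = df.loc[df["tmax_c"] < df["tmin_c"], "date"].tolist()
            raise ValueError(f"Tmax < Tmin on {bad}")
        deltas = pd.to_datetime(df["date"]).diff().dropna().dt.days
        if (deltas != 1).any():
            raise ValueError("weather dates must be contiguous daily records")
        self.df = df

    @classmethod
    def from_csv(cls, path) -> "WeatherSeries":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def compute_agdd(
    weather: WeatherSeries,
    start,
    end,
    tbase: float = 0.0,
    clamp_negative: bool = True,
) -> float:
    """Accumulated growing degree days over [start, end] inclusive.

    Daily GDD is ``(Tmax + Tmin)/2 - Tbase``.  With ``clamp_negative``
    (default, the standard agronomic convention for wheat with Tbase = 0),
    days whose mean temperature falls below Tbase contribute zero rather
    than subtracting thermal time; disable it for the literal unclamped sum.
    """
    start, end = _to_date(start), _to_date(end)
    if start > end:
        raise ValueError("start must be on or before end")
    df = weather.df
    mask = (df["date"] >= start) & (df["date"] <= end)
    sub = df[mask]
    expected = pd.date_range(start, end, freq="D").date
    have = set(sub["date"])
    gaps = [d.isoformat() for d in expected if d not in have]
    if gaps:
        raise CoverageError(f"weather series missing {len(gaps)} day(s): {gaps[:10]}")
    gdd = (sub["tmax_c"].to_numpy() + sub["tmin_c"].to_numpy()) / 2.0 - tbase
    if clamp_negative:
        gdd = np.maximum(gdd, 0.0)
    return float(gdd.sum())


@dataclass(frozen=True)
class CovariateRow:
    """One experiment's drivers feeding the correlation matrix."""

    experiment_id: str
    DMmax: float  # t/ha
    Nmax: float  # % N
    VPD: int  # days
    AGDD: float  # degC day
    GDD_daily: float  # degC day per day
    rainfall_total: float  # mm
    density: float  # plants/m2

    def to_dict(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "DMmax": self.DMmax,
            "Nmax": self.Nmax,
            "VPD": self.VPD,
            "AGDD": self.AGDD,
            "GDD_daily": self.GDD_daily,
            "rainfall_total": self.rainfall_total,
            "density": self.density,
        }


def extract_covariates(ds, weather: WeatherSeries | None = None) -> CovariateRow:
    """Derive one experiment's covariate row from its data and weather.

    The vegetative period is operationalized as sowing to flowering.  DMmax
    and Nmax are taken over shoot observations before flowering.
    """
    weather = weather if weather is not None else ds.weather
    if weather is None:
        raise ValueError(f"{ds.meta.experiment_id}: no weather series available")
    shoot = ds.observations("shoot")
    if shoot.empty:
        raise ValueError(f"{ds.meta.experiment_id}: no shoot observations")
    obs_dates = pd.to_datetime(ds.obs["date"]).dt.date
    before = ds.obs[(ds.obs["organ"] == "shoot") & (obs_dates < ds.meta.flowering_date)]
    if before.empty:
        before = ds.obs[ds.obs["organ"] == "shoot"]
    vpd = (ds.meta.flowering_date - ds.meta.sowing_date).days
    agdd = compute_agdd(weather, ds.meta.sowing_date, ds.meta.flowering_date)
    rain_mask = (weather.df["date"] >= ds.meta.sowing_date) & (
        weather.df["date"] <= ds.meta.flowering_date
    )
    return CovariateRow(
        experiment_id=ds.meta.experiment_id,
        DMmax=float(before["shoot_biomass_t_ha"].max()),
        Nmax=float(before["shoot_n_conc_pct"].max()),
        VPD=int(vpd),
        AGDD=agdd,
        GDD_daily=agdd / vpd,
        rainfall_total=float(weather.df.loc[rain_mask, "rain_mm"].sum()),
        density=float(ds.meta.sowing_density),
    )


def covariate_table(rows: list[CovariateRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows]).set_index("experiment_id")


#: Significance tiers, most stringent first: (p threshold, marker).
SIGNIFICANCE_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "."))


def significance_tier(p: float) -> str:
    """Marker for the most stringent tier the p-value clears ('' if none)."""
    if not np.isfinite(p):
        return "undefined"
    for threshold, marker in SIGNIFICANCE_TIERS:
        if p < threshold:
            return marker
    return ""


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with p-values and significance tiers.

    ``table`` is long format: var1, var2, r, p, n, tier — one row per
    unordered variable pair plus the unit diagonal.
    """

    table: pd.DataFrame

    def r(self, v1: str, v2: str) -> float:
        t = self.table
        row = t[((t.var1 == v1) & (t.var2 == v2)) | ((t.var1 == v2) & (t.var2 == v1))]
        if row.empty:
            raise KeyError(f"no pair ({v1}, {v2})")
        return float(row["r"].iloc[0])

    def pivot(self, value: str = "r") -> pd.DataFrame:
        t = self.table
        sym = pd.concat(
            [t, t.rename(columns={"var1": "var2", "var2": "var1"})], ignore_index=True
        ).drop_duplicates(subset=["var1", "var2"])
        return sym.pivot(index="var1", columns="var2", values=value)


def correlate_drivers(
    params: pd.DataFrame,
    covars: pd.DataFrame,
    method: str = "pearson",
) -> CorrelationMatrix:
    """Correlate fitted curve parameters with G x E x M drivers.

    ``params`` holds one row per experiment (posterior medians of A1/A2,
    possibly per basis); ``covars`` the matching covariate rows.  Both must
    be indexed by experiment_id with at least four matched experiments.
    Pairs involving a constant variable are flagged 'undefined' rather than
    failing the whole matrix.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if not params.index.equals(covars.index):
        if set(params.index) != set(covars.index):
            raise ValueError(
                "params and covars experiment ids do not match: "
                f"{sorted(set(params.index) ^ set(covars.index))}"
            )
        covars = covars.loc[params.index]
    joined = pd.concat([params, covars], axis=1).sort_index()
    if len(joined) < 4:
        raise ValueError("need >= 4 matched experiments for correlation p-values")
    cols = list(joined.columns)
    rows = []
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i, v1 in enumerate(cols):
        for v2 in cols[i:]:
            x = joined[v1].to_numpy(float)
            y = joined[v2].to_numpy(float)
            n = len(x)
            if v1 == v2:
                rows.append((v1, v2, 1.0, 0.0, n, "***"))
                continue
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append((v1, v2, np.nan, np.nan, n, "undefined"))
                continue
            r, p = corr_fn(x, y)
            rows.append((v1, v2, float(r), float(p), n, significance_tier(float(p))))
    table = pd.DataFrame(rows, columns=["var1", "var2", "r", "p", "n", "tier"])
    return CorrelationMatrix(table=table)
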