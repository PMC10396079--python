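"""Field-trial data model, CSV I/O, and observation-selection rules.

A trial ("experiment") is one genotype x environment x management (G x E x M)
condition: a wheat N-fertilizer experiment sampled repeatedly before flowering
under several N application rates.  Observations are stored in a long table
with one row per (sampling date, N treatment, organ, replicate) carrying the
organ biomass (t ha^-1), the organ N concentration (% dry mass), the
plot-level leaf area index, and the shoot totals used for pairing and
filtering.

The dilution-curve bases pair biomass-like quantities with N concentrations:
leaf biomass with leaf N, stem biomass with stem N, shoot biomass with shoot
N, and LAI with shoot N.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Supported dilution-curve bases.
BASES = ("leaf", "stem", "shoot", "lai")

#: Organ labels allowed in the observations table.
ORGANS = ("leaf", "stem", "shoot")

#: Mandatory columns of the observations CSV.
OBS_COLUMNS = [
    "experiment_id",
    "date",
    "treatment_id",
    "organ",
    "biomass_t_ha",
    "lai",
    "n_conc_pct",
    "shoot_biomass_t_ha",
    "shoot_n_conc_pct",
    "replicate",
]

_NUMERIC_COLS = ["biomass_t_ha", "lai", "n_conc_pct", "shoot_biomass_t_ha", "shoot_n_conc_pct"]


class SchemaError(ValueError):
    """The input table does not match the documented column schema."""


class EmptyDatasetError(ValueError):
    """An operation left zero valid observations."""


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    return pd.Timestamp(value).date()


@dataclass(frozen=True)
class ExperimentMeta:
    """Design metadata for one G x E x M trial."""

    experiment_id: str
    site: str
    year: int
    genotype: str
    sowing_density: float  # plants m^-2
    sowing_date: dt.date
    flowering_date: dt.date
    n_rates: tuple[float, ...]  # kg N ha^-1

    def __post_init__(self):
        object.__setattr__(self, "sowing_date", _parse_date(self.sowing_date))
        object.__setattr__(self, "flowering_date", _parse_date(self.flowering_date))
        object.__setattr__(self, "n_rates", tuple(float(r) for r in self.n_rates))
        if self.flowering_date <= self.sowing_date:
            raise ValueError(
                f"{self.experiment_id}: flowering_date must be after sowing_date"
            )
        if not self.n_rates:
            raise ValueError(f"{self.experiment_id}: n_rates must be non-empty")
        if len(set(self.n_rates)) < len(self.n_rates):
            raise ValueError(f"{self.experiment_id}: n_rates must be distinct")
        if any(r < 0 for r in self.n_rates):
            raise ValueError(f"{self.experiment_id}: n_rates must be non-negative")
        if not self.sowing_density > 0:
            raise ValueError(f"{self.experiment_id}: sowing_density must be positive")

    def to_dict(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "site": self.site,
            "year": int(self.year),
            "genotype": self.genotype,
            "density_plants_m2": float(self.sowing_density),
            "sowing_date": self.sowing_date.isoformat(),
            "flowering_date": self.flowering_date.isoformat(),
            "n_rates_kg_ha": ";".join(f"{r:g}" for r in self.n_rates),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentMeta":
        rates = d["n_rates_kg_ha"]
        if isinstance(rates, str):
            rates = [float(x) for x in rates.split(";") if x.strip()]
        return cls(
            experiment_id=str(d["experiment_id"]),
            site=str(d["site"]),
            year=int(d["year"]),
            genotype=str(d["genotype"]),
            sowing_density=float(d["density_plants_m2"]),
            sowing_date=d["sowing_date"],
            flowering_date=d["flowering_date"],
            n_rates=tuple(rates),
        )


@dataclass
class DateGroup:
    """All (W, N%) pairs at one sampling date for one basis.

    This is the unit of the linear-plus-plateau fit: within a date the
    biomass (or LAI) response to N concentration rises linearly to the
    critical point and plateaus at the date's maximal biomass.
    """

    date_index: int
    basis: str
    W: np.ndarray
    N: np.ndarray
    experiment_id: str = ""

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if self.W.shape != self.N.shape:
            raise ValueError("W and N must have equal length")

    @property
    def n(self) -> int:
        return int(self.W.size)


@dataclass
class ExperimentDataset:
    """One validated trial: metadata plus the long observation table.

    ``weather`` optionally references the trial's daily weather series
    (see :mod:`critnc.drivers`).
    """

    meta: ExperimentMeta
    obs: pd.DataFrame
    weather: object | None = None
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        dup = self.obs.duplicated(
            subset=["date_index", "treatment_id", "organ", "replicate"]
        )
        if dup.any():
            raise ValueError(
                f"{self.meta.experiment_id}: duplicate (date, treatment, organ, "
                f"replicate) rows: {self.obs.index[dup].tolist()}"
            )
        pre_flowering = self.obs.loc[
            pd.to_datetime(self.obs["date"]).dt.date < self.meta.flowering_date,
            "date_index",
        ].nunique()
        if pre_flowering < 5:
            warnings.warn(
                f"{self.meta.experiment_id}: only {pre_flowering} sampling dates "
                "before flowering (fewer than the recommended 5)",
                stacklevel=2,
            )

    @property
    def n_observations(self) -> int:
        return len(self.obs)

    def observations(self, basis: str) -> pd.DataFrame:
        """Return the (W, N_conc) observation table for one basis.

        Columns: date_index, treatment_id, replicate, W, N_conc, shoot_W.
        The LAI basis pairs the plot LAI with the shoot N concentration;
        biomass bases pair the organ biomass with the organ N concentration.
        """
        if basis not in BASES:
            raise ValueError(f"unknown basis {basis!r}; expected one of {BASES}")
        if basis == "lai":
            sub = self.obs[self.obs["organ"] == "shoot"]
            sub = sub[np.isfinite(sub["lai"]) & (sub["lai"] > 0)]
            out = pd.DataFrame(
                {
                    "date_index": sub["date_index"].to_numpy(),
                    "treatment_id": sub["treatment_id"].to_numpy(),
                    "replicate": sub["replicate"].to_numpy(),
                    "W": sub["lai"].to_numpy(float),
                    "N_conc": sub["shoot_n_conc_pct"].to_numpy(float),
                    "shoot_W": sub["shoot_biomass_t_ha"].to_numpy(float),
                }
            )
        else:
            sub = self.obs[self.obs["organ"] == basis]
            out = pd.DataFrame(
                {
                    "date_index": sub["date_index"].to_numpy(),
                    "treatment_id": sub["treatment_id"].to_numpy(),
                    "replicate": sub["replicate"].to_numpy(),
                    "W": sub["biomass_t_ha"].to_numpy(float),
                    "N_conc": sub["n_conc_pct"].to_numpy(float),
                    "shoot_W": sub["shoot_biomass_t_ha"].to_numpy(float),
                }
            )
        return out.reset_index(drop=True)


def validate_observations(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate raw observation rows; return (valid, rejected-with-reason)."""
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    df = df.copy()
    df["replicate"] = df["replicate"].fillna(1)
    reasons = pd.Series("", index=df.index)

    for col in _NUMERIC_COLS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if col != "lai":
            bad |= df[col].isna()
        reasons[bad] += f"non-numeric or missing {col}; "
        df[col] = coerced

    bad_organ = ~df["organ"].isin(ORGANS)
    reasons[bad_organ] += "organ not in {leaf, stem, shoot}; "

    ok_num = reasons == ""
    with np.errstate(invalid="ignore"):
        checks = {
            "biomass_t_ha must be > 0": df["biomass_t_ha"] <= 0,
            "n_conc_pct must be in (0, 10)": (df["n_conc_pct"] <= 0)
            | (df["n_conc_pct"] >= 10),
            "shoot_biomass_t_ha must be > 0": df["shoot_biomass_t_ha"] <= 0,
            "shoot_n_conc_pct must be in (0, 10)": (df["shoot_n_conc_pct"] <= 0)
            | (df["shoot_n_conc_pct"] >= 10),
            "lai must be > 0 when present": df["lai"].notna() & (df["lai"] <= 0),
        }
    for msg, bad in checks.items():
        reasons[ok_num & bad.fillna(False)] += msg + "; "

    rejected = df[reasons != ""].copy()
    rejected["reason"] = reasons[reasons != ""].str.rstrip("; ")
    valid = df[reasons == ""].copy()
    if len(rejected):
        logger.warning("rejected %d observation row(s)", len(rejected))
    return valid, rejected


def _assign_date_index(df: pd.DataFrame) -> pd.DataFrame:
    """Assign 1-based date_index by chronological rank of the calendar date."""
    dates = pd.to_datetime(df["date"])
    order = {d: i + 1 for i, d in enumerate(sorted(dates.unique()))}
    df = df.copy()
    df["date"] = dates.dt.date.astype(str)
    df["date_index"] = dates.map(order).astype(int)
    return df


def dataset_from_frame(
    meta: ExperimentMeta, df: pd.DataFrame, weather=None
) -> ExperimentDataset:
    """Build a validated dataset from a raw long-format observation frame."""
    valid, rejected = validate_observations(df)
    if valid.empty:
        raise EmptyDatasetError(
            f"{meta.experiment_id}: zero valid observation rows after validation"
        )
    valid = _assign_date_index(valid)
    return ExperimentDataset(meta=meta, obs=valid.reset_index(drop=True),
                             weather=weather, rejected=rejected)


def load_metadata(path) -> ExperimentMeta:
    """Read experiment metadata from YAML (mapping) or single-row CSV."""
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            d = yaml.safe_load(fh)
    else:
        rows = pd.read_csv(path).to_dict("records")
        if len(rows) != 1:
            raise SchemaError(f"metadata CSV must contain exactly one row, got {len(rows)}")
        d = rows[0]
    return ExperimentMeta.from_dict(d)


def load_experiment(obs_path, meta) -> ExperimentDataset:
    """Load and validate one trial from its observations CSV.

    ``meta`` may be an :class:`ExperimentMeta` or a path to a metadata
    YAML/CSV file.  Rows failing validation are retained in
    ``dataset.rejected`` with a reason string.
    """
    if not isinstance(meta, ExperimentMeta):
        meta = load_metadata(meta)
    df = pd.read_csv(obs_path)
    return dataset_from_frame(meta, df)


def write_experiment(ds: ExperimentDataset, obs_path, meta_path=None) -> None:
    """Write the observation table (CSV) and optionally the metadata (YAML)."""
    cols = OBS_COLUMNS
    ds.obs[cols].to_csv(obs_path, index=False)
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            yaml.safe_dump(ds.meta.to_dict(), fh, sort_keys=False)


def filter_low_biomass(ds: ExperimentDataset, threshold: float = 1.0) -> ExperimentDataset:
    """Drop observations taken while shoot biomass is below ``threshold`` t/ha.

    N concentration barely dilutes while the crop is still establishing, so
    early low-biomass samples are excluded from curve fitting.  The gate is
    the shoot biomass for every basis (one consistent developmental
    criterion), and the boundary value is retained (``shoot_W >= threshold``).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = ds.obs["shoot_biomass_t_ha"] >= threshold
    removed = int((~keep).sum())
    if keep.sum() == 0:
        raise EmptyDatasetError(
            f"{ds.meta.experiment_id}: low-biomass filter at {threshold} t/ha removed "
            "every observation; review the threshold"
        )
    if removed:
        logger.info(
            "%s: low-biomass filter removed %d of %d rows",
            ds.meta.experiment_id, removed, len(ds.obs),
        )
    return ExperimentDataset(
        meta=ds.meta,
        obs=ds.obs[keep].reset_index(drop=True),
        weather=ds.weather,
        rejected=ds.rejected,
    )


def make_date_groups(
    ds: ExperimentDataset, basis: str, min_pairs: int = 3
) -> list[DateGroup]:
    """Partition one basis' observations into per-date (W, N%) groups.

    Groups with fewer than ``min_pairs`` pairs cannot identify a slope plus
    a plateau plus their intersection and are dropped with a warning.
    """
    obs = ds.observations(basis)
    groups: list[DateGroup] = []
    for di, sub in obs.groupby("date_index", sort=True):
        if len(sub) < min_pairs:
            warnings.warn(
                f"{ds.meta.experiment_id}/{basis}: date {di} has only {len(sub)} "
                f"pair(s) (<{min_pairs}); group dropped",
                stacklevel=2,
            )
            continue
        groups.append(
            DateGroup(
                date_index=int(di),
                basis=basis,
                W=sub["W"].to_numpy(),
                N=sub["N_conc"].to_numpy(),
                experiment_id=ds.meta.experiment_id,
            )
        )
    if not groups:
        raise EmptyDatasetError(
            f"{ds.meta.experiment_id}: no date group for basis {basis!r} has "
            f">= {min_pairs} observation pairs"
        )
    return groups
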