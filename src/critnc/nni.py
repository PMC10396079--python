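"""Nitrogen nutrition index (NNI) diagnostics and agreement statistics.

NNI = Nt / Nc, the ratio of the measured N concentration to the critical
concentration at the observation's biomass (or LAI): below 1 the crop is N
deficient, near 1 optimal, above 1 in luxury uptake.  NNI is computed per
observation (never averaged per treatment first).  Agreement between two
NNI series (e.g. hybrid-curve vs condition-specific, or organ vs shoot) is
quantified with RMSE and n-RMSE = RMSE / mean(reference) x 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import NcCurve, nc_value
from .io import ExperimentDataset


def compute_nni(Nt: float, Nc: float) -> float:
    """Nitrogen nutrition index: measured over critical N concentration."""
    if Nc <= 0:
        raise ValueError("critical N concentration must be positive")
    if Nt <= 0:
        raise ValueError("measured N concentration must be positive")
    return Nt / Nc


def nni_series(ds: ExperimentDataset, curve: NcCurve, basis: str) -> pd.DataFrame:
    """Per-observation NNI records for one basis under one curve.

    Columns: experiment_id, date_index, treatment_id, replicate, basis, W,
    Nt, Nc, NNI.  The curve's basis must match the requested basis.
    """
    if curve.basis != basis:
        raise ValueError(
            f"curve basis {curve.basis!r} does not match requested basis {basis!r}"
        )
    obs = ds.observations(basis)
    if obs.empty:
        raise ValueError(f"{ds.meta.experiment_id}: no observations for basis {basis!r}")
    nc = nc_value(curve, obs["W"].to_numpy())
    return pd.DataFrame(
        {
            "experiment_id": ds.meta.experiment_id,
            "date_index": obs["date_index"],
            "treatment_id": obs["treatment_id"],
            "replicate": obs["replicate"],
            "basis": basis,
            "W": obs["W"],
            "Nt": obs["N_conc"],
            "Nc": nc,
            "NNI": obs["N_conc"].to_numpy() / nc,
        }
    )


def weighted_mean_nni(nni_leaf, nni_stem, W_leaf, W_stem):
    """Biomass-weighted mean of leaf and stem NNI.  Vectorized."""
    nni_leaf, nni_stem, W_leaf, W_stem = np.broadcast_arrays(
        np.asarray(nni_leaf, float), np.asarray(nni_stem, float),
        np.asarray(W_leaf, float), np.asarray(W_stem, float),
    )
    if np.any(W_leaf < 0) or np.any(W_stem < 0):
        raise ValueError("weights must be non-negative")
    total = W_leaf + W_stem
    if np.any(total <= 0):
        raise ValueError("at least one weight must be positive")
    out = (nni_leaf * W_leaf + nni_stem * W_stem) / total
    return out if out.shape else float(out)


@dataclass(frozen=True)
class AgreementStats:
    """RMSE and normalized RMSE between a reference and a comparison series."""

    rmse: float
    nrmse_pct: float
    n: int


def agreement(reference, comparison) -> AgreementStats:
    """RMSE and n-RMSE of ``comparison`` against ``reference``.

    RMSE = sqrt(mean((P - O)^2)); n-RMSE = RMSE / mean(O) x 100%, normalized
    by the mean of the *reference* series O, so the statistic is not
    symmetric in its arguments (RMSE is).
    """
    O = np.asarray(reference, float)
    P = np.asarray(comparison, float)
    if O.shape != P.shape:
        raise ValueError(f"length mismatch: {O.shape} vs {P.shape}")
    if O.size < 2:
        raise ValueError("agreement requires at least 2 paired values")
    rmse = float(np.sqrt(np.mean((P - O) ** 2)))
    mean_ref = O.mean()
    if mean_ref == 0:
        raise ValueError("reference mean is zero; n-RMSE undefined")
    return AgreementStats(rmse=rmse, nrmse_pct=rmse / mean_ref * 100.0, n=int(O.size))


_KEY = ["experiment_id", "date_index", "treatment_id", "replicate"]


def basis_crosswalk(
    datasets: ExperimentDataset | list[ExperimentDataset],
    curves: dict[str, NcCurve],
) -> tuple[pd.DataFrame, dict[str, AgreementStats]]:
    """Pair organ-based NNI against shoot-based NNI across observations.

    ``curves`` maps each basis to its dilution curve (must include 'shoot'
    plus the organ bases of interest).  Observations are matched exactly on
    (experiment, date, treatment, replicate); unmatched rows are excluded
    with a warning.  Returns the paired table and agreement statistics for
    leaf-vs-shoot, stem-vs-shoot, lai-vs-shoot and weighted-mean-vs-shoot
    (shoot NNI as the n-RMSE reference).
    """
    if isinstance(datasets, ExperimentDataset):
        datasets = [datasets]
    if "shoot" not in curves:
        raise ValueError("crosswalk requires a shoot curve as the reference")

    per_basis = {}
    for basis, curve in curves.items():
        frames = [nni_series(ds, curve, basis) for ds in datasets]
        tab = pd.concat(frames, ignore_index=True)
        per_basis[basis] = tab.set_index(_KEY)

    shoot = per_basis["shoot"]
    paired = shoot[["W", "NNI"]].rename(columns={"W": "W_shoot", "NNI": "NNI_shoot"})
    for basis in curves:
        if basis == "shoot":
            continue
        other = per_basis[basis][["W", "NNI"]].rename(
            columns={"W": f"W_{basis}", "NNI": f"NNI_{basis}"}
        )
        unmatched = len(shoot.index.symmetric_difference(other.index))
        if unmatched:
            warnings.warn(
                f"crosswalk {basis} vs shoot: {unmatched} unmatched observation(s) excluded",
                stacklevel=2,
            )
        paired = paired.join(other, how="inner")

    stats: dict[str, AgreementStats] = {}
    for basis in curves:
        if basis == "shoot":
            continue
        stats[f"{basis}_vs_shoot"] = agreement(
            paired["NNI_shoot"], paired[f"NNI_{basis}"]
        )
    if {"NNI_leaf", "NNI_stem", "W_leaf", "W_stem"} <= set(paired.columns):
        paired["NNI_weighted"] = weighted_mean_nni(
            paired["NNI_leaf"], paired["NNI_stem"],
            paired["W_leaf"], paired["W_stem"],
        )
        stats["weighted_vs_shoot"] = agreement(
            paired["NNI_shoot"], paired["NNI_weighted"]
        )
    return paired.reset_index(), stats
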