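"""Dilution-curve evaluation, uncertainty bands, hybrid fits, comparisons.

A critical-N dilution curve Nc = A1 * W^-A2 gives the minimum N
concentration (% dry mass) needed for maximal growth at biomass (or LAI) W.
This module evaluates curves, propagates posterior uncertainty along W
(credible-band width profiles), pools data from several experiments into a
hybrid ("universal") curve, and compares fitted parameters across G x E x M
conditions with a posterior-difference rule plus compact letter display.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .bayes import CurveFit, coefficient_of_variation, fit_curve
from .io import ExperimentDataset, filter_low_biomass, make_date_groups


@dataclass(frozen=True)
class NcCurve:
    """One dilution curve: Nc(W) = A1 * W^-A2."""

    A1: float
    A2: float
    basis: str = "shoot"
    provenance: str = "posterior-median"

    def __post_init__(self):
        if self.A1 <= 0:
            raise ValueError("A1 must be positive")
        if self.A2 < 0:
            raise ValueError("A2 must be non-negative")

    def __call__(self, W):
        return nc_value(self, W)


def nc_value(curve: NcCurve, W):
    """Critical N concentration at biomass/LAI ``W`` (> 0). Vectorized."""
    W = np.asarray(W, float)
    if np.any(W <= 0):
        raise ValueError("W must be positive")
    out = curve.A1 * np.power(W, -curve.A2)
    return out if out.shape else float(out)


def curve_from_fit(fit: CurveFit) -> NcCurve:
    """Posterior-median curve of a converged fit."""
    return NcCurve(
        A1=fit.a1_median, A2=fit.a2_median, basis=fit.basis,
        provenance="posterior-median",
    )


@dataclass
class WidthProfile:
    """Pointwise credible band of Nc along a W grid."""

    W: np.ndarray
    lower: np.ndarray
    median: np.ndarray
    upper: np.ndarray

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "W": self.W,
                "nc_lower": self.lower,
                "nc_median": self.median,
                "nc_upper": self.upper,
                "width": self.width,
            }
        )


def credible_band(fit: CurveFit, w_grid) -> WidthProfile:
    """95% credible band of the dilution curve along ``w_grid``.

    At each W the curve is evaluated per posterior draw of (A1, A2) and the
    (2.5%, 50%, 97.5%) quantiles taken.  At W = 1 the band reduces to the
    posterior interval of A1.  Refuses non-converged fits.
    """
    if not fit.converged:
        raise ValueError(
            f"{fit.experiment_id}/{fit.basis}: fit did not converge; "
            "credible band refused"
        )
    w = np.asarray(w_grid, float)
    if np.any(w <= 0) or np.any(np.diff(w) <= 0):
        raise ValueError("w_grid must be positive and strictly ascending")
    a1 = fit.draws.flat("A1")[:, None]
    a2 = fit.draws.flat("A2")[:, None]
    nc = a1 * np.power(w[None, :], -a2)  # (draws, W)
    lo, med, hi = np.quantile(nc, [0.025, 0.5, 0.975], axis=0)
    return WidthProfile(W=w, lower=lo, median=med, upper=hi)


def fit_hybrid(
    datasets: list[ExperimentDataset],
    basis: str,
    filter_threshold: float = 1.0,
    **mcmc_kwargs,
) -> CurveFit:
    """Fit one pooled ("hybrid") curve across several experiments.

    Every experiment-date keeps its own (Bmax, beta) nuisances; only
    (A1, A2) are shared across the pooled groups, so the hybrid curve is the
    single dilution law most consistent with all conditions at once.
    """
    if not datasets:
        raise ValueError("fit_hybrid requires at least one dataset")
    groups = []
    for ds in datasets:
        filtered = filter_low_biomass(ds, threshold=filter_threshold)
        groups.extend(make_date_groups(filtered, basis))
    exp_id = "hybrid"
    return fit_curve(groups, experiment_id=exp_id, basis=basis, **mcmc_kwargs)


@dataclass
class ParameterComparison:
    """Cross-condition comparison of fitted parameters.

    ``table`` has one row per (fit, parameter) with the posterior summary
    and compact letters; fits sharing a letter are pairwise not different at
    the stated level.  ``cv_pct`` is the coefficient of variation of the
    posterior medians across fits, per parameter.
    """

    table: pd.DataFrame
    differences: pd.DataFrame  # fit_a, fit_b, parameter, lo, hi, different
    cv_pct: dict
    alpha: float

    def letters(self, parameter: str) -> dict:
        sub = self.table[self.table["parameter"] == parameter]
        return dict(zip(sub["experiment_id"], sub["letters"]))


def _difference_interval(
    a: np.ndarray, b: np.ndarray, alpha: float, seed: int = 0
) -> tuple[float, float]:
    """Central (1-alpha) interval of the difference of two posteriors.

    Draws are independently permuted and paired, a Monte Carlo approximation
    of the distribution of (theta_a - theta_b) under posterior independence.
    Deterministic: the permutation seed is fixed.
    """
    m = min(a.size, b.size)
    rng = np.random.default_rng(seed)
    d = rng.permutation(a)[:m] - rng.permutation(b)[:m]
    lo, hi = np.quantile(d, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def compare_parameters(
    fits: list[CurveFit],
    alpha: float = 0.05,
    parameters: tuple[str, ...] = ("A1", "A2"),
) -> ParameterComparison:
    """Compare (A1, A2) across converged fits at level ``alpha``.

    Two fits differ on a parameter when the central (1-alpha) interval of
    the between-fit posterior difference excludes zero.  Compact letters are
    assigned from the maximal cliques of the non-difference graph, with
    deterministic ordering by experiment id.  Also reports the CV of
    posterior medians across fits.
    """
    fits = sorted((f for f in fits if f.converged), key=lambda f: f.experiment_id)
    if len(fits) < 2:
        raise ValueError("compare_parameters requires >= 2 converged fits")
    ids = [f.experiment_id for f in fits]
    if len(set(ids)) != len(ids):
        raise ValueError("fits must have distinct experiment ids")

    diff_rows = []
    table_rows = []
    cv = {}
    for param in parameters:
        graph = nx.Graph()
        graph.add_nodes_from(ids)
        for fa, fb in itertools.combinations(fits, 2):
            lo, hi = _difference_interval(
                fa.draws.flat(param), fb.draws.flat(param), alpha
            )
            different = lo > 0 or hi < 0
            diff_rows.append(
                {
                    "fit_a": fa.experiment_id,
                    "fit_b": fb.experiment_id,
                    "parameter": param,
                    "diff_lo": lo,
                    "diff_hi": hi,
                    "different": different,
                }
            )
            if not different:
                graph.add_edge(fa.experiment_id, fb.experiment_id)
        cliques = sorted(sorted(c) for c in nx.find_cliques(graph))
        alphabet = "abcdefghijklmnopqrstuvwxyz"
        letter_of = {fid: "" for fid in ids}
        for k, clique in enumerate(cliques):
            letter = alphabet[k % len(alphabet)] * (k // len(alphabet) + 1)
            for fid in clique:
                letter_of[fid] += letter
        medians = [float(f.summary.loc[param, "median"]) for f in fits]
        cv[param] = coefficient_of_variation(medians)
        for f, med in zip(fits, medians):
            table_rows.append(
                {
                    "experiment_id": f.experiment_id,
                    "parameter": param,
                    "median": med,
                    "q025": float(f.summary.loc[param, "q025"]),
                    "q975": float(f.summary.loc[param, "q975"]),
                    "letters": letter_of[f.experiment_id],
                }
            )
    return ParameterComparison(
        table=pd.DataFrame(table_rows),
        differences=pd.DataFrame(diff_rows),
        cv_pct=cv,
        alpha=alpha,
    )


def load_published_curves() -> list[NcCurve]:
    """Published wheat dilution-curve constants shipped with the package."""
    text = resources.files("critnc").joinpath("published_curves.yaml").read_text()
    entries = yaml.safe_load(text)
    return [
        NcCurve(A1=e["A1"], A2=e["A2"], basis=e["basis"],
                provenance=f"published-constant: {e['source']}")
        for e in entries
    ]
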