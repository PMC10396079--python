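"""End-to-end pipeline: simulate/load -> filter -> fit -> NNI -> drivers -> report.

Stages run in flowchart order and every artifact is a CSV or JSON file in
the output directory, plus a run manifest recording the configuration,
per-stage row and fit counts, and the convergence tally.  The whole run is
deterministic under a fixed seed: each (experiment, basis) fit draws its own
sub-seed from a stable hash so adding an experiment never perturbs others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import CurveFit, fit_curve
from .curves import compare_parameters, credible_band, curve_from_fit, fit_hybrid
from .drivers import correlate_drivers, covariate_table, extract_covariates
from .io import (
    ExperimentDataset,
    filter_low_biomass,
    load_experiment,
    make_date_groups,
    write_experiment,
)
from .nni import agreement, basis_crosswalk, nni_series
from .simulate import default_gem_suite, simulate_gem_suite, subseed

logger = logging.getLogger(__name__)

STAGES = (
    "data",
    "filter",
    "fit",
    "hybrid",
    "compare",
    "nni",
    "drivers",
    "report",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int
    out_dir: str
    bases: tuple[str, ...] = ("leaf", "stem", "shoot", "lai")
    n_experiments: int = 3
    input_experiments: tuple[tuple[str, str], ...] = ()  # (obs_csv, meta_yaml) pairs
    filter_threshold: float = 1.0
    n_chains: int = 4
    n_burn: int = 5000
    n_keep: int = 3000
    w_grid: tuple[float, float, int] = (0.5, 12.0, 24)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.bases:
            raise ValueError("at least one basis must be selected")
        for b in self.bases:
            if b not in ("leaf", "stem", "shoot", "lai"):
                raise ValueError(f"unknown basis {b!r}")
        for obs, meta in self.input_experiments:
            for p in (obs, meta):
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "bases" in d:
            d["bases"] = tuple(d["bases"])
        if "input_experiments" in d:
            d["input_experiments"] = tuple(tuple(x) for x in d["input_experiments"])
        if "w_grid" in d:
            d["w_grid"] = tuple(d["w_grid"])
        return cls(**d)

    def mcmc_kwargs(self) -> dict:
        return {"n_chains": self.n_chains, "n_burn": self.n_burn, "n_keep": self.n_keep}


def _fit_summary_row(fit: CurveFit) -> dict:
    return {
        "experiment_id": fit.experiment_id,
        "basis": fit.basis,
        "A1_median": fit.a1_median,
        "A1_q025": float(fit.summary.loc["A1", "q025"]),
        "A1_q975": float(fit.summary.loc["A1", "q975"]),
        "A2_median": fit.a2_median,
        "A2_q025": float(fit.summary.loc["A2", "q025"]),
        "A2_q975": float(fit.summary.loc["A2", "q975"]),
        "rhat_A1": fit.diagnostics.rhat["A1"],
        "rhat_A2": fit.diagnostics.rhat["A2"],
        "ess_A1": fit.diagnostics.ess["A1"],
        "ess_A2": fit.diagnostics.ess["A2"],
        "converged": fit.converged,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {
            **{k: v for k, v in asdict(cfg).items()},
        },
        "stages": {},
        "completed": [],
    }

    def _checkpoint():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    _checkpoint()

    # --- data -----------------------------------------------------------
    truths = {}
    if cfg.input_experiments:
        datasets = [load_experiment(obs, meta) for obs, meta in cfg.input_experiments]
    else:
        t, c = default_gem_suite(n_experiments=cfg.n_experiments, master_seed=cfg.seed)
        pairs = simulate_gem_suite(t, c, master_seed=cfg.seed)
        datasets = [ds for ds, _ in pairs]
        truths = {ds.meta.experiment_id: tr.to_dict() for ds, tr in pairs}
        for ds in datasets:
            write_experiment(
                ds,
                out / f"obs_{ds.meta.experiment_id}.csv",
                out / f"meta_{ds.meta.experiment_id}.yaml",
            )
            if ds.weather is not None:
                ds.weather.to_csv(out / f"weather_{ds.meta.experiment_id}.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump(truths, fh, indent=2)
    manifest["stages"]["data"] = {
        "n_experiments": len(datasets),
        "rows": {ds.meta.experiment_id: len(ds.obs) for ds in datasets},
    }
    manifest["completed"].append("data")
    _checkpoint()

    # --- filter ----------------------------------------------------------
    filtered = [filter_low_biomass(ds, cfg.filter_threshold) for ds in datasets]
    manifest["stages"]["filter"] = {
        "threshold_t_ha": cfg.filter_threshold,
        "rows_removed": {
            ds.meta.experiment_id: len(ds.obs) - len(f.obs)
            for ds, f in zip(datasets, filtered)
        },
    }
    manifest["completed"].append("filter")
    _checkpoint()

    # --- fit per experiment x basis --------------------------------------
    fits: dict[str, dict[str, CurveFit]] = {b: {} for b in cfg.bases}
    fit_rows = []
    for ds in filtered:
        for basis in cfg.bases:
            groups = make_date_groups(ds, basis)
            fit = fit_curve(
                groups,
                experiment_id=ds.meta.experiment_id,
                basis=basis,
                seed=subseed(cfg.seed, "fit", ds.meta.experiment_id, basis),
                **cfg.mcmc_kwargs(),
            )
            fits[basis][ds.meta.experiment_id] = fit
            fit_rows.append(_fit_summary_row(fit))
            logger.info(
                "fit %s/%s: A1=%.3f A2=%.3f converged=%s",
                ds.meta.experiment_id, basis, fit.a1_median, fit.a2_median,
                fit.converged,
            )
    fits_df = pd.DataFrame(fit_rows)
    fits_df.to_csv(out / "fits.csv", index=False)
    n_conv = int(fits_df["converged"].sum())
    manifest["stages"]["fit"] = {
        "n_fits": len(fits_df),
        "n_converged": n_conv,
        "mcmc": cfg.mcmc_kwargs(),
    }
    manifest["completed"].append("fit")
    _checkpoint()

    # --- hybrid fit per basis --------------------------------------------
    hybrid: dict[str, CurveFit] = {}
    hybrid_rows = []
    band_frames = []
    for basis in cfg.bases:
        hfit = fit_hybrid(
            datasets, basis,
            filter_threshold=cfg.filter_threshold,
            seed=subseed(cfg.seed, "hybrid", basis),
            **cfg.mcmc_kwargs(),
        )
        hybrid[basis] = hfit
        hybrid_rows.append(_fit_summary_row(hfit))
        if hfit.converged:
            lo, hi, num = cfg.w_grid
            band = credible_band(hfit, np.linspace(lo, hi, int(num))).to_frame()
            band.insert(0, "basis", basis)
            band_frames.append(band)
    pd.DataFrame(hybrid_rows).to_csv(out / "hybrid_fits.csv", index=False)
    if band_frames:
        pd.concat(band_frames, ignore_index=True).to_csv(
            out / "hybrid_bands.csv", index=False
        )
    manifest["stages"]["hybrid"] = {
        "n_converged": sum(f.converged for f in hybrid.values())
    }
    manifest["completed"].append("hybrid")
    _checkpoint()

    # --- parameter comparison across conditions ---------------------------
    compare_frames = []
    cv_rows = []
    for basis in cfg.bases:
        conv = [f for f in fits[basis].values() if f.converged]
        if len(conv) < 2:
            logger.warning("compare %s: fewer than 2 converged fits; skipped", basis)
            continue
        comp = compare_parameters(conv)
        tab = comp.table.copy()
        tab.insert(0, "basis", basis)
        compare_frames.append(tab)
        for param, cv in comp.cv_pct.items():
            cv_rows.append({"basis": basis, "parameter": param, "cv_pct": cv})
    if compare_frames:
        pd.concat(compare_frames, ignore_index=True).to_csv(
            out / "letters.csv", index=False
        )
        pd.DataFrame(cv_rows).to_csv(out / "parameter_cv.csv", index=False)
    manifest["stages"]["compare"] = {"n_bases_compared": len(compare_frames)}
    manifest["completed"].append("compare")
    _checkpoint()

    # --- NNI: specific vs hybrid, and organ-vs-shoot crosswalk ------------
    nni_frames = []
    agree_rows = []
    for basis in cfg.bases:
        if not hybrid[basis].converged:
            continue
        hyb_curve = curve_from_fit(hybrid[basis])
        for ds in filtered:
            fit = fits[basis][ds.meta.experiment_id]
            if not fit.converged:
                continue
            spec_tab = nni_series(ds, curve_from_fit(fit), basis)
            hyb_tab = nni_series(ds, hyb_curve, basis)
            spec_tab["curve"] = "specific"
            hyb_tab["curve"] = "hybrid"
            nni_frames += [spec_tab, hyb_tab]
            st = agreement(hyb_tab["NNI"], spec_tab["NNI"])
            agree_rows.append(
                {
                    "experiment_id": ds.meta.experiment_id,
                    "basis": basis,
                    "rmse": st.rmse,
                    "nrmse_pct": st.nrmse_pct,
                    "n": st.n,
                }
            )
    if nni_frames:
        pd.concat(nni_frames, ignore_index=True).to_csv(out / "nni.csv", index=False)
        pd.DataFrame(agree_rows).to_csv(out / "hybrid_agreement.csv", index=False)

    crosswalk_rows = []
    conv_bases = [b for b in cfg.bases if hybrid[b].converged]
    if "shoot" in conv_bases and len(conv_bases) > 1:
        curves = {b: curve_from_fit(hybrid[b]) for b in conv_bases}
        _, xstats = basis_crosswalk(filtered, curves)
        for pair, st in xstats.items():
            crosswalk_rows.append(
                {"pair": pair, "rmse": st.rmse, "nrmse_pct": st.nrmse_pct, "n": st.n}
            )
        pd.DataFrame(crosswalk_rows).to_csv(out / "crosswalk.csv", index=False)
    manifest["stages"]["nni"] = {
        "n_agreement_rows": len(agree_rows),
        "n_crosswalk_pairs": len(crosswalk_rows),
    }
    manifest["completed"].append("nni")
    _checkpoint()

    # --- drivers ----------------------------------------------------------
    corr_done = False
    cov_tab = None
    if all(ds.weather is not None for ds in datasets):
        cov_tab = covariate_table([extract_covariates(ds) for ds in datasets])
        cov_tab.to_csv(out / "covariates.csv")
        if len(datasets) >= 4:
            param_rows = {}
            for basis in cfg.bases:
                for eid, fit in fits[basis].items():
                    if fit.converged:
                        param_rows.setdefault(eid, {})[f"A1_{basis}"] = fit.a1_median
                        param_rows.setdefault(eid, {})[f"A2_{basis}"] = fit.a2_median
            params_df = pd.DataFrame.from_dict(param_rows, orient="index").sort_index()
            params_df = params_df.dropna()
            if len(params_df) >= 4:
                corr = correlate_drivers(params_df, cov_tab.loc[params_df.index])
                corr.table.to_csv(out / "correlation.csv", index=False)
                corr_done = True
    manifest["stages"]["drivers"] = {
        "covariates": cov_tab is not None,
        "correlation": corr_done,
    }
    manifest["completed"].append("drivers")
    _checkpoint()

    # --- report -----------------------------------------------------------
    manifest["completed"].append("report")  # before rendering, so a re-render
    # from the saved manifest reproduces the report verbatim
    report = render_report(manifest, out)
    (out / "report.txt").write_text(report)
    manifest["stages"]["report"] = {"chars": len(report)}
    _checkpoint()
    return manifest


def render_report(manifest: dict, artifact_dir) -> str:
    """Human-readable summary assembled from the saved artifacts.

    Missing artifacts are listed as absent; the report still renders.
    """
    art = Path(artifact_dir)
    lines = [
        "critical-N dilution curve analysis report",
        "=" * 42,
        f"package version: {manifest.get('version', '?')}",
        f"seed: {manifest.get('config', {}).get('seed', '?')}",
        f"completed stages: {', '.join(manifest.get('completed', []))}",
        "",
    ]

    def _section(title: str, filename: str, formatter=None):
        lines.append(title)
        lines.append("-" * len(title))
        path = art / filename
        if not path.exists():
            lines.append(f"[absent: {filename}]")
        else:
            df = pd.read_csv(path)
            lines.append(df.to_string(index=False) if formatter is None else formatter(df))
        lines.append("")

    fit_stage = manifest.get("stages", {}).get("fit", {})
    lines.append(
        f"fits: {fit_stage.get('n_fits', 0)} total, "
        f"{fit_stage.get('n_converged', 0)} converged "
        "(non-converged fits are excluded from every downstream table)"
    )
    lines.append("")
    _section("per-condition parameter estimates (median, 95% CrI)", "fits.csv")
    _section("hybrid (pooled) curves", "hybrid_fits.csv")
    _section("parameter CV across conditions (%)", "parameter_cv.csv")
    _section("significance letters (shared letter = not different)", "letters.csv")
    _section("hybrid-vs-specific NNI agreement", "hybrid_agreement.csv")
    _section("organ-vs-shoot NNI crosswalk", "crosswalk.csv")
    _section("per-experiment covariates", "covariates.csv")

    path = art / "correlation.csv"
    lines.append("driver correlations (significance tiers)")
    lines.append("-" * 40)
    if path.exists():
        corr = pd.read_csv(path)
        flagged = corr[(corr["tier"].notna()) & (corr["tier"] != "") & (corr["var1"] != corr["var2"])]
        lines.append(flagged.to_string(index=False) if len(flagged) else "(no flagged pairs)")
    else:
        lines.append("[absent: correlation.csv]")
    lines.append("")
    return "\n".join(lines)
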