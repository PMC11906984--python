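"""End-to-end pipeline: simulate/ingest -> preprocess -> fit candidate
models -> diagnostics -> comparison -> centile tables.

Driven by a YAML/JSON config; every artefact lands in one output
directory and a structured run report records seeds, exclusion counts
and convergence events. Output content is deterministic for a fixed
config; the wall-clock timestamp appears only in the report metadata.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import centiles as ct
from . import diagnostics as dg
from . import engine as eng
from . import preprocess as pp
from . import synthetic as syn

__all__ = ["load_config", "run_pipeline", "PipelineError", "DEMO_CONFIG"]

DEMO_CONFIG: dict = {
    "simulate": {"n_women": 2000, "seed": 7},
    "shift_delta": 30.0,
    "preprocess": {"week0_error_sd": 0.70, "exclude_4sd": True},
    "models": [
        {"label": "linear", "kind": "baseline", "which": "linear"},
        {
            "label": "cubic_polynomial",
            "kind": "baseline",
            "which": "cubic_polynomial",
        },
        {
            "label": "BCT-cubic-spline",
            "kind": "gamlss",
            "smoother": "cubic_spline",
            "mu_df": 8,
            "sigma_df": 4,
        },
        {
            "label": "BCT-pspline",
            "kind": "gamlss",
            "smoother": "pspline",
            "mu_df": 8,
            "sigma_df": 4,
        },
    ],
    "centile_profiles": [
        {
            "age_years": 28.4,
            "bmi": 24.0,
            "ethnicity_region": "Australian/European",
            "parity_class": "0",
        }
    ],
    "batch_bmi_charts": {"ethnicities": ["Australian/European"]},
}


class PipelineError(RuntimeError):
    """Stage-labelled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config", f"config {path} is not a mapping")
    return cfg


def _spec_from_model_cfg(mcfg: Mapping, shift_delta: float):
    kind = mcfg.get("kind", "gamlss")
    label = mcfg.get("label", "")
    if kind == "baseline":
        return ("baseline", mcfg.get("which", "linear"), label)
    if kind == "gamlss":
        if "family" in mcfg and mcfg["family"] != "BCT":
            # GAM/GLM-style engine configurations: normal family with or
            # without a smooth location term
            fam = mcfg["family"]
            terms = [
                eng.Linear("age_years"),
                eng.Linear("bmi"),
                eng.Categorical("ethnicity_region"),
                eng.Categorical("parity_class"),
            ]
            if mcfg.get("smoother"):
                terms.insert(
                    0,
                    eng.Smooth(
                        "gest_age_weeks",
                        eng.SmootherSpec(
                            kind=mcfg["smoother"],
                            df_target=mcfg.get("mu_df", 8),
                        ),
                    ),
                )
            else:
                terms.insert(0, eng.Linear("gest_age_weeks"))
            spec = eng.ModelSpec(
                family=fam, mu=terms, shift_delta=shift_delta, label=label
            )
            return ("gamlss", spec, label)
        spec = eng.default_bct_spec(
            smoother=mcfg.get("smoother", "pspline"),
            mu_df=float(mcfg.get("mu_df", 8)),
            sigma_df=float(mcfg.get("sigma_df", 4)),
            covariates=bool(mcfg.get("covariates", True)),
            shift_delta=shift_delta,
            label=label,
        )
        return ("gamlss", spec, label)
    raise PipelineError("config", f"unknown model kind {kind!r}")


def run_pipeline(
    config: Mapping | str | Path,
    out_dir,
    seed: Optional[int] = None,
    verbose: bool = False,
) -> dict:
    """Execute the full workflow described by ``config``.

    Returns the run report (also written to ``report.json``); any stage
    failure raises :class:`PipelineError` with a stage label.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def log(msg):
        if verbose:
            print(msg)

    # -- stage 1: simulate or ingest ---------------------------------------
    try:
        if "simulate" in config:
            sim = dict(config["simulate"])
            if seed is not None:
                sim["seed"] = seed
            cc = syn.CohortConfig(**sim)
            truth_cfg = dict(config.get("truth", {}))
            truth = syn.TruthModel(**truth_cfg) if truth_cfg else syn.TruthModel(
                shift_delta=float(config.get("shift_delta", 30.0))
            )
            cohort, visits = syn.simulate_dataset(cc, truth)
            report["stages"]["simulate"] = {
                "seed": cc.seed,
                "n_women": len(cohort),
                "n_visits": len(visits),
            }
        elif "input" in config:
            cohort = pd.read_csv(config["input"]["cohort_csv"])
            visits = pd.read_csv(config["input"]["visits_csv"])
            report["stages"]["ingest"] = {
                "n_women": len(cohort),
                "n_visits": len(visits),
            }
        else:
            raise KeyError("config needs a 'simulate' or 'input' section")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage labelling
        raise PipelineError("simulate", str(exc)) from exc
    cohort.to_csv(out / "cohort.csv", index=False)
    visits.to_csv(out / "visits.csv", index=False)
    log(f"simulate: {len(cohort)} women, {len(visits)} visits")

    # -- stage 2: preprocess ------------------------------------------------
    try:
        pcfg = dict(config.get("preprocess", {}))
        prep = pp.PreprocessReport()
        obs = pp.compute_gwg(visits, cohort, prep)
        w0_seed = seed if seed is not None else int(
            config.get("simulate", {}).get("seed", 0)
        )
        w0 = pp.draw_week0(
            cohort,
            error_sd=float(pcfg.get("week0_error_sd", pp.WEEK0_ERROR_SD)),
            seed=w0_seed,
            report=prep,
        )
        obs = pd.concat([obs, w0], ignore_index=True)
        if pcfg.get("exclude_4sd", True):
            obs, n_excl, _ = pp.exclude_4sd(obs, report=prep)
        report["stages"]["preprocess"] = prep.to_dict()
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("preprocess", str(exc)) from exc
    obs.to_csv(out / "observations.csv", index=False)
    log(f"preprocess: {len(obs)} observations")

    # -- stage 3: fit candidate models --------------------------------------
    shift_delta = float(config.get("shift_delta", 30.0))
    fits = []
    fit_meta = {}
    for mcfg in config.get("models", []):
        kind, payload, label = _spec_from_model_cfg(mcfg, shift_delta)
        try:
            if kind == "baseline":
                fit = eng.fit_baseline(obs, which=payload)
                fit.label = label or payload
            else:
                fit = eng.fit_gamlss(obs, payload)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"fit:{label}", str(exc)) from exc
        fits.append(fit)
        fit_meta[fit.label] = {
            "converged": fit.converged,
            "iterations": fit.iterations,
            "deviance": fit.deviance,
            "edf": fit.edf,
        }
        with open(out / f"model_{fit.label}.json", "w") as fh:
            json.dump(fit.to_dict(), fh)
        log(f"fit {fit.label}: deviance {fit.deviance:.1f}")
    report["stages"]["fit"] = fit_meta
    if not fits:
        raise PipelineError("fit", "no models configured")

    # -- stage 4: diagnostics ------------------------------------------------
    try:
        diag = {}
        for fit in fits:
            r = dg.quantile_residuals(fit)
            diag[fit.label] = dg.residual_summary(r).to_dict()
            dg.worm_plot_data(r).to_csv(
                out / f"worm_{fit.label}.csv", index=False
            )
        report["stages"]["diagnostics"] = diag
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("diagnostics", str(exc)) from exc

    # -- stage 5: comparison --------------------------------------------------
    try:
        comparison = eng.compare_models(fits)
        comparison.to_csv(out / "comparison.csv", index=False)
        report["stages"]["comparison"] = comparison.to_dict(orient="records")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("comparison", str(exc)) from exc

    # -- stage 6: centiles -----------------------------------------------------
    best_label = comparison.iloc[0]["label"]
    best = next(f for f in fits if f.label == best_label)
    try:
        for i, prof in enumerate(config.get("centile_profiles", [])):
            table = ct.centile_curves(best, prof)
            table.to_csv(out / f"centiles_profile{i}.csv")
        bcfg = config.get("batch_bmi_charts")
        if bcfg:
            ct.batch_charts(
                best,
                out / "bmi_charts",
                ethnicities=bcfg.get(
                    "ethnicities", ["Australian/European"]
                ),
                render=bool(bcfg.get("render", False)),
            )
        report["stages"]["centiles"] = {"model": best_label}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("centiles", str(exc)) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
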