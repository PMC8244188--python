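"""End-to-end run: estimates, ratios, categories, meta-analysis, summaries.

Ties the stages together on a set of analysis units (read from CSV or
simulated): per-unit estimates for every estimator and evaluation-time
rule, ratio records with bootstrap SEs against the gold-standard AJE,
frequency-category cross-tabs, event-frequency and composite-endpoint
summaries, and random-effects meta-analysis plus univariable and
multivariable meta-regressions per comparator. All outputs are plain
CSV/JSON under the configured output directory, with a manifest that
records the seed and the per-stage exclusion counts.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparison import compare_unit, composite_endpoint_analysis, summarize_unit
from .estimators import TauRule, compute_estimate, evaluation_time, ESTIMATOR_NAMES
from .event_model import AnalysisSet, count_events
from .frequency_categories import category_crosstab
from .io import PipelineConfig, read_analysis_sets, write_analysis_sets
from .meta_analysis import MetaInput, fit_random_effects, meta_regression
from .synthetic_data import TrialSpec, HazardSpec, simulate_portfolio

__all__ = ["run_pipeline"]


def _load_units(config: PipelineConfig, outdir: Path) -> list[AnalysisSet]:
    if config.input_path is not None:
        return read_analysis_sets(config.input_path)
    sim = dict(config.simulation)
    hz = HazardSpec(**sim.pop("hazard", {}))
    spec = TrialSpec(hazard=hz, **sim)
    units, truth = simulate_portfolio(spec, config.n_trials, config.seed)
    truth.to_csv(outdir / "truth.csv", index=False)
    write_analysis_sets(units, outdir / "portfolio.csv")
    return units


def _meta_rows(records, rule: str) -> list[MetaInput]:
    rows = []
    for r in records:
        if r.defined and r.se_log_ratio is not None and r.se_log_ratio > 0:
            rows.append(
                MetaInput(
                    unit_id=f"{r.trial_id}/{r.ae_type}",
                    y=r.log_ratio,
                    se=r.se_log_ratio,
                    covariates=r.covariates,
                )
            )
    return rows


def _meta_result_dict(res) -> dict:
    d = {
        "average_ratio": res.average_ratio,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "mu": res.mu,
        "se_mu": res.se_mu,
        "tau2": res.tau2,
        "n_units": res.n_units,
        "method": res.method,
    }
    if res.coefficients:
        d["coefficients"] = {k: asdict(v) for k, v in res.coefficients.items()}
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle; returns the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    units = _load_units(config, outdir)

    est_rows, freq_rows, composite_rows, ratio_rows = [], [], [], []
    meta_out: dict = {}
    exclusions: dict[str, int] = {}
    rng = np.random.default_rng(config.seed)

    for rule in config.tau_rules:
        rule = TauRule(rule).value
        records_by_est: dict[str, list] = {e: [] for e in config.estimators}
        gold_by_unit: dict[str, float] = {}
        for unit in units:
            tau = evaluation_time(unit, rule)
            counts = count_events(unit, tau)
            props = counts.proportions()
            freq_rows.append(
                {"trial_id": unit.trial_id, "ae_type": unit.ae_type, "tau_rule": rule,
                 "tau": tau, **{f"prop_{k}": v for k, v in props.items()}}
            )
            for name in dict.fromkeys([*config.estimators, "aje"]):
                res = compute_estimate(unit, tau, name)
                est_rows.append(
                    {"trial_id": unit.trial_id, "arm": unit.arm, "ae_type": unit.ae_type,
                     "tau_rule": rule, "tau": tau, "estimator": name,
                     "estimate": res.estimate, "patient_time": res.patient_time}
                )
                if name == "aje":
                    gold_by_unit[f"{unit.trial_id}/{unit.ae_type}"] = res.estimate
            comp = composite_endpoint_analysis(unit, tau)
            composite_rows.append(
                {"trial_id": unit.trial_id, "ae_type": unit.ae_type,
                 "tau_rule": rule, "tau": tau, **comp}
            )
            recs = compare_unit(
                unit, tuple(config.estimators), rule,
                n_boot=config.n_boot,
                seed=np.random.default_rng(rng.integers(0, 2**31)),
            )
            for r in recs:
                records_by_est[r.estimator_name].append(r)
                ratio_rows.append(
                    {"trial_id": r.trial_id, "ae_type": r.ae_type, "tau_rule": rule,
                     "estimator": r.estimator_name, "ratio": r.ratio,
                     "log_ratio": r.log_ratio, "se_log_ratio": r.se_log_ratio,
                     "ci_low": r.ci_low, "ci_high": r.ci_high,
                     "excluded": r.exclusion_reason,
                     "n_degenerate_replicates": r.n_degenerate_replicates,
                     **r.covariates}
                )

        # frequency-category cross-tabs against the gold standard
        for name, recs in records_by_est.items():
            gold_p, other_p = [], []
            for unit in units:
                tau = evaluation_time(unit, rule)
                gold_p.append(gold_by_unit[f"{unit.trial_id}/{unit.ae_type}"])
                other_p.append(compute_estimate(unit, tau, name).estimate)
            tab = category_crosstab(gold_p, other_p, name)
            tab.to_csv(outdir / f"crosstab_{rule}_{name.replace('-', '_')}.csv")

        # meta-analysis and meta-regressions per comparator
        meta_out[rule] = {}
        for name, recs in records_by_est.items():
            rows = _meta_rows(recs, rule)
            excluded = len(recs) - len(rows)
            exclusions[f"{rule}/{name}"] = excluded
            block: dict = {"n_excluded_units": excluded}
            if len(rows) >= 2:
                block["random_effects"] = _meta_result_dict(
                    fit_random_effects(rows, method=config.meta_method,
                                       knapp_hartung=config.knapp_hartung)
                )
                block["meta_regression_univariable"] = {}
                for cov in config.covariates:
                    if len(rows) >= 4:
                        try:
                            block["meta_regression_univariable"][cov] = _meta_result_dict(
                                meta_regression(rows, [cov], method=config.meta_method,
                                                knapp_hartung=config.knapp_hartung)
                            )
                        except ValueError as exc:  # constant covariate etc.
                            block["meta_regression_univariable"][cov] = {"error": str(exc)}
                mv = config.multivariable_covariates
                if mv and len(rows) >= len(mv) + 3:
                    try:
                        block["meta_regression_multivariable"] = _meta_result_dict(
                            meta_regression(rows, mv, method=config.meta_method,
                                            knapp_hartung=config.knapp_hartung)
                        )
                    except ValueError as exc:
                        block["meta_regression_multivariable"] = {"error": str(exc)}
            meta_out[rule][name] = block

    pd.DataFrame(est_rows).to_csv(outdir / "estimates.csv", index=False)
    pd.DataFrame(freq_rows).to_csv(outdir / "event_frequencies.csv", index=False)
    pd.DataFrame(composite_rows).to_csv(outdir / "composite_endpoint.csv", index=False)
    pd.DataFrame(ratio_rows).to_csv(outdir / "ratios.csv", index=False)
    with open(outdir / "meta.json", "w") as fh:
        json.dump(meta_out, fh, indent=2)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_units": len(units),
        "tau_rules": list(config.tau_rules),
        "estimators": list(config.estimators),
        "n_boot": config.n_boot,
        "meta_method": config.meta_method,
        "excluded_units_per_meta": exclusions,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
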