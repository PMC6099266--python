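"""End-to-end orchestration: score -> stratified estimates -> meta ->
sensitivity -> diagnostics -> power, driven by a single YAML config.

Each cohort (simulated or loaded from genotype + phenotype files) is
scored, causal estimates with the bootstrap weight correction are fit per
geographic stratum for each requested site, strata are pooled by
random-effects meta-analysis, and — when several cohorts are configured —
the per-cohort pooled estimates are themselves pooled at a second level.
An ``exclude_strata`` option reruns the pooling without the named strata
and reports both side by side.  Every random operation's seed is recorded
in the machine-readable JSON report; rerunning with the same config yields
a byte-identical report.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import estimation, meta, power, sensitivity
from .instrument import compute_relative_exposure
from .io_model import (Cohort, GrsmrError, MetaResult, estimates_to_frame,
                       packaged_weights, read_cohort, read_variant_weights)
from .synthetic import SimulationConfig, simulate_cohort

logger = logging.getLogger("grsmr")

DEFAULT_SITES = ("oral", "oropharyngeal", "combined")


class PipelineError(GrsmrError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _meta_to_dict(m: MetaResult) -> dict[str, Any]:
    return {
        "pooled_or": m.pooled_or, "pooled_log_or": m.pooled_log_or,
        "pooled_se": m.pooled_se, "ci95": list(m.ci95), "pvalue": m.pvalue,
        "tau2": m.tau2, "q": m.q, "df": m.df, "i2": m.i2,
        "i2_ci": list(m.i2_ci), "p_het": m.p_het, "k": m.k,
    }


def _build_cohort(spec: Mapping[str, Any], weights, default_seed: int) -> tuple[str, Cohort, dict]:
    name = spec.get("name", "cohort")
    meta_info: dict[str, Any] = {"name": name}
    if "simulate" in spec:
        sim_kwargs = dict(spec["simulate"] or {})
        sim_kwargs.setdefault("seed", default_seed)
        strata = sim_kwargs.get("strata")
        if strata is not None:
            sim_kwargs["strata"] = {k: tuple(v) for k, v in strata.items()}
        cfg = SimulationConfig(weights=tuple(weights), **sim_kwargs)
        cohort = simulate_cohort(cfg)
        meta_info["simulated"] = True
        meta_info["seed"] = cfg.seed
        meta_info["causal_log_or"] = cfg.causal_log_or
    else:
        cohort = read_cohort(spec["genotypes"], spec["phenotypes"], weights)
        meta_info["simulated"] = False
    meta_info["n_cases"] = cohort.n_cases
    meta_info["n_controls"] = cohort.n_controls
    return name, cohort, meta_info


def run_pipeline(config: str | Path | Mapping[str, Any], output_dir: str | Path | None = None) -> dict:
    """Run the full analysis described by ``config`` (YAML path or mapping).

    Writes TSV tables plus ``report.json`` and ``summary.txt`` into the
    configured output directory and returns the report dict.  On a stage
    failure, tables produced so far are written under ``<out>/failed/`` and
    a :class:`PipelineError` naming the stage is raised.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    outdir = Path(output_dir or cfg.get("output_dir", "grsmr_out"))

    tables: dict[str, pd.DataFrame] = {}
    report: dict[str, Any] = {"seed": seed, "cohorts": [], "meta": {}, "power": {}}
    stage = "setup"
    try:
        stage = "weights"
        if cfg.get("weights"):
            weights = read_variant_weights(cfg["weights"])
        else:
            weights = packaged_weights()
        report["weights"] = [w.rsid for w in weights]

        stage = "cohorts"
        cohort_specs = cfg.get("cohorts") or [{"name": "simulated", "simulate": {}}]
        cohorts: list[tuple[str, Cohort]] = []
        for i, cspec in enumerate(cohort_specs):
            name, cohort, info = _build_cohort(cspec, weights, seed + 1000 * (i + 1))
            cohorts.append((name, cohort))
            report["cohorts"].append(info)

        sites = tuple(cfg.get("sites") or DEFAULT_SITES)
        breps = int(cfg.get("bootstrap_reps", 1000))
        covariates = cfg.get("covariates")
        exclude = list(cfg.get("exclude_strata") or [])

        stage = "estimation"
        est_rows = []
        per_cohort_site_meta: dict[str, dict[str, MetaResult]] = {}
        per_cohort_site_meta_excl: dict[str, dict[str, MetaResult]] = {}
        for ci, (name, cohort) in enumerate(cohorts):
            scores = compute_relative_exposure(cohort, weights)
            per_cohort_site_meta[name] = {}
            per_cohort_site_meta_excl[name] = {}
            for site in sites:
                spec = estimation.AnalysisSpec(
                    site_filter=site, covariates=covariates,
                    bootstrap_reps=breps, seed=seed + 7919 * (ci + 1))
                ests = estimation.estimate_all_strata(cohort, scores, spec, weights=weights)
                df = estimates_to_frame(ests)
                df.insert(0, "cohort", name)
                df.insert(1, "site", site)
                est_rows.append(df)
                per_cohort_site_meta[name][site] = meta.dl_random_effects(ests)
                if exclude:
                    kept = [e for e in ests
                            if e.label.split("/", 1)[1] not in exclude]
                    per_cohort_site_meta_excl[name][site] = meta.dl_random_effects(kept)
        tables["estimates"] = pd.concat(est_rows, ignore_index=True)

        stage = "meta"
        for name in per_cohort_site_meta:
            report["meta"][name] = {
                site: _meta_to_dict(m) for site, m in per_cohort_site_meta[name].items()}
            if exclude:
                report["meta"][name + "_excluding_" + "+".join(exclude)] = {
                    site: _meta_to_dict(m)
                    for site, m in per_cohort_site_meta_excl[name].items()}
        if len(cohorts) > 1:
            report["meta"]["pooled_across_cohorts"] = {}
            for site in sites:
                pairs = [(per_cohort_site_meta[n][site].pooled_log_or,
                          per_cohort_site_meta[n][site].pooled_se)
                         for n, _ in cohorts]
                report["meta"]["pooled_across_cohorts"][site] = \
                    _meta_to_dict(meta.dl_random_effects(pairs))
        meta_rows = []
        for block, site_map in report["meta"].items():
            for site, m in site_map.items():
                meta_rows.append({"analysis": block, "site": site, **{
                    k: (v if not isinstance(v, list) else str(v)) for k, v in m.items()}})
        tables["meta"] = pd.DataFrame(meta_rows)

        stage = "sensitivity"
        sens_cfg = cfg.get("sensitivity") or {}
        name0, cohort0 = cohorts[0]
        scores0 = compute_relative_exposure(cohort0, weights)
        spec0 = estimation.AnalysisSpec(site_filter="combined", covariates=covariates,
                                        bootstrap_reps=breps, seed=seed)
        if sens_cfg.get("leave_one_out", True):
            tables["sensitivity_loo"] = sensitivity.leave_one_out(cohort0, weights, spec0)
        if sens_cfg.get("all_subsets", False):
            tables["sensitivity_subsets"] = sensitivity.all_subsets(
                cohort0, weights, spec0, flag_rsid=sens_cfg.get("flag_rsid"))

        stage = "diagnostics"
        bal_covs = cfg.get("balance_covariates") or ["sex", "smoking", "alcohol", "stratum"]
        tables["balance"] = sensitivity.balance_table(scores0, cohort0.phenotypes, bal_covs)
        tables["eaf_by_region"] = sensitivity.eaf_by_group(cohort0, weights).reset_index()

        stage = "power"
        pw = cfg.get("power") or {}
        r2_list = pw.get("r2") or [0.03, 0.05]
        alpha = float(pw.get("alpha", 0.05))
        target = float(pw.get("target_power", 0.8))
        power_rows = []
        for name, cohort in cohorts:
            for r2 in r2_list:
                q = power.PowerQuery(cohort.n_cases, cohort.n_controls,
                                     float(r2), alpha, target)
                protective, risk = power.detectable_or(q)
                power_rows.append({
                    "cohort": name, "n_cases": q.n_cases, "n_controls": q.n_controls,
                    "r2": float(r2), "alpha": alpha, "target_power": target,
                    "detectable_or_protective": protective, "detectable_or_risk": risk})
        tables["power"] = pd.DataFrame(power_rows)
        report["power"] = power_rows

        stage = "report"
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(_summary_text(report))
        return report
    except Exception as exc:
        faildir = outdir / "failed"
        faildir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(faildir / f"{name}.tsv", sep="\t", index=False)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc


def _summary_text(report: dict) -> str:
    lines = ["grsmr pipeline summary", "======================", ""]
    for info in report["cohorts"]:
        lines.append(
            f"cohort {info['name']}: {info['n_cases']} cases / "
            f"{info['n_controls']} controls"
            + (f" (simulated, seed {info['seed']})" if info.get("simulated") else ""))
    lines.append("")
    for block, site_map in report["meta"].items():
        for site, m in site_map.items():
            lines.append(
                f"{block} / {site}: OR = {m['pooled_or']:.2f} "
                f"[{m['ci95'][0]:.2f}, {m['ci95'][1]:.2f}], p = {m['pvalue']:.2f}; "
                f"I2 = {m['i2'] * 100:.0f}%"
                + ("" if m["p_het"] != m["p_het"] else f", p_het = {m['p_het']:.2f}"))
    lines.append("")
    for row in report["power"]:
        lines.append(
            f"power ({row['cohort']}, R2={row['r2']}): detectable protective OR "
            f"{row['detectable_or_protective']:.2f}")
    return "\n".join(lines) + "\n"
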