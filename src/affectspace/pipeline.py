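"""End-to-end orchestration: simulate/ingest -> features -> univariate ->
MFA + resampling inference -> validation, under one configuration and one
master seed.

Every stage writes its tables (CSV) and reports (JSON) under the output
directory, and a run manifest records the configuration echo, per-stage
seeds, row counts and the dropped-row ledger.  Re-running with the same
configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coherence import coherence_model_suite, residualize
from .inference import infer_space
from .io import read_trial_table, write_trial_table
from .mfa import GroupSpec, MFAResult, aggregate_table, fit_mfa
from .schema import PARTICIPANT, VALENCE_CATEGORY
from .signals import PreprocessParams, extract_trial_features
from .synthetic import (
    GeneratorParams,
    generate_raw_signals,
    params_from_dict,
    params_to_dict,
    simulate,
)
from .validation import ForestParams, validate_space

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("affectspace")


@dataclass
class PipelineConfig:
    """Everything a full run needs; the master seed drives every stage."""

    mode: str = "synthetic"  # or "real"
    input_path: str | None = None  # trial-table CSV in real mode
    outdir: str = "affectspace_out"
    seed: int = 0
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    groups: GroupSpec = field(default_factory=GroupSpec)
    n_boot: int = 10_000
    n_perm: int = 10_000
    alpha: float = 0.05
    strata: list[str] = field(default_factory=lambda: [PARTICIPANT, VALENCE_CATEGORY])
    bootstrap_unit: str = "crossed"
    n_dims: int = 2
    split: float = 0.3
    k_range: list[int] = field(default_factory=lambda: list(range(2, 9)))
    n_jobs: int = 1
    aggregations: list[str] = field(default_factory=list)
    use_raw_signals: bool = False
    residualize_pupil: bool = True
    residualize_method: str = "lmm"
    run_univariate: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            d["generator"] = params_from_dict(d["generator"])
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            pp = {
                k: tuple(v) if isinstance(v, list) else v for k, v in d["preprocess"].items()
            }
            d["preprocess"] = PreprocessParams(**pp)
        if "groups" in d and isinstance(d["groups"], dict):
            d["groups"] = GroupSpec(**d["groups"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = params_to_dict(self.generator)
        return d


@dataclass
class PipelineResult:
    table: pd.DataFrame
    mfa: MFAResult
    inference: object
    validation: object
    univariate: dict
    manifest: dict
    outdir: Path


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=1, default=str)


def _write_mfa(result: MFAResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"eigenvalue": result.eigenvalues, "pct_variance": result.pct_variance}
    ).to_csv(outdir / "eigenvalues.csv", index_label="dim")
    result.correlations.to_csv(outdir / "variable_correlations.csv")
    result.contributions.to_csv(outdir / "variable_contributions.csv")
    result.group_contributions.to_csv(outdir / "group_contributions.csv")
    result.scores.to_csv(outdir / "scores.csv")
    for g, ps in result.partial_scores.items():
        ps.to_csv(outdir / f"partial_scores_{g}.csv")
    result.partial_axes_table.to_csv(outdir / "partial_axes.csv")
    summary = {
        "eigenvalues": result.eigenvalues,
        "pct_variance": result.pct_variance,
        "group_weights": result.group_weights,
        "group_first_eigenvalues": result.group_first_eigenvalues,
        "group_contributions": result.group_contributions,
        "n_rows": result.n_rows,
        "n_dropped": result.n_dropped,
        "aggregation": result.aggregation,
    }
    _write_json(summary, outdir / "mfa.json")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order and write every intermediate product."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    log.addHandler(fh)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "warnings": [],
    }
    root = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: s
        for name, s in zip(
            ["simulate", "signals", "inference", "validation"], root.spawn(4)
        )
    }
    manifest["stage_seeds"] = {
        k: int(v.generate_state(1)[0] % (2**31 - 1)) for k, v in stage_seeds.items()
    }

    try:
        # --- stage 1: data ------------------------------------------------
        if config.mode == "synthetic":
            seed = manifest["stage_seeds"]["simulate"]
            stimuli, table = simulate(config.generator, seed=seed)
            stimuli.to_csv(outdir / "stimuli.csv", index=False)
            if config.use_raw_signals:
                recs = generate_raw_signals(
                    table, config.generator, seed=manifest["stage_seeds"]["signals"]
                )
                feats, quality = extract_trial_features(recs, config.preprocess)
                _write_json(quality, outdir / "signal_quality.json")
                merged = table.drop(columns=["pupil", "scr", "hr"]).merge(
                    feats.drop(columns=["trial_id"]), on=[PARTICIPANT, "stimulus"]
                )
                table = merged
            write_trial_table(table, outdir / "trial_table.csv")
        elif config.mode == "real":
            if not config.input_path:
                raise ValueError("real mode requires input_path")
            table = read_trial_table(config.input_path)
            write_trial_table(table, outdir / "trial_table.csv")
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
        manifest["stages"]["data"] = {"rows_in": len(table)}

        # --- stage 2: univariate coherence suite --------------------------
        univariate: dict = {}
        if config.run_univariate:
            univariate = coherence_model_suite(table)
            uni_dir = outdir / "univariate"
            uni_dir.mkdir(exist_ok=True)
            summary = {}
            for name, ct in univariate.items():
                ct.coefficients.to_csv(uni_dir / f"{name}.csv")
                summary[name] = {
                    "converged": ct.converged,
                    "n_obs": ct.n_obs,
                    "n_dropped": ct.n_dropped,
                    "df_method": ct.df_method,
                    "variance_components": ct.variance_components,
                }
            _write_json(summary, uni_dir / "suite.json")
            manifest["stages"]["univariate"] = {"models": len(univariate)}

        # --- stage 3: brightness residualization + MFA ---------------------
        analysis_table = table
        if config.residualize_pupil:
            analysis_table, beta = residualize(
                table, "pupil", "brightness", method=config.residualize_method
            )
            manifest["stages"]["residualize"] = {"brightness_beta": float(beta)}
        mfa_result = fit_mfa(analysis_table, config.groups, n_dims=config.n_dims)
        _write_mfa(mfa_result, outdir / "mfa")
        manifest["stages"]["mfa"] = {
            "rows_used": mfa_result.n_rows,
            "rows_dropped": mfa_result.n_dropped,
        }
        for agg in config.aggregations:
            agg_table = aggregate_table(analysis_table, agg)
            if agg in ("participant", "stimulus"):
                agg_fit = fit_mfa(
                    agg_table,
                    GroupSpec(groups=config.groups.groups, supplementary=[]),
                    n_dims=config.n_dims,
                    aggregation=agg,
                )
            else:
                agg_fit = fit_mfa(agg_table, config.groups, n_dims=config.n_dims, aggregation=agg)
            _write_mfa(agg_fit, outdir / f"mfa_{agg}")

        # --- stage 4: resampling inference ---------------------------------
        inference = infer_space(
            analysis_table,
            config.groups,
            n_boot=config.n_boot,
            n_perm=config.n_perm,
            alpha=config.alpha,
            strata=config.strata,
            unit=config.bootstrap_unit,
            seed=manifest["stage_seeds"]["inference"],
            n_dims=config.n_dims,
            n_jobs=config.n_jobs,
        )
        inf_dir = outdir / "inference"
        inf_dir.mkdir(exist_ok=True)
        inference.eigen_table.to_csv(inf_dir / "eigenvalues.csv")
        for dim, lt in inference.loading_tables.items():
            lt.to_csv(inf_dir / f"loadings_{dim}.csv")
        _write_json(
            {
                "n_boot": inference.n_boot,
                "n_perm": inference.n_perm,
                "alpha": inference.alpha,
                "retained": inference.retained,
                "alignment": inference.alignment,
                "n_boot_dropped": inference.n_boot_dropped,
                "eigen_table": inference.eigen_table,
            },
            inf_dir / "inference.json",
        )
        manifest["stages"]["inference"] = {
            "retained": inference.retained,
            "n_boot_dropped": inference.n_boot_dropped,
        }

        # --- stage 5: validation -------------------------------------------
        scores = mfa_result.scores
        labels = analysis_table.loc[scores.index, VALENCE_CATEGORY]
        variables = analysis_table.loc[scores.index, mfa_result.variables]
        validation = validate_space(
            scores,
            labels,
            variables=variables,
            params=ForestParams(test_size=config.split),
            k_range=config.k_range,
            seed=manifest["stage_seeds"]["validation"],
        )
        val_dir = outdir / "validation"
        val_dir.mkdir(exist_ok=True)
        validation.classification.confusion.to_csv(val_dir / "confusion.csv")
        if validation.clustering.contingency is not None:
            validation.clustering.contingency.to_csv(val_dir / "contingency.csv")
        _write_json(
            {
                "classification": {
                    "oob_accuracy": validation.classification.oob_accuracy,
                    "test_accuracy": validation.classification.test_accuracy,
                    "auc_per_class": validation.classification.auc_per_class,
                    "macro_auc": validation.classification.macro_auc,
                    "importance": validation.classification.importance,
                    "chi2": validation.classification.chi2,
                    "chi2_df": validation.classification.chi2_df,
                    "chi2_p": validation.classification.chi2_p,
                },
                "clustering": {
                    "chosen_k": validation.clustering.chosen_k,
                    "silhouette": validation.clustering.silhouette,
                    "silhouette_by_k": validation.clustering.silhouette_by_k,
                    "pct_between_variance": validation.clustering.pct_between_variance,
                    "chi2": validation.clustering.chi2,
                    "chi2_p": validation.clustering.chi2_p,
                },
            },
            val_dir / "validation.json",
        )
        manifest["stages"]["validation"] = {
            "test_accuracy": validation.classification.test_accuracy,
            "chosen_k": validation.clustering.chosen_k,
        }
    except Exception as exc:
        manifest["error"] = {"stage": "see stages", "message": str(exc)}
        _write_json(manifest, outdir / "manifest.json")
        raise
    finally:
        log.removeHandler(fh)
        fh.close()

    _write_json(manifest, outdir / "manifest.json")
    return PipelineResult(
        table=table,
        mfa=mfa_result,
        inference=inference,
        validation=validation,
        univariate=univariate,
        manifest=manifest,
        outdir=outdir,
    )
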