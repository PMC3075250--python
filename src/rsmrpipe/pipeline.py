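"""End-to-end driver: simulate → cohort → covariates → select → fit → RSMR.

Mirrors the measure-development workflow: build the cohort under the
inclusion/exclusion rules, split it by hospital into derivation and
validation halves, select covariates by backward elimination on the
derivation half, re-estimate the selected model as a random-intercept HGLM
on the full cohort, and report risk-standardized mortality rates plus the
validation battery (discrimination, calibration, overfitting indices,
residuals). All randomness descends from one root seed, deterministically
split per stage; every artifact is stamped with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import covariates as cov_mod
from . import hglm, performance, rsmr
from .io import config_hash, read_claims_bundle, write_claims_bundle
from .synthetic import ClaimsBundle, SimulationConfig, VolumeLaw, generate_dataset

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class ModelOptions:
    alpha_exit: float = 0.01
    n_quad: int = 15
    forced_in: tuple[str, ...] = ()
    frequency_threshold: float = 0.01
    include_demographics: bool = True


@dataclass(frozen=True)
class BootstrapOptions:
    B: int = 0  # 0 disables interval estimation
    level: float = 0.95


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig | None = None
    bundle_dir: str | None = None
    mapping_path: str | None = None
    cohort: cohort_mod.CohortSpec = field(default_factory=cohort_mod.CohortSpec)
    model: ModelOptions = field(default_factory=ModelOptions)
    bootstrap: BootstrapOptions = field(default_factory=BootstrapOptions)
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None and self.bundle_dir is None:
            raise ValueError("need either a simulation config or a bundle_dir")

    @classmethod
    def from_yaml(cls, path, *, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.get("simulation")
        if sim is not None:
            if "volume_law" in sim:
                sim["volume_law"] = VolumeLaw(**sim["volume_law"])
            sim = SimulationConfig(**sim)
        spec = cohort_mod.CohortSpec(**raw.get("cohort", {}))
        model = ModelOptions(**{
            **raw.get("model", {}),
            "forced_in": tuple(raw.get("model", {}).get("forced_in", ())),
        })
        boot = BootstrapOptions(**raw.get("bootstrap", {}))
        root_seed = raw.get("seed", 0) if seed is None else seed
        if sim is not None and seed is not None:
            sim = dataclasses.replace(sim, seed=seed)
        if seed is not None:
            spec = dataclasses.replace(spec, seed=seed)
        return cls(
            simulation=sim,
            bundle_dir=raw.get("bundle_dir"),
            mapping_path=raw.get("mapping_path"),
            cohort=spec,
            model=model,
            bootstrap=boot,
            output_dir=raw.get("output_dir"),
            seed=root_seed,
        )


@dataclass
class PipelineResult:
    bundle: ClaimsBundle
    cohort: pd.DataFrame
    tally: cohort_mod.ExclusionTally
    derivation: pd.DataFrame
    validation: pd.DataFrame
    matrix: cov_mod.CovariateMatrix
    selected_columns: list[str]
    elimination_trace: pd.DataFrame
    glm_fit: hglm.GLMFit
    hglm_fit: hglm.HGLMFit
    rsmr_table: pd.DataFrame
    bootstrap: pd.DataFrame | None
    report: dict


def _design(matrix: cov_mod.CovariateMatrix, episode_ids, include_demo: bool) -> pd.DataFrame:
    df = matrix.data.loc[episode_ids]
    if not include_demo:
        df = df.drop(columns=list(cov_mod.CovariateMatrix.DEMOGRAPHICS))
    return df


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage; artifacts are also written to ``output_dir``
    when one is configured. Stage failures propagate after earlier
    artifacts have been written."""
    t_start = time.time()
    timings: dict[str, float] = {}
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def clock(name):
        timings[name] = time.time() - t_start

    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        bundle, truth = generate_dataset(sim)
        if outdir:
            write_claims_bundle(bundle, outdir / "bundle", config=sim)
    else:
        bundle = read_claims_bundle(config.bundle_dir)
        truth = None
    clock("simulate")

    spec = dataclasses.replace(config.cohort, seed=config.seed)
    cohort, tally = cohort_mod.build_cohort(bundle, spec)
    if len(cohort) == 0:
        raise RuntimeError("cohort is empty after exclusions")
    log.info("cohort: %d episodes; tally %s", len(cohort), tally.counts)
    if outdir:
        cohort.to_csv(outdir / "cohort.csv", index=False)
        tally.as_frame().to_csv(outdir / "exclusions.csv", index=False)
    clock("cohort")

    mapping = (
        cov_mod.ConditionMapping.from_csv(config.mapping_path)
        if config.mapping_path
        else cov_mod.default_mapping()
    )
    matrix = cov_mod.build_candidate_matrix(cohort, bundle, mapping)
    matrix = cov_mod.frequency_filter(matrix, config.model.frequency_threshold)
    if outdir:
        matrix.data.to_csv(outdir / "covariates.csv")
        matrix.provenance.to_csv(outdir / "covariates_provenance.csv", index=False)
    clock("covariates")

    derivation, validation = cohort_mod.split_cohort(cohort, spec)
    y = cohort.set_index("episode_id")["outcome"]
    groups = cohort.set_index("episode_id")["hospital_id"]
    X_der = _design(matrix, derivation["episode_id"], config.model.include_demographics)
    y_der = y.loc[X_der.index].to_numpy()

    degenerate = hglm.screen_separation(X_der, y_der)
    if degenerate:
        log.info("dropping separation-degenerate columns: %s", degenerate)
        X_der = X_der.drop(columns=degenerate)
    selected, glm_fit, trace = hglm.backward_eliminate(
        X_der, y_der, config.model.alpha_exit, forced=config.model.forced_in
    )
    clock("select")

    X_full = matrix.data.loc[cohort["episode_id"], selected]
    hglm_fit = hglm.fit_random_intercept(
        X_full,
        y.loc[X_full.index].to_numpy(),
        groups.loc[X_full.index].to_numpy(),
        hglm.HGLMConfig(n_quad=config.model.n_quad),
    )
    if outdir:
        hglm_fit.to_json(outdir / "fit.json")
        trace.to_csv(outdir / "elimination_trace.csv", index=False)
    clock("fit")

    table = rsmr.rsmr_table(
        hglm_fit,
        X_full,
        groups.loc[X_full.index].to_numpy(),
        y.loc[X_full.index].to_numpy(),
    )
    boot = None
    if config.bootstrap.B >= 2:
        boot = rsmr.bootstrap_intervals(
            X_full,
            y.loc[X_full.index].to_numpy(),
            groups.loc[X_full.index].to_numpy(),
            B=config.bootstrap.B,
            seed=config.seed,
            level=config.bootstrap.level,
            hglm_config=hglm.HGLMConfig(n_quad=config.model.n_quad),
        )
        table = table.merge(boot, on="hospital_id", how="left")
    if outdir:
        table.to_csv(outdir / "rsmr.csv", index=False)
    clock("rsmr")

    p_der = 1 / (1 + np.exp(-glm_fit.linear_predictor(X_der[selected])))
    report = {
        "seed": config.seed,
        "config_hash": config_hash(
            config.simulation if config.simulation is not None else {"bundle": config.bundle_dir}
        ),
        "n_cohort": int(len(cohort)),
        "n_hospitals": int(cohort["hospital_id"].nunique()),
        "national_rate": float(table.attrs.get("national_rate", y.mean())),
        "exclusions": dict(tally.counts) | {"included": tally.included},
        "selected_columns": selected,
        "tau": hglm_fit.tau,
        "derivation": performance.performance_report(p_der, y_der, glm_fit.loglik),
    }
    if len(validation) > 0 and selected:
        X_val = matrix.data.loc[validation["episode_id"], selected]
        y_val = y.loc[X_val.index].to_numpy()
        if 0 < y_val.mean() < 1:
            try:
                intercept, slope = performance.overfitting_indices(glm_fit, X_val, y_val)
                recal = hglm.fit_logistic(X_val, y_val)
                p_val = 1 / (1 + np.exp(-recal.linear_predictor(X_val)))
                report["validation"] = performance.performance_report(
                    p_val, y_val, recal.loglik
                )
                report["overfitting"] = {"intercept": intercept, "slope": slope}
            except (hglm.SeparationError, ValueError) as err:
                # tiny validation halves can be degenerate; report the reason
                log.warning("validation scoring skipped: %s", err)
                report["validation_skipped"] = str(err)
    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    if outdir:
        serializable = json.loads(json.dumps(report, default=_jsonify))
        with open(outdir / "report.json", "w") as fh:
            json.dump(serializable, fh, indent=1)
            fh.write("\n")

    return PipelineResult(
        bundle=bundle,
        cohort=cohort,
        tally=tally,
        derivation=derivation,
        validation=validation,
        matrix=matrix,
        selected_columns=selected,
        elimination_trace=trace,
        glm_fit=glm_fit,
        hglm_fit=hglm_fit,
        rsmr_table=table,
        bootstrap=boot,
        report=report,
    )


def _jsonify(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return str(obj)
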