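"""End-to-end orchestration: generate -> fit -> select -> evaluate -> pta.

A :class:`RunConfig` (plain YAML) drives the stages; every stage writes its
artifacts into the output directory and the run ends with a manifest listing
each file together with the seeds and a hash of the configuration, so any
run is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort, estimation, evaluation, pta as pta_mod
from .population import PopulationModel, final_model, load_model, save_model

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("generate", "fit", "select", "evaluate", "bootstrap", "vpc", "pta")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    output_dir: Path
    seed: int
    stages: tuple[str, ...] = ALL_STAGES
    model_path: Path | None = None  # None -> packaged final model
    dataset_path: Path | None = None  # required when 'generate' is skipped
    n_subjects: int = 245
    bootstrap_reps: int = 200
    vpc_simulations: int = 500
    vpc_bins: int = 6
    pta_subjects: int = 10_000
    pta_targets: tuple[float, ...] = (0.70, 0.40)
    fit_n_starts: int = 3
    candidates: tuple[tuple[str, str, str], ...] = (
        ("cl", "clcr", "linear"),
        ("cl", "alb", "linear"),
        ("q", "bun", "linear"),
    )
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigError("config must set an explicit seed")
        if "output_dir" not in raw:
            raise ConfigError("config must set output_dir")
        stages = tuple(raw.get("stages", ALL_STAGES))
        unknown = [s for s in stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}")
        cfg = cls(
            output_dir=Path(raw["output_dir"]),
            seed=int(raw["seed"]),
            stages=stages,
            model_path=Path(raw["model"]) if raw.get("model") else None,
            dataset_path=Path(raw["dataset"]) if raw.get("dataset") else None,
            n_subjects=int(raw.get("n_subjects", 245)),
            bootstrap_reps=int(raw.get("bootstrap_reps", 200)),
            vpc_simulations=int(raw.get("vpc_simulations", 500)),
            vpc_bins=int(raw.get("vpc_bins", 6)),
            pta_subjects=int(raw.get("pta_subjects", 10_000)),
            pta_targets=tuple(raw.get("pta_targets", (0.70, 0.40))),
            fit_n_starts=int(raw.get("fit_n_starts", 3)),
            candidates=tuple(
                tuple(c) for c in raw.get("candidates", cls.candidates)
            ),
            raw=raw,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.model_path is not None and not self.model_path.exists():
            raise ConfigError(f"model config not found: {self.model_path}")
        if "generate" not in self.stages:
            if self.dataset_path is None:
                needs_data = {"fit", "select", "evaluate", "bootstrap", "vpc"}
                if needs_data & set(self.stages):
                    raise ConfigError(
                        "a dataset path is required when 'generate' is not run"
                    )
            elif not self.dataset_path.exists():
                raise ConfigError(f"dataset not found: {self.dataset_path}")

    def config_hash(self) -> str:
        canon = json.dumps(
            {k: v for k, v in sorted(self.raw.items())}, sort_keys=True, default=str
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _base_model(model: PopulationModel) -> PopulationModel:
    m = model.copy()
    m.effects = []
    return m


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict."""
    config.validate()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    model = load_model(config.model_path) if config.model_path else final_model()
    artifacts: dict[str, str] = {}
    seeds = {"root": config.seed}
    subjects = None
    fit = None

    def record(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    if "generate" in config.stages:
        seeds["generate"] = config.seed
        subjects = cohort.generate_dataset(
            config.n_subjects, model, seed=config.seed
        )
        df = cohort.write_dataset(subjects)
        p = out / "dataset.csv"
        df.to_csv(p, index=False)
        record("dataset", p)
    elif config.dataset_path is not None:
        subjects = cohort.read_dataset(pd.read_csv(config.dataset_path))

    # estimation stages use only subjects with quantifiable observations (M1)
    est_subjects = cohort.filter_estimable(subjects) if subjects is not None else None

    if "fit" in config.stages:
        fit = estimation.fit_fo(
            est_subjects, model, n_starts=config.fit_n_starts, seed=config.seed
        )
        report = {
            "ofv": fit.ofv,
            "converged": fit.converged,
            "estimates": fit.estimates(),
            "se": fit.se,
            "rse_percent": fit.rse_percent,
        }
        p = out / "fit_report.yaml"
        with open(p, "w") as fh:
            yaml.safe_dump(report, fh, sort_keys=False)
        record("fit_report", p)
        save_model(fit.model, out / "fitted_model.yaml")
        record("fitted_model", out / "fitted_model.yaml")

    if "select" in config.stages:
        base = _base_model(model)
        selected, trace = estimation.stepwise_select(
            est_subjects, base, list(config.candidates), seed=config.seed
        )
        p = out / "selection_trace.csv"
        trace.to_csv(p, index=False)
        record("selection_trace", p)
        save_model(selected.model, out / "selected_model.yaml")
        record("selected_model", out / "selected_model.yaml")
        fit = fit or selected

    eval_model = fit.model if fit is not None else model

    if "evaluate" in config.stages:
        gof = evaluation.gof_table(est_subjects, eval_model)
        p = out / "gof_table.csv"
        gof.to_csv(p, index=False)
        record("gof_table", p)
        mask = gof.DV > 0
        pe = evaluation.prediction_errors(gof.PRED[mask], gof.DV[mask])
        summary = evaluation.summarize_pe(pe)
        p = out / "prediction_errors.yaml"
        with open(p, "w") as fh:
            yaml.safe_dump(
                {
                    "mdpe": summary.mdpe,
                    "mape": summary.mape,
                    "f20": summary.f20,
                    "f30": summary.f30,
                    "n": summary.n,
                    "satisfactory": summary.satisfactory,
                },
                fh,
            )
        record("prediction_errors", p)

    if "bootstrap" in config.stages:
        seeds["bootstrap"] = config.seed + 1
        if fit is None:
            fit = estimation.fit_fo(est_subjects, model, n_starts=1, seed=config.seed)
        boot = evaluation.bootstrap_model(
            est_subjects, fit, n_reps=config.bootstrap_reps, seed=seeds["bootstrap"]
        )
        p = out / "bootstrap.csv"
        boot.table.to_csv(p, index=False)
        record("bootstrap", p)

    if "vpc" in config.stages:
        seeds["vpc"] = config.seed + 2
        vpc = evaluation.pc_vpc(
            est_subjects,
            eval_model,
            n_sim=config.vpc_simulations,
            n_bins=config.vpc_bins,
            seed=seeds["vpc"],
        )
        p = out / "vpc_bins.csv"
        vpc.bins.to_csv(p, index=False)
        record("vpc_bins", p)
        with open(out / "vpc_coverage.yaml", "w") as fh:
            yaml.safe_dump({"coverage": vpc.coverage, "n_sim": vpc.n_simulations}, fh)
        record("vpc_coverage", out / "vpc_coverage.yaml")

    if "pta" in config.stages:
        seeds["pta"] = config.seed + 3
        spec = pta_mod.SimulationSpec(
            model=model,
            n_subjects=config.pta_subjects,
            target_fractions=config.pta_targets,
            seed=seeds["pta"],
        )
        result = pta_mod.pta_grid(spec)
        p = out / "pta_table.csv"
        result.table.to_csv(p, index=False)
        record("pta_table", p)
        ranked, pairwise = pta_mod.compare_regimens(result)
        ranked.to_csv(out / "pta_ranked.csv", index=False)
        record("pta_ranked", out / "pta_ranked.csv")
        pairwise.to_csv(out / "pta_pairwise.csv", index=False)
        record("pta_pairwise", out / "pta_pairwise.csv")

    manifest = {
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "stages": list(config.stages),
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
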