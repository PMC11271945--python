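"""Reproducible generate -> calibrate -> predict -> report pipeline.

A :class:`RunConfig` (schema-validated before any computation; unknown keys
rejected) drives the full sequence: synthesize or ingest tension and
relaxation data, fit the Prony spectrum to the normalized relaxation trace,
fit the constitutive constants to the lowest-rate tension data, forward-
predict the remaining rates and score them, then write the parameter file,
per-stage curves and a seeded, versioned report.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationConfig, TensionCurve, goodness_of_fit
from .core import DamageParameters, HyperelasticCoefficients
from .exceptions import ConfigurationError, RenomechError
from .io import dataset_to_curves, read_curves, write_curves, write_dataset
from .materials import MaterialParameters
from .models import PronyRelaxationModel, TensionCalibrationModel
from .synthetic import (
    ExperimentRecipe,
    generate_relaxation_dataset,
    generate_tension_dataset,
    rupture_strain_model,
)

__all__ = ["RunConfig", "PipelineReport", "run_pipeline"]

_CALIBRATION_KEYS = {
    "n_branches", "steps", "vary", "n_rounds", "mu",
    "fixed_damage", "fixed_hyperelastic", "fit_alpha", "refine_prony",
}
_PREDICTION_KEYS = {"rates"}
_RECIPE_KEYS = set(ExperimentRecipe.__dataclass_fields__) - {"material"} | {"material"}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    outdir: str = "renomech_run"
    mode: str = "generate"  # or "ingest"
    seed: int = 0
    inputs: dict = field(default_factory=dict)  # mode="ingest": tension=, relaxation=
    recipe: dict = field(default_factory=dict)  # ExperimentRecipe overrides
    calibration: dict = field(default_factory=dict)
    prediction: dict = field(default_factory=dict)
    log_level: str = "INFO"
    xlsx: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("generate", "ingest"):
            raise ConfigurationError(f"mode must be 'generate' or 'ingest', got {self.mode!r}")
        if self.mode == "ingest":
            for key in ("tension", "relaxation"):
                if key not in self.inputs:
                    raise ConfigurationError(f"mode='ingest' requires inputs.{key}")
                if not Path(self.inputs[key]).exists():
                    raise ConfigurationError(
                        f"inputs.{key} path {self.inputs[key]!r} does not exist"
                    )
        for name, allowed, given in (
            ("recipe", _RECIPE_KEYS, self.recipe),
            ("calibration", _CALIBRATION_KEYS, self.calibration),
            ("prediction", _PREDICTION_KEYS, self.prediction),
        ):
            unknown = set(given) - allowed
            if unknown:
                raise ConfigurationError(f"unknown {name} key(s): {sorted(unknown)}")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(d) - allowed
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(d)

    def canonical_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Outcome of a pipeline run (also written to ``outdir/report.yaml``)."""

    material: MaterialParameters
    prony_m_inf: float
    rmse_MPa: dict
    relative_rmse: dict
    seed: int
    config_hash: str
    outdir: Path
    summary_text: str


def _build_recipe(config: RunConfig) -> ExperimentRecipe:
    overrides = dict(config.recipe)
    material = overrides.pop("material", None)
    recipe = ExperimentRecipe(seed=config.seed)
    if material is not None:
        recipe = replace(recipe, material=MaterialParameters.from_dict(material))
    if "seed" in overrides:
        overrides["seed"] = int(overrides["seed"])
    if "rates" in overrides:
        overrides["rates"] = tuple(float(r) for r in overrides["rates"])
    if "rupture_anchors" in overrides:
        overrides["rupture_anchors"] = tuple(
            (float(a), float(b)) for a, b in overrides["rupture_anchors"]
        )
    return replace(recipe, **overrides)


def _stage(logger: logging.Logger, name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.error("stage %s: FAILED: %s", name, exc)
                if isinstance(exc, RenomechError) and not getattr(exc, "_staged", False):
                    exc._staged = True
                    exc.args = (f"stage '{name}': {exc}",)
            else:
                logger.info("stage %s: done", name)

    return _Ctx()


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the full calibration pipeline described by ``config``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger("renomech.pipeline")
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    try:
        return _run(config, outdir, logger)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path, logger: logging.Logger) -> PipelineReport:
    cal = dict(config.calibration)
    cal_config = CalibrationConfig(
        steps=int(cal.get("steps", 2000)),
        mu=float(cal.get("mu", 0.495)),
        fit_alpha=bool(cal.get("fit_alpha", False)),
        n_rounds=int(cal.get("n_rounds", 2)),
    )
    n_branches = int(cal.get("n_branches", 2))
    vary = str(cal.get("vary", "alternating"))

    recipe = _build_recipe(config)
    logger.info("config hash %s, seed %d", config.canonical_hash(), config.seed)

    with _stage(logger, "data"):
        if config.mode == "generate":
            tension_ds = generate_tension_dataset(recipe)
            relax_ds = generate_relaxation_dataset(recipe)
            write_dataset(tension_ds, outdir / "data" / "tension", xlsx=config.xlsx)
            write_dataset(relax_ds, outdir / "data" / "relaxation", xlsx=config.xlsx)
            tension_tables = dataset_to_curves(tension_ds, "tension")
            relax_tables = dataset_to_curves(relax_ds, "relaxation")
        else:
            tension_tables = read_curves(config.inputs["tension"], "tension")
            relax_tables = read_curves(config.inputs["relaxation"], "relaxation")
        logger.info(
            "%d tension curves, %d relaxation curves",
            len(tension_tables), len(relax_tables),
        )

    with _stage(logger, "fit_prony"):
        norm = [
            PronyRelaxationModel.from_dataframe(t.data, n_branches=n_branches)
            for t in relax_tables
        ]
        # average normalized traces on the first trace's time grid
        grid = norm[0].time_s
        mean_m = np.mean(
            [np.interp(grid, m.time_s, m.values) for m in norm], axis=0
        )
        prony_fit = PronyRelaxationModel(
            grid, mean_m, n_branches=n_branches, ramp_time=norm[0].ramp_time
        ).fit()
        logger.info("prony fit:\n%s", prony_fit.summary())

    with _stage(logger, "fit_tension"):
        start = _start_from_config(cal, cal_config, prony_fit.series)
        curves = [
            TensionCurve(
                eng_strain=t.data["eng_strain"].to_numpy(),
                eng_stress_MPa=t.data["eng_stress_MPa"].to_numpy(),
                rate=t.rate,
                sample_id=t.sample_id,
            )
            for t in tension_tables
        ]
        model = TensionCalibrationModel(curves, prony_fit.series, cal_config)
        fit = model.fit(vary=vary, start=start)
        for meta in fit.result.convergence:
            logger.debug("optimizer stage detail: %s", meta)
        logger.info("tension fit (initial spectrum):\n%s", fit.summary())

    if bool(cal.get("refine_prony", True)):
        with _stage(logger, "refine_prony"):
            from .calibration import refine_prony_forward

            refined = refine_prony_forward(
                grid,
                mean_m,
                fit.params,
                ramp_displacement=recipe.ramp_displacement_mm,
                gauge_length=recipe.gauge_length_mm,
                ramp_rate=recipe.ramp_rate_mm_per_min,
                hold_time=recipe.hold_time_s,
                n_branches=n_branches,
                steps=min(cal_config.steps, 600),
                start=prony_fit.series,
            )
            prony_fit.series = refined
            logger.info(
                "refined spectrum: m_inf=%.5g, branches=%s",
                refined.m_inf,
                [(b.m, b.tau) for b in refined.branches],
            )
            model = TensionCalibrationModel(curves, refined, cal_config)
            fit = model.fit(vary=vary, start=start if start is not None else fit.params)
            logger.info("tension fit (refined spectrum):\n%s", fit.summary())

    fit.save(outdir / "params.yaml")

    with _stage(logger, "predict"):
        rates = config.prediction.get("rates")
        if rates is None:
            rates = sorted({c.rate for c in curves})
        rates = [float(r) for r in rates]
        max_strains = [
            min(
                rupture_strain_model(r, recipe.rupture_anchors),
                max(np.max(c.eng_strain) for c in curves if np.isclose(c.rate, r))
                if any(np.isclose(c.rate, r) for c in curves)
                else rupture_strain_model(r, recipe.rupture_anchors),
            )
            for r in rates
        ]
        predicted = fit.predict(rates, max_strains)
        rmse: dict = {}
        rel: dict = {}
        for r, sim in zip(rates, predicted):
            sim.to_csv(outdir / f"predicted_{r:g}.csv")
            same_rate = [c for c in curves if np.isclose(c.rate, r)]
            if same_rate:
                from .calibration import average_curves

                mean_curve = average_curves(same_rate)
                rmse[r], rel[r] = goodness_of_fit(mean_curve, sim)
        logger.info("prediction RMSE by rate: %s", rmse)

    with _stage(logger, "report"):
        report_payload = {
            "seed": config.seed,
            "config_hash": config.canonical_hash(),
            "versions": {
                "renomech": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "recipe": recipe.to_dict() if config.mode == "generate" else None,
            "prony": {
                "m_inf": prony_fit.series.m_inf,
                "branches": [[b.m, b.tau] for b in prony_fit.series.branches],
                "rmse": prony_fit.rmse,
            },
            "material": fit.params.to_dict(),
            "prediction_rmse_MPa": {float(k): float(v) for k, v in rmse.items()},
            "prediction_relative_rmse": {float(k): float(v) for k, v in rel.items()},
        }
        with open(outdir / "report.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(report_payload, fh, sort_keys=True)

    return PipelineReport(
        material=fit.params,
        prony_m_inf=prony_fit.series.m_inf,
        rmse_MPa=rmse,
        relative_rmse=rel,
        seed=config.seed,
        config_hash=config.canonical_hash(),
        outdir=outdir,
        summary_text=fit.summary(),
    )


def _start_from_config(cal: dict, cal_config: CalibrationConfig, prony):
    """Build start/fixed parameter values from config, or None for defaults."""
    fixed_d = cal.get("fixed_damage")
    fixed_h = cal.get("fixed_hyperelastic")
    if fixed_d is None and fixed_h is None:
        return None
    damage = (
        DamageParameters(**fixed_d)
        if fixed_d is not None
        else DamageParameters(alpha=cal_config.alpha_fixed, beta=1e-4, n_exp=2.0)
    )
    hyper = (
        HyperelasticCoefficients(mu=cal_config.mu, **fixed_h)
        if fixed_h is not None
        else HyperelasticCoefficients(C10=1e-2, C20=0.0, C30=0.0, mu=cal_config.mu)
    )
    return MaterialParameters(hyperelastic=hyper, damage=damage, prony=prony)
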