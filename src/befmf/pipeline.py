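"""End-to-end pipeline: generate or load tables, run the enabled analyses,
write tidy CSV/JSON outputs plus a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import derive_seed
from .covariates import pca_first_axis
from .multifunctionality import (
    Multifunctionality,
    composite_richness,
    multithreshold_counts,
    threshold_slope_curve,
    validate_service_map,
    THRESHOLD_GRID,
)
from .associations import ModelAveraging, spearman
from .sem import PiecewiseSEM, SEMSpec
from .synthetic import (
    MicrocosmConfig,
    SurveyConfig,
    generate_microcosm,
    generate_survey,
)
from .varpart import VariancePartition

log = logging.getLogger("befmf")

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "ValidationReport"]


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    mode: str = "microcosm"  # microcosm | survey | user
    seed: int = 1
    out_dir: str = "befmf_out"
    stages: tuple = ("emf", "thresholds", "associations", "varpart", "modelavg")
    # user mode: paths to input CSVs
    functions_csv: str | None = None
    diversity_csv: str | None = None
    design_csv: str | None = None
    service_map: dict | None = None
    transform_map: dict = field(default_factory=dict)
    sem_spec: dict | None = None
    generator_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.mode not in ("microcosm", "survey", "user"):
            raise ValueError(f"unknown mode {cfg.mode!r}")
        if cfg.mode == "user":
            for attr in ("functions_csv", "diversity_csv"):
                p = getattr(cfg, attr)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{attr} missing or not found: {p}")
        return cfg

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: (tuple(v) if isinstance(v, list) else v) for k, v in self.__dict__.items()},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    functions: pd.DataFrame,
    diversity: pd.DataFrame | None = None,
    design: pd.DataFrame | None = None,
    service_map: dict | None = None,
) -> ValidationReport:
    """Structural checks on the input tables.

    Fatal errors: duplicated sample ids, service-map functions missing
    from the matrix, constant function columns, misaligned ids. Warnings:
    missing cells (with per-column counts).
    """
    rep = ValidationReport()
    for name, tab in (("functions", functions), ("diversity", diversity), ("design", design)):
        if tab is None:
            continue
        dup = tab.index[tab.index.duplicated()].unique().tolist()
        if dup:
            rep.errors.append(f"{name}: duplicated sample ids {dup}")
    if service_map is not None:
        try:
            validate_service_map(service_map, functions.columns)
        except (ValueError, KeyError) as exc:
            rep.errors.append(f"service map: {exc}")
    for col in functions.columns:
        v = functions[col].dropna()
        if v.nunique() < 2:
            rep.errors.append(f"functions: column {col!r} is constant")
    for name, tab in (("diversity", diversity), ("design", design)):
        if tab is not None and not tab.index.equals(functions.index):
            common = tab.index.intersection(functions.index)
            if len(common) < len(functions):
                rep.errors.append(
                    f"{name}: ids not aligned with function matrix "
                    f"({len(common)}/{len(functions)} shared)"
                )
    n_missing = functions.isna().sum()
    if n_missing.any():
        frac = functions.isna().to_numpy().mean()
        rep.warnings.append(
            f"functions: {frac:.1%} missing cells; per-column: "
            + ", ".join(f"{c}={int(k)}" for c, k in n_missing[n_missing > 0].items())
        )
    return rep


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "befmf",
        "version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "stages": list(config.stages),
        "outputs": [],
    }

    log.info("stage: inputs (%s mode)", config.mode)
    if config.mode == "microcosm":
        gcfg = MicrocosmConfig(**config.generator_overrides)
        design, diversity, functions, truth = generate_microcosm(gcfg, seed=config.seed)
        service_map = config.service_map or gcfg.service_map
        truth.to_json(out / "ground_truth.json")
    elif config.mode == "survey":
        gcfg = SurveyConfig(**config.generator_overrides)
        design, diversity, functions, truth = generate_survey(gcfg, seed=config.seed)
        service_map = config.service_map or gcfg.service_map
        truth.to_json(out / "ground_truth.json")
    else:
        functions = pd.read_csv(config.functions_csv, index_col=0)
        diversity = pd.read_csv(config.diversity_csv, index_col=0)
        design = (
            pd.read_csv(config.design_csv, index_col=0) if config.design_csv else None
        )
        if config.service_map is None:
            raise ValueError("user mode requires a service_map")
        service_map = config.service_map

    report = validate_inputs(functions, diversity, design, service_map)
    for w in report.warnings:
        log.warning(w)
    if not report.ok:
        raise ValueError("input validation failed: " + "; ".join(report.errors))

    for name, tab in (("design", design), ("diversity", diversity), ("functions", functions)):
        if tab is not None:
            _write(tab, out / f"{name}.csv")
            manifest["outputs"].append(f"{name}.csv")
    manifest["n_samples"] = int(len(functions))
    manifest["n_functions"] = int(functions.shape[1])
    manifest["services"] = {s: list(m) for s, m in service_map.items()}
    manifest["n_services"] = len(service_map)

    emf_res = None
    if "emf" in config.stages:
        log.info("stage: emf")
        emf_res = Multifunctionality(functions, service_map, config.transform_map).fit()
        _write(emf_res.to_frame(), out / "multifunctionality.csv")
        manifest["outputs"].append("multifunctionality.csv")

    richness_cols = [c for c in diversity.columns if c.endswith("richness")]
    composite = composite_richness(diversity[richness_cols]) if richness_cols else None

    if "thresholds" in config.stages and composite is not None:
        log.info("stage: thresholds")
        counts = multithreshold_counts(functions, THRESHOLD_GRID)
        profile = threshold_slope_curve(composite.to_numpy(), counts)
        _write(profile.slopes, out / "threshold_slopes.csv")
        manifest["outputs"].append("threshold_slopes.csv")

    if "associations" in config.stages and emf_res is not None:
        log.info("stage: associations")
        rows = []
        for col in richness_cols:
            res = spearman(
                diversity[col].to_numpy(),
                emf_res.emf_weighted.to_numpy(),
                names=(col, "emf_weighted"),
            )
            rows.append(
                {"x": col, "y": "emf_weighted", "rho": res.coefficient, "p": res.p, "n": res.n}
            )
        _write(pd.DataFrame(rows).set_index("x"), out / "associations.csv")
        manifest["outputs"].append("associations.csv")

    if "varpart" in config.stages and emf_res is not None:
        log.info("stage: varpart")
        groups = _default_groups(config.mode, design, diversity)
        if groups:
            vp = VariancePartition(emf_res.emf_weighted.to_numpy(), groups).fit_with_tests(
                n_perm=199, seed=derive_seed(config.seed, "varpart")
            )
            _write(vp.to_frame().set_index("fraction"), out / "varpart.csv")
            manifest["outputs"].append("varpart.csv")

    if "modelavg" in config.stages and emf_res is not None:
        log.info("stage: modelavg")
        X = _default_predictors(config.mode, design, diversity)
        if X is not None:
            ma = ModelAveraging(emf_res.emf_weighted.to_numpy(), X).fit()
            tab = pd.DataFrame(
                {
                    "beta_avg": ma.coefficients,
                    "se": ma.coefficient_se,
                    "importance_pct": ma.importance_pct,
                }
            )
            tab["r2adj_averaged"] = ma.r2adj_averaged
            _write(tab, out / "model_averaging.csv")
            manifest["outputs"].append("model_averaging.csv")

    if "sem" in config.stages and config.sem_spec is not None:
        log.info("stage: sem")
        spec = SEMSpec.from_dict(config.sem_spec)
        frames = [functions, diversity]
        if design is not None:
            frames.append(design)
        if emf_res is not None:
            frames.append(emf_res.to_frame())
        data = pd.concat(frames, axis=1)
        data = data.loc[:, ~data.columns.duplicated()]
        fit = PiecewiseSEM(spec, data).fit()
        _write(fit.paths.set_index(["from", "to"]), out / "sem_paths.csv")
        (out / "sem_fit.json").write_text(
            json.dumps(
                {
                    "schema": 1,
                    "C": fit.C,
                    "df": fit.df,
                    "p_C": fit.p_C,
                    "AIC": fit.aic,
                    "saturated": fit.saturated,
                    "r2": fit.r2,
                },
                indent=2,
            )
        )
        manifest["outputs"] += ["sem_paths.csv", "sem_fit.json"]

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("done: %d outputs in %s", len(manifest["outputs"]), out)
    return manifest


def _default_groups(mode: str, design, diversity) -> dict | None:
    if mode == "microcosm":
        return {
            "plant": diversity["plant_richness"].to_numpy(dtype=float),
            "microbial": diversity["microbial_composite"].to_numpy(dtype=float),
            "drought": design["drought"].to_numpy(dtype=float),
        }
    if mode == "survey":
        env_cols = [
            c
            for c in ("soil_pH", "MAT", "clay_pct", "soil_C", "plant_cover_pct", "distance_equator")
            if c in design.columns
        ]
        return {
            "plant": diversity["plant_richness"].to_numpy(dtype=float),
            "microbial": composite_richness(
                diversity[["bacteria_richness", "fungi_richness"]]
            ).to_numpy(),
            "environment": pca_first_axis(design[env_cols]).scores.to_numpy(),
            "aridity": design["aridity_index"].to_numpy(dtype=float),
        }
    return None


def _default_predictors(mode: str, design, diversity) -> pd.DataFrame | None:
    if mode == "microcosm":
        return pd.DataFrame(
            {
                "plant_richness": diversity["plant_richness"].astype(float),
                "microbial_richness": diversity["microbial_composite"],
                "drought": design["drought"].astype(float),
            }
        )
    if mode == "survey":
        env_cols = [
            c
            for c in ("soil_pH", "MAT", "clay_pct", "soil_C", "plant_cover_pct", "distance_equator")
            if c in design.columns
        ]
        return pd.DataFrame(
            {
                "plant_richness": diversity["plant_richness"].astype(float),
                "bacterial_richness": diversity["bacteria_richness"].astype(float),
                "fungal_richness": diversity["fungi_richness"].astype(float),
                "environment": pca_first_axis(design[env_cols]).scores,
                "aridity_index": design["aridity_index"].astype(float),
            }
        )
    return None
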