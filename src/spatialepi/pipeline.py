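"""End-to-end orchestration: weights -> global Moran table -> LISA maps ->
spatial regressions -> AIC model comparison, from a single config.

A master seed drives derived per-stage seeds (stable hashing of the stage
name), so any stage re-run in isolation reproduces its piece of the run.
All tabular outputs are written deterministically: identical config, inputs
and seed give byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .errors import ConfigError, SpatialEpiError
from .geo_io import (align, read_attributes, read_polygons, write_gal,
                     write_lisa_geojson)
from .global_moran import global_moran, global_moran_bivariate
from .local_moran import cluster_counts, lisa
from .regression import (DesignMatrix, compare_models, fit_ols,
                         fit_spatial_error, fit_spatial_lag)
from .weights import queen_adjacency, row_standardize, shared_border_adjacency

__all__ = ["PipelineConfig", "PipelineReport", "validate_config",
           "run_pipeline"]

logger = logging.getLogger("spatialepi.pipeline")

_KNOWN_KEYS = {
    "polygons", "id_field", "attributes", "outcome", "covariates",
    "weights_scheme", "standardize", "snap_tolerance", "permutations",
    "alpha", "seed", "models", "output_dir", "check_range",
}
_SCHEMES = {"queen", "shared_border"}
_MODELS = {"ols", "slm", "sem"}


@dataclass
class PipelineConfig:
    polygons: str
    attributes: str
    outcome: str
    covariates: list[str]
    output_dir: str
    id_field: str = "unit_id"
    weights_scheme: str = "queen"
    standardize: bool = True
    snap_tolerance: float = 1e-7
    permutations: int = 999
    alpha: float = 0.05
    seed: int = 42
    models: list[str] = field(default_factory=lambda: ["ols", "slm", "sem"])
    check_range: bool = True


@dataclass
class PipelineReport:
    table1: pd.DataFrame
    lisa_outputs: dict[str, dict]     # analysis name -> {path, counts}
    table2: pd.DataFrame
    comparison: pd.DataFrame
    files: dict[str, str]
    metadata: dict


def validate_config(raw: dict) -> PipelineConfig:
    """Validate a parsed YAML/JSON config mapping and fill defaults."""
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("polygons", "attributes", "outcome", "covariates", "output_dir"):
        if key not in raw:
            raise ConfigError(f"missing required config key {key!r}")
    cfg = PipelineConfig(**raw)
    if not isinstance(cfg.covariates, list) or not cfg.covariates:
        raise ConfigError("covariates must be a non-empty list")
    if cfg.outcome in cfg.covariates:
        raise ConfigError(f"outcome {cfg.outcome!r} listed among covariates")
    if not (0 < cfg.alpha < 1):
        raise ConfigError(f"alpha must be in (0, 1), got {cfg.alpha}")
    if cfg.permutations < 19:
        raise ConfigError("permutations must be >= 19")
    if cfg.weights_scheme not in _SCHEMES:
        raise ConfigError(f"unknown weights_scheme {cfg.weights_scheme!r}")
    bad = set(cfg.models) - _MODELS
    if bad or not cfg.models:
        raise ConfigError(f"unknown model(s): {sorted(bad)}")
    return cfg


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2 ** 31)


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", name).strip("_").lower()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis and write every artifact to output_dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    stage = "load"
    try:
        logger.info("stage load: reading %s / %s", config.polygons,
                    config.attributes)
        frame = read_polygons(config.polygons, config.id_field)
        table = align(frame, read_attributes(config.attributes, config.id_field,
                                             check_range=config.check_range))
        for name in [config.outcome] + config.covariates:
            if name not in table.variables:
                raise ConfigError(f"variable {name!r} not in attribute table")

        stage = "weights"
        build = (queen_adjacency if config.weights_scheme == "queen"
                 else shared_border_adjacency)
        binary = build(frame, config.snap_tolerance)
        logger.info("stage weights: n=%d, islands=%d", binary.n,
                    len(binary.islands))
        gal_path = out / "weights.gal"
        write_gal(binary, gal_path, id_field=config.id_field)
        files["weights"] = str(gal_path)
        weights = row_standardize(binary) if config.standardize else binary

        stage = "global_moran"
        moran_seed = _stage_seed(config.seed, "global_moran")
        rows = []
        variables = [config.outcome] + config.covariates
        y_out = table.variable(config.outcome)
        for idx, name in enumerate(variables):
            uni = global_moran(weights, table.variable(name), name,
                               permutations=config.permutations,
                               seed=moran_seed + 2 * idx)
            if name == config.outcome:
                biv_i, biv_p = float("nan"), float("nan")
            else:
                biv = global_moran_bivariate(
                    weights, y_out, table.variable(name),
                    config.outcome, name,
                    permutations=config.permutations,
                    seed=moran_seed + 2 * idx + 1)
                biv_i, biv_p = biv.statistic, biv.pseudo_p
            rows.append({"variable": name,
                         "univariate_moran_i": uni.statistic,
                         "univariate_p": uni.pseudo_p,
                         "bivariate_moran_i": biv_i,
                         "bivariate_p": biv_p})
        table1 = pd.DataFrame(rows)
        table1_path = out / "table1.csv"
        table1.to_csv(table1_path, index=False, float_format="%.6f")
        files["table1"] = str(table1_path)

        stage = "lisa"
        lisa_seed = _stage_seed(config.seed, "lisa")
        lisa_outputs = {}
        count_rows = []
        analyses = [(config.outcome, None)] + [(config.outcome, cov)
                                               for cov in config.covariates]
        for idx, (var_x, var_y) in enumerate(analyses):
            key = _slug(var_x) if var_y is None else _slug(var_y)
            stats = lisa(
                weights, table.variable(var_x),
                None if var_y is None else table.variable(var_y),
                variable_x=var_x, variable_y=var_y,
                permutations=config.permutations,
                seed=lisa_seed + idx, alpha=config.alpha)
            path = out / f"lisa_{key}.geojson"
            write_lisa_geojson(frame, stats, path)
            counts = cluster_counts(stats)
            lisa_outputs[key] = {"path": str(path), "counts": counts,
                                 "x": var_x, "y": var_y}
            count_rows.append({"analysis": key, "x": var_x,
                               "y": var_y or "", **counts})
            logger.info("stage lisa: %s -> %d hotspots", key,
                        counts["hotspot"])
        counts_path = out / "cluster_counts.csv"
        pd.DataFrame(count_rows).to_csv(counts_path, index=False)
        files["cluster_counts"] = str(counts_path)

        stage = "regression"
        design = DesignMatrix.from_table(table, config.outcome,
                                         config.covariates)
        fitters = {"ols": lambda: fit_ols(design),
                   "slm": lambda: fit_spatial_lag(weights, design),
                   "sem": lambda: fit_spatial_error(weights, design)}
        results = [fitters[m]() for m in config.models]
        comparison = compare_models(results) if len(results) > 1 else None
        table2 = _table2_frame(results)
        table2_path = out / "table2.csv"
        table2.to_csv(table2_path, index=False, float_format="%.6f")
        files["table2"] = str(table2_path)

        stage = "report"
        metadata = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "n_units": frame.n,
            "islands": sorted(binary.islands),
            "config": asdict(config),
        }
        report_path = out / "report.json"
        with open(report_path, "w") as fh:
            json.dump({"metadata": metadata, "files": files,
                       "cluster_counts": count_rows,
                       "model_ranking": (comparison["model"].tolist()
                                         if comparison is not None else
                                         [r.model_kind for r in results])},
                      fh, indent=2, sort_keys=True)
        files["report"] = str(report_path)
    except SpatialEpiError as exc:
        raise type(exc)(f"pipeline stage {stage!r}: {exc}") from exc

    if comparison is None:
        comparison = _table2_frame(results)
    return PipelineReport(table1=table1, lisa_outputs=lisa_outputs,
                          table2=table2, comparison=comparison,
                          files=files, metadata=metadata)


def _table2_frame(results) -> pd.DataFrame:
    """Model-comparison table shaped like a published regression table:
    one row per predictor with coefficient and p per model, then the
    spatial parameters, AIC, R-squared and n, models ordered by AIC."""
    order = sorted(range(len(results)), key=lambda i: results[i].aic)
    ordered = [results[i] for i in order]
    predictor_names = list(ordered[0].coefficients)
    rows = []
    for name in predictor_names:
        row = {"term": name}
        for res in ordered:
            coef = res.coefficients[name]
            row[f"{res.model_kind}_coef"] = coef.estimate
            row[f"{res.model_kind}_p"] = coef.p_value
        rows.append(row)
    for label, getter in (
        ("rho_delta", lambda r: (r.spatial_parameter[1].estimate
                                 if r.model_kind == "slm" else float("nan"))),
        ("lambda", lambda r: (r.spatial_parameter[1].estimate
                              if r.model_kind == "sem" else float("nan"))),
        ("aic", lambda r: r.aic),
        ("r2", lambda r: r.r2),
        ("n", lambda r: r.n),
    ):
        row = {"term": label}
        for res in ordered:
            row[f"{res.model_kind}_coef"] = getter(res)
            row[f"{res.model_kind}_p"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
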