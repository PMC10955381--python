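"""End-to-end orchestration: DAG validation, data acquisition,
complete-case filtering, fitting, g-computation, optional
poststratification, and reproducible output writing.

Every output embeds the configuration hash and master seed; a rerun with
the same config file is byte-identical.  Row counts are reconciled in the
run log (input = used + dropped + invalid) — the pipeline never imputes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, dag as dag_mod, gcomp, io as io_mod, poststrat
from .dag import AdjustmentQuery
from .model import (
    MODEL_COLUMNS,
    ModelSpec,
    PosteriorDraws,
    diagnostics,
    fit,
)
from .simulate import ScmParams, inject_missingness, simulate_population

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("ordcausal")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int
    input_csv: Optional[str] = None
    simulate: dict = field(default_factory=dict)
    missing_rate: float = 0.0
    outcomes: tuple = ("think_freq", "ritual_freq")
    exposures: tuple = ("food_insecure", "education")
    education_levels: tuple = gcomp.DEFAULT_EDUCATION_LEVELS
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.8
    max_treedepth: int = 10
    thin_to: int = 500
    by_site: bool = True
    interval: float = 0.95
    rhat_threshold: float = 1.01
    allow_nonconverged: bool = False
    dag_path: Optional[str] = None
    strata_path: Optional[str] = None
    write_per_individual: bool = False
    write_draws: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise PipelineError("config", "seed is mandatory")
        for name in ("outcomes", "exposures", "education_levels"):
            object.__setattr__(self, name, tuple(getattr(self, name)))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        """Hash of the result-affecting settings (output location excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _validate_dag(config: PipelineConfig) -> dict:
    if config.dag_path:
        graph = dag_mod.read_edge_list(config.dag_path)
    else:
        graph = dag_mod.build_survey_dag()
    checks = {}
    food_set = frozenset({"Sex", "Age", "Education", "Children"})
    edu_set = frozenset({"Sex", "Age", "Children", "FoodInsecurity"})
    queries = {
        "food_insecure": ("FoodInsecurity", food_set),
        "education": ("Education", edu_set),
    }
    for name, (exposure, zset) in queries.items():
        zset = zset & graph.observed
        ok = dag_mod.backdoor_valid(
            graph, AdjustmentQuery(exposure, "Religiosity", zset)
        )
        checks[name] = {"adjustment_set": sorted(zset), "valid": bool(ok)}
        if not ok:
            raise PipelineError(
                "validate-dag",
                f"adjustment set {sorted(zset)} does not identify the "
                f"{exposure} -> Religiosity effect under the supplied DAG",
            )
    return checks


def _acquire_data(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    accounting: dict = {}
    if config.input_csv:
        result = io_mod.read_survey_csv(config.input_csv)
        table = result.valid_table
        accounting["input_rows"] = result.n_rows
        accounting["invalid_rows"] = result.n_invalid
        accounting["missing_cells"] = {
            k: int(v) for k, v in result.missingness.items()
        }
    else:
        params = ScmParams(**{"seed": config.seed, **config.simulate})
        table = simulate_population(params)
        if config.missing_rate > 0:
            table = inject_missingness(
                table, config.missing_rate, seed=config.seed + 1
            )
        accounting["input_rows"] = len(table)
        accounting["invalid_rows"] = 0
        accounting["simulated"] = True
    return table, accounting


def _grid_for(exposure: str, config: PipelineConfig) -> gcomp.ExposureGrid:
    if exposure == "food_insecure":
        return gcomp.ExposureGrid.food()
    return gcomp.ExposureGrid.education(config.education_levels)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns a manifest of outputs."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stamp = f"config={chash} seed={config.seed} ordcausal={__version__}"
    run_log: dict = {
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": config.seed,
        "version": __version__,
        "outputs": [],
    }

    try:
        run_log["dag_checks"] = _validate_dag(config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("validate-dag", str(exc)) from exc
    log.info("DAG identification checks passed")

    try:
        table, accounting = _acquire_data(config)
    except Exception as exc:
        raise PipelineError("data", str(exc)) from exc
    run_log["rows"] = accounting

    strata = None
    if config.strata_path:
        try:
            strata = poststrat.StrataTable.from_csv(config.strata_path)
        except Exception as exc:
            raise PipelineError("strata", str(exc)) from exc

    manifest = {"run_log": str(out_dir / "run_log.json")}
    for oi, outcome in enumerate(config.outcomes):
        stage = f"fit:{outcome}"
        try:
            used = io_mod.complete_cases(
                table, list(MODEL_COLUMNS) + [outcome]
            )
            accounting[f"{outcome}_complete_cases"] = len(used)
            accounting[f"{outcome}_dropped"] = (
                accounting["input_rows"] - accounting["invalid_rows"]
                - len(used)
            )
            spec = ModelSpec.from_table(used, outcome)
            draws = fit(
                used, spec, chains=config.chains, warmup=config.warmup,
                draws=config.draws, seed=config.seed + oi,
                target_accept=config.target_accept,
                max_treedepth=config.max_treedepth,
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        report = diagnostics(draws, rhat_threshold=config.rhat_threshold)
        run_log[f"diagnostics_{outcome}"] = {
            "max_rhat": None if np.isnan(report.max_rhat)
            else report.max_rhat,
            "n_divergent": report.n_divergent,
            "flagged": report.flagged,
        }
        log.info("fit %s:\n%s", outcome, report)
        if not report.ok and not config.allow_nonconverged:
            raise PipelineError(
                f"diagnostics:{outcome}",
                f"sampler did not converge: {report}".replace("\n", "; "),
            )

        if config.write_draws:
            draws_path = out_dir / f"draws_{outcome}.csv"
            draws.to_csv(draws_path)
            manifest[f"draws_{outcome}"] = str(draws_path)

        thinned = draws.thin(config.thin_to)
        for exposure in config.exposures:
            stage = f"gcomp:{outcome}:{exposure}"
            try:
                grid = _grid_for(exposure, config)
                pot = gcomp.impute_potential_outcomes(thinned, used, grid)
                summary = gcomp.marginalize(
                    pot, used, grid, by_site=config.by_site,
                    interval=config.interval,
                    keep_individual=config.write_per_individual,
                )
                base = f"summary_{outcome}_{exposure}"
                path = out_dir / f"{base}.csv"
                summary.to_csv(path, header_comment=stamp)
                manifest[base] = str(path)
                if config.write_per_individual:
                    ipath = out_dir / f"individual_{outcome}_{exposure}.csv"
                    summary.per_individual_to_csv(ipath)
                    manifest[f"individual_{outcome}_{exposure}"] = str(ipath)
                cpath = out_dir / f"contrast_{outcome}_{exposure}.csv"
                ctr = gcomp.contrast(
                    pot, used, grid, grid.levels[0], grid.levels[-1],
                    by_site=config.by_site, interval=config.interval,
                )
                with open(cpath, "w") as fh:
                    fh.write(f"# {stamp}\n")
                    ctr.to_csv(fh, index=False, lineterminator="\n")
                manifest[f"contrast_{outcome}_{exposure}"] = str(cpath)

                if strata is not None:
                    pot_pop = gcomp.impute_potential_outcomes(
                        thinned, used, grid, population_level=True
                    )
                    ps = poststrat.poststratify(
                        pot_pop, strata, used, grid,
                        interval=config.interval,
                    )
                    ppath = out_dir / f"poststrat_{outcome}_{exposure}.csv"
                    ps.to_csv(ppath, header_comment=stamp)
                    manifest[f"poststrat_{outcome}_{exposure}"] = str(ppath)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc

    # reconciliation: input = invalid + (complete + dropped) per outcome
    for outcome in config.outcomes:
        used_n = accounting[f"{outcome}_complete_cases"]
        dropped = accounting[f"{outcome}_dropped"]
        total = used_n + dropped + accounting["invalid_rows"]
        if total != accounting["input_rows"]:  # pragma: no cover
            raise PipelineError(
                "accounting", f"row reconciliation failed for {outcome}"
            )
    run_log["rows"] = accounting
    run_log["outputs"] = sorted(manifest)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
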