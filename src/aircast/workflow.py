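"""End-to-end workflow runner with a reproducibility manifest.

``run_workflow`` chains simulate/ingest -> decompose -> tune -> forecast ->
evaluate (-> burden when baseline deaths are given) and writes every
artifact plus a manifest JSON capturing the configuration, seed, package
versions, stage timings and the metric outputs — enough to regenerate the
run from scratch.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .cnnlstm import ForecastModelSpec
from .decomposition import decompose
from .evaluation import percent_reduction
from .health import burden_table
from .io import read_panel_csv, write_panel_csv
from .model import HybridForecaster
from .panel import PollutantPanel
from .pipeline import PipelineConfig, persistence_forecast
from .pso import PSOConfig
from .synthetic import PanelSpec, generate_panel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one workflow run."""

    target: str = "PM25"
    panel_csv: str | None = None       # None = simulate a synthetic panel
    seed: int = 0
    decomposition: str = "ceemdan"
    use_covariates: bool = True
    tune: bool = False
    pso: PSOConfig | None = None
    spec: ForecastModelSpec = field(default_factory=ForecastModelSpec)
    pipeline: PipelineConfig | None = None
    baseline_deaths: float | None = None  # annual deaths; enables the burden stage
    burden_year: int = 2021

    def resolved_pipeline(self) -> PipelineConfig:
        cfg = self.pipeline or PipelineConfig()
        return replace(cfg, decomposition=self.decomposition,
                       use_covariates=self.use_covariates, seed=self.seed)


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def run_workflow(config: RunConfig, outdir) -> Path:
    """Execute all stages; returns the artifact directory.

    Any stage failure raises with the stage name; artifacts of completed
    stages are left in place.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "aircast_version": __version__,
        "seed": config.seed,
        "config": _to_jsonable(asdict(config)),
        "stages": {},
    }
    stage = "setup"
    try:
        # -- simulate / ingest ------------------------------------------
        stage = "data"
        t0 = time.perf_counter()
        if config.panel_csv is None:
            panel = generate_panel(PanelSpec(seed=config.seed))
            write_panel_csv(panel, out / "panel.csv")
            source = "synthetic"
        else:
            panel = read_panel_csv(config.panel_csv)
            source = str(config.panel_csv)
        manifest["stages"]["data"] = {
            "source": source, "n_days": len(panel), "seconds": time.perf_counter() - t0,
        }

        pcfg = config.resolved_pipeline()

        # -- decompose ---------------------------------------------------
        if pcfg.decomposition != "none":
            stage = "decompose"
            t0 = time.perf_counter()
            imfset = decompose(
                panel.series(config.target).to_numpy(),
                pcfg.decomposition,
                pcfg.decomp_config,
            )
            imfset.to_frame().to_csv(out / "decomposition.csv", index=False)
            manifest["stages"]["decompose"] = {
                "method": pcfg.decomposition,
                "n_imfs": len(imfset),
                "seconds": time.perf_counter() - t0,
            }

        # -- tune --------------------------------------------------------
        model = HybridForecaster(
            panel, target=config.target, spec=config.spec, config=pcfg
        )
        if config.tune:
            stage = "tune"
            t0 = time.perf_counter()
            spec = model.tune(config.pso)
            manifest["stages"]["tune"] = {
                "window": spec.window,
                "cells": spec.cells,
                "fitness": model.tuning_result.best_fitness,
                "history": model.tuning_result.history,
                "seconds": time.perf_counter() - t0,
            }
            (out / "tuning.json").write_text(
                json.dumps(_to_jsonable(manifest["stages"]["tune"]), indent=2)
            )

        # -- forecast ----------------------------------------------------
        stage = "forecast"
        t0 = time.perf_counter()
        res = model.fit()
        frame = res.to_frame()
        frame.insert(0, "date", frame.index.strftime("%Y-%m-%d"))
        frame.to_csv(out / "predictions.csv", index=False)
        manifest["stages"]["forecast"] = {
            "window": res.model_spec.window,
            "cells": res.model_spec.cells,
            "n_components": int(res.component_predictions.shape[0]),
            "seconds": time.perf_counter() - t0,
        }

        # -- evaluate ----------------------------------------------------
        stage = "evaluate"
        t0 = time.perf_counter()
        base = persistence_forecast(panel, config.target, pcfg.split)
        report = {
            "model": res.metrics.as_dict(),
            "persistence": base.metrics.as_dict(),
            "rmse_reduction_vs_persistence_pct": percent_reduction(
                base.metrics.rmse, res.metrics.rmse
            ),
        }
        (out / "metrics.json").write_text(json.dumps(_to_jsonable(report), indent=2))
        manifest["stages"]["evaluate"] = {
            **report, "seconds": time.perf_counter() - t0,
        }

        # -- burden (optional) ------------------------------------------
        if config.baseline_deaths is not None:
            stage = "burden"
            t0 = time.perf_counter()
            table = burden_table(panel, config.baseline_deaths, year=config.burden_year)
            table.to_csv(out / "burden.csv", index=False)
            manifest["stages"]["burden"] = {
                "baseline_deaths": config.baseline_deaths,
                "year": config.burden_year,
                "seconds": time.perf_counter() - t0,
            }
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(_to_jsonable(manifest), indent=2))
        raise RuntimeError(f"workflow stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(_to_jsonable(manifest), indent=2))
    logger.info("workflow complete: %s", out)
    return out
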