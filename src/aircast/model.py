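"""Model/Results front-end for the hybrid forecaster.

``HybridForecaster`` is built from a :class:`~aircast.panel.PollutantPanel`
and a target pollutant; ``fit()`` returns a
:class:`HybridForecastResults` carrying the reconstructed forecast, the
accuracy metrics, the per-component predictions and a ``summary()`` table.

    >>> model = HybridForecaster(panel, target="PM25")
    >>> model.tune()                      # optional PSO search
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cnnlstm import ForecastModelSpec
from .evaluation import metrics_report, percent_reduction
from .panel import PollutantPanel
from .pipeline import (
    ForecastResult,
    PipelineConfig,
    SplitSpec,
    forecast_hybrid,
    persistence_forecast,
    tune_hyperparameters,
)
from .pso import PSOConfig, PSOResult


class HybridForecaster:
    """Decomposition-ensemble pollutant forecaster.

    Parameters
    ----------
    panel
        Six-channel daily concentration panel.
    target
        Channel to forecast (default PM25).
    decomposition
        ``ceemdan`` (default), ``eemd``, ``emd`` or ``none``.
    use_covariates
        Feed the five other pollutants as raw covariate channels.
    spec
        Hyperparameters; ``None`` uses defaults until :meth:`tune` is
        called.
    config
        Full :class:`PipelineConfig`; built from the other arguments when
        omitted.
    """

    def __init__(
        self,
        panel: PollutantPanel,
        target: str = "PM25",
        decomposition: str = "ceemdan",
        use_covariates: bool = True,
        spec: ForecastModelSpec | None = None,
        config: PipelineConfig | None = None,
        seed: int = 0,
    ):
        self.panel = panel
        self.target = target
        if config is None:
            config = PipelineConfig(
                decomposition=decomposition, use_covariates=use_covariates, seed=seed
            )
        self.config = config
        self.spec = spec or ForecastModelSpec()
        self.tuning_result: PSOResult | None = None

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, target: str = "PM25", **kwargs
    ) -> "HybridForecaster":
        """Build from a date-indexed DataFrame with the six channels."""
        return cls(PollutantPanel(data), target=target, **kwargs)

    def tune(self, pso_config: PSOConfig | None = None) -> ForecastModelSpec:
        """PSO-search (window, cells); stores and returns the tuned spec."""
        self.spec, self.tuning_result = tune_hyperparameters(
            self.panel, self.target, pso_config, self.config, base_spec=self.spec
        )
        return self.spec

    def fit(self, spec: ForecastModelSpec | None = None) -> "HybridForecastResults":
        """Train the per-component models and forecast the test period."""
        if spec is not None:
            self.spec = spec
        raw = forecast_hybrid(self.panel, self.target, self.spec, self.config)
        return HybridForecastResults(self, raw)


class HybridForecastResults:
    """Fitted-forecast container with summary, comparison and plotting."""

    def __init__(self, model: HybridForecaster, result: ForecastResult):
        self.model = model
        self._result = result

    # direct pass-throughs ------------------------------------------------
    @property
    def dates(self) -> pd.DatetimeIndex:
        return self._result.dates

    @property
    def y_true(self) -> np.ndarray:
        return self._result.y_true

    @property
    def y_pred(self) -> np.ndarray:
        return self._result.y_pred

    @property
    def component_predictions(self) -> np.ndarray:
        return self._result.component_predictions

    @property
    def metrics(self):
        return self._result.metrics

    @property
    def validation_rmse(self) -> float:
        return self._result.validation_rmse

    @property
    def model_spec(self) -> ForecastModelSpec:
        return self._result.model_spec

    @property
    def loss_histories(self):
        return self._result.loss_histories

    def to_frame(self) -> pd.DataFrame:
        return self._result.to_frame()

    def persistence_baseline(self) -> ForecastResult:
        """The naive y_hat_t = y_{t-1} forecast on the same test period."""
        return persistence_forecast(self.model.panel, self.model.target, self.model.config.split)

    def skill_vs_persistence(self) -> float:
        """Percent RMSE reduction relative to the persistence baseline."""
        base = self.persistence_baseline().metrics.rmse
        return percent_reduction(base, self.metrics.rmse)

    def summary(self) -> str:
        m = self.metrics
        cfg = self.model.config
        spec = self.model_spec
        lines = [
            "Hybrid pollutant forecast results",
            "=" * 48,
            f"target:            {self.model.target}",
            f"decomposition:     {cfg.decomposition} ({cfg.decomposition_window} window)",
            f"covariates:        {'on' if cfg.use_covariates else 'off'}",
            f"components:        {self.component_predictions.shape[0]}",
            f"window n:          {spec.window}",
            f"LSTM cells:        {spec.cells}",
            f"test samples:      {m.n}",
            "-" * 48,
            f"RMSE:              {m.rmse:.4f}",
            f"MAE:               {m.mae:.4f}",
            f"R2 (conventional): {m.r2_conventional:.4f}",
            f"R2 (EV ratio):     {m.r2_paper:.4f}",
            f"validation RMSE:   {self.validation_rmse:.4f}",
            f"skill vs persistence: {self.skill_vs_persistence():+.2f}% RMSE",
            "=" * 48,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed vs predicted test-period series."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        ax.plot(self.dates, self.y_true, label="observed", lw=1)
        ax.plot(self.dates, self.y_pred, label="predicted", lw=1)
        ax.set_xlabel("date")
        unit = self.model.panel.units.get(self.model.target, "")
        ax.set_ylabel(f"{self.model.target} ({unit})")
        ax.legend()
        return ax

    def compare_with(self, others: list[tuple[str, ForecastResult]]):
        """Comparison table against other runs on the same test period."""
        from .evaluation import comparison_report

        entries = [("this model", self.metrics)]
        for label, res in others:
            entries.append((label, metrics_report(res.y_true, res.y_pred)))
        return comparison_report(entries)
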