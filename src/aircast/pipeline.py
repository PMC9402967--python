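"""The hybrid forecasting pipeline.

End-to-end flow: split the panel chronologically, decompose the target
pollutant into IMFs + residue, build supervised sliding windows per
component (the component itself plus the five other pollutants as
covariate channels), train one CNN-LSTM per component, predict one step
ahead over the test period, and reconstruct the pollutant forecast as the
sum of the component predictions.  PSO tunes one shared (window, cells)
pair per target series using the validation RMSE of the reconstructed
forecast as fitness.

By default the target series is decomposed ONCE over its full span before
splitting — the convention of the source methodology.  Note that this
lets the decomposition stage see test-period values (the component values
at test time are then not strictly causal); ``decomposition_window =
"expanding"`` re-decomposes using only data up to each forecast origin,
at considerable cost.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cnnlstm import CNNLSTMRegressor, ForecastModelSpec
from .decomposition import DecompositionConfig, decompose
from .evaluation import MetricsReport, metrics_report
from .panel import PollutantPanel
from .pso import HYPERPARAMETER_BOUNDS, PSOConfig, PSOResult, encode_hyperparameters, optimize

# ---------------------------------------------------------------------------
# chronological splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Calendar-year split: train+validation years, held-out test years.

    Validation is the last ``validation_fraction`` (rounded down) of the
    training-period rows — chronological, never shuffled.
    """

    train_years: tuple[int, ...] = (2016, 2017, 2018, 2019, 2020)
    test_years: tuple[int, ...] = (2021,)
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if set(self.train_years) & set(self.test_years):
            raise ValueError("train and test years must be disjoint")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


def split_panel(
    panel: PollutantPanel, split: SplitSpec | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row indices of the (train, validation, test) partitions."""
    spec = split or SplitSpec()
    years = panel.dates.year
    present = set(years)
    missing = [y for y in (*spec.train_years, *spec.test_years) if y not in present]
    if missing:
        raise ValueError(f"panel is missing requested years: {missing}")
    trainval = np.flatnonzero(np.isin(years, spec.train_years))
    test = np.flatnonzero(np.isin(years, spec.test_years))
    n_val = int(len(trainval) * spec.validation_fraction)
    train = trainval[: len(trainval) - n_val]
    val = trainval[len(trainval) - n_val:]
    return train, val, test


# ---------------------------------------------------------------------------
# supervised windows
# ---------------------------------------------------------------------------


@dataclass
class SupervisedWindows:
    """Sliding windows X[t] = rows t-n..t-1 of [component || covariates],
    y[t] = component[t]; min-max scaled to [0, 1] with parameters fitted
    on the training partition only."""

    X: np.ndarray          # (samples, n, channels)
    y: np.ndarray          # (samples,)
    t_index: np.ndarray    # target row index of each sample in the source series
    channel_names: list[str]
    ch_min: np.ndarray     # per-channel scaler parameters (training rows only)
    ch_max: np.ndarray
    scaled: bool = True

    def inverse_scale_y(self, values: np.ndarray) -> np.ndarray:
        """Map target-channel values from [0, 1] back to original units."""
        if not self.scaled:
            return np.asarray(values, dtype=float)
        span = self.ch_max[0] - self.ch_min[0]
        return np.asarray(values, dtype=float) * (span if span > 0 else 1.0) + self.ch_min[0]

    def scale_y(self, values: np.ndarray) -> np.ndarray:
        if not self.scaled:
            return np.asarray(values, dtype=float)
        span = self.ch_max[0] - self.ch_min[0]
        return (np.asarray(values, dtype=float) - self.ch_min[0]) / (span if span > 0 else 1.0)

    def rows(self, t_values: np.ndarray) -> np.ndarray:
        """Positions of the samples whose target index is in *t_values*."""
        return np.flatnonzero(np.isin(self.t_index, t_values))


def make_windows(
    component: np.ndarray,
    covariates: np.ndarray | None = None,
    n: int = 2,
    fit_rows: int | None = None,
    channel_names: list[str] | None = None,
    scale: bool = True,
) -> SupervisedWindows:
    """Build one-step-ahead supervised windows for one component.

    ``fit_rows`` bounds the rows used to fit the min-max scaler (the
    training partition); defaults to the whole series.  With ``scale=False``
    raw values are kept (useful for enumeration-style checks).
    """
    comp = np.asarray(component, dtype=float).ravel()
    if n < 1:
        raise ValueError("window length n must be >= 1")
    if len(comp) < n + 1:
        raise ValueError(f"series of length {len(comp)} too short for window {n}")
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(comp):
            cov = cov.T
        if cov.shape[0] != len(comp):
            raise ValueError("covariates are not aligned with the component")
        mat = np.column_stack([comp, cov])
    else:
        mat = comp[:, None]
    n_ch = mat.shape[1]
    names = channel_names or (["target"] + [f"cov_{i}" for i in range(n_ch - 1)])
    if len(names) != n_ch:
        raise ValueError("channel_names length mismatch")

    fr = len(comp) if fit_rows is None else int(fit_rows)
    ch_min = mat[:fr].min(axis=0)
    ch_max = mat[:fr].max(axis=0)
    if scale:
        span = np.where(ch_max - ch_min > 0, ch_max - ch_min, 1.0)
        mat = (mat - ch_min) / span

    t_idx = np.arange(n, len(comp))
    win = np.lib.stride_tricks.sliding_window_view(mat, n, axis=0)  # (N-n+1, C, n)
    X = win[:-1].transpose(0, 2, 1).copy()  # windows ending at t-1
    y = mat[t_idx, 0].copy()
    return SupervisedWindows(X, y, t_idx, list(names), ch_min, ch_max, scaled=scale)


# ---------------------------------------------------------------------------
# pipeline configuration and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Everything around the per-component models.

    ``decomposition`` is one of ``ceemdan | eemd | emd | none``;
    ``decomposition_window`` is ``full`` (decompose the whole series once,
    the source convention) or ``expanding`` (strictly causal, slow).
    ``all_imf_channels`` additionally decomposes every covariate and feeds
    all their components as channels (an exploratory mode).
    """

    split: SplitSpec = field(default_factory=SplitSpec)
    decomposition: str = "ceemdan"
    decomp_config: DecompositionConfig = field(default_factory=DecompositionConfig)
    use_covariates: bool = True
    all_imf_channels: bool = False
    decomposition_window: str = "full"
    epochs: int | None = None          # None = the model spec's epochs
    search_epochs: int = 15
    search_max_windows: int = 192
    search_batch_size: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decomposition not in ("ceemdan", "eemd", "emd", "none"):
            raise ValueError("decomposition must be ceemdan | eemd | emd | none")
        if self.decomposition_window not in ("full", "expanding"):
            raise ValueError("decomposition_window must be 'full' or 'expanding'")


@dataclass
class ForecastResult:
    """Reconstructed one-step-ahead forecast over the test period."""

    dates: pd.DatetimeIndex
    y_true: np.ndarray
    y_pred: np.ndarray
    component_predictions: np.ndarray  # (k, n_test), original units
    model_spec: ForecastModelSpec
    metrics: MetricsReport
    validation_rmse: float
    loss_histories: list[dict[str, list[float]]]
    config: PipelineConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"y_true": self.y_true, "y_pred": self.y_pred}, index=self.dates
        )


# ---------------------------------------------------------------------------
# internal engine
# ---------------------------------------------------------------------------


def _component_seed(base: int, j: int) -> int:
    return int((base * 10007 + 7919 * j + 1) % (2**31 - 1))


@dataclass
class _Prepared:
    components: list[np.ndarray]
    cov_matrix: np.ndarray | None
    cov_names: list[str]
    idx_train: np.ndarray
    idx_val: np.ndarray
    idx_test: np.ndarray
    y_full: np.ndarray
    dates: pd.DatetimeIndex


def _prepare(panel: PollutantPanel, target: str, config: PipelineConfig) -> _Prepared:
    idx_train, idx_val, idx_test = split_panel(panel, config.split)
    y_full = panel.series(target).to_numpy()
    n_obs = len(y_full)

    if config.decomposition == "none":
        components = [y_full.copy()]
    else:
        span = (
            n_obs
            if config.decomposition_window == "full"
            else len(idx_train) + len(idx_val)
        )
        imfset = decompose(y_full[:span], config.decomposition, config.decomp_config)
        if len(imfset) == 0:
            # constant-like series: fall back to the residue alone
            components = [imfset.residue.copy()]
        else:
            components = imfset.components()
        if span < n_obs:
            # expanding mode: training components only; the test loop
            # re-decomposes per origin (see _predict_expanding)
            components = [np.concatenate([c, np.full(n_obs - span, np.nan)]) for c in components]

    cov_names: list[str] = []
    cov_matrix: np.ndarray | None = None
    if config.use_covariates:
        cov_df = panel.covariates(target)
        if config.all_imf_channels and config.decomposition != "none":
            blocks, names = [], []
            for name in cov_df.columns:
                sub = decompose(
                    cov_df[name].to_numpy(), config.decomposition, config.decomp_config
                )
                for i, c in enumerate(sub.components()):
                    blocks.append(c)
                    names.append(f"{name}_c{i}")
            cov_matrix = np.column_stack(blocks)
            cov_names = names
        else:
            cov_matrix = cov_df.to_numpy()
            cov_names = list(cov_df.columns)
    return _Prepared(
        components, cov_matrix, cov_names, idx_train, idx_val, idx_test, y_full, panel.dates
    )


def _fit_component_models(
    prep: _Prepared,
    spec: ForecastModelSpec,
    config: PipelineConfig,
    epochs: int,
    max_windows: int | None = None,
    batch_size: int | None = None,
) -> tuple[list[CNNLSTMRegressor], list[SupervisedWindows], list[dict]]:
    models, windows, histories = [], [], []
    n_train_rows = len(prep.idx_train)
    for j, comp in enumerate(prep.components):
        comp_train = comp[~np.isnan(comp)] if np.isnan(comp).any() else comp
        sw = make_windows(
            comp_train,
            prep.cov_matrix[: len(comp_train)] if prep.cov_matrix is not None else None,
            n=spec.window,
            fit_rows=n_train_rows,
            channel_names=["target", *prep.cov_names],
        )
        rows = sw.rows(prep.idx_train)
        if max_windows is not None and len(rows) > max_windows:
            rows = rows[-max_windows:]
        mspec = replace(
            spec,
            epochs=epochs,
            seed=_component_seed(config.seed, j),
            batch_size=batch_size or spec.batch_size,
        )
        model = CNNLSTMRegressor(mspec, sw.X.shape[2])
        hist = model.fit(sw.X[rows], sw.y[rows])
        models.append(model)
        windows.append(sw)
        histories.append(hist)
    return models, windows, histories


def _predict_partition(
    models: list[CNNLSTMRegressor],
    windows: list[SupervisedWindows],
    part_idx: np.ndarray,
) -> np.ndarray:
    """Per-component predictions on a partition, in original units; shape
    (k, len(part_idx))."""
    preds = np.empty((len(models), len(part_idx)))
    for j, (model, sw) in enumerate(zip(models, windows)):
        rows = sw.rows(part_idx)
        if len(rows) != len(part_idx):
            raise ValueError("partition rows fall outside the window range")
        preds[j] = sw.inverse_scale_y(model.predict(sw.X[rows]))
    return preds


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def forecast_hybrid(
    panel: PollutantPanel,
    target: str,
    spec: ForecastModelSpec,
    config: PipelineConfig | None = None,
) -> ForecastResult:
    """Run the full decompose -> per-component CNN-LSTM -> sum pipeline.

    The reconstructed prediction is exactly the sum of the per-component
    prediction vectors (each inverse-scaled to original units).
    """
    cfg = config or PipelineConfig()
    prep = _prepare(panel, target, cfg)
    epochs = cfg.epochs if cfg.epochs is not None else spec.epochs
    models, windows, histories = _fit_component_models(prep, spec, cfg, epochs)

    if cfg.decomposition != "none" and cfg.decomposition_window == "expanding":
        comp_preds = _predict_expanding(panel, target, spec, cfg, models, windows)
    else:
        comp_preds = _predict_partition(models, windows, prep.idx_test)
    y_pred = comp_preds.sum(axis=0)
    y_true = prep.y_full[prep.idx_test]

    val_preds = (
        _predict_partition(models, windows, prep.idx_val).sum(axis=0)
        if cfg.decomposition_window == "full" or cfg.decomposition == "none"
        else np.full(len(prep.idx_val), np.nan)
    )
    if np.isnan(val_preds).any():
        val_rmse = float("nan")
    else:
        val_rmse = float(np.sqrt(np.mean((val_preds - prep.y_full[prep.idx_val]) ** 2)))

    return ForecastResult(
        dates=prep.dates[prep.idx_test],
        y_true=y_true,
        y_pred=y_pred,
        component_predictions=comp_preds,
        model_spec=spec,
        metrics=metrics_report(y_true, y_pred),
        validation_rmse=val_rmse,
        loss_histories=histories,
        config=cfg,
    )


def _predict_expanding(
    panel: PollutantPanel,
    target: str,
    spec: ForecastModelSpec,
    cfg: PipelineConfig,
    models: list[CNNLSTMRegressor],
    windows: list[SupervisedWindows],
) -> np.ndarray:
    """Strictly causal test predictions: re-decompose the history before
    each forecast origin and roll the trained component models forward."""
    idx_test = split_panel(panel, cfg.split)[2]
    y_full = panel.series(target).to_numpy()
    cov = panel.covariates(target).to_numpy() if cfg.use_covariates else None
    k = len(models)
    preds = np.zeros((k, len(idx_test)))
    n = spec.window
    for col, t in enumerate(idx_test):
        sub = decompose(y_full[:t], cfg.decomposition, cfg.decomp_config)
        comps = sub.components()
        for j in range(k):
            sw = windows[j]
            c = comps[j] if j < len(comps) else np.zeros(t)
            span = np.where(sw.ch_max - sw.ch_min > 0, sw.ch_max - sw.ch_min, 1.0)
            block = c[t - n: t, None]
            if cov is not None:
                block = np.column_stack([block, cov[t - n: t]])
            x = (block - sw.ch_min) / span
            preds[j, col] = sw.inverse_scale_y(models[j].predict(x[None])[0])
    return preds


def forecast_single(
    panel: PollutantPanel,
    target: str,
    spec: ForecastModelSpec,
    config: PipelineConfig | None = None,
    use_covariates: bool = True,
) -> ForecastResult:
    """Decomposition-free variant (plain PSO-CNN-LSTM), with or without
    the five covariate pollutant channels."""
    cfg = replace(
        config or PipelineConfig(), decomposition="none", use_covariates=use_covariates
    )
    return forecast_hybrid(panel, target, spec, cfg)


def persistence_forecast(
    panel: PollutantPanel, target: str, split: SplitSpec | None = None
) -> ForecastResult:
    """Naive baseline: tomorrow equals today (y_hat_t = y_{t-1})."""
    idx_train, idx_val, idx_test = split_panel(panel, split)
    y = panel.series(target).to_numpy()
    y_pred = y[idx_test - 1]
    y_true = y[idx_test]
    val_pred = y[idx_val - 1]
    cfg = PipelineConfig(split=split or SplitSpec(), decomposition="none")
    return ForecastResult(
        dates=panel.dates[idx_test],
        y_true=y_true,
        y_pred=y_pred,
        component_predictions=y_pred[None, :],
        model_spec=ForecastModelSpec(window=1, cells=1),
        metrics=metrics_report(y_true, y_pred),
        validation_rmse=float(np.sqrt(np.mean((val_pred - y[idx_val]) ** 2))),
        loss_histories=[],
        config=cfg,
    )


def tune_hyperparameters(
    panel: PollutantPanel,
    target: str,
    pso_config: PSOConfig | None = None,
    config: PipelineConfig | None = None,
    base_spec: ForecastModelSpec | None = None,
) -> tuple[ForecastModelSpec, PSOResult]:
    """PSO search over (window, cells) in [1,20] x [1,100].

    Fitness is the validation RMSE of the reconstructed forecast, with the
    component models trained at a reduced epoch budget on the most recent
    training windows.  Integer configurations are cached, and every
    evaluation is seeded, so the search is reproducible.
    """
    cfg = config or PipelineConfig()
    pcfg = pso_config or PSOConfig(bounds=HYPERPARAMETER_BOUNDS, seed=cfg.seed)
    spec0 = base_spec or ForecastModelSpec()
    prep = _prepare(panel, target, cfg)
    if cfg.decomposition != "none" and cfg.decomposition_window == "expanding":
        raise ValueError("tuning is only supported with full-window or no decomposition")
    cache: dict[tuple[int, int], float] = {}

    def fitness(position: np.ndarray) -> float:
        n, cells = encode_hyperparameters(position)
        key = (n, cells)
        if key not in cache:
            spec = replace(spec0, window=n, cells=cells)
            models, windows, _ = _fit_component_models(
                prep,
                spec,
                cfg,
                epochs=cfg.search_epochs,
                max_windows=cfg.search_max_windows,
                batch_size=cfg.search_batch_size,
            )
            val_pred = _predict_partition(models, windows, prep.idx_val).sum(axis=0)
            cache[key] = float(
                np.sqrt(np.mean((val_pred - prep.y_full[prep.idx_val]) ** 2))
            )
        return cache[key]

    result = optimize(fitness, pcfg)
    n, cells = encode_hyperparameters(result.best_position)
    return replace(spec0, window=n, cells=cells), result
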