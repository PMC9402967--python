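"""Seeded synthetic pollutant panels and analytic test signals.

The real six-city monitoring series behind this methodology are not
publicly deposited, so the package ships a generator that emulates their
documented statistical structure: an annual cycle peaking in January for
PM2.5/PM10/SO2/NO2/CO ("U" shape over the calendar year) and in summer
for O3 ("Λ" shape), multi-year declining trends, cross-pollutant
correlation, and autocorrelated day-to-day noise.

Each channel is generated as

    c(t) = max(0, base * (1 + trend * t/365.25)
                  + amplitude * cos(2*pi*(t - t_peak)/365.25)
                  + e(t))

where ``e`` is a per-channel AR(1) process driven by innovations that are
correlated across channels through the Cholesky factor of the configured
correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import POLLUTANTS, UNITS, PollutantPanel

# Day-of-year at which the seasonal cosine peaks.
_PEAK_DOY = {"winter-peak": 15.0, "summer-peak": 196.0}

_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ChannelSpec:
    """Generator block for one pollutant channel.

    base_level and seasonal_amplitude / noise_sd are in the channel's
    concentration units (ug/m3; mg/m3 for CO); annual_trend is a signed
    fraction of base_level per year; ar_coefficient in [0, 1).
    """

    base_level: float
    seasonal_amplitude: float
    seasonal_phase: str = "winter-peak"
    annual_trend: float = 0.0
    ar_coefficient: float = 0.5
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.seasonal_phase not in _PEAK_DOY:
            raise ValueError(f"seasonal_phase must be one of {sorted(_PEAK_DOY)}")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _default_channels() -> dict[str, ChannelSpec]:
    # Magnitudes chosen to resemble heavily polluted northern-Chinese cities
    # (annual means of tens of ug/m3, winter maxima 2-3x summer minima,
    # gradual multi-year decline); see docs/methods.md.
    return {
        "PM25": ChannelSpec(55.0, 30.0, "winter-peak", -0.06, 0.6, 12.0),
        "PM10": ChannelSpec(95.0, 40.0, "winter-peak", -0.05, 0.6, 18.0),
        "SO2": ChannelSpec(25.0, 15.0, "winter-peak", -0.12, 0.5, 6.0),
        "NO2": ChannelSpec(40.0, 15.0, "winter-peak", -0.03, 0.5, 8.0),
        "CO": ChannelSpec(1.1, 0.5, "winter-peak", -0.06, 0.6, 0.2),
        "O3": ChannelSpec(95.0, 45.0, "summer-peak", 0.01, 0.5, 15.0),
    }


def _default_correlation() -> np.ndarray:
    # Moderate positive dependence among the five winter-peaking channels,
    # weak negative dependence with O3 (placeholder values; the source data
    # quantify no correlations).
    corr = np.full((6, 6), 0.5)
    np.fill_diagonal(corr, 1.0)
    corr[5, :5] = corr[:5, 5] = -0.2
    return corr


@dataclass(frozen=True)
class PanelSpec:
    """Full specification of a synthetic six-channel panel."""

    n_days: int = 2192  # Jan 1 2016 .. Dec 31 2021 inclusive
    start_date: str = "2016-01-01"
    seed: int = 0
    channels: dict[str, ChannelSpec] = field(default_factory=_default_channels)
    cross_correlation: np.ndarray = field(default_factory=_default_correlation)

    def __post_init__(self) -> None:
        if self.n_days < 40:
            raise ValueError("n_days must be at least 40 (twice the maximum window length)")
        missing = [p for p in POLLUTANTS if p not in self.channels]
        if missing:
            raise ValueError(f"channel blocks missing for: {missing}")
        corr = np.asarray(self.cross_correlation, dtype=float)
        if corr.shape != (6, 6):
            raise ValueError("cross_correlation must be 6x6")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("cross_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("cross_correlation must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(corr).min())
        if eigmin < -1e-10:
            raise ValueError(
                f"cross_correlation is not positive semidefinite (min eigenvalue {eigmin:.3e})"
            )
        object.__setattr__(self, "cross_correlation", corr)

    def with_seed(self, seed: int) -> "PanelSpec":
        return replace(self, seed=seed)

    # -- JSON interchange ---------------------------------------------------

    def to_json(self, path) -> None:
        import json
        from dataclasses import asdict

        payload = {
            "n_days": self.n_days,
            "start_date": str(self.start_date),
            "seed": self.seed,
            "channels": {k: asdict(v) for k, v in self.channels.items()},
            "cross_correlation": self.cross_correlation.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PanelSpec":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        channels = {k: ChannelSpec(**v) for k, v in payload.pop("channels", {}).items()}
        corr = np.asarray(payload.pop("cross_correlation", _default_correlation()))
        return cls(channels=channels or _default_channels(), cross_correlation=corr, **payload)


def generate_panel(spec: PanelSpec) -> PollutantPanel:
    """Generate a seeded :class:`PollutantPanel` from *spec*.

    Deterministic for a fixed spec (bit-identical repeats); all
    concentrations are clipped at zero.
    """
    rng = np.random.default_rng(spec.seed)
    dates = pd.date_range(spec.start_date, periods=spec.n_days, freq="D")
    t = np.arange(spec.n_days, dtype=float)
    doy = dates.dayofyear.to_numpy(dtype=float)

    # Correlated innovations: z ~ N(0, I) mapped through the Cholesky-like
    # factor of the correlation matrix (eigen factorisation tolerates PSD
    # matrices that are not strictly positive definite).
    w, v = np.linalg.eigh(spec.cross_correlation)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((spec.n_days, 6))
    eta = z @ factor.T  # unit-variance, cross-correlated innovations

    out = np.empty((spec.n_days, 6))
    for j, name in enumerate(POLLUTANTS):
        ch = spec.channels[name]
        trend = ch.base_level * (1.0 + ch.annual_trend * t / _DAYS_PER_YEAR)
        seasonal = ch.seasonal_amplitude * np.cos(
            2.0 * np.pi * (doy - _PEAK_DOY[ch.seasonal_phase]) / _DAYS_PER_YEAR
        )
        phi = ch.ar_coefficient
        e = np.empty(spec.n_days)
        prev = 0.0
        shocks = ch.noise_sd * eta[:, j]
        for i in range(spec.n_days):
            prev = phi * prev + shocks[i]
            e[i] = prev
        out[:, j] = trend + seasonal + e

    np.clip(out, 0.0, None, out=out)
    df = pd.DataFrame(out, index=dates, columns=list(POLLUTANTS))
    return PollutantPanel(df, dict(UNITS))


@dataclass(frozen=True)
class ToneSignal:
    """A sum of sinusoids with the exact components kept for oracle tests."""

    t: np.ndarray
    signal: np.ndarray
    components: tuple[np.ndarray, ...]  # one per frequency, fastest last
    noise: np.ndarray
    frequencies: tuple[float, ...]
    amplitudes: tuple[float, ...]


def generate_tone_signal(
    frequencies: list[float],
    amplitudes: list[float],
    n_points: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ToneSignal:
    """Build ``sum_k a_k sin(2 pi f_k t)`` on t = 0..n_points-1 plus noise.

    The exact noiseless components are retained (sorted by ascending
    frequency) so decomposition tests can compare against ground truth.
    """
    if len(frequencies) == 0:
        raise ValueError("at least one frequency is required")
    if len(frequencies) != len(amplitudes):
        raise ValueError("frequencies and amplitudes must have equal length")
    order = np.argsort(frequencies)
    freqs = tuple(float(frequencies[i]) for i in order)
    amps = tuple(float(amplitudes[i]) for i in order)
    if len(set(freqs)) != len(freqs):
        raise ValueError("frequencies must be distinct")

    t = np.arange(n_points, dtype=float)
    components = tuple(a * np.sin(2.0 * np.pi * f * t) for f, a in zip(freqs, amps))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else np.zeros(n_points)
    signal = np.sum(components, axis=0) + noise
    return ToneSignal(t, signal, components, noise, freqs, amps)
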