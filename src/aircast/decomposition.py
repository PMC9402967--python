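"""Empirical mode decomposition and its noise-assisted ensemble variants.

EMD splits a series x(t) into intrinsic mode functions (IMFs) c_i(t) plus a
low-frequency residue r(t) such that x(t) = sum_i c_i(t) + r(t).  Each IMF
is obtained by *sifting*: repeatedly subtracting the mean of the upper and
lower cubic-spline envelopes through the local extrema until the candidate
is locally symmetric.

Three ensemble variants address mode mixing:

- ``eemd``   — average full EMD decompositions of white-noise-perturbed
  copies of the signal (reconstruction only approximate).
- ``ceemdan`` — Torres-style complete ensemble EMD with adaptive noise:
  IMF_k is the ensemble mean of the first EMD mode of the running residue
  perturbed with the k-th EMD mode of each noise realisation; the final
  residue is defined by subtraction, so reconstruction is exact by
  construction.  With ``paired_noise`` every noise draw is used with both
  + and - signs, which cancels residual noise to first order.

Boundary handling mirrors the two extrema nearest each endpoint before the
spline fit; sifting stops on Huang's Cauchy-like SD criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass(frozen=True)
class DecompositionConfig:
    """Knobs for EMD and its ensemble variants.

    max_imfs limits the number of extracted modes (None = until the residue
    has fewer than two extrema of each kind); noise_scale is the ensemble
    noise amplitude as a fraction of the perturbed series' standard
    deviation; adaptive_noise rescales it by the running residue's standard
    deviation at each CEEMDAN stage.
    """

    max_imfs: int | None = None
    max_sift_iterations: int = 50
    sd_threshold: float = 0.2
    ensemble_size: int = 100
    noise_scale: float = 0.2
    paired_noise: bool = True
    adaptive_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")
        if not 0.0 < self.noise_scale < 1.0:
            raise ValueError("noise_scale must be in (0, 1)")
        if self.ensemble_size < 2:
            raise ValueError("ensemble_size must be at least 2")
        if self.paired_noise and self.ensemble_size % 2:
            raise ValueError("ensemble_size must be even when paired_noise is set")
        if self.max_sift_iterations < 1:
            raise ValueError("max_sift_iterations must be at least 1")


@dataclass
class IMFSet:
    """Ordered IMFs (highest frequency first) plus the residue."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        for c in self.imfs:
            if len(c) != self.source_length:
                raise ValueError("IMF length differs from source_length")
        if len(self.residue) != self.source_length:
            raise ValueError("residue length differs from source_length")

    def __len__(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """sum of IMFs + residue; equals the decomposed signal."""
        out = self.residue.copy()
        for c in self.imfs:
            out += c
        return out

    def components(self) -> list[np.ndarray]:
        """IMFs followed by the residue, each a separate forecast target."""
        return [*self.imfs, self.residue]

    def to_frame(self):
        import pandas as pd

        cols = {f"imf_{i}": c for i, c in enumerate(self.imfs)}
        cols["residue"] = self.residue
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# extrema and envelopes
# ---------------------------------------------------------------------------

def find_extrema(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior maxima and minima.

    Plateau runs (consecutive equal values) count once, at the midpoint
    index of the run.  Endpoints are never returned; boundary effects are
    handled by mirroring in :func:`compute_envelopes`.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("signal must be 1-D with length >= 3")
    keep = np.concatenate(([True], np.diff(x) != 0.0))
    vals = x[keep]
    if len(vals) < 3:  # constant or single-step signal
        return np.array([], dtype=int), np.array([], dtype=int)
    starts = np.flatnonzero(keep)
    ends = np.append(starts[1:], len(x)) - 1
    mids = (starts + ends) // 2
    dv = np.sign(np.diff(vals))
    maxima = mids[1:-1][(dv[:-1] > 0) & (dv[1:] < 0)]
    minima = mids[1:-1][(dv[:-1] < 0) & (dv[1:] > 0)]
    return maxima.astype(int), minima.astype(int)


def _mirror_extend(idx: np.ndarray, val: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    # Reflect the two extrema nearest each endpoint about that endpoint.
    left_i = (-idx[:2])[::-1]
    left_v = val[:2][::-1]
    right_i = (2 * (n - 1) - idx[-2:])[::-1]
    right_v = val[-2:][::-1]
    return (
        np.concatenate([left_i, idx, right_i]),
        np.concatenate([left_v, val, right_v]),
    )


def compute_envelopes(
    signal: np.ndarray,
    maxima: np.ndarray,
    minima: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Cubic-spline upper/lower envelopes and their mean.

    Returns ``None`` when fewer than two maxima or two minima exist — the
    caller treats that as "residue reached", not as an error.
    """
    x = np.asarray(signal, dtype=float)
    if len(maxima) < 2 or len(minima) < 2:
        return None
    n = len(x)
    s = np.arange(n, dtype=float)
    mi, mv = _mirror_extend(np.asarray(maxima), x[maxima], n)
    upper = CubicSpline(mi, mv)(s)
    ni, nv = _mirror_extend(np.asarray(minima), x[minima], n)
    lower = CubicSpline(ni, nv)(s)
    return upper, lower, 0.5 * (upper + lower)


# ---------------------------------------------------------------------------
# sifting and EMD
# ---------------------------------------------------------------------------

def sift(signal: np.ndarray, config: DecompositionConfig | None = None) -> np.ndarray:
    """Extract one IMF candidate by envelope-mean subtraction.

    Iterates ``h <- h - mean_envelope(h)`` until both the SD stopping
    criterion ``sum((h_prev - h)^2) / sum(h_prev^2) < sd_threshold`` and
    the IMF condition |#extrema - #zero-crossings| <= 1 hold, or the
    iteration cap is reached.  Termination is guaranteed by the cap.
    """
    cfg = config or DecompositionConfig()
    h = np.asarray(signal, dtype=float).copy()
    for _ in range(cfg.max_sift_iterations):
        maxima, minima = find_extrema(h)
        env = compute_envelopes(h, maxima, minima)
        if env is None:
            break
        mean = env[2]
        denom = float(np.dot(h, h))
        if denom == 0.0:
            break
        sd = float(np.dot(mean, mean)) / denom
        h = h - mean
        if sd < cfg.sd_threshold and imf_criterion_gap(h) <= 1:
            break
    return h


def _has_enough_extrema(x: np.ndarray) -> bool:
    maxima, minima = find_extrema(x)
    return len(maxima) >= 2 and len(minima) >= 2


def emd(signal: np.ndarray, config: DecompositionConfig | None = None) -> IMFSet:
    """Plain empirical mode decomposition.

    Extracts IMFs from the running residue until it is monotone (fewer than
    two extrema of either kind) or ``max_imfs`` is hit.  A constant input
    yields zero IMFs with residue equal to the input.
    """
    cfg = config or DecompositionConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 10:
        raise ValueError("signal must be 1-D with length >= 10")
    residue = x.copy()
    imfs: list[np.ndarray] = []
    scale = float(np.max(np.abs(x))) or 1.0
    while _has_enough_extrema(residue):
        if cfg.max_imfs is not None and len(imfs) >= cfg.max_imfs:
            break
        c = sift(residue, cfg)
        if float(np.max(np.abs(c))) < 1e-12 * scale:
            break
        imfs.append(c)
        residue = residue - c
    return IMFSet(imfs, residue, len(x))


# ---------------------------------------------------------------------------
# ensemble variants
# ---------------------------------------------------------------------------

def _noise_bank(cfg: DecompositionConfig, n: int) -> np.ndarray:
    """Unit-variance white-noise realisations; paired draws get +/- signs."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.paired_noise:
        half = rng.standard_normal((cfg.ensemble_size // 2, n))
        return np.concatenate([half, -half], axis=0)
    return rng.standard_normal((cfg.ensemble_size, n))


def _first_mode(x: np.ndarray, cfg: DecompositionConfig) -> np.ndarray:
    """First EMD mode of x, or zeros when x has too few extrema."""
    if not _has_enough_extrema(x):
        return np.zeros_like(x)
    return sift(x, cfg)


def eemd(signal: np.ndarray, config: DecompositionConfig | None = None) -> IMFSet:
    """Ensemble EMD: average full decompositions of noisy copies.

    Components are aligned by index (shorter decompositions padded with
    zeros).  Reconstruction is NOT exact; the ensemble-mean residue absorbs
    the mismatch only on average.
    """
    cfg = config or DecompositionConfig()
    x = np.asarray(signal, dtype=float)
    noise = _noise_bank(cfg, len(x))
    eps = cfg.noise_scale * float(np.std(x))
    decomps = [emd(x + eps * w, cfg) for w in noise]
    k = max(len(d) for d in decomps)
    imfs = [np.zeros_like(x) for _ in range(k)]
    residue = np.zeros_like(x)
    for d in decomps:
        for i, c in enumerate(d.imfs):
            imfs[i] += c
        residue += d.residue
        # pad: missing high-order modes of shallow decompositions stay zero,
        # their residue already carries the remainder
    m = float(len(decomps))
    imfs = [c / m for c in imfs]
    residue /= m
    return IMFSet(imfs, residue, len(x))


def ceemdan(signal: np.ndarray, config: DecompositionConfig | None = None) -> IMFSet:
    """Complete ensemble EMD with adaptive noise (Torres scheme).

    Stage k extracts IMF_k as the ensemble mean over realisations i of the
    first EMD mode of ``r_{k-1} + eps_k * E_k(w_i)`` where E_k is the k-th
    EMD mode of the i-th white-noise realisation and r is the running
    residue (r_0 = signal, perturbed directly with w_i).  The final residue
    is ``signal - sum(IMFs)``, so reconstruction is exact to machine
    precision for any seed.
    """
    cfg = config or DecompositionConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 10:
        raise ValueError("signal must be 1-D with length >= 10")
    noise = _noise_bank(cfg, len(x))
    # Pre-decompose every noise realisation once; stage k draws its k-th mode.
    noise_modes = [emd(w, cfg).imfs for w in noise]

    sigma_x = float(np.std(x)) or 1.0
    residue = x.copy()
    imfs: list[np.ndarray] = []
    stage = 0
    while _has_enough_extrema(residue):
        if cfg.max_imfs is not None and len(imfs) >= cfg.max_imfs:
            break
        scale_ref = float(np.std(residue)) if cfg.adaptive_noise else sigma_x
        eps = cfg.noise_scale * (scale_ref or sigma_x)
        acc = np.zeros_like(x)
        for i in range(len(noise)):
            if stage == 0:
                perturb = noise[i]
            else:
                modes = noise_modes[i]
                perturb = modes[stage - 1] if stage - 1 < len(modes) else None
            y = residue if perturb is None else residue + eps * perturb
            acc += _first_mode(y, cfg)
        mode = acc / float(len(noise))
        # Averaging over realisations breaks the IMF property (spurious
        # ripples); post-sift the ensemble mean to restore it.  The removed
        # remainder stays in the running residue, and the final residue is
        # defined by subtraction, so reconstruction remains exact.
        if _has_enough_extrema(mode):
            mode = sift(mode, cfg)
        if float(np.max(np.abs(mode))) < 1e-12 * sigma_x:
            break
        imfs.append(mode)
        residue = residue - mode
        stage += 1
    # Exact reconstruction: residue is literally what is left.
    residue = x - np.sum(imfs, axis=0) if imfs else x.copy()
    return IMFSet(imfs, residue, len(x))


def decompose(
    signal: np.ndarray,
    method: str = "ceemdan",
    config: DecompositionConfig | None = None,
) -> IMFSet:
    """Dispatch to :func:`emd`, :func:`eemd` or :func:`ceemdan` by name."""
    methods = {"emd": emd, "eemd": eemd, "ceemdan": ceemdan}
    if method not in methods:
        raise ValueError(f"unknown decomposition method {method!r}; expected one of {sorted(methods)}")
    return methods[method](signal, config)


def zero_crossings(x: np.ndarray) -> int:
    """Number of sign changes (zeros counted once)."""
    s = np.sign(np.asarray(x, dtype=float))
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def imf_criterion_gap(x: np.ndarray) -> int:
    """|#extrema - #zero-crossings| — at most 1 for a valid IMF."""
    maxima, minima = find_extrema(x)
    return abs((len(maxima) + len(minima)) - zero_crossings(x))
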