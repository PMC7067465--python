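"""Power spectral pipeline for the thalamic output.

Three steps, applied per realization to the post-transient V_tcr series:

1. decimation from the integration grid to the analysis rate ``fs``;
2. zero-phase (forward-backward) band-pass filtering with an order-10
   Butterworth design, cut-offs 1 and 50 Hz;
3. Welch PSD with a Hamming window.

Ensemble results average the PSD *curves* across realizations (raw
signals are phase-incoherent between realizations, so signal averaging
would cancel the oscillation), then extract the maximum of the averaged
PSD inside the alpha band (7.5-13.5 Hz).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .params import Connectivity, ModelParameters
from .simulate import (SimulationConfig, Trajectory, child_seed,
                       euler_integrate)

__all__ = [
    "SpectralConfig",
    "PSDResult",
    "decimate_to_fs",
    "bandpass",
    "welch_psd",
    "alpha_peak_of_run",
    "peak_power_sweep",
    "set_swept_parameter",
    "DeclineSegment",
    "decline_segment",
    "write_sweep_csv",
]


@dataclass(frozen=True)
class SpectralConfig:
    """Filter, Welch and band settings for the spectral pipeline."""

    fs: float = 1000.0          # analysis rate after decimation, Hz
    band_lo: float = 1.0        # Butterworth low cut-off, Hz
    band_hi: float = 50.0       # Butterworth high cut-off, Hz
    filter_order: int = 10      # design order (per direction)
    alpha_lo: float = 7.5       # alpha band, Hz
    alpha_hi: float = 13.5
    welch_segment: float = 2.0  # segment length, s
    welch_overlap: float = 0.5  # overlap fraction

    def __post_init__(self) -> None:
        if not 0 < self.band_lo < self.band_hi < self.fs / 2:
            raise ValueError("need 0 < band_lo < band_hi < fs/2")
        if not (self.band_lo <= self.alpha_lo < self.alpha_hi <= self.band_hi):
            raise ValueError("alpha band must lie inside the filter band")
        if not 0 <= self.welch_overlap < 1:
            raise ValueError("welch_overlap must be in [0, 1)")

    def replace(self, **changes) -> "SpectralConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PSDResult:
    """Frequency grid, power density (mV^2/Hz) and alpha-band peak."""

    freqs: np.ndarray
    psd: np.ndarray
    alpha_peak: float
    alpha_peak_freq: float


def decimate_to_fs(x: np.ndarray, dt: float, fs: float) -> np.ndarray:
    """Anti-aliased decimation from sample spacing ``dt`` to rate ``fs``."""
    factor = int(round(1.0 / (dt * fs)))
    if factor < 1 or abs(1.0 / (dt * fs) - factor) > 1e-6:
        raise ValueError(f"1/dt={1/dt:g} Hz is not an integer multiple of fs={fs:g}")
    out = np.asarray(x, dtype=float)
    while factor > 1:
        q = min(factor, 10)
        out = sps.decimate(out, q, ftype="fir", zero_phase=True)
        factor //= q
    return out


def bandpass(x: np.ndarray, cfg: SpectralConfig) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    if cfg.fs / 2 <= cfg.band_hi:
        raise ValueError("upper cut-off must be below the Nyquist rate")
    x = np.asarray(x, dtype=float)
    if x.size <= 3 * cfg.filter_order:
        raise ValueError("signal too short for the filter order")
    sos = sps.butter(cfg.filter_order, [cfg.band_lo, cfg.band_hi],
                     btype="bandpass", fs=cfg.fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def welch_psd(x: np.ndarray, cfg: SpectralConfig) -> PSDResult:
    """Welch PSD with a Hamming window; Parseval-consistent normalisation."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(cfg.welch_segment * cfg.fs))
    if x.size < nperseg:
        raise ValueError(
            f"signal ({x.size} samples) shorter than one Welch segment ({nperseg})")
    freqs, psd = sps.welch(x, fs=cfg.fs, window="hamming", nperseg=nperseg,
                           noverlap=int(round(cfg.welch_overlap * nperseg)),
                           detrend="constant")
    return _with_alpha_peak(freqs, psd, cfg)


def _with_alpha_peak(freqs: np.ndarray, psd: np.ndarray,
                     cfg: SpectralConfig) -> PSDResult:
    band = (freqs >= cfg.alpha_lo) & (freqs <= cfg.alpha_hi)
    if not np.any(band):
        raise ValueError("frequency grid does not cover the alpha band")
    i = np.argmax(np.where(band, psd, -np.inf))
    return PSDResult(freqs=freqs, psd=psd, alpha_peak=float(psd[i]),
                     alpha_peak_freq=float(freqs[i]))


def alpha_peak_of_run(trajs: Sequence[Trajectory],
                      cfg: SpectralConfig) -> PSDResult:
    """Ensemble-averaged PSD of the thalamic output and its alpha-band peak.

    Per realization: discard the transient, decimate V_tcr to ``cfg.fs``,
    band-pass, Welch.  The PSD curves are then averaged across
    realizations and the peak taken on the averaged curve.
    """
    if len(trajs) == 0:
        raise ValueError("ensemble must be non-empty")
    acc = None
    freqs = None
    for traj in trajs:
        _, v = traj.post_transient()
        if v.size == 0:
            raise ValueError("empty post-transient window")
        y = decimate_to_fs(v, traj.dt, cfg.fs)
        y = bandpass(y, cfg)
        res = welch_psd(y, cfg)
        acc = res.psd if acc is None else acc + res.psd
        freqs = res.freqs
    return _with_alpha_peak(freqs, acc / len(trajs), cfg)


def set_swept_parameter(name: str, value: float, p: ModelParameters,
                        C: Connectivity) -> tuple[ModelParameters, Connectivity]:
    """Override one connectivity constant or model parameter by name."""
    if name in Connectivity.names():
        return p, C.replace(**{name: value})
    if name in ("v", "e0", "s0"):
        return p.replace(sigmoid=dataclasses.replace(p.sigmoid, **{name: value})), C
    model_fields = {f.name for f in dataclasses.fields(ModelParameters)} - {"sigmoid"}
    if name in model_fields:
        return p.replace(**{name: value}), C
    raise KeyError(
        f"unknown parameter {name!r}; valid names: "
        f"{sorted(Connectivity.names()) + sorted(model_fields) + ['v', 'e0', 's0']}")


def peak_power_sweep(param_name: str, values: Sequence[float],
                     p: ModelParameters, C: Connectivity,
                     sim_cfg: SimulationConfig,
                     spec_cfg: SpectralConfig) -> pd.DataFrame:
    """Peak alpha power versus a swept parameter, with stochastic ensembles.

    Realization ``k`` of sweep point ``i`` uses the child seed derived
    from ``(sim_cfg.seed, i, k)``, so every cell of the sweep is
    individually reproducible.
    """
    values = np.asarray(list(values), dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("sweep values must be finite")
    rows = []
    for i, val in enumerate(values):
        pi, Ci = set_swept_parameter(param_name, float(val), p, C)
        trajs = []
        for k in range(sim_cfg.n_realizations):
            sub = sim_cfg.replace(seed=child_seed(sim_cfg.seed, i, k),
                                  n_realizations=1, record_states=False)
            trajs.append(euler_integrate(pi, Ci, sub))
        res = alpha_peak_of_run(trajs, spec_cfg)
        rows.append({param_name: float(val),
                     "alpha_peak": res.alpha_peak,
                     "alpha_peak_freq": res.alpha_peak_freq,
                     "n_realizations": sim_cfg.n_realizations,
                     "seed": sim_cfg.seed})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DeclineSegment:
    """Boundaries of the steep-decline segment of a peak-power curve.

    ``onset`` is the upper-parameter edge (where the drop begins when
    moving downward from the high plateau), ``end`` the lower edge where
    the curve rejoins the low plateau.  ``significant`` is False when
    the curve shows no genuine decline — the drop across the segment
    must exceed 30% of the curve's full range *and* the high side must
    be at least twice the low side (the drops of interest are
    order-of-magnitude); otherwise the boundaries are meaningless.
    """

    onset: float
    end: float
    significant: bool


def decline_segment(values: np.ndarray, powers: np.ndarray,
                    slope_frac: float = 0.2,
                    min_drop_frac: float = 0.3,
                    min_ratio: float = 2.0) -> DeclineSegment:
    """Locate the steep decline of a two-plateau sweep curve.

    The curve is smoothed with a 3-point moving average; the decline is
    the contiguous region around the maximum-|slope| point where the
    slope magnitude stays above ``slope_frac`` of its maximum.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(powers, dtype=float)
    order = np.argsort(v)
    v, y = v[order], y[order]
    if v.size < 5:
        raise ValueError("need at least 5 sweep points")
    ys = np.convolve(y, np.ones(3) / 3, mode="same")
    ys[0], ys[-1] = y[0], y[-1]
    slope = np.gradient(ys, v)
    k = int(np.argmax(np.abs(slope)))
    thresh = slope_frac * np.abs(slope[k])
    lo = k
    while lo > 0 and np.abs(slope[lo - 1]) >= thresh and slope[lo - 1] * slope[k] > 0:
        lo -= 1
    hi = k
    while hi < len(v) - 1 and np.abs(slope[hi + 1]) >= thresh and slope[hi + 1] * slope[k] > 0:
        hi += 1
    drop = abs(ys[hi] - ys[lo])
    rng = float(np.max(ys) - np.min(ys))
    low, high = sorted((float(ys[lo]), float(ys[hi])))
    ratio_ok = low <= 0 or high / low >= min_ratio
    significant = bool(rng > 0 and drop >= min_drop_frac * rng and ratio_ok)
    return DeclineSegment(onset=float(v[hi]), end=float(v[lo]),
                          significant=significant)


def write_sweep_csv(path: str | Path, sweep: pd.DataFrame) -> None:
    sweep.to_csv(path, sep="\t", index=False)
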