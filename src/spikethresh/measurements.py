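"""Post-hoc trace analysis: onset detection, slopes, threshold statistics.

The operations here mirror how spike-threshold dynamics are quantified in
intracellular recordings: the first-derivative method for spike onset, the
pre-spike depolarization slope by linear regression over a window equal to
the threshold time constant, membrane-potential statistics with post-spike
transients excluded, the mean-threshold-vs-mean-potential regression split
at the half-inactivation voltage, firing-rate maps over input statistics,
and rank-correlation sign tests for the slope-threshold relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inputs import ou_series
from .simulators import MembraneParams, SimConfig, Trace, simulate_ilif
from .threshold_analytics import ThresholdModel

__all__ = [
    "ThresholdStats",
    "RegressionResult",
    "onset_first_derivative",
    "prespike_slope",
    "vm_stats_excluding_spikes",
    "mean_threshold_regression",
    "threshold_stats",
    "ou_drive_sweep",
    "rate_map",
    "slope_correlation_sign",
]


@dataclass(frozen=True)
class ThresholdStats:
    """Per-condition summary: membrane-potential and threshold moments."""

    mean_V: float
    sd_V: float
    mean_theta: float
    sd_theta: float
    spike_count: int
    rate_hz: float


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary (slope, intercept, n, slope standard error)."""

    slope: float
    intercept: float
    n: int
    stderr: float


def onset_first_derivative(
    trace: Trace, k_th: float = 5.0
) -> tuple[np.ndarray, list[int]]:
    """Spike-onset voltages by the first-derivative method.

    For each spike, scans backward from the spike time to the latest upward
    crossing of ``dV/dt`` through the criterion ``k_th`` (default 5 mV/ms)
    and returns V there.  The derivative uses a centered finite-difference
    stencil.  Because the onset is detected on the rising phase, it
    overestimates the underlying threshold.  Returns ``(onsets, missing)``
    where ``missing`` lists spike indices with no criterion crossing.
    """
    if k_th <= 0:
        raise ValueError("k_th must be positive")
    if trace.n_spikes == 0:
        raise ValueError("trace has no spikes")
    dVdt = np.gradient(trace.V, trace.dt)
    above = dVdt >= k_th
    # upward crossings: below at i-1, at-or-above at i
    up = np.nonzero(~above[:-1] & above[1:])[0] + 1
    onsets, missing = [], []
    for j, ts in enumerate(trace.spike_times):
        idx = int(np.floor(ts / trace.dt)) + 1
        cand = up[up <= idx]
        if cand.size == 0:
            missing.append(j)
            continue
        k = int(cand[-1])
        onsets.append(trace.V[k])
    return np.asarray(onsets), missing


def prespike_slope(
    trace: Trace, window: float = 5.0
) -> tuple[np.ndarray, list[int]]:
    """Depolarization slope before each spike by OLS over ``window`` ms.

    The default window equals the threshold time constant (5 ms).  Spikes
    closer than ``window`` to the trace start — or to the previous spike's
    reset, which would contaminate the regression — are skipped and
    reported in the second return value.
    """
    nw = int(round(window / trace.dt))
    if nw < 2:
        raise ValueError("window must span at least 2 samples")
    slopes, skipped = [], []
    tw = np.arange(nw) * trace.dt
    prev_spike = -np.inf
    for j, ts in enumerate(trace.spike_times):
        k1 = int(np.floor(ts / trace.dt)) + 1  # exclusive end: t < t_spike
        k0 = k1 - nw
        if k0 < 0 or ts - prev_spike < window:
            skipped.append(j)
            prev_spike = ts
            continue
        seg = trace.V[k0:k1]
        slope = np.polyfit(tw, seg, 1)[0]
        slopes.append(slope)
        prev_spike = ts
    return np.asarray(slopes), skipped


def vm_stats_excluding_spikes(
    trace: Trace, exclusion_window: float = 5.0
) -> tuple[float, float]:
    """Mean and s.d. of V excluding a window after each spike (reset
    transients).  Raises if the exclusion empties the trace."""
    if exclusion_window < 0:
        raise ValueError("exclusion_window must be nonnegative")
    keep = np.ones(trace.V.size, dtype=bool)
    nw = int(round(exclusion_window / trace.dt))
    for ts in trace.spike_times:
        k = int(np.floor(ts / trace.dt))
        keep[k: k + nw + 1] = False
    if not keep.any():
        raise ValueError("exclusion removed every sample")
    v = trace.V[keep]
    return float(np.mean(v)), float(np.std(v))


def threshold_stats(trace: Trace, exclusion_window: float = 5.0) -> ThresholdStats:
    """Condition summary from one trace: V moments (spikes excluded) and
    threshold-at-spike moments."""
    mean_v, sd_v = vm_stats_excluding_spikes(trace, exclusion_window)
    th = trace.threshold_at_spike
    return ThresholdStats(
        mean_V=mean_v,
        sd_V=sd_v,
        mean_theta=float(np.mean(th)) if th.size else np.nan,
        sd_theta=float(np.std(th)) if th.size else np.nan,
        spike_count=trace.n_spikes,
        rate_hz=trace.rate(),
    )


def mean_threshold_regression(
    conditions: list[ThresholdStats], V_split: float
) -> tuple[RegressionResult, RegressionResult]:
    """OLS of mean threshold on mean V, split at ``V_split`` (= V_i).

    Returns ``(above, below)`` fits over conditions whose mean V lies above
    or below the split voltage; each side needs at least 2 conditions with
    spikes.
    """
    pts = [
        (c.mean_V, c.mean_theta)
        for c in conditions
        if c.spike_count > 0 and np.isfinite(c.mean_theta)
    ]
    out = []
    for side in ("above", "below"):
        sel = [(v, th) for v, th in pts if (v > V_split) == (side == "above")]
        if len(sel) < 2:
            raise ValueError(f"fewer than 2 usable conditions {side} V_split")
        v, th = np.array(sel).T
        fit = stats.linregress(v, th)
        out.append(
            RegressionResult(
                slope=float(fit.slope), intercept=float(fit.intercept),
                n=len(sel), stderr=float(fit.stderr),
            )
        )
    return out[0], out[1]


def ou_drive_sweep(
    model: ThresholdModel,
    membrane: MembraneParams,
    mean_depolarizations,
    sigma_V: float = 6.0,
    tau_c: float = 2.0,
    duration: float = 100000.0,
    dt: float = 0.01,
    seed: int = 0,
    refractory_mode: str = "increment",
    increment: float = 3.6,
) -> list[ThresholdStats]:
    """Simulate the iLIF over OU-current levels of varying mean.

    ``mean_depolarizations`` are target mean depolarizations ``R*mu`` above
    rest, in mV.  The input s.d. is set so the *subthreshold* membrane
    potential s.d. equals ``sigma_V`` (an OU current of correlation time
    ``tau_c`` filtered by the membrane gives
    ``sigma_V = R*sigma_I*sqrt(tau_c/(tau_c + tau_m))``).  Each level runs
    ``duration`` ms with an independent sub-seed.  Returns one
    :class:`ThresholdStats` per level.
    """
    sigma_I = sigma_V / (membrane.R * np.sqrt(tau_c / (tau_c + membrane.tau_m)))
    seeds = np.random.SeedSequence(seed).spawn(len(list(mean_depolarizations)))
    out = []
    for drive, ss in zip(mean_depolarizations, seeds):
        I = ou_series(
            mu=float(drive) / membrane.R, sigma=sigma_I, tau_c=tau_c,
            dt=dt, duration=duration, seed=np.random.default_rng(ss),
        )
        config = SimConfig(
            dt=dt, duration=duration, seed=0,
            refractory_mode=refractory_mode, increment=increment,
        )
        trace = simulate_ilif(model, membrane, I, config)
        out.append(threshold_stats(trace))
    return out


def rate_map(
    mean_grid,
    sigma_grid,
    model: ThresholdModel,
    membrane: MembraneParams,
    duration: float = 5000.0,
    dt: float = 0.01,
    tau_c: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Firing rate (Hz) over a grid of OU input mean and s.d.

    ``mean_grid`` are mean depolarizations ``R*mu`` (mV above rest) and
    ``sigma_grid`` membrane-potential standard deviations (mV); both are
    converted to current units through the membrane filter.  With strong
    threshold adaptation (k_a/k_i = 1) the rate varies far less along the
    mean axis than along the sigma axis.
    """
    mean_grid = np.asarray(mean_grid, dtype=float)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if mean_grid.size == 0 or sigma_grid.size == 0:
        raise ValueError("grids must be nonempty")
    rates = np.zeros((mean_grid.size, sigma_grid.size))
    factor = membrane.R * np.sqrt(tau_c / (tau_c + membrane.tau_m))
    seeds = np.random.SeedSequence(seed).spawn(rates.size)
    idx = 0
    for i, m in enumerate(mean_grid):
        for j, sv in enumerate(sigma_grid):
            I = ou_series(
                mu=m / membrane.R, sigma=sv / factor, tau_c=tau_c,
                dt=dt, duration=duration, seed=np.random.default_rng(seeds[idx]),
            )
            config = SimConfig(dt=dt, duration=duration)
            rates[i, j] = simulate_ilif(model, membrane, I, config).rate()
            idx += 1
    return rates


def slope_correlation_sign(
    slopes, thresholds
) -> tuple[int, float]:
    """Sign and Spearman rank correlation of (pre-spike slope, threshold).

    Negative under threshold adaptation (faster depolarizations catch the
    threshold before it rises), positive for the stochastic-threshold and
    distal-initiation control models.  Requires >= 10 samples and
    non-degenerate inputs.
    """
    slopes = np.asarray(slopes, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if slopes.size != thresholds.size or slopes.size < 10:
        raise ValueError("need >= 10 paired samples")
    if np.ptp(slopes) == 0 or np.ptp(thresholds) == 0:
        raise ValueError("degenerate constant samples")
    rho = float(stats.spearmanr(slopes, thresholds).statistic)
    return int(np.sign(rho)), rho
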