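"""Time-domain neuron simulators with inactivation-driven threshold dynamics.

Two single-compartment models:

* **iEIF** — exponential integrate-and-fire with a multiplicative Na
  inactivation gate ``h`` on the exponential term::

      tau_m dV/dt = (E_L - V) + k_a h exp((V - V_T)/k_a) + R I(t)
      tau_i dh/dt = h_inf(V) - h

  A spike is recorded when ``V`` crosses 0 mV; ``V`` is reset to ``E_L``
  and ``h`` is unchanged.

* **iLIF** — leaky integrate-and-fire with an explicit adaptive threshold::

      tau_m     dV/dt     = (E_L - V) + R I(t)
      tau_theta dtheta/dt = theta_inf(V) - theta

  A spike is recorded when ``V`` reaches ``theta``; ``V`` is reset to
  ``E_L`` and refractoriness is either a 5 ms hold at ``E_L`` or an
  additive threshold increment (default 3.6 mV).

Both use explicit Euler integration (default dt = 0.01 ms) with threshold
crossings located by linear interpolation within the step; resets are
applied at the following grid point.  The hot loops are numba-compiled.
Also here: the stochastic-threshold control model (OU threshold against a
ramp), a voltage-dependent-``tau_theta`` iLIF variant, and the
clamp-and-release protocol that measures the steady-state threshold
empirically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .channels import NaChannelParams, h_inf
from .inputs import StimulusSpec
from .threshold_analytics import ThresholdModel, steady_state_threshold

__all__ = [
    "MembraneParams",
    "SimConfig",
    "Trace",
    "NoiseThresholdParams",
    "SimulationError",
    "simulate_ieif",
    "simulate_ilif",
    "simulate_ilif_vdep_tau",
    "simulate_stochastic_threshold",
    "measure_steady_state_threshold_empirical",
]


class SimulationError(RuntimeError):
    """Raised on numerical blow-up (dt too large) or protocol failure."""


@dataclass(frozen=True)
class MembraneParams:
    """Passive membrane: leak reversal E_L (mV), time constant tau_m (ms),
    input resistance R (mV per current unit).  Capacitance is tau_m/R."""

    E_L: float = -70.0
    tau_m: float = 5.0
    R: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.R <= 0:
            raise ValueError("tau_m and R must be positive")

    @property
    def C(self) -> float:
        return self.tau_m / self.R

    @property
    def g_L(self) -> float:
        return 1.0 / self.R


@dataclass(frozen=True)
class SimConfig:
    """Integration and refractory settings.

    ``refractory_mode``: ``"increment"`` bumps the threshold by
    ``increment`` mV after each spike (default 3.6 mV, the per-spike shift
    for a 3 ms spike with k_a = 6 mV and mean tau 5 ms); ``"hold"`` clamps
    V at rest for ``hold_duration`` ms.
    """

    dt: float = 0.01
    duration: float = 1000.0
    seed: int = 0
    refractory_mode: str = "increment"
    hold_duration: float = 5.0
    increment: float = 3.6

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("need dt > 0 and duration >= dt")
        if self.hold_duration < 0:
            raise ValueError("hold_duration must be nonnegative")
        if self.refractory_mode not in ("increment", "hold"):
            raise ValueError("refractory_mode must be 'increment' or 'hold'")


@dataclass
class Trace:
    """Time-gridded simulation record.

    ``theta`` holds the threshold series (iLIF) and ``h`` the inactivation
    series (iEIF); one of the two is None.  ``spike_times`` are the
    interpolated crossing instants, strictly increasing;
    ``threshold_at_spike`` the interpolated threshold values there.
    """

    t: np.ndarray
    V: np.ndarray
    theta: np.ndarray | None = None
    h: np.ndarray | None = None
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    threshold_at_spike: np.ndarray = field(default_factory=lambda: np.empty(0))
    dt: float = 0.01

    def __post_init__(self) -> None:
        for series in (self.theta, self.h):
            if series is not None and len(series) != len(self.V):
                raise ValueError("series lengths must match")
        if np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike_times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] + self.dt) if self.t.size else 0.0

    def rate(self) -> float:
        """Firing rate in Hz (spike count over duration)."""
        return 1000.0 * self.n_spikes / self.duration

    def to_frame(self) -> pd.DataFrame:
        cols = {"t_ms": self.t, "V_mV": self.V}
        if self.theta is not None:
            cols["theta_mV"] = self.theta
        if self.h is not None:
            cols["h"] = self.h
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class NoiseThresholdParams:
    """Stochastic-threshold control model: OU threshold with mean theta0,
    s.d. sigma_theta (mV) and fluctuation time constant tau_N (ms)."""

    theta0: float = -55.0
    sigma_theta: float = 2.0
    tau_N: float = 5.0

    def __post_init__(self) -> None:
        if self.sigma_theta < 0 or self.tau_N <= 0:
            raise ValueError("sigma_theta >= 0 and tau_N > 0 required")


# ---------------------------------------------------------------------------
# compiled Euler kernels


def _ilif_loop_py(I, off, dt, EL, taum, R, VT, Vi, beta, ka, ki, tau_th,
                  exact, refr_incr, hold_steps, increment, theta0,
                  V, TH, spike_t, spike_th):
    # off: extrinsic threshold offset series (zeros when no hook is set);
    # TH stores the intrinsic threshold, spiking compares against TH + off
    n = I.size
    V[0] = EL
    TH[0] = theta0
    hold = 0
    ns = 0
    for k in range(1, n):
        vp = V[k - 1]
        thp = TH[k - 1]
        if hold > 0:
            vn = EL
            hold -= 1
        else:
            vn = vp + dt * ((EL - vp) + R * I[k - 1]) / taum
        if exact:
            x = (vp - Vi) / ki
            if x > 30.0:
                thinf = VT + beta * (vp - Vi)
            else:
                thinf = VT + ka * math.log1p(math.exp(x))
        else:
            d = vp - Vi
            thinf = VT + beta * d if d > 0.0 else VT
        thn = thp + dt * (thinf - thp) / tau_th
        if hold == 0 and vn >= thn + off[k]:
            d0 = vp - (thp + off[k - 1])
            d1 = vn - (thn + off[k])
            frac = -d0 / (d1 - d0) if d1 > d0 and d0 < 0.0 else 0.0
            spike_t[ns] = (k - 1 + frac) * dt
            spike_th[ns] = thp + off[k - 1] + frac * (thn + off[k] - thp - off[k - 1])
            ns += 1
            vn = EL
            if refr_incr:
                thn += increment
            else:
                hold = hold_steps
        if not math.isfinite(vn) or vn < EL - 500.0:
            return -1
        V[k] = vn
        TH[k] = thn
    return ns


def _ieif_loop_py(I, dt, EL, taum, R, VT, Vi, ka, ki, taui, h0,
                  V, H, spike_t, spike_h):
    n = I.size
    V[0] = EL
    H[0] = h0
    ns = 0
    for k in range(1, n):
        vp = V[k - 1]
        hp = H[k - 1]
        vn = vp + dt * ((EL - vp) + ka * hp * math.exp((vp - VT) / ka) + R * I[k - 1]) / taum
        hinf = 1.0 / (1.0 + math.exp((vp - Vi) / ki))
        hn = hp + dt * (hinf - hp) / taui
        if vn >= 0.0:
            frac = (0.0 - vp) / (vn - vp)
            spike_t[ns] = (k - 1 + frac) * dt
            spike_h[ns] = hp
            ns += 1
            vn = EL
        if not math.isfinite(vn) or vn < EL - 500.0 or not math.isfinite(hn):
            return -1
        V[k] = vn
        H[k] = hn
    return ns


try:
    from numba import njit

    _ilif_loop = njit(cache=False)(_ilif_loop_py)
    _ieif_loop = njit(cache=False)(_ieif_loop_py)
except Exception:  # pragma: no cover
    _ilif_loop = _ilif_loop_py
    _ieif_loop = _ieif_loop_py


def _render_stimulus(stimulus, config: SimConfig) -> np.ndarray:
    n = int(round(config.duration / config.dt))
    if isinstance(stimulus, StimulusSpec):
        return np.ascontiguousarray(
            stimulus.render(config.dt, config.duration, seed=config.seed), dtype=float
        )
    if np.isscalar(stimulus):
        return np.full(n, float(stimulus))
    arr = np.ascontiguousarray(stimulus, dtype=float)
    if arr.size != n:
        raise ValueError(f"stimulus has {arr.size} samples, expected {n}")
    return arr


def simulate_ilif(
    model: ThresholdModel,
    membrane: MembraneParams,
    stimulus,
    config: SimConfig,
    theta_init: float | None = None,
) -> Trace:
    """Simulate the iLIF adaptive-threshold model.

    ``stimulus`` may be a :class:`StimulusSpec`, a scalar (constant current)
    or a sample array on the config grid.  The threshold starts at its
    steady state for the resting potential unless ``theta_init`` is given.
    Deterministic for fixed config seed and stimulus.
    """
    I = _render_stimulus(stimulus, config)
    ch = model.channel
    n = I.size
    V = np.empty(n)
    TH = np.empty(n)
    spike_t = np.empty(n)
    spike_th = np.empty(n)
    theta0 = (
        float(steady_state_threshold(membrane.E_L, model))
        if theta_init is None
        else float(theta_init)
    )
    t = np.arange(n) * config.dt
    if model.threshold_offset is not None:
        off = np.asarray([float(model.threshold_offset(tk)) for tk in t])
    else:
        off = np.zeros(n)
    ns = _ilif_loop(
        I, off, config.dt, membrane.E_L, membrane.tau_m, membrane.R,
        ch.V_T, ch.V_i, ch.slope_ratio, ch.k_a, ch.k_i, model.tau_theta,
        model.steady_state_mode == "exact",
        config.refractory_mode == "increment",
        int(round(config.hold_duration / config.dt)),
        config.increment, theta0, V, TH, spike_t, spike_th,
    )
    if ns < 0:
        raise SimulationError(
            "membrane potential diverged; reduce dt or check parameters"
        )
    if model.threshold_offset is not None:
        TH = TH + off
    return Trace(
        t=t, V=V, theta=TH,
        spike_times=spike_t[:ns].copy(),
        threshold_at_spike=spike_th[:ns].copy(),
        dt=config.dt,
    )


def simulate_ieif(
    channel: NaChannelParams,
    membrane: MembraneParams,
    stimulus,
    config: SimConfig,
    h_init: float | None = None,
    V_clamp: np.ndarray | None = None,
) -> Trace:
    """Simulate the iEIF model.

    ``h`` starts at its steady state for the resting potential unless
    ``h_init`` is given.  ``threshold_at_spike`` records the instantaneous
    threshold ``V_T - k_a ln(h)`` at each spike.  If ``V_clamp`` is given,
    the voltage follows that prescribed series and only ``h`` is integrated
    (voltage-clamp mode, no spikes).
    """
    config_n = int(round(config.duration / config.dt))
    if V_clamp is not None:
        V = np.ascontiguousarray(V_clamp, dtype=float)
        if V.size != config_n:
            raise ValueError("V_clamp length must match the config grid")
        h0 = h_inf(V[0], channel) if h_init is None else float(h_init)
        H = np.empty(config_n)
        H[0] = h0
        rho = config.dt / channel.tau_i
        hinf = np.asarray(h_inf(V, channel))
        for k in range(1, config_n):  # same Euler update as the free run
            H[k] = H[k - 1] + rho * (hinf[k - 1] - H[k - 1])
        t = np.arange(config_n) * config.dt
        return Trace(t=t, V=V.copy(), h=H, dt=config.dt)
    I = _render_stimulus(stimulus, config)
    n = I.size
    V = np.empty(n)
    H = np.empty(n)
    spike_t = np.empty(n)
    spike_h = np.empty(n)
    h0 = h_inf(membrane.E_L, channel) if h_init is None else float(h_init)
    ns = _ieif_loop(
        I, config.dt, membrane.E_L, membrane.tau_m, membrane.R,
        channel.V_T, channel.V_i, channel.k_a, channel.k_i, channel.tau_i,
        h0, V, H, spike_t, spike_h,
    )
    if ns < 0:
        raise SimulationError(
            "membrane potential diverged; reduce dt or check parameters"
        )
    t = np.arange(n) * config.dt
    with np.errstate(divide="ignore"):
        th_at = channel.V_T - channel.k_a * np.log(spike_h[:ns])
    return Trace(
        t=t, V=V, h=H,
        spike_times=spike_t[:ns].copy(),
        threshold_at_spike=th_at.copy(),
        dt=config.dt,
    )


def simulate_ilif_vdep_tau(
    model: ThresholdModel,
    membrane: MembraneParams,
    stimulus,
    config: SimConfig,
    tau_theta_of_V: Callable[[float], float],
) -> Trace:
    """iLIF with a voltage-dependent threshold time constant.

    Same dynamics as :func:`simulate_ilif` but ``tau_theta`` is evaluated at
    the instantaneous V each step (e.g. Na inactivation speeding up with
    depolarization, which sharpens effective PSPs at depolarized levels).
    Pure-Python loop, intended for desk-scale demonstrations.
    """
    I = _render_stimulus(stimulus, config)
    ch = model.channel
    n = I.size
    dt = config.dt
    V = np.empty(n)
    TH = np.empty(n)
    spike_t, spike_th = [], []
    V[0] = membrane.E_L
    TH[0] = float(steady_state_threshold(membrane.E_L, model))
    hold = 0
    hold_steps = int(round(config.hold_duration / dt))
    for k in range(1, n):
        vp, thp = V[k - 1], TH[k - 1]
        tau = float(tau_theta_of_V(vp))
        if tau <= 0:
            raise SimulationError(f"tau_theta_of_V({vp:.2f}) = {tau} is not positive")
        if hold > 0:
            vn = membrane.E_L
            hold -= 1
        else:
            vn = vp + dt * ((membrane.E_L - vp) + membrane.R * I[k - 1]) / membrane.tau_m
        thinf = float(steady_state_threshold(vp, model))
        thn = thp + dt * (thinf - thp) / tau
        if hold == 0 and vn >= thn:
            d0, d1 = vp - thp, vn - thn
            frac = -d0 / (d1 - d0) if d1 > d0 and d0 < 0 else 0.0
            spike_t.append((k - 1 + frac) * dt)
            spike_th.append(thp + frac * (thn - thp))
            vn = membrane.E_L
            if config.refractory_mode == "increment":
                thn += config.increment
            else:
                hold = hold_steps
        V[k] = vn
        TH[k] = thn
    t = np.arange(n) * dt
    return Trace(
        t=t, V=V, theta=TH,
        spike_times=np.asarray(spike_t), threshold_at_spike=np.asarray(spike_th),
        dt=dt,
    )


def simulate_stochastic_threshold(
    noise: NoiseThresholdParams,
    membrane: MembraneParams,
    ramp_slopes: Sequence[float],
    config: SimConfig,
    n_trials: int = 100,
) -> dict[float, np.ndarray]:
    """Stochastic-threshold control model: ramp depolarization against an
    Ornstein-Uhlenbeck threshold.

    For each slope ``s`` the membrane follows ``V(t) = E_L + s t`` while the
    threshold fluctuates as an OU process (mean ``theta0``, s.d.
    ``sigma_theta``, time constant ``tau_N``); the threshold value at the
    first crossing is recorded, ``n_trials`` independent trials per slope.
    Slow ramps catch downward threshold excursions (samples below
    ``theta0``); fast ramps sample the stationary distribution, so the mean
    recorded threshold *increases* with slope — the opposite correlation to
    threshold adaptation.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.dt
    out: dict[float, np.ndarray] = {}
    for s in ramp_slopes:
        if s <= 0:
            raise ValueError("ramp slopes must be positive")
        samples = np.full(n_trials, np.nan)
        theta = noise.theta0 + noise.sigma_theta * rng.standard_normal(n_trials)
        rho = math.exp(-dt / noise.tau_N)
        noise_sd = noise.sigma_theta * math.sqrt(1.0 - rho * rho)
        v = membrane.E_L
        alive = np.arange(n_trials)
        prev_theta = theta.copy()
        k = 0
        # run until every trial has crossed (ramp is unbounded, so it will)
        while alive.size:
            k += 1
            v_next = membrane.E_L + s * k * dt
            theta[alive] = (
                noise.theta0
                + (theta[alive] - noise.theta0) * rho
                + noise_sd * rng.standard_normal(alive.size)
            )
            crossed = alive[v_next >= theta[alive]]
            if crossed.size:
                d0 = v - prev_theta[crossed]
                d1 = v_next - theta[crossed]
                with np.errstate(invalid="ignore"):
                    frac = np.where(d1 > d0, -d0 / (d1 - d0), 0.0)
                frac = np.clip(frac, 0.0, 1.0)
                samples[crossed] = prev_theta[crossed] + frac * (
                    theta[crossed] - prev_theta[crossed]
                )
                alive = alive[v_next < theta[alive]]
            prev_theta[alive] = theta[alive]
            v = v_next
        out[float(s)] = samples
    return out


def measure_steady_state_threshold_empirical(
    V0: float,
    channel: NaChannelParams,
    membrane: MembraneParams,
    tol: float = 0.3,
    max_iter: int = 60,
    t_max: float = 1500.0,
) -> float:
    """Clamp-and-release measurement of the steady-state threshold.

    The membrane is clamped at ``V0`` until inactivation equilibrates
    (``h = h_inf(V0)``, held frozen during the brief test pulse — the
    time-scale separation that defines the steady-state threshold), then
    released with a constant injected current.  Bisection on the current
    amplitude brackets the maximum voltage reachable without triggering a
    spike, which converges to the minimum of the excitability curve,
    i.e. ``theta_inf(V0)``.  ``tol`` (mV) sets the target accuracy on that
    voltage; the bisection stops once the bracket on ``R*I`` is tight enough
    that the saddle-node scaling ``dV ~ sqrt(2 k_a R dI)`` is below ``tol``
    (a finer bracket would need release episodes far longer than ``t_max``
    because the passage through the bottleneck slows critically).
    """
    h0 = float(h_inf(V0, channel))
    if h0 <= 0:
        raise ValueError("h_inf(V0) must be positive")
    EL, taum, R = membrane.E_L, membrane.tau_m, membrane.R
    theta_ss = channel.V_T - channel.k_a * math.log(h0)
    if V0 >= theta_ss:
        raise ValueError("V0 already exceeds its own steady-state threshold")

    def rhs(t, y, RI):
        v = y[0]
        return [((EL - v) + channel.k_a * h0 * math.exp((v - channel.V_T) / channel.k_a) + RI) / taum]

    def crossed(t, y, RI):
        return y[0]

    crossed.terminal = True
    crossed.direction = 1

    def run(RI: float) -> tuple[bool, float]:
        sol = solve_ivp(
            rhs, (0.0, t_max), [V0], args=(RI,), events=crossed,
            rtol=1e-8, atol=1e-8, max_step=t_max / 50.0,
        )
        spiked = len(sol.t_events[0]) > 0
        return spiked, float(np.max(sol.y[0]))

    lo, hi = 0.0, (1.0 - EL)
    spiked_hi, _ = run(hi)
    if not spiked_hi:
        raise SimulationError("failed to bracket the spiking current")
    best_peak = -math.inf
    spiked_lo, peak_lo = run(lo)
    if spiked_lo:
        raise SimulationError("resting release already spikes; V0 too high")
    best_peak = max(best_peak, peak_lo)
    gap_target = tol * tol / (2.0 * channel.k_a)
    for _ in range(max_iter):
        if hi - lo < gap_target:
            break
        mid = 0.5 * (lo + hi)
        spiked, peak = run(mid)
        if spiked:
            hi = mid
        else:
            lo = mid
            best_peak = max(best_peak, peak)
    return best_peak
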