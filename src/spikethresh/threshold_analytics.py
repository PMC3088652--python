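"""Closed-form and semi-analytic operations on the adaptive spike threshold.

Core relation: with a fraction ``h`` of Na channels available, the spike
threshold is ``theta = V_T - k_a * ln(h)``.  Substituting the first-order
kinetics of inactivation yields a relaxation equation

    tau_theta * dtheta/dt = theta_inf(V(t)) - theta

where ``theta_inf`` is the steady-state threshold curve.  Everything here is
derived from that equation: the steady-state curve and its piecewise-linear
approximation, the threshold sensitivity ``dtheta/dV``, the slope-threshold
relation for linear depolarizations (numeric solver plus the ``k_a = k_i``
closed form), the per-spike additive threshold increment, composition rules
for several channel subtypes and slow/fast inactivation, and the somatic
onset shift produced by remote (axonal) spike initiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .channels import NaChannelParams, h_inf

__all__ = [
    "ThresholdModel",
    "SlopeThresholdResult",
    "threshold_from_h",
    "steady_state_threshold",
    "dtheta_dV",
    "divergence_slope",
    "slope_threshold",
    "slope_threshold_closed_form",
    "slope_threshold_curve",
    "spike_increment",
    "combine_subtypes",
    "slow_fast_threshold",
    "distal_onset",
]


@dataclass(frozen=True)
class ThresholdModel:
    """Adaptive-threshold model: channel parameters plus the relaxation time.

    ``tau_theta`` is the threshold adaptation time constant in ms (taken
    equal to the Na inactivation time constant by default).
    ``steady_state_mode`` selects the exact steady-state curve or its
    piecewise-linear approximation.  An optional ``threshold_offset`` hook
    (a function of time, ms -> mV) is added to the threshold to emulate
    modulation by other conductances; it defaults to None (no offset).
    """

    channel: NaChannelParams
    tau_theta: float = 5.0
    steady_state_mode: str = "exact"
    threshold_offset: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if not self.tau_theta > 0:
            raise ValueError(f"tau_theta must be positive, got {self.tau_theta}")
        if self.steady_state_mode not in ("exact", "piecewise"):
            raise ValueError(
                f"steady_state_mode must be 'exact' or 'piecewise', "
                f"got {self.steady_state_mode!r}"
            )

    def theta_inf(self, V):
        return steady_state_threshold(V, self)


@dataclass(frozen=True)
class SlopeThresholdResult:
    """Threshold at spike for a linear depolarization of slope ``s``.

    ``theta_star`` is None when the depolarization never catches the
    adapting threshold (no spike); ``s_star`` is the divergence slope below
    which that happens, when defined (asymptote slope k_a/k_i >= 1).
    """

    s: float
    theta_star: float | None
    s_star: float | None


def threshold_from_h(h, channel: NaChannelParams):
    """Instantaneous spike threshold from the inactivation variable.

    ``theta = V_T - k_a * ln(h)``; equals ``V_T`` for fully available
    channels and rises as channels inactivate.  Raises for ``h <= 0``
    (threshold undefined/infinite).
    """
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr <= 0):
        raise ValueError("threshold is undefined (infinite) for h <= 0")
    if np.any(h_arr > 1):
        raise ValueError("h is a fraction and cannot exceed 1")
    out = channel.V_T - channel.k_a * np.log(h_arr)
    return out if out.ndim else float(out)


def steady_state_threshold(V, model: ThresholdModel):
    """Steady-state threshold curve ``theta_inf(V)``.

    Exact mode: ``V_T - k_a * ln(h_inf(V))``, a softplus-shaped curve with
    horizontal asymptote ``V_T`` at hyperpolarized potentials and a linear
    asymptote of slope ``k_a/k_i`` above the half-inactivation voltage.
    Piecewise mode: ``V_T`` for ``V <= V_i``, then
    ``V_T + (k_a/k_i)(V - V_i)``.  Both are nondecreasing in ``V``; the
    piecewise curve underestimates the exact one by at most ``k_a*ln 2``,
    with the maximum gap at the corner ``V = V_i``.
    """
    ch = model.channel
    V = np.asarray(V, dtype=float)
    if model.steady_state_mode == "piecewise":
        out = ch.V_T + ch.slope_ratio * np.maximum(V - ch.V_i, 0.0)
        return out if out.ndim else float(out)
    from .channels import _theta_inf_exact

    return _theta_inf_exact(V, ch)


def dtheta_dV(V, model: ThresholdModel):
    """Threshold sensitivity ``d(theta_inf)/dV`` on the exact curve.

    Equals ``(k_a/k_i) * (1 - h_inf(V))``: zero far below half-inactivation,
    approaching ``k_a/k_i`` at depolarized potentials.
    """
    ch = model.channel
    V = np.asarray(V, dtype=float)
    out = ch.slope_ratio * (1.0 - np.asarray(h_inf(V, ch)))
    return out if out.ndim else float(out)


def divergence_slope(model: ThresholdModel) -> float | None:
    """Slope ``s*`` below which a linear depolarization never spikes.

    Derived on the piecewise-linear steady-state curve.  For
    ``k_a = k_i``: ``s* = (V_T - V_i)/tau_theta``.  For ``k_a/k_i = b > 1``:
    ``s* = (V_T - V_i) / (tau_theta * (1 - (b-1) ln(b/(b-1))))``, which is
    continuous with the ``b = 1`` case.  Returns None for ``k_a < k_i``
    (every positive slope eventually produces a spike) and None when
    ``V_T <= V_i`` makes the notion vacuous.
    """
    ch = model.channel
    b = ch.slope_ratio
    if b < 1.0 or ch.V_T <= ch.V_i:
        return None
    if b == 1.0:
        return (ch.V_T - ch.V_i) / model.tau_theta
    denom = 1.0 - (b - 1.0) * math.log(b / (b - 1.0))
    return (ch.V_T - ch.V_i) / (model.tau_theta * denom)


def slope_threshold(
    s: float,
    model: ThresholdModel,
    E_L: float = -70.0,
    dt: float = 0.01,
    horizon: float | None = None,
) -> SlopeThresholdResult:
    """Threshold at spike under a linear depolarization ``V(t) = E_L + s*t``.

    Integrates ``tau_theta * dtheta/dt = theta_inf(V(t)) - theta`` from the
    stationary initial condition ``theta(0) = theta_inf(E_L)`` with a fixed
    Euler step and locates the first crossing ``theta(t*) = V(t*)`` by linear
    interpolation between steps.  Returns ``theta_star = None`` when no
    crossing occurs within the horizon (default: time to reach ``V_i`` plus
    ``30 * tau_theta``, enough for any slope safely above the divergence
    slope).  For very fast depolarizations ``theta_star`` tends to ``V_T``.
    """
    if not s > 0:
        raise ValueError("depolarization slope s must be positive")
    ch = model.channel
    tau = model.tau_theta
    if horizon is None:
        horizon = max(ch.V_i - E_L, 0.0) / s + 30.0 * tau
    n = max(int(math.ceil(horizon / dt)), 2)
    t = np.arange(n + 1) * dt
    V = E_L + s * t
    theta_inf = np.asarray(steady_state_threshold(V, model))
    theta = np.empty_like(V)
    theta[0] = float(steady_state_threshold(E_L, model))
    for i in range(n):  # Euler on the scalar relaxation equation
        theta[i + 1] = theta[i] + dt * (theta_inf[i] - theta[i]) / tau
    gap = V - theta
    idx = np.nonzero(gap >= 0)[0]
    s_star = divergence_slope(model)
    if idx.size == 0:
        return SlopeThresholdResult(s=s, theta_star=None, s_star=s_star)
    k = int(idx[0])
    if k == 0:
        theta_star = theta[0]
    else:
        frac = -gap[k - 1] / (gap[k] - gap[k - 1])
        theta_star = theta[k - 1] + frac * (theta[k] - theta[k - 1])
    return SlopeThresholdResult(s=s, theta_star=float(theta_star), s_star=s_star)


def slope_threshold_closed_form(s: float, model: ThresholdModel) -> float | None:
    """Closed-form threshold at spike for ``k_a = k_i`` (piecewise curve).

    ``theta* = V_i - s*tau_theta * ln(1 - (V_T - V_i)/(s*tau_theta))`` when
    ``s*tau_theta > V_T - V_i``; None otherwise (depolarization slower than
    the divergence slope never spikes).  This expression is a re-derivation
    verified against the numeric solver; it depends on ``s`` and
    ``tau_theta`` only through their product.
    """
    ch = model.channel
    if not math.isclose(ch.k_a, ch.k_i, rel_tol=1e-12):
        raise ValueError("closed form requires k_a = k_i")
    if not s > 0:
        raise ValueError("depolarization slope s must be positive")
    stau = s * model.tau_theta
    arg = 1.0 - (ch.V_T - ch.V_i) / stau
    if arg <= 0:
        return None
    return ch.V_i - stau * math.log(arg)


def slope_threshold_curve(
    slopes: Sequence[float], model: ThresholdModel, E_L: float = -70.0, **kwargs
) -> "np.ndarray":
    """theta*(s) over a slope grid as a (n, 2) array [s, theta*] (NaN = no spike)."""
    out = np.full((len(slopes), 2), np.nan)
    for i, s in enumerate(slopes):
        res = slope_threshold(float(s), model, E_L=E_L, **kwargs)
        out[i, 0] = s
        if res.theta_star is not None:
            out[i, 1] = res.theta_star
    return out


def spike_increment(k_a: float, T_spike: float, tau_bar: float) -> float:
    """Additive threshold shift caused by one action potential.

    ``delta_theta = k_a * T_spike / tau_bar`` where ``T_spike`` is the spike
    duration and ``tau_bar`` the mean inactivation time constant during the
    spike.  With ``k_a = 6`` mV, a 3 ms spike and ``tau_bar = 5`` ms this is
    3.6 mV.  ``T_spike = 0`` gives 0; negative inputs are rejected.
    """
    if k_a <= 0 or tau_bar <= 0 or T_spike < 0:
        raise ValueError("k_a and tau_bar must be positive, T_spike nonnegative")
    return k_a * T_spike / tau_bar


def combine_subtypes(
    components: Sequence[tuple[float, float, float]], k_a: float
) -> tuple[float, float]:
    """Effective (V_T, h) for several Na channel subtypes sharing ``k_a``.

    Each component is ``(g_j, V_T_j, h_j)`` with ``g_j`` the (relative)
    maximal conductance.  The summed exponential Na currents collapse to a
    single term with coefficients ``c_j = g_j * exp(-V_T_j / k_a)``:

        h_eff   = sum(c_j h_j) / sum(c_j)
        V_T_eff = -k_a * ln( sum(c_j) / sum(g_j) )

    The normalization by total conductance makes a single component recover
    its own ``V_T``.  Only the combined threshold
    ``threshold_from_h(h_eff, ...) = V_T_eff - k_a*ln(h_eff)`` is uniquely
    defined; the (V_T_eff, h_eff) split is a convention.
    """
    if len(components) == 0:
        raise ValueError("at least one component required")
    if k_a <= 0:
        raise ValueError("k_a must be positive")
    g = np.array([c[0] for c in components], dtype=float)
    vt = np.array([c[1] for c in components], dtype=float)
    h = np.array([c[2] for c in components], dtype=float)
    if np.any(g <= 0):
        raise ValueError("component weights must be positive")
    if np.any((h < 0) | (h > 1)):
        raise ValueError("h must lie in [0, 1]")
    c = g * np.exp(-vt / k_a)
    h_eff = float(np.sum(c * h) / np.sum(c))
    V_T_eff = float(-k_a * math.log(np.sum(c) / np.sum(g)))
    return V_T_eff, h_eff


def slow_fast_threshold(
    V_T: float, k_a: float, h_slow: float, h_fast: float
) -> float:
    """Threshold with independent slow and fast inactivation gates.

    The gates multiply in the Na current, so they add in the threshold:
    ``theta = V_T - k_a*ln(h_slow) - k_a*ln(h_fast)``, identical to
    ``threshold_from_h(h_slow * h_fast)``.  Slow inactivation acts as a slow
    drift of the effective minimal threshold.
    """
    if not (0 < h_slow <= 1 and 0 < h_fast <= 1):
        raise ValueError("h_slow and h_fast must lie in (0, 1]")
    return V_T - k_a * math.log(h_slow) - k_a * math.log(h_fast)


def distal_onset(
    s: float, delta_f: float, delta_b: float, V_T: float
) -> float:
    """Somatic spike onset under remote (axonal) initiation.

    With forward propagation delay ``delta_f`` and backpropagation delay
    ``delta_b`` (ms), a somatic depolarization of slope ``s`` produces an
    apparent onset ``V_T + s*(delta_f + delta_b)`` at the soma — a
    *positive* slope dependence, opposite in sign to threshold adaptation.
    """
    if delta_f < 0 or delta_b < 0:
        raise ValueError("delays must be nonnegative")
    return V_T + s * (delta_f + delta_b)
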