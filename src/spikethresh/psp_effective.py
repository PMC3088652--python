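"""Effective-PSP kernel algebra.

When the spike threshold adapts linearly to voltage (sensitivity
``a = dtheta/dV``, time constant ``tau_theta``), the threshold response to a
single PSP is ``a * L[PSP]`` where ``L`` is a unit-DC-gain first-order
low-pass filter of time constant ``tau_theta`` (the *threshold PSP*).  The
*effective* PSP is the difference ``PSP - a*L[PSP]``: the part of the PSP
that actually moves the membrane potential toward the (moving) threshold.
Effective PSPs are always sharper than PSPs, may change sign (a late lobe of
opposite polarity, which underlies postinhibitory facilitation for IPSPs),
and peak earlier for biexponential PSPs.

All kernels here are closed-form; metrics are computed on the closed forms
with bracketed root-finding, never on sampled simulation traces.
Degenerate equal-time-constant cases use explicit analytic limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Callable

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "PSPKernel",
    "EffectivePSP",
    "KernelMetrics",
    "threshold_psp",
    "effective_psp",
    "kernel_metrics",
    "sign_change_condition",
    "sweep",
]

_EQ_RTOL = 1e-9  # relative tolerance for "equal time constants"


def _close(x: float, y: float) -> bool:
    return math.isclose(x, y, rel_tol=_EQ_RTOL)


def _lowpass_exp(t, tau_in: float, tau_f: float):
    """Unit-DC-gain first-order low-pass of exp(-t/tau_in), causal, t >= 0.

    L[e^{-t/tau_in}](t) = tau_in/(tau_in - tau_f) * (e^{-t/tau_in} - e^{-t/tau_f})
    with the analytic limit (t/tau) e^{-t/tau} at tau_f = tau_in.
    """
    t = np.asarray(t, dtype=float)
    tpos = np.maximum(t, 0.0)
    if _close(tau_in, tau_f):
        out = (tpos / tau_in) * np.exp(-tpos / tau_in)
    else:
        out = (tau_in / (tau_in - tau_f)) * (
            np.exp(-tpos / tau_in) - np.exp(-tpos / tau_f)
        )
    return np.where(t < 0, 0.0, out)


@dataclass(frozen=True)
class PSPKernel:
    """Analytic postsynaptic-potential kernel.

    ``exponential``: ``A * e^{-t/tau_m}`` (instantaneous synaptic current).
    ``biexponential``: synaptic current filtered with rise time ``tau_s``,
    normalized to unit peak, i.e.
    ``A * (e^{-t/tau_m} - e^{-t/tau_s}) / peak`` (analytic ``tau_s = tau_m``
    limit handled).  ``sign`` is +1 for EPSPs, -1 for IPSPs; ``amplitude``
    is the peak magnitude in mV.
    """

    kind: str = "exponential"
    tau_m: float = 10.0
    tau_s: float | None = None
    amplitude: float = 1.0
    sign: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("exponential", "biexponential"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.kind == "biexponential":
            if self.tau_s is None or self.tau_s <= 0:
                raise ValueError("biexponential kernel requires tau_s > 0")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")

    def _unit(self, t):
        """Unit-peak, positive-sign kernel shape."""
        t = np.asarray(t, dtype=float)
        tpos = np.maximum(t, 0.0)
        if self.kind == "exponential":
            out = np.exp(-tpos / self.tau_m)
        else:
            tm, ts = self.tau_m, self.tau_s
            if _close(tm, ts):
                # limit of (e^{-t/tm} - e^{-t/ts})/(tm - ts) ~ alpha function
                shape = (tpos / tm) * np.exp(-tpos / tm)
                peak = math.exp(-1.0)
            else:
                shape = np.exp(-tpos / tm) - np.exp(-tpos / ts)
                t_pk = self.peak_time()
                peak = math.exp(-t_pk / tm) - math.exp(-t_pk / ts)
            out = shape / peak
        return np.where(t < 0, 0.0, out)

    def __call__(self, t):
        out = self.sign * self.amplitude * self._unit(t)
        return out if out.ndim else float(out)

    def peak_time(self) -> float:
        """Time of the kernel's peak, ms (0 for exponential kernels)."""
        if self.kind == "exponential":
            return 0.0
        tm, ts = self.tau_m, self.tau_s
        if _close(tm, ts):
            return tm
        return (math.log(tm) - math.log(ts)) / (1.0 / ts - 1.0 / tm)

    def integral(self) -> float:
        """Analytic integral of the signed kernel over t >= 0."""
        if self.kind == "exponential":
            return self.sign * self.amplitude * self.tau_m
        tm, ts = self.tau_m, self.tau_s
        if _close(tm, ts):
            raw, peak = tm * tm, tm * math.exp(-1.0)
        else:
            t_pk = self.peak_time()
            raw = tm - ts
            peak = math.exp(-t_pk / tm) - math.exp(-t_pk / ts)
        return self.sign * self.amplitude * raw / peak

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PSPKernel":
        return cls(**d)


def threshold_psp(kernel: PSPKernel, a: float, tau_theta: float, t):
    """Threshold response ``a * L[kernel](t)`` to a single PSP.

    ``L`` is the unit-DC-gain first-order low-pass with time constant
    ``tau_theta``; the closed form is applied exponential-term-by-term, so
    the DC gain identity ``integral(threshold_psp) = a * integral(kernel)``
    holds exactly.  Starts at 0 for any causal kernel.
    """
    if a < 0:
        raise ValueError("threshold sensitivity a must be nonnegative")
    if tau_theta <= 0:
        raise ValueError("tau_theta must be positive")
    t = np.asarray(t, dtype=float)
    if kernel.kind == "exponential":
        out = a * kernel.sign * kernel.amplitude * _lowpass_exp(t, kernel.tau_m, tau_theta)
    else:
        tm, ts = kernel.tau_m, kernel.tau_s
        if _close(tm, ts):
            # alpha-kernel limit: L[(u/tm) e^{-u/tm}] in closed form
            tpos = np.maximum(t, 0.0)
            if _close(tau_theta, tm):
                lp = 0.5 * (tpos / tm) ** 2 * np.exp(-tpos / tm)
            else:
                c = 1.0 / tm - 1.0 / tau_theta
                lp = (
                    np.exp(-tpos / tau_theta) - (1.0 + c * tpos) * np.exp(-tpos / tm)
                ) / (tau_theta * tm * c * c)
            lp = np.where(t < 0, 0.0, lp)
            peak = math.exp(-1.0)
            out = a * kernel.sign * kernel.amplitude * lp / peak
        else:
            t_pk = kernel.peak_time()
            peak = math.exp(-t_pk / tm) - math.exp(-t_pk / ts)
            lp = _lowpass_exp(t, tm, tau_theta) - _lowpass_exp(t, ts, tau_theta)
            out = a * kernel.sign * kernel.amplitude * lp / peak
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class EffectivePSP:
    """Effective PSP: the PSP minus its threshold PSP.

    Callable over ``t >= 0``.  At ``a = 0`` it reduces to the PSP itself;
    its integral is ``(1 - a)`` times the PSP integral, so at ``a = 1`` the
    total area vanishes and a sign change is forced.
    """

    kernel: PSPKernel
    a: float
    tau_theta: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("a must be nonnegative")
        if self.tau_theta <= 0:
            raise ValueError("tau_theta must be positive")

    def __call__(self, t):
        k = self.kernel(t)
        if self.a == 0:
            return k
        return k - threshold_psp(self.kernel, self.a, self.tau_theta, t)

    def integral(self) -> float:
        return (1.0 - self.a) * self.kernel.integral()


def effective_psp(kernel: PSPKernel, a: float, tau_theta: float) -> EffectivePSP:
    """Build the effective-PSP evaluator ``t -> PSP(t) - a*L[PSP](t)``."""
    return EffectivePSP(kernel=kernel, a=a, tau_theta=tau_theta)


@dataclass(frozen=True)
class KernelMetrics:
    """Shape metrics of a (effective) PSP evaluator.

    ``half_width`` is the full width at half of the peak; ``zero_crossing``
    is the first sign change after the peak, None when the kernel never
    changes sign on the analysis window.
    """

    peak_time: float
    peak_amplitude: float
    half_width: float
    zero_crossing: float | None


def kernel_metrics(
    evaluator: Callable, t_max: float = 200.0, resolution: int = 2000,
    xtol: float = 1e-5,
) -> KernelMetrics:
    """Measure peak, half-width and zero crossing of a kernel evaluator.

    The peak is located by golden-section refinement around the grid
    maximum; half-peak crossings and the post-peak sign change by bracketed
    root-finding (``xtol`` in ms).  Works on sign-flipped (inhibitory)
    kernels by operating on ``sign(peak) * evaluator``.
    """
    tgrid = np.linspace(0.0, t_max, resolution)
    vals = np.asarray(evaluator(tgrid), dtype=float)
    if np.allclose(vals, 0.0):
        raise ValueError("flat zero kernel has no metrics")
    i_pk = int(np.argmax(np.abs(vals)))
    sgn = 1.0 if vals[i_pk] >= 0 else -1.0
    fvals = sgn * vals

    def f(t):
        return sgn * np.asarray(evaluator(t), dtype=float)

    if i_pk == 0:
        t_pk, v_pk = 0.0, float(fvals[0])
    else:
        lo = tgrid[max(i_pk - 1, 0)]
        hi = tgrid[min(i_pk + 1, resolution - 1)]
        res = minimize_scalar(lambda t: -float(f(t)), bounds=(lo, hi), method="bounded",
                              options={"xatol": xtol})
        t_pk, v_pk = float(res.x), float(f(res.x))
        if float(fvals[0]) >= v_pk:  # grid artifact: true max at the origin
            t_pk, v_pk = 0.0, float(fvals[0])
    half = v_pk / 2.0

    def g(t):
        return float(f(t)) - half

    # right half-crossing: scan precomputed grid values for a bracket
    t_right = None
    right = np.nonzero((tgrid > t_pk) & (fvals < half))[0]
    if right.size:
        k = int(right[0])
        t_right = float(brentq(g, max(t_pk, tgrid[k - 1]), tgrid[k], xtol=xtol))
    if t_right is None:
        raise ValueError("no half-peak crossing within t_max; increase t_max")
    # left half-crossing (0 if the kernel starts above half peak)
    if t_pk == 0.0 or g(0.0) >= 0:
        t_left = 0.0
    else:
        t_left = float(brentq(g, 0.0, t_pk, xtol=xtol))
    # first sign change after the peak
    zero = None
    neg = np.nonzero((tgrid > max(t_pk, t_right)) & (fvals < 0))[0]
    if neg.size:
        k = int(neg[0])
        lo = max(t_pk, t_right, tgrid[k - 1])
        zero = float(brentq(lambda u: float(f(u)), lo, tgrid[k], xtol=xtol))
    return KernelMetrics(
        peak_time=t_pk,
        peak_amplitude=sgn * v_pk,
        half_width=t_right - t_left,
        zero_crossing=zero,
    )


def sign_change_condition(a: float, tau_theta: float, tau_m: float) -> bool:
    """Does the effective PSP of an exponential PSP change sign?

    The late tail of the effective PSP
    ``e^{-t/tau_m} - a*L[e^{-t/tau_m}]`` is negative exactly when
    ``a > 1 - tau_theta/tau_m``: for ``tau_theta >= tau_m`` the slower
    threshold-PSP tail dominates for any ``a > 0``; for faster thresholds
    the sensitivity must exceed ``1 - tau_theta/tau_m``.  At ``a = 1`` the
    zero total area forces a sign change for every ``tau_theta``.
    """
    if a < 0 or tau_theta <= 0 or tau_m <= 0:
        raise ValueError("a must be >= 0 and time constants positive")
    if a == 0:
        return False
    return a > 1.0 - tau_theta / tau_m


def sweep(
    kernel: PSPKernel,
    a_grid,
    tau_theta_grid,
    t_max: float = 200.0,
) -> dict[str, np.ndarray]:
    """Metric maps over a (a, tau_theta) grid.

    Returns dict with ``half_width``, ``peak_time``, ``peak_amplitude`` and
    ``zero_crossing`` arrays of shape (len(a_grid), len(tau_theta_grid));
    zero-crossing entries are NaN where the effective PSP keeps its sign.
    """
    a_grid = np.asarray(a_grid, dtype=float)
    tau_grid = np.asarray(tau_theta_grid, dtype=float)
    if a_grid.size == 0 or tau_grid.size == 0:
        raise ValueError("grids must be nonempty")
    shape = (a_grid.size, tau_grid.size)
    maps = {k: np.full(shape, np.nan) for k in
            ("half_width", "peak_time", "peak_amplitude", "zero_crossing")}
    for i, a in enumerate(a_grid):
        for j, tau in enumerate(tau_grid):
            m = kernel_metrics(effective_psp(kernel, float(a), float(tau)), t_max=t_max)
            maps["half_width"][i, j] = m.half_width
            maps["peak_time"][i, j] = m.peak_time
            maps["peak_amplitude"][i, j] = m.peak_amplitude
            if m.zero_crossing is not None:
                maps["zero_crossing"][i, j] = m.zero_crossing
    return maps
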