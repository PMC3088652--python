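"""Stimulus generation: OU currents, ramps, Poisson PSP trains.

All generators are pure functions of their parameters and seed, return
series sampled on a regular grid of step ``dt`` (ms), and are exactly
reproducible.  The Ornstein-Uhlenbeck generator uses the exact
discretization of the process, so its first two moments are unbiased at any
step size (unlike a naive Euler-Maruyama update).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .psp_effective import PSPKernel

__all__ = [
    "StimulusSpec",
    "ou_series",
    "ramp_series",
    "voltage_ramp_current",
    "psp_train_series",
    "pif_protocol",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _grid(dt: float, duration: float) -> np.ndarray:
    if dt <= 0 or duration < dt:
        raise ValueError("need dt > 0 and duration >= dt")
    n = int(round(duration / dt))
    return np.arange(n) * dt


def ou_series(
    mu: float,
    sigma: float,
    tau_c: float,
    dt: float,
    duration: float,
    seed=0,
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck series (exact discretization).

    ``x[k+1] = mu + (x[k] - mu)*exp(-dt/tau_c)
             + sigma*sqrt(1 - exp(-2 dt/tau_c)) * xi_k``
    with standard-normal ``xi_k`` and stationary initialization
    ``x[0] ~ N(mu, sigma)``.  ``tau_c`` is the autocorrelation time constant
    in ms; defaults elsewhere use 10 ms.
    """
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    t = _grid(dt, duration)
    n = t.size
    rng = _rng(seed)
    if sigma == 0:
        return np.full(n, float(mu))
    rho = np.exp(-dt / tau_c)
    noise_sd = sigma * np.sqrt(1.0 - rho * rho)
    xi = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = mu + sigma * xi[0]
    # scan implemented via the AR(1) recursion; vectorized with cumulative
    # products would lose numerical stability for long series, keep the loop
    # in compiled form below when available
    _ar1_scan(x, xi, rho, noise_sd, mu)
    return x


def _ar1_scan_py(x, xi, rho, noise_sd, mu):
    for k in range(x.size - 1):
        x[k + 1] = mu + (x[k] - mu) * rho + noise_sd * xi[k + 1]


try:  # hot path: 2e6-sample series inside the simulation sweeps
    from numba import njit

    _ar1_scan = njit(cache=False)(_ar1_scan_py)
except Exception:  # pragma: no cover - numba present in supported envs
    _ar1_scan = _ar1_scan_py


def ramp_series(E_L: float, s: float, dt: float, duration: float) -> np.ndarray:
    """Linear series ``E_L + s*t`` (slope ``s`` in units per ms)."""
    if not np.isfinite(s):
        raise ValueError("slope must be finite")
    return E_L + s * _grid(dt, duration)


def voltage_ramp_current(
    s: float, tau_m: float, R: float, dt: float, duration: float
) -> np.ndarray:
    """Current that linearly depolarizes the passive membrane at slope ``s``.

    Injecting ``I(t) = (s*tau_m + s*t)/R`` into
    ``tau_m dV/dt = (E_L - V) + R I`` starting from rest gives exactly
    ``V(t) = E_L + s*t`` — the protocol used for slope-threshold
    measurements, where the *voltage* ramp (not the current) is prescribed.
    """
    if s <= 0:
        raise ValueError("ramp slope must be positive")
    return (s * tau_m + s * _grid(dt, duration)) / R


def psp_train_series(
    kernels: Sequence["PSPKernel"],
    rates: Sequence[float],
    signs: Sequence[int] | None,
    dt: float,
    duration: float,
    seed=0,
) -> np.ndarray:
    """Superposition of PSP kernels at homogeneous-Poisson event times.

    One independent Poisson process per kernel, with ``rates`` in events/ms.
    Event times are drawn by inversion of exponential inter-event intervals
    and each kernel copy is evaluated analytically at ``t - t_event`` on the
    grid, so sub-step timing is exact.  ``signs`` (+1/-1) override each
    kernel's own sign when given.
    """
    if len(kernels) != len(rates):
        raise ValueError("kernels and rates must have equal length")
    if signs is not None and len(signs) != len(kernels):
        raise ValueError("signs must match kernels")
    t = _grid(dt, duration)
    out = np.zeros_like(t)
    rng = _rng(seed)
    for j, (kernel, rate) in enumerate(zip(kernels, rates)):
        if rate < 0:
            raise ValueError("rates must be nonnegative")
        if rate == 0:
            continue
        # an explicit sign replaces the kernel's own sign
        sign = signs[j] if signs is not None else getattr(kernel, "sign", 1)
        own_sign = getattr(kernel, "sign", 1)
        t_ev = 0.0
        while True:
            t_ev += rng.exponential(1.0 / rate)
            if t_ev >= duration:
                break
            k0 = int(np.ceil((t_ev - t[0]) / dt))
            out[k0:] += (sign / own_sign) * kernel(t[k0:] - t_ev)
    return out


def pif_protocol(
    ramp_slope: float,
    ipsp_rate: float,
    ipsp_kernel: "PSPKernel",
    dt: float,
    duration: float,
    seed=0,
    E_L: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Postinhibitory-facilitation stimulus: ramp plus random IPSPs.

    Returns ``(composite, control)``: the depolarizing ramp with a Poisson
    train of inhibitory PSPs superposed, and the ramp-only control.  The
    caller chooses a ramp slope below the divergence slope so that the
    control alone does not spike; the delayed positive lobe of inhibitory
    effective PSPs can then rescue spiking.
    """
    control = ramp_series(E_L, ramp_slope, dt, duration)
    train = psp_train_series(
        [ipsp_kernel], [ipsp_rate], [-1], dt, duration, seed=seed
    )
    return control + train, control


@dataclass(frozen=True)
class StimulusSpec:
    """Declarative description of an input current (or voltage command).

    ``kind`` is one of ``constant``, ``ramp``, ``ou``, ``psp_train``,
    ``composite``.  Only the fields relevant to the kind are used:
    ``mean`` (constant/ou/ramp start), ``slope`` (ramp, per ms), ``sigma``
    and ``tau_c`` (ou), ``rate``/``kernel``/``sign`` (psp_train), and
    ``components`` (composite: tuple of specs summed sample-wise).
    Rendering is deterministic given ``seed``.
    """

    kind: str
    mean: float = 0.0
    slope: float = 0.0
    sigma: float = 0.0
    tau_c: float = 10.0
    rate: float = 0.0
    kernel: "PSPKernel | None" = None
    sign: int = 1
    components: tuple = field(default_factory=tuple)
    seed: int = 0

    _KINDS = ("constant", "ramp", "ou", "psp_train", "composite")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "ou" and self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        if self.sigma < 0 or self.rate < 0:
            raise ValueError("sigma and rate must be nonnegative")

    def render(self, dt: float, duration: float, seed=None) -> np.ndarray:
        """Sample the stimulus on a grid of step ``dt`` over ``duration`` ms."""
        seed = self.seed if seed is None else seed
        if self.kind == "constant":
            return np.full(_grid(dt, duration).size, float(self.mean))
        if self.kind == "ramp":
            return ramp_series(self.mean, self.slope, dt, duration)
        if self.kind == "ou":
            return ou_series(self.mean, self.sigma, self.tau_c, dt, duration, seed)
        if self.kind == "psp_train":
            if self.kernel is None:
                raise ValueError("psp_train requires a kernel")
            return psp_train_series(
                [self.kernel], [self.rate], [self.sign], dt, duration, seed
            )
        # composite: independent sub-seeds derived from the master seed
        seqs = np.random.SeedSequence(seed).spawn(len(self.components))
        total = np.zeros(_grid(dt, duration).size)
        for comp, ss in zip(self.components, seqs):
            total += comp.render(dt, duration, seed=np.random.default_rng(ss))
        return total

    def to_json(self) -> str:
        d = asdict(self)
        if self.kernel is not None:
            d["kernel"] = self.kernel.to_dict()
        d["components"] = [json.loads(c.to_json()) for c in self.components]
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "StimulusSpec":
        from .psp_effective import PSPKernel

        d = json.loads(text)
        if d.get("kernel") is not None:
            d["kernel"] = PSPKernel.from_dict(d["kernel"])
        d["components"] = tuple(
            cls.from_json(json.dumps(c)) for c in d.get("components", ())
        )
        return cls(**d)
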