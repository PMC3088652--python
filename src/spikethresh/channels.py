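"""Sodium-channel parameterizations and the threshold-variability criterion.

The spike threshold of a neuron whose Na channels inactivate is set by the
channel's Boltzmann parameters: the half-inactivation voltage ``V_i``, the
inactivation slope factor ``k_i`` and the activation slope factor ``k_a``,
together with the non-inactivated (minimum) threshold ``V_T``.  Whether the
threshold is constant, varies over a bounded range, or can grow without bound
is decided by where ``V_i`` sits relative to ``V_T`` and by the ratio
``k_a / k_i`` — the asymptotic slope of the steady-state threshold curve.

This module houses the parameter containers, the steady-state inactivation
curve, the three-case variability classifier, and CSV I/O plus auditing for
tables of measured channel properties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "NaChannelParams",
    "with_threshold_from_g_ratio",
    "VariabilityLabel",
    "VariabilityClass",
    "ChannelTable",
    "h_inf",
    "classify_variability",
    "max_observable_threshold",
    "read_channel_table",
    "write_channel_table",
    "audit_table",
    "generate_synthetic_table",
]


@dataclass(frozen=True)
class NaChannelParams:
    """Boltzmann and threshold parameters of one Na channel population.

    Parameters
    ----------
    V_T : float
        Minimum (non-inactivated) spike threshold, mV.
    V_i : float
        Half-inactivation voltage, mV.
    k_a : float
        Activation slope factor, mV (> 0).
    k_i : float
        Inactivation slope factor, mV (> 0).
    tau_i : float
        Inactivation time constant, ms (> 0).  A voltage-dependent time
        constant is handled by the simulators via a user-supplied function;
        this field holds the constant used elsewhere.
    g_ratio : float, optional
        Maximal Na conductance over leak conductance (dimensionless, > 0).
    V_a : float, optional
        Half-activation voltage, mV.
    E_Na : float, optional
        Na reversal potential, mV.
    """

    V_T: float
    V_i: float
    k_a: float
    k_i: float
    tau_i: float = 5.0
    g_ratio: float | None = None
    V_a: float | None = None
    E_Na: float | None = None

    def __post_init__(self) -> None:
        if not self.k_a > 0:
            raise ValueError(f"k_a must be positive, got {self.k_a}")
        if not self.k_i > 0:
            raise ValueError(f"k_i must be positive, got {self.k_i}")
        if not self.tau_i > 0:
            raise ValueError(f"tau_i must be positive, got {self.tau_i}")
        if self.g_ratio is not None and not self.g_ratio > 0:
            raise ValueError(f"g_ratio must be positive, got {self.g_ratio}")

    @property
    def slope_ratio(self) -> float:
        """Asymptotic slope ``k_a / k_i`` of the steady-state threshold."""
        return self.k_a / self.k_i

    def shifted(self, dv: float) -> "NaChannelParams":
        """Return a copy with all voltages shifted by ``dv`` mV."""
        kwargs = {"V_T": self.V_T + dv, "V_i": self.V_i + dv}
        if self.V_a is not None:
            kwargs["V_a"] = self.V_a + dv
        if self.E_Na is not None:
            kwargs["E_Na"] = self.E_Na + dv
        return replace(self, **kwargs)


def with_threshold_from_g_ratio(
    params: NaChannelParams, vt_of_g_ratio
) -> NaChannelParams:
    """Return a copy with ``V_T`` computed from the conductance ratio.

    The minimum threshold depends on the maximal Na conductance relative to
    leak, but no closed form is bundled here: ``V_T`` is a primary user
    parameter. Callers who have such a relation supply it as
    ``vt_of_g_ratio(g_ratio) -> mV``; requires ``params.g_ratio``.
    """
    if params.g_ratio is None:
        raise ValueError("params.g_ratio is not set")
    return replace(params, V_T=float(vt_of_g_ratio(params.g_ratio)))


class VariabilityLabel(str, Enum):
    """Three-case threshold-variability classification."""

    CONSTANT = "CONSTANT"
    BOUNDED = "BOUNDED"
    UNBOUNDED = "UNBOUNDED"


@dataclass(frozen=True)
class VariabilityClass:
    """Result of the three-case criterion.

    ``theta_min`` equals ``V_T``; ``theta_max`` is the largest observable
    threshold (the intersection of the steady-state threshold curve with the
    diagonal), or ``+inf`` when no such intersection exists.
    """

    label: VariabilityLabel
    theta_min: float
    theta_max: float

    def __post_init__(self) -> None:
        if not self.theta_min <= self.theta_max:
            raise ValueError("theta_min must not exceed theta_max")
        if self.label is VariabilityLabel.UNBOUNDED and math.isfinite(self.theta_max):
            raise ValueError("UNBOUNDED requires theta_max = +inf")


def h_inf(V, params: NaChannelParams):
    """Steady-state Na inactivation (fraction of available channels).

    Boltzmann sigmoid ``1 / (1 + exp((V - V_i) / k_i))``; strictly decreasing
    in ``V``, equal to 1/2 at the half-inactivation voltage.  Accepts scalars
    or arrays.
    """
    V = np.asarray(V, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow saturates cleanly to 0
        out = 1.0 / (1.0 + np.exp((V - params.V_i) / params.k_i))
    return out if out.ndim else float(out)


def _softplus(x):
    # stable log(1 + e^x): linear branch avoids overflow for large x
    x = np.asarray(x, dtype=float)
    return np.where(x > 30.0, x, np.log1p(np.exp(np.minimum(x, 30.0))))


def _theta_inf_exact(V, params: NaChannelParams):
    # theta = V_T - k_a ln h_inf(V), i.e. a softplus above V_i
    V = np.asarray(V, dtype=float)
    out = params.V_T + params.k_a * _softplus((V - params.V_i) / params.k_i)
    return out if out.ndim else float(out)


def max_observable_threshold(params: NaChannelParams, mode: str = "exact") -> float:
    """Largest observable spike threshold, or ``+inf``.

    The membrane potential is always below threshold between spikes, so
    observable thresholds cannot exceed the intersection of the steady-state
    threshold curve with the diagonal ``theta = V``.  In ``piecewise`` mode
    this solves ``V_T + (k_a/k_i)(V - V_i) = V`` in closed form; in ``exact``
    mode it root-finds on the exact curve.  Returns ``+inf`` when no
    intersection exists (``k_a >= k_i`` in piecewise mode, up to the corner
    offset in exact mode).
    """
    beta = params.slope_ratio
    if mode == "piecewise":
        if beta >= 1.0:
            # parallel or steeper asymptote: the piecewise curve sits above
            # the diagonal whenever V_T > V_i and never meets it
            if params.V_T > params.V_i:
                return math.inf
            # V_T <= V_i: the flat branch already touches the diagonal
            return params.V_T
        return (params.V_T - beta * params.V_i) / (1.0 - beta)
    if mode != "exact":
        raise ValueError(f"mode must be 'exact' or 'piecewise', got {mode!r}")

    def gap(V: float) -> float:
        return _theta_inf_exact(V, params) - V

    # gap is +inf at V -> -inf; its derivative is beta*(1 - h_inf) - 1
    lo = min(params.V_T, params.V_i) - 400.0
    if beta < 1.0:
        # gap decreases monotonically to -inf: unique intersection
        hi = max(params.V_T, params.V_i) + 200.0
        while gap(hi) > 0:
            hi += 400.0
        return float(brentq(gap, lo, hi, xtol=1e-10))
    if beta == 1.0:
        # gap decreases monotonically to the limit V_T - V_i
        if params.V_T >= params.V_i:
            return math.inf
        hi = max(params.V_T, params.V_i) + 200.0
        while gap(hi) > 0:
            hi += 400.0
        return float(brentq(gap, lo, hi, xtol=1e-10))
    # beta > 1: gap has a single minimum at V_i - k_i*ln(beta - 1) and grows
    # on both sides; intersections exist only when that minimum dips below 0
    V_min = params.V_i - params.k_i * math.log(beta - 1.0)
    if gap(V_min) > 0:
        return math.inf
    return float(brentq(gap, lo, V_min, xtol=1e-10))


def classify_variability(
    params: NaChannelParams, tolerance: float = 1.0
) -> VariabilityClass:
    """Classify the threshold-variability regime of a channel.

    CONSTANT when the half-inactivation voltage lies at or above the minimum
    threshold (inactivation only engages above the operating range, so the
    steady-state threshold rise over the reachable range stays below
    ``tolerance``); otherwise BOUNDED when the steady-state threshold curve
    intersects the diagonal (guaranteed for ``k_a < k_i``); otherwise
    UNBOUNDED — arbitrarily slow depolarization then fails to trigger spikes.

    ``tolerance`` (mV) softens the CONSTANT boundary: channels with
    ``V_i >= V_T - tolerance`` whose threshold rise below ``V_T`` is within
    ``tolerance`` are labeled CONSTANT.
    """
    theta_rise_at_VT = _theta_inf_exact(params.V_T, params) - params.V_T
    if params.V_i >= params.V_T or theta_rise_at_VT <= tolerance:
        return VariabilityClass(
            VariabilityLabel.CONSTANT, params.V_T, params.V_T + min(theta_rise_at_VT, tolerance)
        )
    theta_max = max_observable_threshold(params, mode="exact")
    if math.isfinite(theta_max):
        return VariabilityClass(VariabilityLabel.BOUNDED, params.V_T, theta_max)
    return VariabilityClass(VariabilityLabel.UNBOUNDED, params.V_T, math.inf)


# ---------------------------------------------------------------------------
# channel tables

REQUIRED_COLUMNS = ("id", "subtype", "tissue", "V_i_mV", "k_i_mV", "k_a_mV")
OPTIONAL_COLUMNS = ("V_a_mV", "source")
TISSUE_TAGS = ("central", "sensory", "muscular", "synthetic")


@dataclass
class ChannelTable:
    """Tabular collection of Na-channel records for variability auditing.

    Thin, validated wrapper around a :class:`pandas.DataFrame` with the
    documented column schema.  Row ids must be unique and slope factors
    strictly positive.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"channel table missing required column(s): {missing}")
        errors = []
        for col in ("V_i_mV", "k_i_mV", "k_a_mV"):
            vals = pd.to_numeric(df[col], errors="coerce")
            for idx in df.index[vals.isna()]:
                errors.append(f"row {idx} (id={df.at[idx, 'id']!r}): non-numeric {col}")
            if col in ("k_i_mV", "k_a_mV"):
                for idx in df.index[vals <= 0]:
                    errors.append(
                        f"row {idx} (id={df.at[idx, 'id']!r}): non-positive {col}"
                    )
        if df["id"].duplicated().any():
            dups = df["id"][df["id"].duplicated()].tolist()
            errors.append(f"duplicate ids: {dups}")
        if errors:
            raise ValueError("invalid channel table:\n" + "\n".join(errors))
        for col in ("V_i_mV", "k_i_mV", "k_a_mV"):
            df[col] = pd.to_numeric(df[col])

    def __len__(self) -> int:
        return len(self.frame)

    def row_params(self, idx, V_T: float) -> NaChannelParams:
        """Channel parameters of one row under an assumed minimum threshold."""
        r = self.frame.loc[idx]
        return NaChannelParams(
            V_T=V_T, V_i=float(r["V_i_mV"]), k_a=float(r["k_a_mV"]), k_i=float(r["k_i_mV"])
        )


def read_channel_table(path) -> ChannelTable:
    """Read a channel table from CSV (comma-separated, header required)."""
    df = pd.read_csv(path, dtype={"id": str})
    return ChannelTable(df)


def write_channel_table(table: ChannelTable, path) -> None:
    """Write a channel table to CSV; round-trips through `read_channel_table`."""
    table.frame.to_csv(path, index=False)


def audit_table(
    table: ChannelTable, V_T_low: float = -55.0, V_T_high: float = -45.0,
    tolerance: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Classify every row at both assumed minimum-threshold bounds.

    Mirrors the literature-survey analysis: each channel is classified under
    a minimum spike threshold at ``V_T_low`` and at ``V_T_high`` (defaults
    -55 and -45 mV).  Returns the per-row frame (columns ``class_at_low``,
    ``class_at_high``) and a summary dict with counts per class and per
    tissue tag.
    """
    if not V_T_low < V_T_high:
        raise ValueError("V_T_low must be below V_T_high")
    if len(table) == 0:
        raise ValueError("cannot audit an empty channel table")
    rows = []
    for idx in table.frame.index:
        rec = {"id": table.frame.at[idx, "id"], "tissue": table.frame.at[idx, "tissue"]}
        for tag, vt in (("class_at_low", V_T_low), ("class_at_high", V_T_high)):
            rec[tag] = classify_variability(table.row_params(idx, vt), tolerance).label.value
        rows.append(rec)
    per_row = pd.DataFrame(rows)
    summary = {
        "n": len(per_row),
        "counts_at_low": per_row["class_at_low"].value_counts().to_dict(),
        "counts_at_high": per_row["class_at_high"].value_counts().to_dict(),
        "by_tissue_at_low": {
            t: g["class_at_low"].value_counts().to_dict()
            for t, g in per_row.groupby("tissue")
        },
    }
    return per_row, summary


def generate_synthetic_table(
    n: int,
    seed: int,
    V_i_range: tuple[float, float] = (-90.0, -25.0),
    k_i_range: tuple[float, float] = (4.0, 9.0),
    k_a_range: tuple[float, float] = (3.0, 9.0),
    tissues: Iterable[str] = TISSUE_TAGS[:3],
) -> ChannelTable:
    """Generate a synthetic channel table emulating the survey schema.

    Parameters are drawn uniformly within the given ranges (defaults span
    the reported range of half-inactivation voltages, −90 to −25 mV, and
    typical Boltzmann slopes).  Reproducible for a fixed ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, (lo, hi) in (("V_i", V_i_range), ("k_i", k_i_range), ("k_a", k_a_range)):
        if not lo < hi:
            raise ValueError(f"invalid {name} range {lo, hi}")
        if name != "V_i" and lo <= 0:
            raise ValueError(f"{name} range must be positive")
    rng = np.random.default_rng(seed)
    tissues = list(tissues)
    df = pd.DataFrame(
        {
            "id": [f"syn{i:03d}" for i in range(n)],
            "subtype": [f"Nav1.{rng.integers(1, 10)}" for _ in range(n)],
            "tissue": [tissues[rng.integers(0, len(tissues))] for _ in range(n)],
            "V_i_mV": np.round(rng.uniform(*V_i_range, size=n), 2),
            "k_i_mV": np.round(rng.uniform(*k_i_range, size=n), 2),
            "k_a_mV": np.round(rng.uniform(*k_a_range, size=n), 2),
            "source": ["synthetic"] * n,
        }
    )
    return ChannelTable(df)
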