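# spikethresh

Spike-threshold dynamics from fast sodium-channel inactivation: simulators,
closed-form analytics and measurement tools for the adaptive-threshold view
of neuronal excitability.

## The problem

In central neurons the spike threshold is not a constant: *in vivo* it is
correlated with the preceding membrane potential and *anti*-correlated with
the preceding rate of depolarization. A parsimonious biophysical candidate
is fast inactivation of the Na channels that initiate the spike, because it
moves the threshold without touching the membrane potential. With a
Boltzmann steady-state inactivation curve
h<sub>∞</sub>(V) = 1/(1 + exp((V − V<sub>i</sub>)/k<sub>i</sub>)) and an
exponential (EIF-type) approximation of the Na current, the threshold obeys

&nbsp;&nbsp;&nbsp;&nbsp;θ = V<sub>T</sub> − k<sub>a</sub> ln h,

where V<sub>T</sub> is the non-inactivated (minimum) threshold and
k<sub>a</sub> the activation slope factor. Substituting first-order
inactivation kinetics gives a relaxation equation for the threshold itself:

&nbsp;&nbsp;&nbsp;&nbsp;τ<sub>θ</sub> dθ/dt = θ<sub>∞</sub>(V) − θ,

with a steady-state curve θ<sub>∞</sub>(V) that is flat (V<sub>T</sub>)
below the half-inactivation voltage V<sub>i</sub> and rises with slope
k<sub>a</sub>/k<sub>i</sub> above it. Everything in this package unfolds
from these two equations:

* **`channels`** — channel parameter sets, the Boltzmann curve, the
  three-case threshold-variability criterion (constant / bounded /
  unbounded, decided by V<sub>i</sub> vs V<sub>T</sub> and
  k<sub>a</sub> vs k<sub>i</sub>), and CSV tables of measured channel
  properties with an auditing report.
* **`threshold_analytics`** — θ from h, the steady-state curve (exact and
  piecewise-linear), threshold sensitivity dθ/dV, the slope-threshold
  relation for linear depolarizations (numeric solver, closed form for
  k<sub>a</sub> = k<sub>i</sub>, divergence slope s*), the per-spike
  threshold increment, multi-subtype and slow/fast-gate composition, and
  the somatic onset shift under remote (axonal) spike initiation.
* **`simulators`** — the iEIF (exponential integrate-and-fire with an
  inactivation gate) and iLIF (leaky integrate-and-fire with an explicit
  adaptive threshold), a voltage-dependent-τ<sub>θ</sub> variant, a
  stochastic-threshold control model, and the clamp-and-release protocol
  that measures θ<sub>∞</sub> empirically. Hot loops are numba-compiled.
* **`inputs`** — Ornstein-Uhlenbeck currents (exact discretization), ramps,
  Poisson PSP trains and the ramp-plus-IPSP postinhibitory-facilitation
  protocol, all pure functions of (parameters, seed).
* **`psp_effective`** — closed-form effective-PSP algebra: the threshold's
  response to a PSP is a scaled unit-gain low-pass of the PSP, the
  effective PSP is the difference, and its half-width / peak time / zero
  crossing quantify how threshold adaptation sharpens synaptic integration.
* **`measurements`** — spike-onset detection (first-derivative method),
  pre-spike slope regression, threshold statistics and firing-rate maps.
* **`cli`** — `spikethresh` command with registered, seeded, desk-scale
  experiments that write CSV/JSON artifacts plus a checksummed manifest.

## Worked example

```python
import numpy as np
from spikethresh import (
    NaChannelParams, ThresholdModel, MembraneParams, SimConfig, StimulusSpec,
    classify_variability, steady_state_threshold, slope_threshold,
    simulate_ilif, prespike_slope, slope_correlation_sign,
    PSPKernel, effective_psp, kernel_metrics,
)

channel = NaChannelParams(V_T=-55.0, V_i=-63.0, k_a=6.0, k_i=6.0, tau_i=5.0)
model = ThresholdModel(channel=channel, tau_theta=5.0, steady_state_mode="piecewise")
membrane = MembraneParams(E_L=-70.0, tau_m=5.0, R=1.0)

print("variability class:", classify_variability(channel).label.value)
print("theta_inf(-60 mV) = %.2f mV" % steady_state_threshold(-60.0, model))
for s in (2.0, 5.0, 20.0):
    res = slope_threshold(s, model, E_L=-70.0)
    print("theta*(s=%4.1f mV/ms) = %.2f mV" % (s, res.theta_star))

cfg = SimConfig(dt=0.01, duration=20000.0, seed=42)
ou = StimulusSpec(kind="ou", mean=12.0, sigma=11.0, tau_c=2.0)
trace = simulate_ilif(model, membrane, ou, cfg)
print("OU-driven iLIF: %d spikes (%.1f Hz)" % (trace.n_spikes, trace.rate()))
slopes, skipped = prespike_slope(trace, window=5.0)
sign, rho = slope_correlation_sign(slopes, np.delete(trace.threshold_at_spike, skipped))
print("slope-threshold Spearman rho = %.2f" % rho)

psp = PSPKernel(kind="exponential", tau_m=10.0)
m_psp = kernel_metrics(psp)
m_epsp = kernel_metrics(effective_psp(psp, a=1.0, tau_theta=10.0))
print("PSP half-width %.2f ms, ePSP half-width %.2f ms (ratio %.2f)"
      % (m_psp.half_width, m_epsp.half_width, m_psp.half_width / m_epsp.half_width))
```

prints

```
variability class: UNBOUNDED
theta_inf(-60 mV) = -52.00 mV
theta*(s= 2.0 mV/ms) = -46.92 mV
theta*(s= 5.0 mV/ms) = -53.37 mV
theta*(s=20.0 mV/ms) = -54.67 mV
OU-driven iLIF: 73 spikes (3.6 Hz)
slope-threshold Spearman rho = -0.51
PSP half-width 6.93 ms, ePSP half-width 3.15 ms (ratio 2.20)
```

Reading: with k<sub>a</sub> = k<sub>i</sub> and V<sub>i</sub> below
V<sub>T</sub>, the steady-state curve runs parallel to the identity line,
so the observable threshold is unbounded — a sufficiently slow
depolarization (below s* = (V<sub>T</sub> − V<sub>i</sub>)/τ<sub>θ</sub> =
1.6 mV/ms here) never fires. Faster ramps catch the threshold closer and
closer to its floor V<sub>T</sub> = −55 mV, which is the negative
slope-threshold relation the Spearman ρ of the fluctuation-driven run
exhibits. On the synaptic side, an adapting threshold with
dθ/dV = 1 and τ<sub>θ</sub> equal to the PSP decay time cuts the effective
width of a PSP by a factor of 2.2 — coincidence detection tightens as the
neuron depolarizes.

Named experiments (steady-state curves, regression sweeps, threshold and
rate maps, ePSP sweeps, postinhibitory facilitation, control models) run
from the shell:

```bash
spikethresh list-experiments
spikethresh experiment slope-threshold --seed 1 --out results
spikethresh audit-channels my_channels.csv --out audit
```

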