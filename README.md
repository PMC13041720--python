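# dcsmc

Monte Carlo simulation of time-of-flight-resolved diffuse correlation
spectroscopy (DCS) and pulsatile blood-flow recovery in layered tissue at
1064 nm.

## The problem

Optical monitors of cerebral blood flow (CW-DCS, time-domain DCS, speckle
contrast optical spectroscopy) infer a blood-flow index (BFi ∝ the Brownian
diffusion coefficient αDB of red blood cells) from the decorrelation of
multiply-scattered coherent light. The measured signal mixes brain and
scalp blood flow; instrument designers must choose source–detector
separation (SDS), photon time-of-flight (ToF) gating, and acquisition
frequency to make the recovered *pulsatile* waveform brain-dominated. This
package provides the forward simulation machinery to quantify those
trade-offs: for which SDS, ToF gate, or minimum autocorrelation lag does
the recovered BFi pulse track cerebral rather than scalp flow?

## The model

A scattering-only ("white") Monte Carlo traces photons through a layered
slab (scalp/skull/CSF/brain, or a bilayer phantom), recording each detected
photon's per-layer partial pathlengths `L_pn` and dimensionless momentum
transfers `Y_pn = Σ(1−cosθ)`. The ToF-resolved field autocorrelation for
any flow/absorption state follows without re-simulation:

```
G1(ts, τ) = (1/Np) Σ_p w_p exp(−2 τ Σ_n k0,n² Y_pn αDB,n),
w_p = exp(−Σ_n μa,n L_pn),   k0,n = 2π n_n / λ
```

(Brownian scatterer motion, ⟨Δr²⟩ = 6 αDB τ). Derived observables:
the CW autocorrelation (ToF integral), g2 via the Siegert relation
`g2 = 1 + β|g1|²`, and the SCOS squared speckle contrast
`K²(T) = (2β/T)∫₀ᵀ(1−τ/T)|g1|²dτ`. Layer sensitivities are the analytic
lag integrals `S_n = |∫ αDB,n ∂g1/∂αDB,n dτ|` and brain sensitivity is
`S_brain/(S_brain+S_scalp)`. BFi is recovered per modality: per-ToF
single-exponential fits `g1 = e^{−ξ(ts)τ}` inverted through the
diffusing-wave relation `ξ = 2k²μs′(c/n)αDB·ts` (TD), a semi-infinite
correlation-diffusion fit (CW-DCS), or the speckle contrast used directly
(SCOS). A synthetic cardiac waveform drives pulsatile scalp/brain αDB and
μa; Pearson correlations of the recovered rBFi against the brain and scalp
ground truths locate the **crossing SDS / crossing ToF** — the operating
point beyond which the measurement is brain-dominated.

## Worked example

```python
import numpy as np
from dcsmc import (adult_head_preset, wavelength_1064, simulate,
                   TransportConfig, FlowAbsorptionState, IRFKernel,
                   layer_sensitivities, WaveformSpec, make_waveform,
                   td_tof_crossing)

wl = wavelength_1064()
medium = adult_head_preset()                      # 4 mm scalp / 6 mm skull / 2 mm CSF / brain
table = simulate(medium, wl, TransportConfig(
    n_photons=1_000_000, rng_seed=7, max_tof=1.9e-9, max_radius=60.0))

# brain sensitivity of a time-resolved measurement, 10 mm SDS, 200 kHz,
# IRF-convolved 1.2 ns gate
sens = layer_sensitivities(table, FlowAbsorptionState.from_medium(medium),
                           wl, tau_min=5e-6, annulus=(9.0, 11.0),
                           irf=IRFKernel(125e-12, 25e-12), gate_center=1.2e-9)
print(f"brain sensitivity at 1.2 ns: {sens.brain_sensitivity:.3f}")

# crossing ToF of the pulsatile recovery
series = make_waveform(WaveformSpec(n_points=400), medium)
cross = td_tof_crossing(table, series, wl)
print(f"crossing ToF: {cross.crossing*1e9:.2f} ns")
```

Output from this exact run (seed 7):

```
brain sensitivity at 1.2 ns: 0.403
crossing ToF: 0.98 ns
```

The first number is the fraction of the measurement's lag-integrated
relative-flow sensitivity attributable to the brain layer: at a 1.2 ns
gate, brain and scalp contribute almost equally. The second is the gate
time at which the recovered pulsatile rBFi switches from correlating more
with scalp flow to correlating more with cerebral flow — at this 10 mm SDS
the recovery is brain-dominated only for gates beyond ~1 ns.

A CLI mirrors the library (`dcsmc presets`, `dcsmc simulate`,
`dcsmc forward`, `dcsmc sensitivity`, `dcsmc fit`, `dcsmc pulsatile`,
`dcsmc crossing`, `dcsmc run scenario.yaml`); photon tables persist as
HDF5, curves as CSV, and every scenario writes a JSON manifest with the
seed and configuration hash (cached transport is reused across analyses).

## Layout

- `src/dcsmc/medium.py` — layered media and presets (adult head, bilayer
  intralipid phantom, homogeneous reference)
- `src/dcsmc/transport.py`, `_kernels.py` — numba photon transport, photon
  lookup tables (HDF5)
- `src/dcsmc/forward.py` — G1 surfaces, IRF convolution, Siegert, speckle
  contrast, log-lag resampling
- `src/dcsmc/sensitivity.py` — analytic ∂g1/∂αDB and lag-integrated layer
  sensitivities
- `src/dcsmc/recovery.py` — TD / CW-DCS / SCOS BFi extraction
- `src/dcsmc/pulsatile.py` — pulsatile ground truth, table replay,
  crossing analysis, depth sweeps
- `src/dcsmc/config.py`, `cli.py` — scenarios, presets, caching, CLI
- `src/dcsmc/oracles.py` — independent closed-form/brute-force references
  used by the tests
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  details, and known limitations
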