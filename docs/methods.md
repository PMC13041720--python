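# Methods

## Transport model

Photons are launched as a pencil beam normal to the top surface of a
plane-parallel layered slab and traced with exponential free paths (local
μs = μs′/(1−g)), Henyey–Greenstein deflections (local g), and
Snell/Fresnel interface handling (unpolarized reflectance, total internal
reflection; ambient index 1.0 above the top surface, i.e. a bare probe in
air). Transport is scattering-only — *white Monte Carlo*: absorption never
terminates a photon but is applied afterwards as weights
`w_p = exp(−Σ_n μa,n L_pn)` from the stored per-layer partial pathlengths.
One transport run therefore serves every absorption and flow state, which
is what makes the 1000-point pulsatile replays affordable.

Each detected photon records per-layer pathlength `L_pn` and dimensionless
momentum transfer `Y_pn = Σ(1−cosθ)` over its scattering events in layer
n; boundary refractions do not contribute to Y. ToF is Σ L_pn·n_n/c.
Detection accepts *every* photon crossing the top surface regardless of
exit angle or azimuth, binned by exit radius into annuli. The lateral
symmetry of the slab turns a fiber-sized detector into a full ring,
multiplying the effective detector area by ~10³ — necessary for per-ToF
statistics at desk scale. This changes absolute detected fractions
relative to a finite-NA fiber but not the normalized g1 shapes; it is the
main known systematic relative to point-detector simulations.

Termination: ToF > `max_tof` (default 5 ns), lateral radius > `max_radius`
(default 120 mm), or exit through the bottom of the deepest layer. The
deepest layer is "semi-infinite" via a 150 mm thickness combined with the
ToF cap. CSF is an ordinary low-scattering layer (μs = 0.09 mm⁻¹), no
specialty transport. The RNG is the numba-seeded NumPy generator; each
200 000-photon chunk gets a derived sub-seed, so runs are deterministic
for a fixed seed and reproducible across machines.

## Media

The default four-layer adult head (1064 nm): scalp 4 mm (μa 0.012, μs′
0.84 mm⁻¹, g 0.9, n 1.4, αDB 1×10⁻⁶ mm²/s), skull 6 mm (μa 0.013, αDB
2×10⁻⁸), CSF 2 mm (μa 0.012, μs′ 0.009, n 1.33, αDB 5×10⁻⁸), brain
semi-infinite (μa 0.017, αDB 5×10⁻⁶). Distance-to-brain is varied 9–18 mm
through skull thickness. The bilayer intralipid phantom preset is a 10 mm
top layer (μs′ 0.55 mm⁻¹) over a semi-infinite bottom layer of selectable
μs′ (0.55/1.0/1.8/2.6 mm⁻¹), both with μa 0.015 mm⁻¹ (water), n 1.33 and
g 0.53 (intralipid at 1064 nm); the thin separating film of the physical
phantom is neglected. Intralipid αDB is not tabulated, so both layers use
1×10⁻⁵ mm²/s — the phantom's depth-selectivity behaviour (late-ToF ξ
upturn ordered by bottom μs′) is independent of its absolute value.

## Autocorrelation synthesis

For a state (αDB, μa) per layer,

    G1(ts, τ) = (1/Np) Σ_p w_p exp(−2 τ Σ_n k0,n² Y_pn αDB,n)

on a uniform ToF grid (default 25 ps bins over 0–3 ns, well below the
125 ps IRF) and a lag grid of τ=0 plus 40 log-spaced points per decade
(default 10⁻⁸–1 s). `Np` is the total detected count, so the τ=0 column is
the absorption-weighted TPSF. The wavenumber is evaluated per layer
(k0,n = 2πn_n/λ) inside the layer sum, consistent with per-layer Y
accumulation; for the head's indices (1.33/1.4) the difference from a
single global k0 is below 1%.

Time-resolved measurements convolve G1 along ToF with a Gaussian IRF
surrogate (FWHM 125 ps, truncated at ±4σ, unit sum) — only the width of
the hardware IRF is modelled; users probing IRF effects vary the FWHM. A
ToF gate is one post-convolution 25 ps bin; in the optimized replay path
the same operation is applied per photon as a kernel weight at the
photon's bin offset from the gate bin, which is algebraically identical to
convolving the binned surface (a unit test asserts the equivalence to
1e-6). g1 for a gate is normalized gate-locally; CW uses the
ToF-integrated G1(0). β defaults to 1 (noise-free limit) and enters only
the Siegert relation and speckle contrast.

Quadrature throughout (speckle-contrast exposure integral, sensitivity lag
integrals) is composite Simpson on the log-spaced grid via
`scipy.integrate.simpson`, trapezoid below 3 nodes, with interpolated
endpoints where the integration limit falls between nodes.

## Sensitivity metrics

The relative-flow sensitivity of layer n is s′_n(τ) = αDB,n ∂g1/∂αDB,n,
computed analytically from the photon sums (G1(0) carries no αDB
dependence, so no quotient-rule term; validated against central finite
differences to 1e-5 relative). Layer sensitivity for an acquisition with
minimum resolvable lag τmin = 1/f_acq is |∫_{τmin}^{1 s} s′_n dτ|; 1 s is
an effectively infinite upper bound. Brain sensitivity is
S_brain/(S_brain+S_scalp): raw sensitivities are single-signed (negative),
magnitudes are reported so the ratio lies in [0, 1]; skull and CSF
sensitivities are computed but excluded from the ratio (they are 20–50×
smaller than scalp on the default head).

A caveat at very large minimum lags: S_n(τmin = 1 ms) is carried by the
rare photons whose total decorrelation rate is ≲10³ s⁻¹. In a 10⁶-photon
desk run, a 30 mm annulus holds only tens of such photons, so
brain-sensitivity values at millisecond minimum lags are extreme-tail
statistics with large MC uncertainty; the qualitative collapse (a >2×
drop from the small-lag plateau) is robust, the exact ratio is not.

## Pulsatile pipeline

The ground-truth waveform is synthetic: a periodic cardiac-like beat (two
Gaussian lobes per cycle — systolic peak and dicrotic bump) at 1 Hz,
sampled at 50 Hz for 1000 points (20 s). Each of scalp and brain αDB(t)
is scaled about its baseline to a pulsatility index (max−min)/mean of 0.8;
the scalp waveform is the brain waveform delayed by π/4 of a cycle
(0.125 s). Absorption in scalp and brain follows the low-pass-filtered
(2 Hz, second-order Butterworth, zero-phase) flow waveform rescaled to a
3% peak deviation — a blood-volume surrogate in the middle of the
physiological 2–4% range; both extremes are exposed as configuration.
Crossing points are insensitive to the beat morphology (asserted in the
suite by swapping in an asymmetric sawtooth at the same pulsatility and
phase), which is what justifies a synthetic stand-in for a measured
arterial waveform.

Replay: one photon table, 1000 states. TD recovers αDB(t) by per-ToF
single-exponential fits of ln g1 through the origin — lags below
τmin = 1/f_acq are unavailable to the instrument; points with g1 < 0.5 are
discarded unless fewer than six would remain, in which case the first six
lags are used — then inverts ξ = 2k²μs′(c/n)αDB·ts at the gate ToF with
the scalp-layer optics as the effective homogeneous medium. CW-DCS fits
the semi-infinite extrapolated-boundary correlation-diffusion model
(decay argument K² = 3μaμs′ + 6μs′²k²αDBτ, source depth 1/μs′,
extrapolated boundary from the effective reflection coefficient at the
tissue/air index ratio), one free parameter (log10 αDB), over lags where
the model stays above g1 = 0.01 (the window is re-evaluated once after an
initial fit). SCOS uses K²(T) directly with rBFi = 1 − K²/K²(t₀) so
higher flow is positive. All rBFi are relative to the first time point.
Pearson correlations against the brain and scalp ground truths are
computed per operating point; the crossing SDS/ToF is the linear
interpolation of the zero of r_CBF − r_SBF between the bracketing grid
points (the curves are smooth and near-linear there). Default sweeps:
ToF 0.3–1.6 ns in 0.1 ns steps at 10 mm SDS (TD, 200 kHz); SDS 10–50 mm in
2.5 mm annuli (CW at 5000 kHz, SCOS at 250 μs exposure).

For CW/SCOS replays an annulus is deterministically thinned to at most
30 000 photons (seeded subsample) — a variance/runtime trade-off that
leaves Pearson correlations unchanged at the three-decimal level.

## Problem sizes

The test suite runs transports of 0.4–1.5×10⁶ photons per geometry and
shares each table across a module; the acceptance script uses 4×10⁶
photons, 1000 time points and the full 14-gate ToF sweep. At these sizes
per-gate photon counts at 10 mm SDS range from ~10⁴ (0.3 ns) to ~10²
(1.6 ns), so late-gate quantities carry a few-percent MC scatter and
stochastic tolerances apply to all headline numbers.

## Design choices that were genuinely open

- **Eq-form of the exponent.** The mean-squared-displacement form
  (1/3)k0²Y⟨Δr²⟩ with ⟨Δr²⟩ = 6αDBτ is collapsed algebraically to
  2k0²τ·Σ Y αDB; per-layer k0 inside the sum.
- **Normalization of g1 for sensitivities** is at τ = 0 (the TPSF), which
  is flow-independent; renormalizing at the first *measured* lag instead
  would introduce a quotient-rule term and destroys the small-lag plateau
  of brain sensitivity, contradicting the behaviour the metric is meant to
  capture.
- **TD fit** is log-linear least squares through the origin rather than a
  nonlinear fit: the model is one-parameter and the simulation noise-free,
  so the estimator is exact on pure exponentials.
- **CW fit optics**: the scalp layer's (μa, μs′, n) serve as the effective
  homogeneous medium — fitting a homogeneous model to layered data is
  deliberate, mirroring how such measurements are analyzed in practice.
- **Ambient index** 1.0 (air); index-matched detection would mildly raise
  detected fractions but not normalized decays.

## Known limitations

- No hardware noise, photon shot noise, speckle/β statistics, or
  detection-chain modelling: every result is a noise-free upper bound on
  real-instrument performance.
- Annular full-angle detection (see above): absolute photon yields are not
  those of a fiber; comparisons are between operating points, not absolute
  count rates.
- Slab geometry only; no anatomical meshes or curved surfaces.
- The Gaussian IRF surrogate carries only the width of a real instrument
  response; asymmetric tails are not modelled.
- The synthetic-data generator emulates waveform phase, pulsatility and
  blood-volume coupling, but not beat-to-beat variability, respiration, or
  motion artifacts — passing tests demonstrate correct forward physics and
  recovery machinery, not robustness to physiological confounds.
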