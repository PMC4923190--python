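# Methods

## Volume-conductor model

The extracellular medium is treated as an infinite, homogeneous, isotropic,
purely ohmic volume conductor under the quasistatic approximation: electric
and magnetic fields decouple and the potential follows the source currents
instantaneously. Conductivity `σ` defaults to 0.3 S/m (resistivity
1/0.3 ≈ 3.33 Ω·m is stored as the exact reciprocal); both are configurable,
and amplitudes of the point- and line-source schemas are exactly linear in
resistivity. Frequency-dependent or anisotropic conductivity, electrode tip
geometry, impedance, and slice–chip saline layers are out of scope.

Units at the API surface are the electrophysiology conventions — µm, ms,
nA, µV, S/m — chosen so that `I/(4πσr)` with I in nA, r in µm and σ in S/m
is exactly mV·10⁻³, i.e. a single factor of 10³ converts to µV.
Outward membrane current is positive and produces a positive extracellular
potential.

### Point-source and line-source schemas

PSA places each compartment's current at the neurite centre
(`Φ = I/(4πσr)`); LSA distributes it uniformly along the axis segment and
uses the closed-form log expression with the cylindrical coordinates
`(r, h, l)` of the electrode relative to the segment (`h` measured from the
segment end, `l = Δs + h` from its start). The closed form holds for every
sign of `h`; both log factors are positive whenever `r > 0`. Numerical
care: for `h > 0` (or `l > 0`) the factor `√(v²+r²) − v` is evaluated as
`r²/(√(v²+r²)+v)` to avoid catastrophic cancellation at far field. An
adaptive-quadrature evaluation of the defining integral is shipped as a
test oracle and agrees with the closed form to better than 10⁻⁶ relative
over randomized geometries.

Distances are clamped from below to `max(min_distance, segment radius)`
with `min_distance` defaulting to 1 µm: the line-source kernel is only
meaningful outside the neurite and diverges logarithmically at `r → 0`.
Zero-length (spherical soma) sources always use the point-source kernel,
whatever schema is selected, since the line source is undefined at
`Δs = 0`.

### RC schema

The printed first-order form of the RC schema multiplies each current by a
constant exponential factor and carries no distance dependence, which is
dimensionally incomplete as a field model. It is implemented here as the
physically standard reading: a causal first-order low-pass filter with
normalized kernel `(1/τ)e^{−t/τ}` (discretized as
`y[k] = α x[k] + (1−α) y[k−1]`, `α = dt/(τ+dt)`, DC gain exactly 1)
applied to every source current, combined with the PSA geometric factor so
the output is a distance-dependent voltage. The literal distance-free
summation of filtered currents remains available behind the
`rc_literal=True` flag. The time constant `τ` is exposed directly
(default 5 ms) because the stored medium parameters `E_R = 0.35` Ω·m
(squid-axon cytoplasmic resistivity convention) and `E_C = 0.01` F/m²
(1 µF/cm², the specific membrane capacitance) do not reduce to a time
without an unstated length scale; they are kept on `Medium` for
provenance. The filter reduces and smooths fast transients; quantitative
wave-width claims are deliberately not part of the test surface.

## Cable simulator

The simulator exists to produce the per-compartment transmembrane currents
(ionic + synaptic + capacitive, outward-positive) that the forward schemas
consume. Design choices:

* **Membrane**: classical Hodgkin–Huxley squid kinetics
  (ḡNa = 120, ḡK = 36, g_leak = 0.3 mS/cm², ENa = 50, EK = −77,
  EL = −54.3 mV, c_m = 1 µF/cm²) as the default spiking mechanism;
  passive compartments are the same machinery with zero Na/K density and
  EL = −65 mV. These reduced membranes stand in for detailed published
  channel sets, which are out of scope; network results are therefore
  qualitative (directions, orderings, frequencies), never absolute
  amplitudes or latencies of any specific preparation.
* **Integration**: backward-Euler voltage step on the branched tree, solved
  by Hines elimination (parent-before-child ordering), with gating
  variables advanced by exponential Euler at the pre-step voltage.
  Unconditionally stable for the stiff cable system; first-order accurate
  (halving dt moves spike times by less than dt). Default dt = 0.025 ms,
  the conventional compartmental step.
* **Kirchhoff closure by construction**: the recorded transmembrane current
  is evaluated from the same implicit update that advances the voltage, so
  per cell it sums to exactly the injected electrode current at every step
  (machine precision). This is what makes the dipolar far-field decay of a
  synaptically driven cell a testable property. At the initial sample all
  compartments share one potential, so the recorded currents are exactly
  zero there.
* **Synapses**: conductance-based double-exponential kinetics
  (`tau_decay > tau_rise > 0`, peak-normalized). Excitatory synapses are
  AMPA-like with an optional colocated NMDA-simplified slow component
  (fraction of the fast weight, decay ≈ 30–50 ms, optional sigmoidal
  voltage scaling in place of full Mg-block kinetics); inhibition is
  GABA-A-like (E_rev = −75 mV). Synaptic current counts as transmembrane
  current of the target compartment, which both matches the physical
  picture and preserves Kirchhoff closure. Presynaptic spikes are thinned
  per event by the synapse's release probability using one uniform draw
  per spike in a fixed deterministic order — so scaling release
  probability (plasticity) grows or shrinks the released-event set
  monotonically at a fixed seed.
* **Population engine**: the integrator is vectorized across cells sharing
  one morphology template (state arrays of shape `n_cells × n_comp`);
  single-cell simulation is the `n_cells = 1` case. The default 730-cell
  evoked protocol (200 ms at dt = 0.025 ms) runs in seconds on one CPU.
  Network runs record currents at a 4-step stride (0.1 ms) to bound
  memory; single-cell runs record every step.
* Divergence (non-finite or > 10⁶ mV voltages) raises a solver error
  naming the simulated time.

## Demo morphologies and networks

`granule_like` is a spherical soma (6 µm), four short passive dendrites
each carrying one excitatory and one inhibitory synapse at its tip
(8 synapses: 4 + 4), and a two-compartment active ascending axon.
`ball_and_stick` (10 µm soma + 100 µm passive dendrite, one excitatory
synapse) and `pyramidal_like` (soma, apical trunk, two basals) cover the
other demos. The seed only perturbs dendrite azimuths.

The granular-layer generator packs its default 730 granule-like somata
uniformly at random (overlap permitted) into a 35 µm cube around the
origin, wires each cell's 4 excitatory synapses to randomly chosen mossy
fibers (default 40) and its 4 inhibitory synapses to a single lumped
Golgi-like feedback population with a fixed 2 ms delay — the full
multi-channel Golgi model is out of scope and inhibition here only shapes
the falling phase of the evoked wave. The generator reports its realized
synapse count (730 × 8 = 5840).

Protocols:

* **in vitro**: one mossy-fiber volley at t = 20 ms in a 200 ms run, with
  0.2 ms per-cell Gaussian jitter. The population discharge produces the
  evoked negative LFP wave above the patch. With `doublet=True` a second
  volley follows 8 ms later — long enough for the HH stand-in cells to
  recover excitability — giving two separable negative components
  (N2a/N2b-like pair). Negative-wave detection: peaks of the
  baseline-subtracted, sign-flipped trace within 25 ms of onset with
  prominence ≥ 10% of the global extremum.
* **in vivo**: a 3-spike 500 Hz-like burst (2 ms intervals) followed by a
  second burst 15 ms later, yielding two separated evoked components
  (trigeminal- and cortical-like). The 15 ms latency is a design choice
  that separates the components cleanly; it is not a measured physiological
  value.
* **center-surround**: Gaussian spatial weighting of the excitatory drive
  (center radius = volume edge / 4 by default); cells outside the center
  receive drive scaled by max(Gaussian, 0.5) and delayed 2 ms. On the
  default 4×4 grid this makes the 4 central electrodes read larger evoked
  amplitudes than the 12 peripheral ones.
* **plasticity**: LTP/LTD as multiplicative changes to excitatory release
  probability (clipped to [0, 1]) and Na-channel density — presets
  (1.5, 1.2) and (0.6, 0.85). Because release draws are monotone in the
  probability at fixed seed, the evoked-amplitude ordering
  LTP > baseline > LTD is a designed, assertable property. At very small
  populations (≈100 cells) weaker drive can occasionally *sharpen*
  population-spike synchrony enough to blur the ordering for particular
  seeds; at the default 730-cell scale the ordering holds with wide
  margins, and that is the scale at which the property is asserted.
* **oscillation**: ball-and-stick populations (default 64 cells in a 50 µm
  cube) receive synaptic volleys at the drive period with 1.5 ms per-cell
  jitter; the LFP spectrum peaks at the drive frequency (8/32/56 Hz
  demos). The generator requires the duration to cover at least 8 drive
  cycles.

## Spectral and amplitude metrics

`dominant_frequency` uses a plain Hann-windowed FFT periodogram (bin width
= 1/duration) and requires at least 8 cycles of the band's low edge;
`spectral_peak_ratio` (peak vs median power, used to *reject* spurious
peaks) instead uses a Welch estimate over ~8 segments so single-bin
fluctuations of a flat spectrum are averaged down, and treats spectra
below the floating-point floor of the signal's own scale as peakless.
`peak_amplitude` subtracts the pre-window baseline and returns the signed
extremum of largest magnitude. Attenuation curves report peak magnitude
versus distance along a ray from the source centroid; the PSA/LSA
"similarity distance" uses a 1% relative-difference threshold (the
qualitative claim being operationalized is "similar amplitude and shape"
beyond roughly 120 µm for granule-scale segments).

## What the synthetic data does and does not show

The generators emulate population geometry, synaptic convergence, release
stochasticity, evoked timing structure and oscillatory entrainment — the
ingredients the forward model integrates over. They do not emulate real
channel complements, dendritic nonlinearities, realistic axonal
propagation, ephaptic coupling, electrode filtering or tissue
heterogeneity. Passing tests therefore validate the forward schemas, the
integrator's conservation and convergence properties, and the qualitative
population phenomena (wave directions and counts, spatial contrast,
plasticity ordering, spectral entrainment) — not quantitative agreement
with any experimental recording.

## Numerical conventions

CSV output uses a fixed dialect (comma separator, header row, 9
significant digits) so identical inputs and seeds give byte-identical
files. Grids are ordered row-major from the origin with labels `r{i}c{j}`.
SWC coordinates are taken as-is in a right-handed µm frame; single-point
somata become equivalent spheres (membrane area πd², exported as
zero-length sources). All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; no global RNG state is touched.
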