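# neurolfp

Forward modeling of extracellular electric potentials and local field
potentials (LFPs) from compartmental neuron models.

Extracellular electrodes see the superposed volume-conducted signature of
the transmembrane currents of nearby neurons. `neurolfp` computes that
signature — for a single reconstructed neuron or for a simulated
population, at one electrode or across a simulated multi-electrode array
(MEA) — from per-compartment transmembrane current time series. It is
aimed at computational neuroscientists who want reproducible forward
models of LFPs and simulated MEA recordings without coupling to a full
simulation platform: the package ships a minimal Hodgkin–Huxley cable
simulator and network generators, so every computation here runs from
scratch with no external data.

## The forward model

A neuron is decomposed into compartments; each compartment *i* contributes
its transmembrane current `I_i(t)` (ionic + synaptic + capacitive,
outward-positive, in nA) as a current source in an infinite, homogeneous,
purely ohmic volume conductor with conductivity `σ` (quasistatic
approximation). Three schemas map sources to the potential `Φ` at an
electrode:

* **Point-source approximation (PSA)** — the current emanates from the
  compartment centre:

      Φ = I / (4π σ r),      Φ_LFP = Σ_i  I_i / (4π σ r_i)

* **Line-source approximation (LSA)** — the current is spread uniformly
  along the compartment axis of length `Δs`; integrating the point-source
  kernel along the segment gives

      Φ = I / (4π σ Δs) · ln[ (√(h²+r²) − h) / (√(l²+r²) − l) ]

  where `r` is the radial distance from the line, `h` the axial distance
  from the segment end and `l = Δs + h` the distance from its start.
  A quadrature evaluation of the underlying integral is provided as an
  independent oracle (`lsa_quadrature`).

* **RC schema** — the medium's low-pass property modeled as a first-order
  resistance–capacitance filter (time constant `τ`, DC gain 1) applied to
  each source current and combined with the PSA geometric factor.

Spherical somata (zero-length sources) always use the point-source kernel.
An MEA recording is the same computation evaluated on an ordered electrode
grid — by default 4×4 electrodes at 100 µm pitch.

Everything upstream of these formulas is also included: a
backward-Euler/Hines compartmental cable simulator with classical
Hodgkin–Huxley channels and conductance synapses (AMPA with optional
NMDA-like slow component, GABA), demo morphologies, a cerebellar
granular-layer network generator (730 granule-like cells, 40 mossy
fibers in a 35 µm cube, 4 excitatory + 4 inhibitory synapses per cell)
with evoked and plasticity (LTP/LTD) protocols, and an oscillatory
population demo (8/32/56 Hz drives). See `docs/methods.md` for the model
details and their assumptions.

## Worked example

```python
import numpy as np
from neurolfp import *

# a granule-scale line source: 10 um segment, 1 um diameter
seg = SegmentSource("dend", Point3(0, 0, 0), Point3(10, 0, 0), 1.0)
med = Medium()                       # sigma = 0.3 S/m, resistivity 1/0.3 Ohm*m
lsa_potential(1.0, seg, (5.0, 10.0, 0.0), med)   # -> 25.529 uV
psa_potential(1.0, 100.0, med)                   # -> 2.6526 uV

# simulate a spiking demo neuron and compute its extracellular signature
model = make_demo_neuron("ball_and_stick", seed=0)
proto = StimulusProtocol(spike_trains={0: [10.0, 25.0, 40.0]})
res = simulate(model, proto, t_stop=60.0, seed=0)
res.spikes                                        # -> [11.7, 26.725, 41.775] ms
trace = compute_lfp(res.sources, ElectrodeArray.single((20.0, 0.0, 0.0)), med, "lsa")
```

The first value is the line-source potential of a 1 nA current 10 µm from
the segment midpoint; the second, the point-source potential at 100 µm —
both in microvolts, positive for net outward current. The simulated cell
fires three synaptically evoked spikes; near the soma each appears in the
LFP trace as a sharp negative deflection (the peak in a window around the
first spike is −7.91 µV), the classic signature of the somatic sodium
sink.

The same pipelines are scriptable from the shell:

```sh
neurolfp simulate --demo granule_like --t-stop 100 --out currents/
neurolfp mea --currents currents/ --method lsa --out mea            # 4x4 grid
neurolfp demo-granular --mode in_vitro --n-cells 730 --seed 1 --out evoked
neurolfp demo-oscillation --freq 32 --n-cells 16 --duration 2000 --out osc
# INFO neurolfp: dominant LFP frequency: 32.00 Hz (drive 32.00 Hz)
```

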