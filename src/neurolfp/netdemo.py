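"""Synthetic population generators and stimulation protocols.

Reproduces, at demonstration scale, the two population settings the
forward model is typically used in:

* a cerebellar **granular-layer** patch — granule-like cells packed in a
  small cubic volume, driven by mossy-fiber (MF) volleys, with lumped
  Golgi-type feedback inhibition — producing the evoked post-synaptic LFP
  (in vitro N2a/N2b-like waves, in vivo T/C-like double volley), optionally
  under LTP/LTD-style plasticity (release-probability and Na-excitability
  scaling);
* an **oscillatory** population of reduced neurons receiving periodic
  synaptic volleys at a stated drive frequency (8/32/56 Hz demos), whose
  LFP spectrum peaks at the drive frequency.

Default network scale: 730 granule-like neurons, 40 mossy fibers, packed
in a 35 um cube, 4 excitatory + 4 inhibitory synapses per cell. These are
the study conditions, not tuning knobs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cablesim import (
    CableModel,
    StimulusProtocol,
    make_demo_neuron,
    simulate_population,
)
from .core import (
    ConfigurationError,
    ElectrodeArray,
    LFPTrace,
    Medium,
    Point3,
)
from .forward import compute_lfp

GOLGI_FEEDBACK_DELAY_MS = 2.0  # lumped inhibitory population, fixed delay
# Second-volley offset when doublet firing is enabled: long enough for the
# stand-in HH cells to leave their refractory period and discharge again,
# giving two separable evoked components.
DOUBLET_INTERVAL_MS = 8.0


@dataclass(frozen=True)
class CenterSurround:
    """Gaussian spatial weighting of the afferent drive.

    Cells within ``center_radius`` of the volume centre receive full,
    immediate drive; cells outside receive drive scaled by
    ``max(surround_scale, exp(-r^2 / 2 center_radius^2))`` and delayed by
    ``surround_delay``.
    """

    center_radius: float
    surround_scale: float = 0.5
    surround_delay: float = 2.0


@dataclass
class ProtocolSpec:
    """A stimulation protocol for :func:`run_protocol`.

    mode          one of ``in_vitro`` (single MF volley), ``in_vivo``
                  (burst followed by a delayed second volley: T- and C-like
                  components), ``oscillation`` (periodic volleys at
                  ``drive_freq``)
    onset         stimulus onset, ms
    duration      total simulated time, ms
    burst_n       spikes per volley (in vivo default 3)
    burst_interval  intra-burst interval, ms
    second_volley_dt  onset of the second (cortical-like) volley relative
                  to the first, ms (in vivo)
    drive_freq    Hz, oscillation mode only
    drive_amplitude  multiplier on synaptic drive (0 disables the stimulus)
    jitter_ms     s.d. of per-cell Gaussian timing jitter
    doublet       in vitro only: add a second volley 5 ms after the first
                  so the population fires a doublet (N2a/N2b-like pair)
    center_surround  optional spatial weighting of the drive
    """

    mode: str
    onset: float = 20.0
    duration: float = 200.0
    burst_n: int = 1
    burst_interval: float = 2.0
    second_volley_dt: float = 15.0
    drive_freq: float | None = None
    drive_amplitude: float = 1.0
    jitter_ms: float = 0.2
    doublet: bool = False
    center_surround: CenterSurround | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("in_vitro", "in_vivo", "oscillation"):
            raise ConfigurationError(f"unknown protocol mode {self.mode!r}")
        if not (self.duration > self.onset >= 0):
            raise ConfigurationError("require duration > onset >= 0")
        if self.mode == "oscillation":
            if self.drive_freq is None or not self.drive_freq > 0:
                raise ConfigurationError("oscillation mode requires drive_freq > 0")
        if self.drive_amplitude < 0:
            raise ConfigurationError("drive_amplitude must be >= 0")

    def volley_times(self) -> np.ndarray:
        """Stimulus volley onsets in ms (before per-cell jitter/delay)."""
        burst = self.onset + self.burst_interval * np.arange(self.burst_n)
        if self.mode == "in_vitro":
            times = burst
            if self.doublet:
                times = np.concatenate([times, burst + DOUBLET_INTERVAL_MS])
        elif self.mode == "in_vivo":
            n = max(self.burst_n, 3)
            burst = self.onset + self.burst_interval * np.arange(n)
            times = np.concatenate([burst, burst + self.second_volley_dt])
        else:  # oscillation
            period = 1000.0 / self.drive_freq
            times = np.arange(self.onset, self.duration, period)
        return np.sort(times)


@dataclass(frozen=True)
class PlasticityParams:
    """Multiplicative LTP/LTD-style modifications.

    ``release_scale`` multiplies the release probability of excitatory
    synapses (clipped to [0, 1]); ``na_gain`` multiplies the sodium channel
    density everywhere (intrinsic-excitability change).
    """

    release_scale: float = 1.0
    na_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.release_scale < 0 or self.na_gain < 0:
            raise ConfigurationError("plasticity multipliers must be >= 0")


LTP_PRESET = PlasticityParams(release_scale=1.5, na_gain=1.2)
LTD_PRESET = PlasticityParams(release_scale=0.6, na_gain=0.85)


@dataclass
class NetworkModel:
    """A placed population of identical-topology cells with afferent wiring.

    ``mf_of_exc[j, k]`` is the mossy-fiber index feeding the k-th excitatory
    synapse of cell j (all afferents carry the common volley in the built-in
    protocols; the wiring is reported for inspection). Inhibitory synapses
    are driven by a single lumped feedback population with a fixed delay.
    """

    neurons: list[CableModel]
    positions: np.ndarray  # (n_cells, 3) soma centres, um
    n_mf: int
    mf_of_exc: np.ndarray
    volume_edge: float
    seed: int
    kind: str = "granular"

    @property
    def n_cells(self) -> int:
        return len(self.neurons)

    @property
    def n_synapses(self) -> int:
        return sum(len(m.synapses) for m in self.neurons)

    def centre(self) -> np.ndarray:
        return np.zeros(3)


def build_granular_network(
    n_granule: int = 730,
    n_mf: int = 40,
    volume_edge: float = 35.0,
    seed: int = 0,
) -> NetworkModel:
    """A granular-layer patch: granule-like cells packed in a cube.

    Somata are placed uniformly at random (overlap permitted) in a cube of
    the given edge centred at the origin. Each cell's 4 excitatory synapses
    are wired to randomly chosen mossy fibers; its 4 inhibitory synapses to
    the lumped feedback population.
    """
    if n_granule < 1 or n_mf < 1:
        raise ConfigurationError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    half = volume_edge / 2.0
    positions = rng.uniform(-half, half, size=(n_granule, 3))
    neurons = [
        make_demo_neuron("granule_like", seed=int(rng.integers(2**31))).translated(positions[j])
        for j in range(n_granule)
    ]
    n_exc = sum(s.excitatory for s in neurons[0].synapses)
    mf_of_exc = rng.integers(0, n_mf, size=(n_granule, n_exc))
    return NetworkModel(neurons, positions, n_mf, mf_of_exc, volume_edge, seed)


def apply_plasticity(network: NetworkModel, params: PlasticityParams) -> NetworkModel:
    """Return a modified copy of the network; the original is untouched."""
    neurons = []
    for m in network.neurons:
        comps = [
            replace(c, channels=replace(c.channels, gbar_na=c.channels.gbar_na * params.na_gain))
            for c in m.compartments
        ]
        syns = []
        for s in m.synapses:
            if s.excitatory:
                p = float(np.clip(s.release_prob * params.release_scale, 0.0, 1.0))
                syns.append(replace(s, release_prob=p))
            else:
                syns.append(copy.deepcopy(s))
        neurons.append(CableModel(comps, syns))
    return NetworkModel(
        neurons,
        network.positions.copy(),
        network.n_mf,
        network.mf_of_exc.copy(),
        network.volume_edge,
        network.seed,
        network.kind,
    )


def electrode_above(
    network: NetworkModel, height: float = 50.0, label: str = "e0"
) -> ElectrodeArray:
    """A single electrode ``height`` um above the population centre."""
    c = network.centre()
    return ElectrodeArray.single(Point3(c[0], c[1], c[2] + network.volume_edge / 2 + height), label)


def run_protocol(
    network: NetworkModel,
    protocol: ProtocolSpec,
    electrodes: ElectrodeArray,
    medium: Medium,
    method: str = "lsa",
    dt: float = 0.025,
    seed: int = 0,
    record_stride: int = 4,
) -> tuple[LFPTrace, pd.DataFrame]:
    """Simulate the population under a protocol and compute its LFP.

    Excitatory synapses receive the protocol's volleys (with per-cell
    jitter and optional center-surround scaling/delay); inhibitory synapses
    receive the same volleys via the lumped feedback population at a fixed
    2 ms delay. Release is thinned per spike by each synapse's release
    probability inside the integrator (seeded, so identical seeds give
    bit-identical traces). Returns the LFP at the given electrodes and a
    tidy spike record (columns: cell, t_ms).
    """
    volleys = protocol.volley_times()
    rng = np.random.default_rng(seed)
    n_cells = network.n_cells

    # per-cell spatial weighting
    scale = np.full(n_cells, protocol.drive_amplitude)
    delay = np.zeros(n_cells)
    if protocol.center_surround is not None:
        cs_spec = protocol.center_surround
        r = np.linalg.norm(network.positions - network.centre(), axis=1)
        gauss = np.exp(-(r**2) / (2.0 * cs_spec.center_radius**2))
        scale = scale * np.maximum(gauss, cs_spec.surround_scale)
        delay = np.where(r <= cs_spec.center_radius, 0.0, cs_spec.surround_delay)

    jitter = rng.normal(0.0, protocol.jitter_ms, size=(n_cells, volleys.size))

    cells: list[CableModel] = []
    protocols: list[StimulusProtocol] = []
    for j, m in enumerate(network.neurons):
        if scale[j] != 1.0:
            syns = [
                replace(s, weight=s.weight * scale[j]) if s.excitatory else copy.deepcopy(s)
                for s in m.synapses
            ]
            m = CableModel(list(m.compartments), syns)
        cells.append(m)
        trains: dict[int, list[float]] = {}
        if protocol.drive_amplitude > 0:
            exc_times = np.clip(volleys + delay[j] + jitter[j], 0.0, None)
            inh_times = exc_times + GOLGI_FEEDBACK_DELAY_MS
            for k, s in enumerate(m.synapses):
                trains[k] = list(exc_times if s.excitatory else inh_times)
        protocols.append(StimulusProtocol(spike_trains=trains))

    pop = simulate_population(
        cells,
        protocols,
        dt=dt,
        t_stop=protocol.duration,
        seed=int(rng.integers(2**31)),
        record_stride=record_stride,
    )
    trace = compute_lfp(pop.sources, electrodes, medium, method)
    rows = [(j, t) for j, ts in enumerate(pop.spikes) for t in ts]
    spikes = pd.DataFrame(rows, columns=["cell", "t_ms"])
    return trace, spikes


def oscillatory_population(
    n_cells: int = 64,
    drive_freq: float = 32.0,
    duration: float = 1000.0,
    seed: int = 0,
) -> tuple[NetworkModel, ProtocolSpec]:
    """A reduced population receiving periodic synaptic volleys.

    Each cell is a ball-and-stick neuron with one excitatory synapse driven
    every ``1000/drive_freq`` ms with small per-cell jitter. The duration
    must cover at least 8 drive cycles for the spectral peak to resolve.
    """
    if not drive_freq > 0:
        raise ConfigurationError("drive_freq must be > 0")
    if duration < 8 * 1000.0 / drive_freq:
        raise ConfigurationError(
            f"duration {duration} ms covers fewer than 8 cycles of {drive_freq} Hz"
        )
    rng = np.random.default_rng(seed)
    edge = 50.0
    positions = rng.uniform(-edge / 2, edge / 2, size=(n_cells, 3))
    neurons = [
        make_demo_neuron("ball_and_stick", seed=int(rng.integers(2**31))).translated(positions[j])
        for j in range(n_cells)
    ]
    network = NetworkModel(
        neurons,
        positions,
        n_mf=1,
        mf_of_exc=np.zeros((n_cells, 1), dtype=int),
        volume_edge=edge,
        seed=seed,
        kind="oscillation",
    )
    protocol = ProtocolSpec(
        mode="oscillation",
        onset=0.0,
        duration=duration,
        drive_freq=drive_freq,
        jitter_ms=1.5,
    )
    return network, protocol
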