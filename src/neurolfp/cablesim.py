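"""Minimal multicompartment cable simulator.

Produces the per-compartment transmembrane current time series that feed
the forward schemas: for every compartment, transmembrane current = ionic
+ synaptic + capacitive membrane current, outward-positive, in nA. By
construction of the implicit update this equals the net axial current plus
any injected electrode current, so the currents of a whole cell sum to the
injected current at every step (Kirchhoff closure) to machine precision.

Membrane dynamics are classical Hodgkin-Huxley (squid parameters) as the
default spiking mechanism, with passive compartments expressed as zero
Na/K conductance. Integration is an implicit (backward Euler) step on the
branched tree solved by the standard Hines elimination, with gating
variables advanced by exponential Euler at the pre-step voltage —
unconditionally stable for the stiff cable system.

The integrator is written once as a *population* engine vectorized across
cells that share a morphology template (states are (n_cells, n_comp)
arrays); :func:`simulate` is the single-cell case. This is what makes the
networks in :mod:`neurolfp.netdemo` tractable at their stated scale.

Internal unit system: mV, ms, nA, uF/cm^2 -> nF, mS/cm^2 -> uS, um.
(uS * mV = nA and nF * mV / ms = nA, so the system is consistent.)
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import (
    ConfigurationError,
    DataError,
    GeometryError,
    Point3,
    SegmentSource,
    SolverError,
    SourceSet,
)

DEFAULT_DT = 0.025  # ms, conventional compartmental step

SPIKE_THRESHOLD_MV = 0.0


@dataclass(frozen=True)
class ChannelSet:
    """Hodgkin-Huxley channel densities for one compartment.

    Conductances in mS/cm^2, reversals in mV. The defaults are the classical
    squid-axon parameters (gNa=120, gK=36, gL=0.3, ENa=50, EK=-77,
    EL=-54.3), which rest near -65 mV.
    """

    gbar_na: float = 120.0
    gbar_k: float = 36.0
    g_leak: float = 0.3
    e_na: float = 50.0
    e_k: float = -77.0
    e_leak: float = -54.3

    def __post_init__(self) -> None:
        if min(self.gbar_na, self.gbar_k, self.g_leak) < 0:
            raise ConfigurationError("channel conductances must be >= 0")

    @classmethod
    def passive(cls, g_leak: float = 0.3, e_leak: float = -65.0) -> "ChannelSet":
        return cls(gbar_na=0.0, gbar_k=0.0, g_leak=g_leak, e_leak=e_leak)


@dataclass
class Compartment:
    """One electrical compartment of a cable tree.

    ``spherical`` marks a single-point soma: its membrane area is that of a
    sphere (pi*d^2) and its source segment is exported with zero length so
    the forward model treats it as an equivalent-sphere point source.
    """

    id: str
    length: float  # um
    diameter: float  # um
    p0: Point3
    p1: Point3
    parent: str | None = None
    c_m: float = 1.0  # uF/cm^2
    r_a: float = 100.0  # Ohm*cm axial resistivity
    channels: ChannelSet = field(default_factory=ChannelSet.passive)
    spherical: bool = False

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.diameter > 0):
            raise GeometryError(f"compartment {self.id}: length and diameter must be > 0")
        if not (self.c_m > 0 and self.r_a > 0):
            raise ConfigurationError(f"compartment {self.id}: c_m and r_a must be > 0")

    @property
    def area_um2(self) -> float:
        if self.spherical:
            return math.pi * self.diameter**2  # sphere of that diameter
        return math.pi * self.diameter * self.length


@dataclass
class SynapseModel:
    """A conductance-based synapse on one compartment.

    kind is one of ``ampa`` (fast excitatory), ``nmda`` (slow excitatory,
    simplified: double-exponential conductance with optional Mg-block-like
    voltage scaling), ``gaba`` (inhibitory). An ``ampa`` synapse with
    ``nmda_ratio > 0`` carries a colocated NMDA-simplified component of
    weight ``weight * nmda_ratio`` — the usual composite excitatory synapse.

    weight in nS; time constants in ms with ``tau_decay > tau_rise > 0``;
    ``release_prob`` thins presynaptic spikes per-event (Bernoulli, seeded).
    """

    target: str
    kind: str
    tau_rise: float
    tau_decay: float
    e_rev: float
    weight: float
    release_prob: float = 1.0
    delay: float = 0.0
    nmda_ratio: float = 0.0
    nmda_tau_decay: float = 50.0
    mg_block: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("ampa", "nmda", "gaba"):
            raise ConfigurationError(f"unknown synapse kind {self.kind!r}")
        if not (self.tau_decay > self.tau_rise > 0):
            raise ConfigurationError(
                f"require tau_decay > tau_rise > 0, got rise={self.tau_rise}, "
                f"decay={self.tau_decay}"
            )
        if not 0.0 <= self.release_prob <= 1.0:
            raise ConfigurationError(f"release_prob must be in [0, 1], got {self.release_prob}")
        if self.weight < 0 or self.nmda_ratio < 0:
            raise ConfigurationError("synaptic weights must be >= 0")

    @property
    def excitatory(self) -> bool:
        return self.kind != "gaba"


@dataclass
class CableModel:
    """A compartment tree plus its synapses.

    Compartments must form a tree (unique root, every parent defined);
    they are stored in a parent-before-child order.
    """

    compartments: list[Compartment]
    synapses: list[SynapseModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compartments]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate compartment ids")
        by_id = {c.id: c for c in self.compartments}
        roots = [c for c in self.compartments if c.parent is None]
        if len(roots) != 1:
            raise DataError(f"expected exactly one root compartment, found {len(roots)}")
        for c in self.compartments:
            if c.parent is not None and c.parent not in by_id:
                raise DataError(f"compartment {c.id}: unknown parent {c.parent!r}")
        # topological order (parent before child); also rejects cycles
        ordered: list[Compartment] = []
        children: dict[str | None, list[Compartment]] = {}
        for c in self.compartments:
            children.setdefault(c.parent, []).append(c)
        stack = [roots[0]]
        while stack:
            c = stack.pop()
            ordered.append(c)
            stack.extend(reversed(children.get(c.id, [])))
        if len(ordered) != len(self.compartments):
            raise DataError("compartments do not form a single connected tree")
        self.compartments = ordered
        self._index = {c.id: i for i, c in enumerate(self.compartments)}
        for s in self.synapses:
            if s.target not in self._index:
                raise DataError(f"synapse targets unknown compartment {s.target!r}")

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def index_of(self, comp_id: str) -> int:
        return self._index[comp_id]

    def parent_indices(self) -> np.ndarray:
        return np.array(
            [-1 if c.parent is None else self._index[c.parent] for c in self.compartments]
        )

    def source_segments(self, prefix: str = "") -> list[SegmentSource]:
        """Export compartments as forward-model source segments.

        Spherical somata become zero-length (equivalent-sphere) sources at
        the compartment centre.
        """
        segs = []
        for c in self.compartments:
            if c.spherical:
                centre = Point3(*(0.5 * (c.p0.as_array() + c.p1.as_array())))
                segs.append(SegmentSource(prefix + c.id, centre, centre, c.diameter, spherical=True))
            else:
                segs.append(SegmentSource(prefix + c.id, c.p0, c.p1, c.diameter))
        return segs

    def translated(self, offset: Sequence[float]) -> "CableModel":
        """A copy of the model rigidly shifted by ``offset`` (um)."""
        off = Point3.of(offset)
        comps = [replace(c, p0=c.p0 + off, p1=c.p1 + off) for c in self.compartments]
        return CableModel(comps, copy.deepcopy(self.synapses))


@dataclass(frozen=True)
class CurrentInjection:
    target: str
    amp_pA: float
    onset: float
    dur: float


@dataclass
class StimulusProtocol:
    """Electrode current injections and presynaptic spike trains.

    ``spike_trains`` maps a synapse index (position in
    ``CableModel.synapses``) to presynaptic spike times in ms.
    """

    injections: list[CurrentInjection] = field(default_factory=list)
    spike_trains: dict[int, list[float]] = field(default_factory=dict)


@dataclass
class SimResult:
    """Single-cell simulation output."""

    time: np.ndarray  # recorded times, ms
    v: np.ndarray  # (n_comp, n_rec) membrane potential, mV
    sources: SourceSet  # transmembrane currents, nA, outward-positive
    spikes: np.ndarray  # somatic spike times, ms
    dt: float


@dataclass
class PopulationResult:
    """Population simulation output; sources are concatenated across cells."""

    time: np.ndarray
    v_soma: np.ndarray  # (n_cells, n_rec)
    sources: SourceSet
    spikes: list[np.ndarray]  # per-cell somatic spike times
    dt: float
    v_full: np.ndarray | None = None  # (n_cells, n_comp, n_rec) if requested


# ---------------------------------------------------------------------------
# Hodgkin-Huxley gating (voltage in mV, rates in 1/ms)

def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity handled."""
    x = np.asarray(x, dtype=float)
    ratio = x / y
    small = np.abs(ratio) < 1e-6
    with np.errstate(over="ignore"):
        out = np.where(small, y * (1.0 - ratio / 2.0), x / np.expm1(np.where(small, 1.0, ratio)))
    return out


def hh_rates(v):
    """HH alpha/beta for m, h, n at membrane potential v (mV)."""
    am = 0.1 * _vtrap(-(v + 40.0), 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.01 * _vtrap(-(v + 55.0), 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return (am, bm), (ah, bh), (an, bn)


def _steady_gates(v):
    (am, bm), (ah, bh), (an, bn) = hh_rates(v)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def _dual_exp_norm(tau_rise: float, tau_decay: float) -> float:
    """Peak-normalization factor for g(t) = exp(-t/td) - exp(-t/tr)."""
    tp = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    return 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))


# ---------------------------------------------------------------------------
# Population engine


class _Template:
    """Per-compartment arrays shared by all cells of a population."""

    def __init__(self, models: list[CableModel]):
        ref = models[0]
        n_comp = ref.n_compartments
        ids = [c.id for c in ref.compartments]
        for m in models[1:]:
            if [c.id for c in m.compartments] != ids:
                raise DataError("population cells must share an identical compartment topology")
            if len(m.synapses) != len(ref.synapses):
                raise DataError("population cells must have the same synapse count")
        self.n_comp = n_comp
        self.parent = ref.parent_indices()
        if not np.all(self.parent[1:] < np.arange(1, n_comp)):
            raise DataError("compartment ordering violates parent-before-child")

        n_cells = len(models)
        area = np.array([[c.area_um2 for c in m.compartments] for m in models])
        self.c_nf = (
            np.array([[c.c_m for c in m.compartments] for m in models]) * area * 1e-5
        )  # uF/cm^2 * um^2 -> nF
        ch = lambda attr: np.array(
            [[getattr(c.channels, attr) for c in m.compartments] for m in models]
        )
        dens_to_us = area * 1e-5  # mS/cm^2 * um^2 -> uS
        self.gbar_na = ch("gbar_na") * dens_to_us
        self.gbar_k = ch("gbar_k") * dens_to_us
        self.g_leak = ch("g_leak") * dens_to_us
        self.e_na = ch("e_na")
        self.e_k = ch("e_k")
        self.e_leak = ch("e_leak")

        # axial coupling conductance between each compartment and its parent
        def half_r(c: Compartment) -> float:
            # effective cylinder: spherical soma uses length = diameter
            length = c.diameter if c.spherical else c.length
            radius = c.diameter / 2.0
            return (c.r_a * 1e4) * (length / 2.0) / (math.pi * radius**2)  # Ohm

        g_ax = np.zeros((n_cells, n_comp))
        for j, m in enumerate(models):
            comps = m.compartments
            for i in range(1, n_comp):
                p = comps[self.parent[i]]
                g_ax[j, i] = 1e6 / (half_r(comps[i]) + half_r(p))  # uS
        self.g_ax = g_ax

        # synapse template (kinetics shared across cells; weights per cell)
        self.syn_comp: list[int] = []
        self.syn_tau_r: list[float] = []
        self.syn_tau_d: list[float] = []
        self.syn_e: list[float] = []
        self.syn_mg: list[bool] = []
        self.syn_w = []  # per component: (n_cells,) effective weight, uS
        self.syn_p = []
        self.syn_delay = []
        self.syn_owner: list[int] = []  # index into model.synapses
        ref_syns = ref.synapses
        for k, s in enumerate(ref_syns):
            comp_idx = ref.index_of(s.target)
            comps_of_cells = [m.synapses[k] for m in models]
            norm = _dual_exp_norm(s.tau_rise, s.tau_decay)
            self._add_component(
                comp_idx,
                s.tau_rise,
                s.tau_decay,
                s.e_rev,
                s.kind == "nmda" and s.mg_block,
                np.array([c.weight for c in comps_of_cells]) * norm * 1e-3,
                np.array([c.release_prob for c in comps_of_cells]),
                np.array([c.delay for c in comps_of_cells]),
                k,
            )
            if s.kind == "ampa" and s.nmda_ratio > 0:
                norm2 = _dual_exp_norm(s.tau_rise, s.nmda_tau_decay)
                self._add_component(
                    comp_idx,
                    s.tau_rise,
                    s.nmda_tau_decay,
                    s.e_rev,
                    s.mg_block,
                    np.array([c.weight * c.nmda_ratio for c in comps_of_cells]) * norm2 * 1e-3,
                    np.array([c.release_prob for c in comps_of_cells]),
                    np.array([c.delay for c in comps_of_cells]),
                    k,
                )
        self.syn_w = np.array(self.syn_w).T if self.syn_w else np.zeros((n_cells, 0))
        self.syn_p = np.array(self.syn_p).T if self.syn_p else np.zeros((n_cells, 0))
        self.syn_delay = np.array(self.syn_delay).T if self.syn_delay else np.zeros((n_cells, 0))

    def _add_component(self, comp_idx, tr, td, e, mg, w, p, delay, owner):
        self.syn_comp.append(comp_idx)
        self.syn_tau_r.append(tr)
        self.syn_tau_d.append(td)
        self.syn_e.append(e)
        self.syn_mg.append(mg)
        self.syn_w.append(w)
        self.syn_p.append(p)
        self.syn_delay.append(delay)
        self.syn_owner.append(owner)


def simulate_population(
    models: list[CableModel],
    protocols: list[StimulusProtocol],
    dt: float = DEFAULT_DT,
    t_stop: float = 100.0,
    seed: int = 0,
    record_stride: int = 1,
    record_full_v: bool = False,
) -> PopulationResult:
    """Integrate a population of cells sharing one morphology template.

    ``protocols[j]`` applies to cell ``j``. Transmembrane currents are
    recorded every ``record_stride`` steps (plus the initial state) into a
    single SourceSet whose segments keep each cell's own 3-D placement.
    Deterministic given (models, protocols, dt, seed).
    """
    if not dt > 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")
    if t_stop < dt:
        raise ConfigurationError(f"t_stop must be >= dt, got {t_stop}")
    if len(models) != len(protocols):
        raise DataError("one protocol per cell is required")
    tpl = _Template(models)
    n_cells, n_comp = len(models), tpl.n_comp
    n_steps = int(round(t_stop / dt))
    rng = np.random.default_rng(seed)

    # --- initial state
    v = np.full((n_cells, n_comp), -65.0)
    m, h, n = _steady_gates(v)

    # --- synaptic release events (sorted deterministically, thinned by p)
    n_syn = len(tpl.syn_comp)
    raw: list[tuple[float, int, int]] = []  # (time, cell, syn component)
    for j, proto in enumerate(protocols):
        for syn_idx, times in proto.spike_trains.items():
            comp_ids = [k for k, owner in enumerate(tpl.syn_owner) if owner == syn_idx]
            if not comp_ids:
                raise DataError(f"protocol references unknown synapse index {syn_idx}")
            for t in times:
                for k in comp_ids:
                    raw.append((float(t) + tpl.syn_delay[j, k], j, k))
    raw.sort()
    # one uniform draw per (synapse-owner) spike event; colocated NMDA
    # components release together with their AMPA parent
    ev_step, ev_cell, ev_syn, ev_inc = [], [], [], []
    draw_cache: dict[tuple[float, int, int], float] = {}
    for t, j, k in raw:
        owner = tpl.syn_owner[k]
        key = (t - tpl.syn_delay[j, k], j, owner)
        if key not in draw_cache:
            draw_cache[key] = rng.random()
        if draw_cache[key] < tpl.syn_p[j, k]:
            step = int(round(t / dt))
            if 0 <= step < n_steps:
                ev_step.append(step)
                ev_cell.append(j)
                ev_syn.append(k)
                ev_inc.append(tpl.syn_w[j, k])
    ev_step = np.array(ev_step, dtype=int)
    order = np.argsort(ev_step, kind="stable")
    ev_step = ev_step[order]
    ev_cell = np.array(ev_cell, dtype=int)[order]
    ev_syn = np.array(ev_syn, dtype=int)[order]
    ev_inc = np.array(ev_inc, dtype=float)[order]

    # --- injections as step-indexed on/off deltas, nA
    inj_delta: dict[int, list[tuple[int, int, float]]] = {}
    for j, proto in enumerate(protocols):
        for inj in proto.injections:
            ci = models[j].index_of(inj.target)
            amp = inj.amp_pA * 1e-3
            s_on = int(round(inj.onset / dt))
            s_off = int(round((inj.onset + inj.dur) / dt))
            inj_delta.setdefault(s_on, []).append((j, ci, amp))
            inj_delta.setdefault(s_off, []).append((j, ci, -amp))
    i_inj = np.zeros((n_cells, n_comp))

    # --- synapse state (dual-exponential as difference of two decays)
    a_state = np.zeros((n_cells, n_syn))
    b_state = np.zeros((n_cells, n_syn))
    dec_a = np.exp(-dt / np.array(tpl.syn_tau_r)) if n_syn else np.zeros(0)
    dec_b = np.exp(-dt / np.array(tpl.syn_tau_d)) if n_syn else np.zeros(0)
    syn_comp = np.array(tpl.syn_comp, dtype=int)
    syn_e = np.array(tpl.syn_e, dtype=float)
    syn_mg = np.array(tpl.syn_mg, dtype=bool)

    # --- static part of the linear system
    c_over_dt = tpl.c_nf / dt
    diag_static = c_over_dt + tpl.g_leak + tpl.g_ax
    np.add.at(diag_static.T, tpl.parent[1:], tpl.g_ax.T[1:])  # parent side of coupling

    # --- recording
    rec_steps = np.arange(record_stride - 1, n_steps, record_stride)
    n_rec = rec_steps.size + 1
    rec_time = np.concatenate([[0.0], (rec_steps + 1) * dt])
    i_rec = np.empty((n_rec, n_cells, n_comp))
    v_soma = np.empty((n_cells, n_rec))
    v_full = np.empty((n_rec, n_cells, n_comp)) if record_full_v else None
    v_soma[:, 0] = v[:, 0]
    if v_full is not None:
        v_full[0] = v
    spikes: list[list[float]] = [[] for _ in range(n_cells)]
    prev_soma = v[:, 0].copy()

    # At t=0 all compartments sit at the same potential, so net axial flow
    # and injected current are zero; the capacitive term implied by the
    # dynamics exactly cancels the ionic term, giving zero transmembrane
    # current at the initial sample.
    i_rec[0] = 0.0

    ev_ptr = 0
    rec_ptr = 1
    parent = tpl.parent
    check_every = max(1, n_steps // 50)
    for step in range(n_steps):
        # gates via exponential Euler at pre-step voltage
        (am, bm), (ah, bh), (an, bn) = hh_rates(v)
        for gate, aa, bb in ((0, am, bm), (1, ah, bh), (2, an, bn)):
            tau = 1.0 / (aa + bb)
            inf = aa * tau
            if gate == 0:
                m = inf + (m - inf) * np.exp(-dt / tau)
            elif gate == 1:
                h = inf + (h - inf) * np.exp(-dt / tau)
            else:
                n = inf + (n - inf) * np.exp(-dt / tau)

        # synaptic events and decay
        if n_syn:
            a_state *= dec_a
            b_state *= dec_b
            while ev_ptr < ev_step.size and ev_step[ev_ptr] == step:
                k = ev_ptr
                while k < ev_step.size and ev_step[k] == step:
                    k += 1
                np.add.at(a_state, (ev_cell[ev_ptr:k], ev_syn[ev_ptr:k]), ev_inc[ev_ptr:k])
                np.add.at(b_state, (ev_cell[ev_ptr:k], ev_syn[ev_ptr:k]), ev_inc[ev_ptr:k])
                ev_ptr = k
            g_syn = b_state - a_state
            if syn_mg.any():
                vm_t = v[:, syn_comp[syn_mg]]
                g_syn = g_syn.copy()
                g_syn[:, syn_mg] *= 1.0 / (1.0 + 0.28 * np.exp(-0.062 * vm_t))
        # injections
        if step in inj_delta:
            for j, ci, amp in inj_delta[step]:
                i_inj[j, ci] += amp

        # assemble and solve (backward Euler, Hines elimination on the tree)
        g_na = tpl.gbar_na * m**3 * h
        g_k = tpl.gbar_k * n**4
        diag = diag_static + g_na + g_k
        rhs = (
            c_over_dt * v
            + tpl.g_leak * tpl.e_leak
            + g_na * tpl.e_na
            + g_k * tpl.e_k
            + i_inj
        )
        g_syn_comp = np.zeros((n_cells, n_comp))
        if n_syn:
            for k in range(n_syn):
                ci = syn_comp[k]
                gk = g_syn[:, k]
                g_syn_comp[:, ci] += gk
                rhs[:, ci] += gk * syn_e[k]
            diag = diag + g_syn_comp

        for i in range(n_comp - 1, 0, -1):
            p = parent[i]
            g = tpl.g_ax[:, i]
            f = g / diag[:, i]
            diag[:, p] -= g * f
            rhs[:, p] += f * rhs[:, i]
        v_new = np.empty_like(v)
        v_new[:, 0] = rhs[:, 0] / diag[:, 0]
        for i in range(1, n_comp):
            p = parent[i]
            v_new[:, i] = (rhs[:, i] + tpl.g_ax[:, i] * v_new[:, p]) / diag[:, i]

        # transmembrane current (ionic + synaptic + capacitive), nA
        i_tm = (
            g_na * (v_new - tpl.e_na)
            + g_k * (v_new - tpl.e_k)
            + tpl.g_leak * (v_new - tpl.e_leak)
            + c_over_dt * (v_new - v)
        )
        if n_syn:
            for k in range(n_syn):
                ci = syn_comp[k]
                i_tm[:, ci] += g_syn[:, k] * (v_new[:, ci] - syn_e[k])

        # spike detection on the soma (compartment 0), full resolution
        soma = v_new[:, 0]
        crossed = (soma >= SPIKE_THRESHOLD_MV) & (prev_soma < SPIKE_THRESHOLD_MV)
        if crossed.any():
            t_now = (step + 1) * dt
            for j in np.nonzero(crossed)[0]:
                spikes[j].append(t_now)
        prev_soma = soma.copy()
        v = v_new

        if rec_ptr < n_rec and step == rec_steps[rec_ptr - 1]:
            i_rec[rec_ptr] = i_tm
            v_soma[:, rec_ptr] = soma
            if v_full is not None:
                v_full[rec_ptr] = v_new
            rec_ptr += 1

        if step % check_every == 0:
            vmax = np.abs(v).max()
            if not np.isfinite(vmax) or vmax > 1e6:
                raise SolverError(
                    f"membrane potential diverged at t = {(step + 1) * dt:.3f} ms"
                )

    if not np.all(np.isfinite(v)):
        raise SolverError(f"non-finite membrane potential at t = {n_steps * dt:.3f} ms")

    segments = [s for j, mdl in enumerate(models) for s in mdl.source_segments(prefix=f"c{j}.")]
    currents = i_rec.reshape(n_rec, n_cells * n_comp).T
    sources = SourceSet(segments, currents, dt * record_stride, t0=0.0)
    return PopulationResult(
        time=rec_time,
        v_soma=v_soma,
        sources=sources,
        spikes=[np.array(s) for s in spikes],
        dt=dt,
        v_full=None if v_full is None else np.moveaxis(v_full, 0, 2),
    )


def simulate(
    model: CableModel,
    protocol: StimulusProtocol,
    dt: float = DEFAULT_DT,
    t_stop: float = 100.0,
    seed: int = 0,
) -> SimResult:
    """Integrate one cell; see :func:`simulate_population` for the scheme.

    Records membrane potential of every compartment and the per-compartment
    transmembrane currents (nA, outward-positive) at full resolution.
    """
    pop = simulate_population(
        [model], [protocol], dt=dt, t_stop=t_stop, seed=seed, record_full_v=True
    )
    return SimResult(
        time=pop.time, v=pop.v_full[0], sources=pop.sources, spikes=pop.spikes[0], dt=dt
    )


def transmembrane_currents(result: "SimResult | PopulationResult", t_index: int) -> np.ndarray:
    """Per-compartment transmembrane currents (nA) at one recorded step.

    Their sum equals the total externally injected electrode current at
    that step (Kirchhoff closure of the membrane system).
    """
    n = result.sources.n_steps
    if not -n <= t_index < n:
        raise DataError(f"time index {t_index} out of range for {n} recorded steps")
    return result.sources.currents[:, t_index]


# ---------------------------------------------------------------------------
# Demo morphologies


def make_demo_neuron(kind: str, seed: int = 0) -> CableModel:
    """Reduced demonstration morphologies.

    ``granule_like``: spherical soma, four short dendrites each carrying one
    excitatory (AMPA + colocated NMDA-simplified) and one inhibitory (GABA)
    synapse at its tip, and an ascending axon — 8 synapses total, matching
    the cerebellar granule cell's 4 excitatory + 4 inhibitory arrangement.
    ``ball_and_stick``: soma plus one passive dendrite with one excitatory
    synapse. ``pyramidal_like``: soma, apical trunk, two basal dendrites.

    The seed perturbs dendrite azimuths only (placement variety); electrical
    parameters are fixed.
    """
    rng = np.random.default_rng(seed)
    if kind == "granule_like":
        return _granule_like(rng)
    if kind == "ball_and_stick":
        return _ball_and_stick(rng)
    if kind == "pyramidal_like":
        return _pyramidal_like(rng)
    raise ConfigurationError(f"unknown demo neuron kind {kind!r}")


def _soma(diameter: float, active: bool = True) -> Compartment:
    half = diameter / 2.0
    ch = ChannelSet() if active else ChannelSet.passive()
    return Compartment(
        "soma",
        length=diameter,
        diameter=diameter,
        p0=Point3(0.0, 0.0, -half),
        p1=Point3(0.0, 0.0, half),
        channels=ch,
        spherical=True,
    )


def _granule_like(rng: np.random.Generator) -> CableModel:
    comps = [_soma(6.0)]
    syns: list[SynapseModel] = []
    base = rng.uniform(0.0, 2 * np.pi)
    for i in range(4):
        phi = base + i * np.pi / 2.0
        tilt = np.deg2rad(35.0)
        d = np.array([np.cos(phi) * np.sin(tilt), np.sin(phi) * np.sin(tilt), -np.cos(tilt)])
        p0 = Point3(*(3.0 * d))
        p1 = Point3(*(3.0 * d + 15.0 * d))
        comps.append(
            Compartment(
                f"dend{i}",
                length=15.0,
                diameter=1.0,
                p0=p0,
                p1=p1,
                parent="soma",
                channels=ChannelSet.passive(),
            )
        )
        syns.append(
            SynapseModel(
                target=f"dend{i}",
                kind="ampa",
                tau_rise=0.4,
                tau_decay=2.0,
                e_rev=0.0,
                weight=1.2,
                release_prob=0.5,
                nmda_ratio=0.6,
                nmda_tau_decay=30.0,
                mg_block=True,
            )
        )
        syns.append(
            SynapseModel(
                target=f"dend{i}",
                kind="gaba",
                tau_rise=0.5,
                tau_decay=12.0,
                e_rev=-75.0,
                weight=0.8,
                release_prob=0.5,
            )
        )
    comps.append(
        Compartment(
            "axon0",
            length=30.0,
            diameter=0.6,
            p0=Point3(0.0, 0.0, 3.0),
            p1=Point3(0.0, 0.0, 33.0),
            parent="soma",
            channels=ChannelSet(),
        )
    )
    comps.append(
        Compartment(
            "axon1",
            length=30.0,
            diameter=0.6,
            p0=Point3(0.0, 0.0, 33.0),
            p1=Point3(0.0, 0.0, 63.0),
            parent="axon0",
            channels=ChannelSet(),
        )
    )
    return CableModel(comps, syns)


def _ball_and_stick(rng: np.random.Generator) -> CableModel:
    comps = [_soma(10.0)]
    phi = rng.uniform(0.0, 2 * np.pi)
    d = np.array([0.2 * np.cos(phi), 0.2 * np.sin(phi), 1.0])
    d /= np.linalg.norm(d)
    start = 5.0 * d
    comps.append(
        Compartment(
            "dend",
            length=100.0,
            diameter=2.0,
            p0=Point3(*start),
            p1=Point3(*(start + 100.0 * d)),
            parent="soma",
            channels=ChannelSet.passive(),
        )
    )
    syn = SynapseModel(
        target="dend",
        kind="ampa",
        tau_rise=0.4,
        tau_decay=2.5,
        e_rev=0.0,
        weight=3.0,
        release_prob=0.9,
        nmda_ratio=0.4,
        nmda_tau_decay=30.0,
    )
    return CableModel(comps, [syn])


def _pyramidal_like(rng: np.random.Generator) -> CableModel:
    comps = [_soma(20.0)]
    z = 10.0
    parent = "soma"
    for i in range(3):
        comps.append(
            Compartment(
                f"apical{i}",
                length=100.0,
                diameter=3.0 - 0.5 * i,
                p0=Point3(0.0, 0.0, z),
                p1=Point3(0.0, 0.0, z + 100.0),
                parent=parent,
                channels=ChannelSet.passive(),
            )
        )
        parent = f"apical{i}"
        z += 100.0
    base = rng.uniform(0.0, 2 * np.pi)
    for i in range(2):
        phi = base + i * np.pi
        d = np.array([np.cos(phi), np.sin(phi), -0.6])
        d /= np.linalg.norm(d)
        start = 10.0 * d
        comps.append(
            Compartment(
                f"basal{i}",
                length=80.0,
                diameter=2.0,
                p0=Point3(*start),
                p1=Point3(*(start + 80.0 * d)),
                parent="soma",
                channels=ChannelSet.passive(),
            )
        )
    syns = [
        SynapseModel(
            target="apical1",
            kind="ampa",
            tau_rise=0.4,
            tau_decay=2.5,
            e_rev=0.0,
            weight=2.0,
            nmda_ratio=0.5,
        ),
        SynapseModel(
            target="apical0",
            kind="ampa",
            tau_rise=0.4,
            tau_decay=2.5,
            e_rev=0.0,
            weight=2.0,
            nmda_ratio=0.5,
        ),
        SynapseModel(
            target="soma",
            kind="gaba",
            tau_rise=0.5,
            tau_decay=10.0,
            e_rev=-75.0,
            weight=2.0,
        ),
    ]
    return CableModel(comps, syns)
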