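import numpy as np
import pytest
from scipy.integrate import solve_ivp

from neurolfp import (
    CableModel,
    ChannelSet,
    Compartment,
    ConfigurationError,
    CurrentInjection,
    DataError,
    ElectrodeArray,
    Medium,
    Point3,
    StimulusProtocol,
    compute_lfp,
    make_demo_neuron,
    simulate,
    transmembrane_currents,
)
from neurolfp.cablesim import hh_rates


def _sphere(diameter, channels):
    half = diameter / 2
    return Compartment(
        "soma",
        length=diameter,
        diameter=diameter,
        p0=Point3(0, 0, -half),
        p1=Point3(0, 0, half),
        channels=channels,
        spherical=True,
    )


def _passive_soma_model(g_leak=0.3):
    return CableModel([_sphere(20.0, ChannelSet.passive(g_leak=g_leak))])


def _hh_soma_model(diameter=10.0):
    return CableModel([_sphere(diameter, ChannelSet())])


class TestMembraneDynamics:
    def test_passive_charging_time_constant(self):
        """A passive isopotential compartment charges with tau_m = c_m/g_leak."""
        tau_m = 1.0 / 0.3  # ms, c_m = 1 uF/cm^2, g_leak = 0.3 mS/cm^2
        dt = tau_m / 200
        model = _passive_soma_model()
        proto = StimulusProtocol(injections=[CurrentInjection("soma", 100.0, 5.0, 60.0)])
        res = simulate(model, proto, dt=dt, t_stop=50.0)
        v = res.v[0]
        t = res.time
        on = np.searchsorted(t, 5.0 + 1e-9)
        plateau_idx = np.searchsorted(t, 5.0 + 12 * tau_m)
        v0, v_inf = v[on - 1], v[plateau_idx]
        # fit tau from the log of the remaining charge over [onset, onset+2 tau]
        seg = slice(on, np.searchsorted(t, 5.0 + 2 * tau_m))
        frac = (v_inf - v[seg]) / (v_inf - v0)
        slope = np.polyfit(t[seg] - 5.0, np.log(frac), 1)[0]
        assert -1.0 / slope == pytest.approx(tau_m, rel=0.02)

    def test_hh_soma_spikes_match_reference_integration(self):
        """Somatic step drives spikes; an independent fine-dt ODE solve agrees."""
        model = _hh_soma_model()
        proto = StimulusProtocol(injections=[CurrentInjection("soma", 200.0, 10.0, 80.0)])
        res = simulate(model, proto, dt=0.025, t_stop=100.0)
        assert len(res.spikes) >= 1
        assert res.v.max() > 0.0

        # independent oracle: classical HH point ODE, current density of the
        # same 200 pA over the sphere area, integrated by solve_ivp
        area_cm2 = np.pi * 10.0**2 * 1e-8
        j_inj = 200e-6 / area_cm2  # uA/cm^2

        def rhs(t, y):
            v, m, h, n = y
            (am, bm), (ah, bh), (an, bn) = hh_rates(np.array(v))
            stim = j_inj if 10.0 <= t <= 90.0 else 0.0
            dv = (
                stim
                - 120.0 * m**3 * h * (v - 50.0)
                - 36.0 * n**4 * (v + 77.0)
                - 0.3 * (v + 54.3)
            )
            return [dv, am * (1 - m) - bm * m, ah * (1 - h) - bh * h, an * (1 - n) - bn * n]

        (am, bm), (ah, bh), (an, bn) = hh_rates(np.array(-65.0))
        y0 = [-65.0, am / (am + bm), ah / (ah + bh), an / (an + bn)]
        sol = solve_ivp(rhs, (0, 100), y0, max_step=0.01, rtol=1e-8, atol=1e-8, dense_output=True)
        t = np.arange(0, 100, 0.01)
        v_ref = sol.sol(t)[0]
        ref_spikes = t[1:][(v_ref[1:] >= 0) & (v_ref[:-1] < 0)]
        assert len(ref_spikes) >= 1
        assert res.spikes[0] == pytest.approx(ref_spikes[0], abs=1.0)
        assert len(res.spikes) == len(ref_spikes)

    def test_resting_cell_stays_at_rest(self):
        model = make_demo_neuron("granule_like", seed=0)
        res = simulate(model, StimulusProtocol(), t_stop=100.0)
        rest = res.v[:, -1]
        late = res.time >= 50.0
        assert np.all(np.abs(res.v[:, late] - rest[:, None]) < 1.0)
        assert np.abs(res.sources.currents[:, res.sources.time >= 50.0]).max() < 0.01

    def test_blowup_raises_solver_error(self):
        from neurolfp import SolverError

        model = _hh_soma_model()
        proto = StimulusProtocol(injections=[CurrentInjection("soma", 1e300, 1.0, 50.0)])
        with pytest.raises(SolverError):
            simulate(model, proto, t_stop=20.0)


class TestCurrentConservation:
    def test_sum_is_zero_without_injection(self, synaptic_cell):
        total = synaptic_cell.sources.currents.sum(axis=0)
        scale = np.abs(synaptic_cell.sources.currents).max()
        assert np.abs(total).max() <= 1e-6 * scale

    def test_sum_equals_injected_current(self):
        model = make_demo_neuron("granule_like", seed=0)
        proto = StimulusProtocol(injections=[CurrentInjection("soma", 70.0, 10.0, 40.0)])
        res = simulate(model, proto, t_stop=60.0)
        total = res.sources.currents.sum(axis=0)
        scale = np.abs(res.sources.currents).max()
        during = (res.sources.time > 10.0 + res.dt) & (res.sources.time <= 50.0)
        assert np.allclose(total[during], 0.07, atol=1e-6 * scale)

    def test_two_route_recomputation_passive(self):
        """Recorded currents equal g_leak*(V-E) + C*dV/dt recomputed from V."""
        comps = [
            _sphere(20.0, ChannelSet.passive()),
            Compartment(
                "dend",
                length=50.0,
                diameter=2.0,
                p0=Point3(0, 0, 10),
                p1=Point3(0, 0, 60),
                parent="soma",
                channels=ChannelSet.passive(),
            ),
        ]
        model = CableModel(comps)
        proto = StimulusProtocol(injections=[CurrentInjection("soma", 50.0, 5.0, 20.0)])
        dt = 0.025
        res = simulate(model, proto, dt=dt, t_stop=30.0)
        areas = np.array([c.area_um2 for c in model.compartments])
        g = 0.3 * areas * 1e-5  # uS
        c = 1.0 * areas * 1e-5  # nF
        v = res.v
        ionic = g[:, None] * (v[:, 1:] + 65.0)
        capacitive = c[:, None] * np.diff(v, axis=1) / dt
        recomputed = ionic + capacitive
        recorded = res.sources.currents[:, 1:]
        scale = np.abs(recorded).max()
        assert np.allclose(recorded, recomputed, atol=1e-6 * scale)

    def test_transmembrane_currents_accessor(self, synaptic_cell):
        vals = transmembrane_currents(synaptic_cell, 100)
        assert vals.shape == (synaptic_cell.sources.n_sources,)
        assert np.array_equal(vals, synaptic_cell.sources.currents[:, 100])
        with pytest.raises(DataError):
            transmembrane_currents(synaptic_cell, synaptic_cell.sources.n_steps)


class TestNumerics:
    def test_first_order_convergence_of_spike_times(self):
        model = _hh_soma_model()
        proto = StimulusProtocol(injections=[CurrentInjection("soma", 200.0, 5.0, 90.0)])
        coarse = simulate(model, proto, dt=0.02, t_stop=60.0)
        fine = simulate(model, proto, dt=0.01, t_stop=60.0)
        assert len(coarse.spikes) == len(fine.spikes) >= 2
        assert np.abs(coarse.spikes[0] - fine.spikes[0]) < 0.02

    def test_determinism(self):
        model = make_demo_neuron("granule_like", seed=1)
        proto = StimulusProtocol(spike_trains={k: [15.0, 30.0] for k in range(8)})
        a = simulate(model, proto, t_stop=50.0, seed=9)
        b = simulate(model, proto, t_stop=50.0, seed=9)
        assert np.array_equal(a.sources.currents, b.sources.currents)
        assert np.array_equal(a.v, b.v)

    def test_release_probability_thins_events(self):
        model = make_demo_neuron("granule_like", seed=1)
        # silence release entirely: no synaptic response at all
        for s in model.synapses:
            s.release_prob = 0.0
        proto = StimulusProtocol(spike_trains={k: [15.0] for k in range(8)})
        res = simulate(model, proto, t_stop=40.0, seed=2)
        assert np.abs(res.sources.currents[:, res.sources.time > 15.0]).max() < 0.01


class TestExtracellularSignature:
    def test_spike_is_negative_near_soma(self, synaptic_cell):
        """Na influx at the soma makes a negative extracellular deflection."""
        res = synaptic_cell
        assert len(res.spikes) >= 1
        trace = compute_lfp(
            res.sources, ElectrodeArray.single((20.0, 0.0, 0.0)), Medium(), "psa"
        )
        t_spk = res.spikes[0]
        win = (trace.time > t_spk - 1.0) & (trace.time < t_spk + 1.0)
        seg = trace.values[0][win]
        assert seg.min() < 0
        assert np.abs(seg.min()) > np.abs(seg.max())


class TestDemoMorphologies:
    def test_granule_like_has_four_plus_four_synapses(self):
        model = make_demo_neuron("granule_like", seed=0)
        exc = [s for s in model.synapses if s.excitatory]
        inh = [s for s in model.synapses if not s.excitatory]
        assert len(model.synapses) == 8
        assert len(exc) == 4 and len(inh) == 4
        assert all(s.kind == "gaba" for s in inh)

    def test_ball_and_stick_is_depth_one(self):
        model = make_demo_neuron("ball_and_stick", seed=0)
        assert model.n_compartments >= 2
        assert model.compartments[0].parent is None
        assert all(c.parent == "soma" for c in model.compartments[1:])

    def test_pyramidal_like_builds_and_simulates(self):
        model = make_demo_neuron("pyramidal_like", seed=0)
        proto = StimulusProtocol(injections=[CurrentInjection("soma", 200.0, 5.0, 20.0)])
        res = simulate(model, proto, t_stop=30.0)
        assert np.all(np.isfinite(res.v))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            make_demo_neuron("unknown")

    def test_model_validation(self):
        c0 = _sphere(10.0, ChannelSet.passive())
        dangling = Compartment(
            "d", 10, 1, Point3(0, 0, 0), Point3(10, 0, 0), parent="nope",
            channels=ChannelSet.passive(),
        )
        with pytest.raises(DataError):
            CableModel([c0, dangling])
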