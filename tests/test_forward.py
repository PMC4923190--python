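import numpy as np
import pytest

from neurolfp import (
    ConfigurationError,
    ElectrodeArray,
    GeometryError,
    Medium,
    Point3,
    SegmentSource,
    SourceSet,
    compute_lfp,
    compute_mea,
    lsa_potential,
    lsa_quadrature,
    make_grid,
    psa_potential,
    rc_filter,
)

from conftest import biphasic_current


class TestPointSource:
    def test_zero_current_gives_zero(self, medium):
        assert psa_potential(0.0, 37.0, medium) == 0.0

    def test_hand_computed_reference(self, medium):
        # 1 nA / (4 pi * 0.3 S/m * 100 um) = 2.6526 uV
        assert psa_potential(1.0, 100.0, medium) == pytest.approx(2.6526, rel=1e-4)

    def test_inverse_distance_scaling(self, medium):
        assert psa_potential(1.0, 200.0, medium) == pytest.approx(
            psa_potential(1.0, 100.0, medium) / 2, rel=1e-12
        )

    def test_min_distance_clamp(self, medium):
        assert psa_potential(1.0, 0.0, medium) == psa_potential(1.0, medium.min_distance, medium)

    def test_nonfinite_rejected(self, medium):
        from neurolfp import DataError

        with pytest.raises(DataError):
            psa_potential(np.nan, 10.0, medium)


class TestLineSource:
    def test_midpoint_value_matches_quadrature_oracle(self, granule_segment, medium):
        # frozen from adaptive quadrature of the integral form
        expected = 25.529080210836092
        got = lsa_potential(1.0, granule_segment, (5.0, 10.0, 0.0), medium)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_far_field_matches_point_source(self, granule_segment, medium):
        far = lsa_potential(1.0, granule_segment, (5.0, 1000.0, 0.0), medium)
        assert far == pytest.approx(psa_potential(1.0, 1000.0, medium), rel=1e-4)

    def test_zero_current(self, granule_segment, medium):
        assert lsa_potential(0.0, granule_segment, (5.0, 10.0, 0.0), medium) == 0.0

    def test_zero_length_rejected(self, medium):
        soma = SegmentSource("s", Point3(0, 0, 0), Point3(0, 0, 0), 2.0, spherical=True)
        with pytest.raises(GeometryError):
            lsa_potential(1.0, soma, (5, 5, 5), medium)

    def test_closed_form_equals_quadrature_on_random_geometries(self, medium):
        """Closed-form log expression vs adaptive quadrature, 1000 geometries."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(1000):
            p0 = rng.normal(scale=20, size=3)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ds = rng.uniform(0.5, 40.0)
            seg = SegmentSource("s", Point3(*p0), Point3(*(p0 + ds * axis)), 1.0)
            e = rng.normal(scale=100, size=3)
            closed = lsa_potential(1.0, seg, e, medium)
            quad = lsa_quadrature(1.0, seg, e, medium, tol=1e-12)
            worst = max(worst, abs(closed - quad) / max(abs(quad), 1e-300))
        assert worst < 1e-6

    def test_quadrature_point_source_limit(self, medium):
        seg = SegmentSource("s", Point3(0, 0, 0), Point3(1e-3, 0, 0), 0.5)
        val = lsa_quadrature(1.0, seg, (0.0, 50.0, 0.0), medium)
        assert val == pytest.approx(psa_potential(1.0, 50.0, medium), rel=1e-6)

    def test_far_field_numerically_stable_beyond_distal_end(self, granule_segment, medium):
        # electrode far beyond the end: both log factors suffer cancellation
        # in the naive form; result must still match quadrature
        e = (5e4, 3.0, 0.0)
        closed = lsa_potential(1.0, granule_segment, e, medium)
        quad = lsa_quadrature(1.0, granule_segment, e, medium, tol=1e-12)
        assert closed == pytest.approx(quad, rel=1e-9)
        assert closed > 0


class TestRCFilter:
    def test_dc_gain_is_one(self):
        y = rc_filter(np.full(5000, 3.7), dt=0.1, tau=5.0)
        assert y[-1] == pytest.approx(3.7, rel=1e-9)

    def test_tiny_tau_is_identity(self):
        x = np.sin(np.arange(200) * 0.3)
        y = rc_filter(x, dt=0.1, tau=0.1 * 1e-6)
        assert np.allclose(y, x, rtol=1e-6, atol=1e-6 * np.abs(x).max())

    def test_step_response_at_tau(self):
        # the filter starts at rest on the first sample, so the step must
        # rise after the start for the continuous charging curve to apply
        tau = 5.0
        dt = 0.001 * tau
        on = 100
        x = np.concatenate([np.zeros(on), np.ones(int(3 * tau / dt))])
        y = rc_filter(x, dt=dt, tau=tau)
        k = on + int(tau / dt) - 1
        assert y[k] == pytest.approx(1 - np.exp(-1), rel=0.01)

    def test_magnitude_response_monotone_nonincreasing(self):
        from scipy.signal import freqz

        dt, tau = 0.1, 5.0
        alpha = dt / (tau + dt)
        w, h = freqz([alpha], [1, -(1 - alpha)], worN=512)
        mag = np.abs(h)
        assert np.all(np.diff(mag) <= 1e-12)

    def test_invalid_tau(self):
        with pytest.raises(ConfigurationError):
            rc_filter(np.ones(10), dt=0.1, tau=0.0)


def _two_segment_sources(dt=0.025):
    segs = [
        SegmentSource("a", Point3(0, 0, 0), Point3(10, 0, 0), 1.0),
        SegmentSource("b", Point3(0, 0, 20), Point3(0, 10, 20), 1.0),
    ]
    cur = np.vstack([biphasic_current(dt=dt), -0.5 * biphasic_current(dt=dt)])
    return SourceSet(segs, cur, dt)


class TestSuperposition:
    @pytest.mark.parametrize("method", ["psa", "lsa", "rc"])
    def test_lfp_is_additive_over_sources(self, medium, method):
        ss = _two_segment_sources()
        a = SourceSet(ss.segments[:1], ss.currents[:1], ss.dt)
        b = SourceSet(ss.segments[1:], ss.currents[1:], ss.dt)
        el = ElectrodeArray.single((30.0, 40.0, 10.0))
        full = compute_lfp(ss, el, medium, method).values
        parts = (
            compute_lfp(a, el, medium, method).values
            + compute_lfp(b, el, medium, method).values
        )
        assert np.allclose(full, parts, rtol=1e-12, atol=1e-300)

    def test_empty_sourceset_gives_zero_trace(self, medium):
        ss = SourceSet.empty(100, 0.025)
        trace = compute_lfp(ss, make_grid(), medium, "lsa")
        assert trace.values.shape == (16, 100)
        assert np.all(trace.values == 0)

    def test_single_source_psa_reduces_to_samplewise_formula(self, medium):
        ss = _two_segment_sources()
        one = SourceSet(ss.segments[:1], ss.currents[:1], ss.dt)
        e = (5.0, 80.0, 0.0)
        trace = compute_lfp(one, ElectrodeArray.single(e), medium, "psa")
        r = np.linalg.norm(one.segments[0].midpoint - np.array(e))
        expected = psa_potential(one.currents[0], r, medium)
        assert np.allclose(trace.values[0], expected, rtol=1e-12)

    def test_amplitude_linear_in_resistivity(self, granule_segment):
        ss = SourceSet([granule_segment], biphasic_current()[None, :], 0.025)
        el = ElectrodeArray.single((5.0, 50.0, 0.0))
        base = compute_lfp(ss, el, Medium.from_resistivity(0.30), "lsa").values
        for k in (0.8, 1.4, 2.0):
            scaled = compute_lfp(ss, el, Medium.from_resistivity(0.30 * k), "lsa").values
            assert np.allclose(scaled, k * base, rtol=1e-12)

    def test_conserving_dipole_far_field_slope(self, medium):
        """Zero-net-current pair decays at least as fast as r^-2."""
        segs = [
            SegmentSource("p", Point3(0, 0, 5), Point3(0, 0, 5), 1.0, spherical=True),
            SegmentSource("n", Point3(0, 0, -5), Point3(0, 0, -5), 1.0, spherical=True),
        ]
        cur = np.vstack([biphasic_current(), -biphasic_current()])
        ss = SourceSet(segs, cur, 0.025)
        dists = np.geomspace(100, 1000, 8)  # 10x to 100x the 10 um extent
        amps = []
        for r in dists:
            tr = compute_lfp(ss, ElectrodeArray.single((0, 0, r)), medium, "psa")
            amps.append(np.abs(tr.values).max())
        slope = np.polyfit(np.log(dists), np.log(amps), 1)[0]
        assert slope <= -2.0


class TestRCSchema:
    def test_rc_equals_filtered_currents_through_psa_geometry(self, medium):
        ss = _two_segment_sources()
        el = ElectrodeArray.single((40.0, 10.0, 0.0))
        rc = compute_lfp(ss, el, medium, "rc").values
        filtered = SourceSet(ss.segments, rc_filter(ss.currents, ss.dt, medium.tau), ss.dt)
        manual = compute_lfp(filtered, el, medium, "psa").values
        assert np.allclose(rc, manual, rtol=1e-12)

    def test_rc_literal_is_distance_free(self, medium):
        ss = _two_segment_sources()
        el = ElectrodeArray(
            [
                *ElectrodeArray.single((10, 0, 0), "near").electrodes,
                *ElectrodeArray.single((500, 0, 0), "far").electrodes,
            ]
        )
        trace = compute_lfp(ss, el, medium, "rc", rc_literal=True)
        assert np.allclose(trace.values[0], trace.values[1])

    def test_rc_reduces_peak_amplitude_of_fast_transients(self, medium):
        ss = _two_segment_sources()
        el = ElectrodeArray.single((40.0, 10.0, 0.0))
        psa = compute_lfp(ss, el, medium, "psa").values
        rc = compute_lfp(ss, el, medium, "rc").values
        assert np.abs(rc).max() < np.abs(psa).max()


class TestMEA:
    def test_single_electrode_array_matches_compute_lfp(self, medium):
        ss = _two_segment_sources()
        el = ElectrodeArray.single((25, 25, 50))
        assert np.array_equal(
            compute_mea(ss, el, medium, "lsa").values,
            compute_lfp(ss, el, medium, "lsa").values,
        )

    def test_default_grid_yields_16_traces(self, medium):
        ss = _two_segment_sources()
        trace = compute_mea(ss, make_grid(), medium, "lsa")
        assert trace.values.shape[0] == 16
        assert trace.labels[:2] == ["r0c0", "r0c1"]

    def test_central_source_amplitude_map_is_symmetric(self, medium):
        # grid centred on the source: amplitudes invariant under the grid's
        # reflection symmetries
        src = SegmentSource("c", Point3(150, 150, -30), Point3(150, 150, -30), 2.0, spherical=True)
        ss = SourceSet([src], biphasic_current()[None, :], 0.025)
        trace = compute_mea(ss, make_grid(), medium, "psa")
        amp = np.abs(trace.values).max(axis=1).reshape(4, 4)
        assert np.allclose(amp, amp[::-1, :], rtol=1e-9)
        assert np.allclose(amp, amp[:, ::-1], rtol=1e-9)
        assert np.allclose(amp, amp.T, rtol=1e-9)

    def test_unknown_method_rejected(self, medium):
        ss = _two_segment_sources()
        with pytest.raises(ConfigurationError):
            compute_lfp(ss, make_grid(), medium, "csd")
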