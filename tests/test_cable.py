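"""Axon model: geometry tables, resting state, propagation, detection,
activation criterion, and threshold search mechanics."""

import numpy as np
import pytest

from dbsim import cable
from dbsim.cable import (
    FLUT,
    MYSA,
    NODE,
    STIN,
    MRG_GEOMETRY_TABLE,
    StimProtocol,
    build_morphology,
    detect_spikes,
    find_threshold,
    is_activated,
    mrg_geometry,
    simulate,
)

from conftest import analytic_ve


class TestGeometryTable:
    def test_tabulated_diameter_exact(self):
        g = mrg_geometry(5.7)
        assert (g["axonD"], g["nodeD"], g["deltax"], g["nl"]) == (3.4, 1.9, 500.0, 80)
        assert g["flut_length"] == 35.0

    def test_interpolation_between_entries(self):
        g = mrg_geometry(6.5)
        lo, hi = MRG_GEOMETRY_TABLE[5.7], MRG_GEOMETRY_TABLE[7.3]
        t = (6.5 - 5.7) / (7.3 - 5.7)
        assert g["deltax"] == pytest.approx(lo[4] + t * (hi[4] - lo[4]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mrg_geometry(1.0)
        with pytest.raises(ValueError):
            mrg_geometry(17.0)

    def test_internode_spacing_monotone_in_diameter(self):
        d = [mrg_geometry(x)["deltax"] for x in (2.0, 5.7, 8.7, 11.5, 16.0)]
        assert np.all(np.diff(d) > 0)


class TestMorphology:
    def test_repeating_unit_structure(self, straight_trajectory):
        m = build_morphology(5.7, straight_trajectory, n_nodes=21)
        assert m.n_nodes == 21
        unit = [NODE, MYSA, FLUT] + [STIN] * 6 + [FLUT, MYSA]
        assert m.ctype[:11].tolist() == unit
        assert m.ctype[-1] == NODE
        assert m.n_compartments == 20 * 11 + 1

    def test_straight_trajectory_equal_arc_spacing(self, straight_trajectory):
        m = build_morphology(8.7, straight_trajectory)
        nodes = m.positions_mm[m.node_indices]
        gaps = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        assert np.allclose(gaps, 1.0, atol=1e-9)  # deltax = 1000 um

    def test_too_short_trajectory_rejected(self):
        short = np.stack([np.zeros(5), np.zeros(5), np.linspace(0, 4, 5)], axis=1)
        with pytest.raises(ValueError, match="too short"):
            build_morphology(8.7, short)

    def test_minimum_node_count(self, straight_trajectory):
        with pytest.raises(ValueError, match="21 nodes"):
            build_morphology(5.7, straight_trajectory, n_nodes=15)

    def test_positions_on_trajectory(self):
        # gentle arc in the x-z plane
        s = np.linspace(0, np.pi, 200)
        traj = np.stack([5 * np.cos(s), np.zeros_like(s), 30 * s / np.pi - 15], axis=1)
        m = build_morphology(5.7, traj)
        # every compartment center lies within the polyline's bounding box
        assert (m.positions_mm[:, 0] >= -5 - 1e-9).all()
        assert (m.positions_mm[:, 0] <= 5 + 1e-9).all()


class TestRestingState:
    def test_rest_is_fixed_point(self, axon_57):
        tr = simulate(axon_57, duration_ms=500.0)
        assert np.abs(tr.vm_mV + 80.0).max() < 0.1

    def test_zero_stimulus_flat_everywhere(self, axon_57):
        tr = simulate(axon_57, duration_ms=20.0)
        assert np.abs(np.diff(tr.vm_mV, axis=0)).max() < 1e-6


class TestPropagation:
    @pytest.mark.parametrize("diameter", [2.0, 5.7, 8.7])
    def test_intracellular_pulse_propagates(self, straight_trajectory, diameter):
        m = build_morphology(diameter, straight_trajectory)
        tr = simulate(
            m, duration_ms=8.0, iinj_nA=2000.0, iinj_comp=0,
            iinj_window_ms=(1.0, 1.1),
        )
        spikes_last = detect_spikes(tr.vm_mV[:, -1], tr.times_ms)
        assert len(spikes_last) >= 1


def conduction_velocity(diameter, trajectory):
    m = build_morphology(diameter, trajectory)
    tr = simulate(
        m, duration_ms=8.0, iinj_nA=2000.0, iinj_comp=0, iinj_window_ms=(1.0, 1.1)
    )
    nodes = m.node_indices
    t14 = detect_spikes(tr.vm_mV[:, 14], tr.times_ms)[0]
    t19 = detect_spikes(tr.vm_mV[:, 19], tr.times_ms)[0]
    dist = np.linalg.norm(m.positions_mm[nodes[19]] - m.positions_mm[nodes[14]])
    return dist / (t19 - t14)  # mm/ms == m/s


class TestSpikeDetection:
    def test_flat_trace_no_spikes(self):
        t = np.linspace(0, 10, 1001)
        assert detect_spikes(np.full_like(t, -80.0), t).size == 0

    def test_single_synthetic_ap(self):
        t = np.linspace(0, 10, 1001)
        v = -80 + 110 * np.exp(-((t - 4.0) ** 2) / 0.05)
        spikes = detect_spikes(v, t)
        assert len(spikes) == 1
        # upward -20 mV crossing just before the peak
        assert 3.5 < spikes[0] < 4.0

    def test_train_of_ten(self):
        t = np.linspace(0, 500, 50001)
        v = np.full_like(t, -80.0)
        for k in range(10):
            v += 110 * np.exp(-((t - (5.0 + 50.0 * k)) ** 2) / 0.05)
        spikes = detect_spikes(v, t)
        assert len(spikes) == 10
        assert np.allclose(np.diff(spikes), 50.0, atol=0.02)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(np.array([0.0, np.nan]), np.array([0.0, 1.0]))


class TestActivationCriterion:
    """The quoted pulse-train criterion, exact: >= 8 of 10 pulses with a
    spike latency inside the closed [1, 3] ms window."""

    protocol = StimProtocol(amplitude_ma=1.0)  # onsets at 1, 51, ... 451 ms

    def onsets(self):
        return self.protocol.pulse_onsets_ms()

    def test_response_to_every_pulse(self):
        spikes = self.onsets() + 2.0
        assert is_activated(spikes, self.protocol) is True

    def test_seven_of_ten_fails(self):
        spikes = self.onsets()[:7] + 2.0
        assert is_activated(spikes, self.protocol) is False

    def test_eight_of_ten_boundary_passes(self):
        spikes = self.onsets()[:8] + 2.0
        assert is_activated(spikes, self.protocol) is True

    def test_latency_below_window_fails(self):
        spikes = self.onsets() + 0.5
        assert is_activated(spikes, self.protocol) is False

    def test_latency_above_window_fails(self):
        spikes = self.onsets() + 3.5
        assert is_activated(spikes, self.protocol) is False

    def test_window_boundaries_closed(self):
        assert is_activated(self.onsets() + 1.0, self.protocol) is True
        assert is_activated(self.onsets() + 3.0, self.protocol) is True


class TestThresholdSearch:
    def test_activated_at_every_amplitude_returns_first_grid_point(
        self, straight_trajectory
    ):
        # rheobase ~1.1 mA here, so every amplitude on a 1.2-2.0 grid fires
        m = build_morphology(5.7, straight_trajectory)
        ve = analytic_ve(m.positions_mm, (2.0, 0.0, 0.0))
        thr = find_threshold(
            m, ve, protocol=StimProtocol(latency_window_ms=(0.0, 3.0)),
            amp_grid=np.round(np.arange(1.2, 2.01, 0.1), 10),
            confirm_train=False,
        )
        assert thr == pytest.approx(1.2)

    def test_never_activated_returns_sentinel(self, straight_trajectory):
        m = build_morphology(2.0, straight_trajectory)
        ve = analytic_ve(m.positions_mm, (15.0, 0.0, 0.0))
        thr = find_threshold(
            m, ve, protocol=StimProtocol(latency_window_ms=(0.0, 3.0)),
            confirm_train=False,
        )
        assert np.isnan(thr)

    def test_bisection_matches_full_scan(self, straight_trajectory):
        m = build_morphology(5.7, straight_trajectory)
        ve = analytic_ve(m.positions_mm, (2.0, 0.0, 0.0))
        proto = StimProtocol(latency_window_ms=(0.0, 3.0))
        fast = find_threshold(m, ve, protocol=proto, confirm_train=False)
        # brute-force ascending scan with the same single-pulse probe
        from dbsim.cable import MembraneParams, _single_pulse_response, build_system
        from dataclasses import replace

        params = MembraneParams()
        system = build_system(m, params)
        scan = np.nan
        for a in np.round(np.arange(0.1, 3.51, 0.1), 10):
            if _single_pulse_response(
                m, params, ve, replace(proto, amplitude_ma=a), 0.005, system
            ):
                scan = a
                break
        assert fast == pytest.approx(scan)

    def test_refinement_within_one_grid_step(self, straight_trajectory):
        m = build_morphology(5.7, straight_trajectory)
        ve = analytic_ve(m.positions_mm, (2.0, 0.0, 0.0))
        proto = StimProtocol(latency_window_ms=(0.0, 3.0))
        coarse = find_threshold(m, ve, protocol=proto, confirm_train=False)
        refined = find_threshold(
            m, ve, protocol=proto, confirm_train=False, refine_ma=0.01
        )
        assert coarse - 0.1 < refined <= coarse + 1e-9

    def test_invalid_grid_rejected(self, axon_57):
        with pytest.raises(ValueError, match="ascending"):
            find_threshold(axon_57, np.zeros(axon_57.n_compartments),
                           amp_grid=np.array([1.0, 0.5]))


class TestProtocolValidation:
    def test_pulse_width_must_fit_period(self):
        with pytest.raises(ValueError):
            StimProtocol(pulse_width_us=60_000.0, rate_hz=20.0)

    def test_amplitude_positive(self):
        with pytest.raises(ValueError):
            StimProtocol(amplitude_ma=-1.0)

    def test_polarity_checked(self):
        with pytest.raises(ValueError):
            StimProtocol(polarity="sideways")


def test_membrane_params_reject_negative_conductance():
    from dbsim.cable import MembraneParams

    with pytest.raises(ValueError, match="non-negative"):
        MembraneParams(gks=-0.1)
    with pytest.raises(ValueError, match="positive"):
        MembraneParams(rho_axial=0.0)
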