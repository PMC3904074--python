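import math

import numpy as np
import pytest

from cablekit.channels import LeakChannel
from cablekit.errors import DiscretizationError
from cablekit.model import Cell, Simulation, SpikeTimesTrigger, SynapseTemplate
from cablekit.morphology import Morphology, MorphLocation, build_soma_from_area
from cablekit.solver import ThresholdDetector, detect_events, discretize
from cablekit.traces import spike_count, window_stat

from conftest import PASSIVE, make_hh_sim, make_passive_sim
from oracles import passive_step_response


def passive_cell(name="c"):
    cell = Cell(name, build_soma_from_area(1000))
    cell.apply_channel(LeakChannel("lk", "0.3 mS/cm2", "-51 mV"))
    return cell


class TestDiscretize:
    def test_soma_single_segment(self):
        d = discretize(passive_cell())
        assert d.n == 1
        assert d.area_cm2[0] == pytest.approx(1000e-8, rel=1e-9)
        assert d.c_nF[0] == pytest.approx(0.01, rel=1e-9)  # 10 pF
        assert d.parent[0] == -1

    def test_uniform_cylinder_two_segments(self):
        cell = Cell("c", build_soma_from_area(1000), nseg_map={"soma": 2})
        cell.apply_channel(LeakChannel("lk", "0.3 mS/cm2", "-51 mV"))
        d = discretize(cell)
        assert d.n == 2
        assert d.area_cm2[0] == pytest.approx(d.area_cm2[1])
        assert d.parent.tolist() == [-1, 0]
        assert d.g_axial_uS[1] > 0

    def test_area_conserved_over_random_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = Morphology("t")
            m.add_section("s0", (0, 0, 0), (rng.uniform(5, 30), 0, 0),
                          rng.uniform(1, 5), rng.uniform(1, 5), "soma")
            for i in range(rng.integers(1, 6)):
                parent = m.sections[int(rng.integers(0, len(m)))]
                end = parent.distal + rng.uniform(1, 40, size=3)
                m.add_section(f"s{i+1}", parent.distal, end,
                              rng.uniform(0.5, 3), rng.uniform(0.5, 3),
                              "dendrite", parent=parent)
            cell = Cell("c", m, nseg_map={
                s.id: int(rng.integers(1, 7)) for s in m})
            cell.apply_channel(LeakChannel("lk", "0.3 mS/cm2", "-51 mV"))
            d = discretize(cell)
            assert d.area_cm2.sum() * 1e8 == pytest.approx(
                m.surface_area().magnitude_in("um2"), rel=1e-9)

    def test_bad_nseg_rejected(self):
        with pytest.raises(DiscretizationError):
            discretize(passive_cell(), nseg_map={"soma": 0})

    def test_hines_order_parents_first(self):
        cell = Cell("c", build_soma_from_area(1000), nseg_map={"soma": 5})
        cell.apply_channel(LeakChannel("lk", "0.3 mS/cm2", "-51 mV"))
        d = discretize(cell)
        assert all(d.parent[i] < i for i in range(1, d.n))


class TestPassiveAccuracy:
    def test_step_response_matches_closed_form(self):
        sim = make_passive_sim(duration="100 ms")
        tr = sim.run().traces[0]
        exact = passive_step_response(tr.times, **PASSIVE, I_nA=0.1)
        err = np.max(np.abs(tr.values - exact))
        # backward Euler at dt = 0.025 ms; bound loose by design
        assert err < 0.05  # mV

    def test_delta_v_at_one_tau(self):
        """At t = tau the response is (1 - 1/e) of 33.33 mV = 21.07 mV."""
        sim = make_passive_sim(duration="100 ms", dt="0.005 ms")
        tr = sim.run().traces[0]
        tau = PASSIVE["C_nF"] / PASSIVE["G_uS"]
        idx = int(round(tau / 0.005))
        dv = tr.values[idx] - PASSIVE["E_mV"]
        assert dv == pytest.approx(33.3333 * (1 - math.exp(-1)), rel=2e-3)
        assert dv == pytest.approx(21.07, abs=0.05)

    def test_equilibrium_is_preserved(self):
        sim = make_passive_sim(amp="0 pA")
        tr = sim.run().traces[0]
        assert np.all(np.abs(tr.values + 51.0) < 1e-9)

    def test_convergence_orders(self):
        dts = (0.1, 0.05, 0.025, 0.0125)
        for method, lo, hi in (("backward_euler", 1.7, 2.3),
                               ("crank_nicolson", 3.5, 4.5)):
            errs = []
            for dt in dts:
                tr = make_passive_sim(dt=f"{dt} ms").run(
                    method=method).traces[0]
                exact = passive_step_response(tr.times, **PASSIVE, I_nA=0.1)
                errs.append(np.max(np.abs(tr.values - exact)))
            for a, b in zip(errs, errs[1:]):
                assert lo < a / b < hi


class TestCable:
    def test_two_segment_charge_decay_monotonic(self):
        cell = Cell("c", build_soma_from_area(1000), nseg_map={"soma": 2},
                    initial_voltage="-30 mV")
        cell.apply_channel(LeakChannel("lk", "0.3 mS/cm2", "-51 mV"))
        sim = Simulation("decay", duration="50 ms")
        sim.add_cell(cell)
        sim.record(cell, "Voltage", location=MorphLocation(
            cell.morphology.root, 0.0))
        tr = sim.run().traces[0]
        # relaxation toward the leak equilibrium, monotonically
        diffs = np.diff(tr.values)
        assert np.all(diffs <= 1e-12)
        assert tr.values[-1] == pytest.approx(-51.0, abs=0.01)

    def test_fine_spatial_discretization_consistent(self):
        """nseg 1 vs nseg 8 on an isopotential soma agree to ~numerics."""
        results = []
        for n in (1, 8):
            cell = Cell("c", build_soma_from_area(1000),
                        nseg_map={"soma": n})
            cell.apply_channel(LeakChannel("lk", "0.3 mS/cm2", "-51 mV"))
            sim = Simulation("s", duration="50 ms")
            sim.add_cell(cell)
            sim.create_currentclamp(cell, amp="100 pA")
            sim.record(cell, "Voltage")
            results.append(sim.run().traces[0].values)
        assert np.max(np.abs(results[0] - results[1])) < 1e-3


class TestGapJunction:
    def _coupled(self, g_nS):
        sim = Simulation("gj", duration="200 ms")
        c1 = sim.add_cell(passive_cell("cell1"))
        c2 = sim.add_cell(passive_cell("cell2"))
        sim.create_gapjunction(f"{g_nS} nS", cell1=c1, cell2=c2)
        sim.create_currentclamp(c1, amp="100 pA")
        sim.record(c1, "Voltage")
        sim.record(c2, "Voltage")
        return sim.run()

    def test_coupling_coefficient(self):
        res = self._coupled(1.0)
        dv1 = window_stat(res.traces[0], 190, 200).magnitude + 51
        dv2 = window_stat(res.traces[1], 190, 200).magnitude + 51
        # g/(G+g) = 1/(3+1)
        assert dv2 / dv1 == pytest.approx(0.25, rel=5e-3)

    def test_zero_conductance_decouples(self):
        res = self._coupled(0.0)
        assert np.all(np.abs(res.traces[1].values + 51.0) < 1e-9)

    def test_iteration_metadata_reported(self):
        res = self._coupled(1.0)
        assert res.metadata["gap_junction_iterations"] >= res.metadata["steps"]


class TestSynapseRuntime:
    def test_vclamp_psr_matches_analytic_waveform(self):
        sim = Simulation("syn", duration="60 ms")
        cell = sim.add_cell(passive_cell("cell1"))
        sim.create_voltageclamp(cell, voltage="-51 mV")
        tmpl = SynapseTemplate.build("ampa", "0.5 ms", "5 ms", "2 nS", "0 mV")
        syn = sim.create_synapse(tmpl, post_cell=cell,
                                 trigger=SpikeTimesTrigger([20.0]))
        sim.record(syn, "Conductance")
        tr = sim.run().traces[0]
        from cablekit.channels import psr_conductance

        rel = np.maximum(tr.times - 20.0, 0.0)
        expected = np.where(
            tr.times >= 20.0, psr_conductance(tmpl.psr, rel).magnitude, 0.0)
        scale = expected.max()
        assert np.max(np.abs(tr.values - expected)) / scale < 5e-3

    def test_multiple_events_sum_linearly(self):
        def peak(times):
            sim = Simulation("syn", duration="80 ms")
            cell = sim.add_cell(passive_cell("cell1"))
            sim.create_voltageclamp(cell, voltage="-51 mV")
            tmpl = SynapseTemplate.build("a", "0.5 ms", "5 ms", "2 nS",
                                         "0 mV")
            syn = sim.create_synapse(tmpl, post_cell=cell,
                                     trigger=SpikeTimesTrigger(times))
            sim.record(syn, "Conductance")
            return sim.run().traces[0]

        single = peak([20.0])
        double = peak([20.0, 20.0])  # coincident events double the waveform
        assert np.allclose(double.values, 2 * single.values, atol=1e-12)

    def test_late_events_dropped_and_counted(self):
        sim = Simulation("syn", duration="30 ms")
        cell = sim.add_cell(passive_cell("cell1"))
        tmpl = SynapseTemplate.build("a", "0.5 ms", "5 ms", "2 nS", "0 mV")
        sim.create_synapse(tmpl, post_cell=cell,
                           trigger=SpikeTimesTrigger([10.0, 50.0]))
        sim.record(cell, "Voltage")
        res = sim.run()
        assert res.metadata["dropped_events"] == 1


class TestHHSanity:
    def test_spikes_for_strong_step_none_for_weak(self):
        strong = make_hh_sim(amp="200 pA").run().traces[0]
        weak = make_hh_sim(amp="1 pA").run().traces[0]
        assert spike_count(strong, "0 mV") >= 1
        assert spike_count(weak, "0 mV") == 0

    def test_resting_cell_is_quiet(self):
        sim = make_hh_sim(amp="0 pA", duration="50 ms")
        tr = sim.run().traces[0]
        assert spike_count(tr, "0 mV") == 0
        assert abs(tr.values[-1] - tr.values[0]) < 2.0  # settles near rest


class TestDetectEvents:
    def test_single_ramp_crossing(self):
        det = ThresholdDetector(0.0, -60.0)
        v = np.linspace(-60, 60, 25)
        hits = [det.update(i * 1.0, (i + 1) * 1.0, v[i], v[i + 1])
                for i in range(24)]
        assert sum(h is not None for h in hits) == 1

    def test_sine_five_upward_crossings(self):
        t = np.linspace(0, 5, 5001)  # 5 cycles of a 1 kHz sine
        v = 20 * np.sin(2 * np.pi * t - 0.1)  # starts just below threshold
        det = ThresholdDetector(0.0, v[0])
        hits = 0
        for i in range(len(t) - 1):
            if det.update(t[i], t[i + 1], v[i], v[i + 1]) is not None:
                hits += 1
        assert hits == 5

    def test_starting_above_threshold_requires_fall_rise(self):
        det = ThresholdDetector(0.0, 10.0)
        assert det.update(0, 1, 10.0, 20.0) is None
        assert det.update(1, 2, 20.0, -5.0) is None  # falls: re-arms
        assert det.update(2, 3, -5.0, 5.0) is not None

    def test_interpolated_crossing_time(self):
        det = ThresholdDetector(0.0, -10.0)
        t = det.update(0.0, 1.0, -10.0, 10.0)
        assert t == pytest.approx(0.5)

    def test_batch_helper(self):
        dets = [ThresholdDetector(0.0, -10.0), ThresholdDetector(0.0, -10.0)]
        events = detect_events(dets, 0.0, 1.0, [-10.0, -10.0], [5.0, -5.0])
        assert [i for i, _ in events] == [0]


class TestEventDelivery:
    def test_synaptic_delay_folded_to_next_boundary(self):
        # presynaptic explicit event at 10.01 ms with 0 delay must act at
        # the 10.025 boundary (dt 0.025), not before
        sim = Simulation("syn", duration="20 ms")
        cell = sim.add_cell(passive_cell("cell1"))
        sim.create_voltageclamp(cell, voltage="-51 mV")
        tmpl = SynapseTemplate.build("a", "0.5 ms", "5 ms", "2 nS", "0 mV")
        syn = sim.create_synapse(tmpl, post_cell=cell,
                                 trigger=SpikeTimesTrigger([10.01]))
        sim.record(syn, "Conductance")
        tr = sim.run().traces[0]
        nonzero = tr.times[tr.values > 0]
        assert nonzero[0] == pytest.approx(10.05, abs=1e-9)
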