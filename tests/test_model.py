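import numpy as np
import pytest

from cablekit.channels import LeakChannel, hh_sodium
from cablekit.components import build_hh_soma_cell, standard_libraries
from cablekit.errors import ReferenceError_, ValidationError
from cablekit.io import (
    load_simulation,
    save_simulation,
    simulation_from_document,
    simulation_to_document,
)
from cablekit.model import ComponentLibrary, Simulation, SpikeTimesTrigger, \
    SynapseTemplate
from cablekit.morphology import build_soma_from_area

from conftest import make_passive_sim


class TestStimuli:
    def _sim_cell(self):
        sim = Simulation("s", duration="200 ms")
        cell = sim.create_cell("cell1", build_soma_from_area(1000))
        cell.apply_channel(LeakChannel("lk", "0.3 mS/cm2", "-51 mV"))
        return sim, cell

    def test_step_inside_window(self):
        sim, cell = self._sim_cell()
        stim = sim.create_currentclamp(cell, amp="100 pA", delay="50 ms",
                                       duration="100 ms")
        assert float(stim.current_nA(75.0)) == pytest.approx(0.1)
        assert float(stim.current_nA(25.0)) == 0.0
        assert float(stim.current_nA(151.0)) == 0.0

    def test_sine_quarter_period(self):
        sim, cell = self._sim_cell()
        stim = sim.create_currentclamp(cell, protocol="sine", amp="50 pA",
                                       frequency="10 Hz", delay="0 ms")
        # 2*pi*10Hz*25ms = pi/2 -> full amplitude
        assert float(stim.current_nA(25.0)) == pytest.approx(0.05, rel=1e-9)
        assert float(stim.current_nA(0.0)) == pytest.approx(0.0, abs=1e-12)

    def test_ramp_midpoint(self):
        sim, cell = self._sim_cell()
        stim = sim.create_currentclamp(cell, protocol="ramp", amp0="0 pA",
                                       amp1="100 pA", delay="0 ms",
                                       duration="100 ms")
        assert float(stim.current_nA(50.0)) == pytest.approx(0.05)

    def test_default_protocol_is_step(self):
        sim, cell = self._sim_cell()
        stim = sim.create_currentclamp(cell, amp="10 pA")
        assert stim.kind == "step"

    def test_missing_parameter_named(self):
        sim, cell = self._sim_cell()
        with pytest.raises(ValidationError, match="amp"):
            sim.create_currentclamp(cell, protocol="step")

    def test_unknown_protocol(self):
        sim, cell = self._sim_cell()
        with pytest.raises(ValidationError, match="sawtooth"):
            sim.create_currentclamp(cell, protocol="sawtooth", amp="1 pA")

    def test_negative_delay_rejected(self):
        sim, cell = self._sim_cell()
        with pytest.raises(ValidationError):
            sim.create_currentclamp(cell, amp="1 pA", delay="-5 ms")


class TestComponentLibrary:
    def test_register_and_instantiate_defaults(self):
        lib = ComponentLibrary("channel")
        lib.register("std", "leak",
                     lambda **kw: LeakChannel("lk", "0.3 mS/cm2", "-51 mV"))
        chl = lib.instantiate("std", "leak")
        assert chl.name == "lk"

    def test_kwargs_forwarded_to_builder(self):
        libs = standard_libraries()
        cell = libs["cell"].instantiate("hh", "soma_cell",
                                        include_sodium=False)
        names = [a.channel.name for a in cell.applications]
        assert "hh_na" not in names
        assert "hh_k" in names and "leak" in names
        full = libs["cell"].instantiate("hh", "soma_cell")
        assert "hh_na" in [a.channel.name for a in full.applications]

    def test_duplicate_registration_rejected(self):
        lib = ComponentLibrary("cell")
        lib.register("a", "b", lambda: None)
        with pytest.raises(ValueError, match="duplicate"):
            lib.register("a", "b", lambda: None)

    def test_unknown_key_lists_known(self):
        lib = ComponentLibrary("cell")
        lib.register("src", "typeA", lambda: None)
        with pytest.raises(LookupError, match="typeA"):
            lib.instantiate("src", "missing")

    def test_summary_table_iterates_registrations(self):
        libs = standard_libraries()
        rows = libs["channel"].summary_table()
        assert ("hh", "na", "hh_sodium") in rows
        assert len(rows) == len(libs["channel"])

    def test_empty_library_summary(self):
        assert ComponentLibrary("x").summary_table() == []


class TestRecord:
    def test_voltage_tags(self):
        sim = make_passive_sim()
        results = sim.run()
        tr = results.traces[0]
        assert {"Voltage", "cell1", "loc:soma"} <= tr.tags

    def test_user_tags_present(self):
        sim = Simulation("s", duration="10 ms")
        cell = sim.create_cell("c", build_soma_from_area(1000))
        cell.apply_channel(LeakChannel("lk", "0.3 mS/cm2", "-51 mV"))
        sim.record(cell, "Voltage", user_tags={"NMDA"})
        results = sim.run()
        assert "NMDA" in results.traces[0].tags

    def test_channel_not_on_cell_is_reference_error(self):
        sim = Simulation("s", duration="10 ms")
        cell = sim.create_cell("c", build_soma_from_area(1000))
        cell.apply_channel(LeakChannel("lk", "0.3 mS/cm2", "-51 mV"))
        with pytest.raises(ReferenceError_):
            sim.record(cell, "CurrentDensity", channel=hh_sodium())

    def test_foreign_cell_rejected(self):
        sim = Simulation("s", duration="10 ms")
        other = build_hh_soma_cell("stranger")
        with pytest.raises(ReferenceError_):
            sim.record(other, "Voltage")


class TestRun:
    def test_empty_simulation_is_validation_error(self):
        sim = Simulation("empty", duration="10 ms")
        with pytest.raises(ValidationError, match="no cells"):
            sim.run()

    def test_listing1_analogue_produces_three_traces(self):
        sim = Simulation("ex", duration="200 ms")
        cell = sim.create_cell("cell1", build_soma_from_area("1000 um2"))
        lk = LeakChannel("lk", "0.3 mS/cm2", "-51 mV")
        cell.apply_channel(lk)
        cc = sim.create_currentclamp(cell, amp="100 pA", delay="100 ms",
                                     duration="50 ms")
        sim.record(cell, "Voltage")
        sim.record(cell, "CurrentDensity", channel=lk)
        sim.record(cc, "Current")
        results = sim.run()
        assert len(results.traces) == 3
        assert [tr.name for tr in results.traces] == ["rec1", "rec2", "rec3"]

    def test_deterministic_rerun_bit_identical(self):
        r1 = make_passive_sim().run()
        r2 = make_passive_sim().run()
        for a, b in zip(r1.traces, r2.traces):
            assert np.array_equal(a.values, b.values)

    def test_graph_construction_is_inert(self):
        sim = make_passive_sim()
        # nothing recorded yet; building the graph allocated no result data
        assert sim.recordings[0].name == "rec1"
        assert not hasattr(sim, "results")

    def test_independent_simulations_do_not_share_state(self):
        s1 = make_passive_sim(amp="100 pA")
        s2 = make_passive_sim(amp="0 pA")
        r1 = s1.run()
        r2 = s2.run()
        assert r1.traces[0].values[-1] > -20
        assert r2.traces[0].values[-1] == pytest.approx(-51.0, abs=1e-6)

    def test_results_count_matches_requests(self):
        sim = make_passive_sim()
        cell = sim.cells[0]
        sim.record(cell, "Events", threshold="0 mV")
        results = sim.run()
        assert len(results.traces) + len(results.events) == len(
            sim.recordings)


class TestDocumentRoundTrip:
    def test_full_graph_round_trip(self, tmp_path):
        sim = Simulation("doc", duration="50 ms")
        c1 = sim.add_cell(build_hh_soma_cell("pre"))
        c2 = sim.create_cell("post", build_soma_from_area(1000))
        c2.apply_channel(LeakChannel("lk", "0.3 mS/cm2", "-60 mV"))
        tmpl = SynapseTemplate.build("ampa", "0.5 ms", "5 ms", "2 nS", "0 mV")
        sim.create_synapse(tmpl, post_cell=c2,
                           trigger=SpikeTimesTrigger([10.0]))
        sim.create_gapjunction("1 nS", cell1=c1, cell2=c2)
        sim.create_currentclamp(c1, amp="100 pA")
        sim.record(c1, "Voltage")
        sim.record(c2, "Voltage")
        path = tmp_path / "sim.json"
        save_simulation(sim, path)
        sim2 = load_simulation(path)
        assert [c.name for c in sim2.cells] == ["pre", "post"]
        assert len(sim2.synapses) == 1 and len(sim2.gap_junctions) == 1
        r1, r2 = sim.run(), sim2.run()
        for a, b in zip(r1.traces, r2.traces):
            assert np.allclose(a.values, b.values)

    def test_document_is_pure_data(self):
        sim = make_passive_sim()
        doc = simulation_to_document(sim)
        import json

        doc2 = json.loads(json.dumps(doc))
        sim2 = simulation_from_document(doc2)
        assert sim2.duration.si == sim.duration.si
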