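import matplotlib
import pytest

matplotlib.use("Agg", force=True)

from cablekit.channels import LeakChannel, hh_potassium, hh_sodium, make_leak
from cablekit.model import Simulation
from cablekit.morphology import build_soma_from_area


# Canonical passive test cell: 1000 um2, 1 uF/cm2, 0.3 mS/cm2 leak at -51 mV
# => G = 3 nS = 0.003 uS, C = 10 pF = 0.01 nF, tau = 10/3 ms.
PASSIVE = dict(E_mV=-51.0, G_uS=0.003, C_nF=0.01)


def make_passive_sim(duration="100 ms", dt="0.025 ms", amp="100 pA",
                     delay="0 ms", stim_duration=None):
    sim = Simulation("passive", duration=duration, dt=dt)
    cell = sim.create_cell("cell1", build_soma_from_area("1000 um2"))
    cell.apply_channel(LeakChannel("lk", "0.3 mS/cm2", "-51 mV"))
    sim.create_currentclamp(cell, amp=amp, delay=delay,
                            duration=stim_duration)
    sim.record(cell, "Voltage")
    return sim


def make_hh_sim(amp="200 pA", delay="10 ms", stim_duration="100 ms",
                duration="120 ms", dt="0.025 ms"):
    sim = Simulation("hh", duration=duration, dt=dt)
    cell = sim.create_cell("cell1", build_soma_from_area("1000 um2"),
                           initial_voltage="-65 mV")
    cell.apply_channel(make_leak())
    cell.apply_channel(hh_sodium())
    cell.apply_channel(hh_potassium())
    sim.create_currentclamp(cell, amp=amp, delay=delay,
                            duration=stim_duration)
    sim.record(cell, "Voltage")
    return sim


@pytest.fixture
def passive_sim():
    return make_passive_sim()


@pytest.fixture
def hh_sim():
    return make_hh_sim()
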