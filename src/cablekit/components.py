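"""Standard component libraries and builder functions.

Libraries start empty on construction; :func:`standard_libraries` returns a
fresh set of the four registries (morphology, channel, psr, cell) with the
stock builders registered. Keyword arguments given to
``ComponentLibrary.instantiate`` are forwarded to the builder, so variants
(e.g. a cell without sodium channels, mimicking TTX application) need no
copy-and-paste.
"""

from __future__ import annotations

from .channels import hh_potassium, hh_sodium, make_leak
from .model import Cell, ComponentLibrary, SynapseTemplate
from .morphology import build_soma_from_area

__all__ = ["standard_libraries", "build_hh_soma_cell"]


def build_hh_soma_cell(
    name: str = "cell",
    area="1000 um2",
    include_sodium: bool = True,
    include_potassium: bool = True,
    leak_gbar="0.3 mS/cm2",
    leak_erev="-54.3 mV",
    initial_voltage="-65 mV",
) -> Cell:
    """Single-compartment squid-axon cell; channels are switchable."""
    cell = Cell(name, build_soma_from_area(area),
                initial_voltage=initial_voltage)
    cell.apply_channel(make_leak(gbar=leak_gbar, erev=leak_erev))
    if include_sodium:
        cell.apply_channel(hh_sodium())
    if include_potassium:
        cell.apply_channel(hh_potassium())
    return cell


def build_passive_soma_cell(
    name: str = "cell", area="1000 um2", gbar="0.3 mS/cm2", erev="-51 mV",
    capacitance="1.0 uF/cm2",
) -> Cell:
    from .channels import LeakChannel

    cell = Cell(name, build_soma_from_area(area), capacitance=capacitance)
    cell.apply_channel(LeakChannel("lk", gbar, erev))
    return cell


def standard_libraries() -> dict[str, ComponentLibrary]:
    """Fresh registries with the stock builders registered."""
    morphology = ComponentLibrary("morphology")
    morphology.register("std", "soma", build_soma_from_area)

    channel = ComponentLibrary("channel")
    channel.register("std", "leak", make_leak)
    channel.register("hh", "na", hh_sodium)
    channel.register("hh", "k", hh_potassium)

    psr = ComponentLibrary("psr")
    psr.register("std", "exp2syn", SynapseTemplate.build)

    cell = ComponentLibrary("cell")
    cell.register("hh", "soma_cell", build_hh_soma_cell)
    cell.register("std", "passive_soma", build_passive_soma_cell)

    return {
        "morphology": morphology,
        "channel": channel,
        "psr": psr,
        "cell": cell,
    }
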