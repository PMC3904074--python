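import random

import pytest

from cablekit.channels import LeakChannel, hh_potassium
from cablekit.distribution import (
    Applicator,
    ChannelApplication,
    Targeter,
    distribution_table,
    resolve_distribution,
)
from cablekit.errors import AmbiguityError, DomainError
from cablekit.morphology import Morphology


def soma_dendrite_morphology():
    m = Morphology("cell")
    m.add_section("soma", (0, 0, 0), (20, 0, 0), 10, 10, "soma")
    m.add_section("d1", (20, 0, 0), (120, 0, 0), 2, 2, "dendrites",
                  parent="soma")
    m.add_section("d2", (120, 0, 0), (220, 0, 0), 1, 1, "dendrites",
                  parent="d1")
    m.add_section("ax", (0, 0, 0), (-300, 0, 0), 1, 1, "axon", parent="soma")
    return m


class TestResolveDistribution:
    def test_everywhere_defaults(self):
        m = soma_dendrite_morphology()
        k = hh_potassium()
        apps = [ChannelApplication(k, Applicator(), Targeter.everywhere())]
        resolved = resolve_distribution(apps, m)
        assert set(resolved) == {(s.id, "hh_k") for s in m}
        for params in resolved.values():
            assert params["gbar"].magnitude_in("mS/cm2") == 36.0

    def test_region_multiplier_doubles_dendritic_gbar(self):
        """Uniform K everywhere plus 2x multiplier on the dendrites."""
        m = soma_dendrite_morphology()
        k = hh_potassium()
        apps = [
            ChannelApplication(k, Applicator(), Targeter.everywhere()),
            ChannelApplication(k, Applicator(multipliers={"gbar": 2.0}),
                               Targeter.region("dendrites")),
        ]
        resolved = resolve_distribution(apps, m)
        g0 = k.get_defaults()["gbar"].magnitude_in("mS/cm2")
        assert resolved[("soma", "hh_k")]["gbar"].magnitude_in(
            "mS/cm2") == pytest.approx(g0)
        assert resolved[("ax", "hh_k")]["gbar"].magnitude_in(
            "mS/cm2") == pytest.approx(g0)
        for sid in ("d1", "d2"):
            assert resolved[(sid, "hh_k")]["gbar"].magnitude_in(
                "mS/cm2") == pytest.approx(2 * g0)

    def test_region_override_beats_everywhere_override(self):
        """30 mS/cm2 everywhere except 50 mS/cm2 in the apical dendrites."""
        m = Morphology("cell")
        m.add_section("soma", (0, 0, 0), (20, 0, 0), 10, 10, "soma")
        m.add_section("ap", (20, 0, 0), (120, 0, 0), 2, 2, "apicaldendrite",
                      parent="soma")
        k = hh_potassium()
        apps = [
            ChannelApplication(k, Applicator(overrides={"gbar": "30 mS/cm2"}),
                               Targeter.everywhere()),
            ChannelApplication(k, Applicator(overrides={"gbar": "50 mS/cm2"}),
                               Targeter.region("apicaldendrite")),
        ]
        resolved = resolve_distribution(apps, m)
        assert resolved[("soma", "hh_k")]["gbar"].magnitude_in(
            "mS/cm2") == pytest.approx(30.0)
        assert resolved[("ap", "hh_k")]["gbar"].magnitude_in(
            "mS/cm2") == pytest.approx(50.0)

    def test_equal_priority_is_ambiguity_error(self):
        m = soma_dendrite_morphology()
        k = hh_potassium()
        apps = [
            ChannelApplication(k, Applicator(multipliers={"gbar": 2.0}),
                               Targeter.region("dendrites")),
            ChannelApplication(k, Applicator(), Targeter.region("dendrites")),
        ]
        with pytest.raises(AmbiguityError, match="dendrites"):
            resolve_distribution(apps, m)

    def test_unknown_region_is_key_error(self):
        m = soma_dendrite_morphology()
        apps = [ChannelApplication(hh_potassium(), Applicator(),
                                   Targeter.region("basal"))]
        with pytest.raises(KeyError, match="basal"):
            resolve_distribution(apps, m)

    def test_section_targeter_outranks_region(self):
        m = soma_dendrite_morphology()
        k = hh_potassium()
        apps = [
            ChannelApplication(k, Applicator(), Targeter.everywhere()),
            ChannelApplication(k, Applicator(multipliers={"gbar": 2.0}),
                               Targeter.region("dendrites")),
            ChannelApplication(k, Applicator(overrides={"gbar": "5 mS/cm2"}),
                               Targeter.section("d2")),
        ]
        resolved = resolve_distribution(apps, m)
        assert resolved[("d2", "hh_k")]["gbar"].magnitude_in(
            "mS/cm2") == pytest.approx(5.0)
        assert resolved[("d1", "hh_k")]["gbar"].magnitude_in(
            "mS/cm2") == pytest.approx(72.0)

    def test_unmatched_sections_carry_no_channel(self):
        m = soma_dendrite_morphology()
        apps = [ChannelApplication(hh_potassium(), Applicator(),
                                   Targeter.region("axon"))]
        resolved = resolve_distribution(apps, m)
        assert set(resolved) == {("ax", "hh_k")}


class TestApplicator:
    def test_override_and_multiplier_conflict_rejected(self):
        with pytest.raises(DomainError):
            Applicator(overrides={"gbar": "1 mS/cm2"},
                       multipliers={"gbar": 2.0})

    def test_unknown_parameter_rejected(self):
        with pytest.raises(DomainError, match="frobnicate"):
            ChannelApplication(hh_potassium(),
                               Applicator(overrides={"frobnicate": "1 mV"}))

    def test_bare_number_override_uses_default_unit(self):
        chl = LeakChannel("lk", "0.3 mS/cm2", "-51 mV")
        app = ChannelApplication(chl, Applicator(overrides={"gbar": 0.5}))
        assert app.resolved_params()["gbar"].magnitude_in(
            "mS/cm2") == pytest.approx(0.5)

    def test_multiplier_applies_after_override(self):
        chl = LeakChannel("lk", "0.3 mS/cm2", "-51 mV")
        app = ChannelApplication(
            chl, Applicator(overrides={"erev": "-60 mV"},
                            multipliers={"gbar": 3.0}))
        params = app.resolved_params()
        assert params["gbar"].magnitude_in("mS/cm2") == pytest.approx(0.9)
        assert params["erev"].magnitude_in("mV") == pytest.approx(-60.0)


class TestProperties:
    def _random_apps(self, rng, channel):
        """Random unambiguous application sets (unique priorities)."""
        targeters = [
            Targeter.everywhere(priority=1),
            Targeter.region("dendrites", priority=2),
            Targeter.region("axon", priority=3),
            Targeter.section("d1", priority=4),
            Targeter.section("soma", priority=5),
        ]
        chosen = rng.sample(targeters, rng.randint(1, len(targeters)))
        apps = []
        for t in chosen:
            if rng.random() < 0.5:
                app = Applicator(multipliers={"gbar": rng.choice([0.5, 2, 3])})
            else:
                app = Applicator(
                    overrides={"gbar": f"{rng.choice([10, 20, 30])} mS/cm2"})
            apps.append(ChannelApplication(channel, app, t))
        return apps

    def test_order_independence(self):
        m = soma_dendrite_morphology()
        k = hh_potassium()
        rng = random.Random(42)
        for _ in range(50):
            apps = self._random_apps(rng, k)
            base = resolve_distribution(apps, m)
            for _ in range(5):
                shuffled = apps[:]
                rng.shuffle(shuffled)
                other = resolve_distribution(shuffled, m)
                assert set(base) == set(other)
                for key in base:
                    for p in base[key]:
                        assert base[key][p].si == other[key][p].si

    def test_lower_priority_never_shadows_higher(self):
        m = soma_dendrite_morphology()
        k = hh_potassium()
        high = ChannelApplication(
            k, Applicator(overrides={"gbar": "50 mS/cm2"}),
            Targeter.region("dendrites"))
        before = resolve_distribution([high], m)
        low = ChannelApplication(k, Applicator(multipliers={"gbar": 9.0}),
                                 Targeter.everywhere())
        after = resolve_distribution([high, low], m)
        for key in before:  # claimed sections unchanged
            assert after[key]["gbar"].si == before[key]["gbar"].si

    def test_resolved_params_dimensionally_valid(self):
        m = soma_dendrite_morphology()
        k = hh_potassium()
        apps = [ChannelApplication(k, Applicator(multipliers={"gbar": 2.0}),
                                   Targeter.everywhere())]
        for params in resolve_distribution(apps, m).values():
            defaults = k.get_defaults()
            for name, q in params.items():
                assert q.dimensions == defaults[name].dimensions


def test_distribution_table_rows():
    m = soma_dendrite_morphology()
    k = hh_potassium()
    apps = [ChannelApplication(k, Applicator(), Targeter.everywhere())]
    rows = distribution_table(resolve_distribution(apps, m), m)
    assert len(rows) == len(m) * len(k.get_variables())
    assert rows[0][0] == "soma"
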