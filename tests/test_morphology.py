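import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cablekit.errors import DimensionError, DomainError, MorphologyError
from cablekit.morphology import (
    Morphology,
    MorphLocation,
    build_soma_from_area,
    frustum_lateral_area,
    read_swc,
    resolve_location,
    surface_area,
    write_swc,
)
from cablekit.units import parse_quantity


class TestBuildSoma:
    def test_1000um2_cylinder_dimensions(self):
        m = build_soma_from_area("1000 um2")
        sec = m.root
        d = math.sqrt(1000.0 / math.pi)
        assert sec.length == pytest.approx(d)
        assert 2 * sec.proximal_radius == pytest.approx(d)
        assert d == pytest.approx(17.8412, abs=1e-4)

    def test_pi_um2_unit_case(self):
        m = build_soma_from_area(math.pi)
        assert m.root.length == pytest.approx(1.0)
        assert 2 * m.root.proximal_radius == pytest.approx(1.0)

    def test_area_round_trip(self):
        m = build_soma_from_area("1000 um2")
        assert surface_area(m).magnitude_in("um2") == pytest.approx(
            1000.0, rel=1e-9)

    def test_non_area_dimensions_rejected(self):
        with pytest.raises(DimensionError):
            build_soma_from_area(parse_quantity("10 mV"))

    def test_negative_area_rejected(self):
        with pytest.raises(DomainError):
            build_soma_from_area(-5.0)


class TestSurfaceArea:
    def test_frustum(self):
        m = Morphology("t")
        m.add_section("a", (0, 0, 0), (10, 0, 0), 2.0, 4.0, "soma")
        expected = math.pi * 6 * math.sqrt(104)  # 192.22 um2
        assert surface_area(m).magnitude == pytest.approx(expected)
        assert expected == pytest.approx(192.22, abs=0.01)

    def test_unit_cylinder(self):
        m = Morphology("t")
        m.add_section("a", (0, 0, 0), (1, 0, 0), 1.0, 1.0, "soma")
        assert surface_area(m).magnitude == pytest.approx(2 * math.pi)

    def test_unknown_region_is_key_error(self):
        m = build_soma_from_area(1000)
        with pytest.raises(KeyError):
            surface_area(m, region_filter="axon")

    def test_region_filter(self):
        m = Morphology("t")
        m.add_section("a", (0, 0, 0), (1, 0, 0), 1.0, 1.0, "soma")
        m.add_section("b", (1, 0, 0), (2, 0, 0), 1.0, 1.0, "dendrite",
                      parent="a")
        assert surface_area(m, "dendrite").magnitude == pytest.approx(
            2 * math.pi)


class TestSectionInvariants:
    def test_nonpositive_radius_rejected(self):
        m = Morphology("t")
        with pytest.raises(MorphologyError):
            m.add_section("a", (0, 0, 0), (1, 0, 0), 0.0, 1.0, "soma")

    def test_zero_length_rejected(self):
        m = Morphology("t")
        with pytest.raises(MorphologyError):
            m.add_section("a", (0, 0, 0), (0, 0, 0), 1.0, 1.0, "soma")

    def test_duplicate_id_rejected(self):
        m = Morphology("t")
        m.add_section("a", (0, 0, 0), (1, 0, 0), 1.0, 1.0, "soma")
        with pytest.raises(MorphologyError):
            m.add_section("a", (1, 0, 0), (2, 0, 0), 1.0, 1.0, "soma",
                          parent="a")

    def test_second_root_rejected(self):
        m = Morphology("t")
        m.add_section("a", (0, 0, 0), (1, 0, 0), 1.0, 1.0, "soma")
        with pytest.raises(MorphologyError):
            m.add_section("b", (5, 0, 0), (6, 0, 0), 1.0, 1.0, "soma")

    def test_traversal_visits_each_section_once(self):
        m = Morphology("t")
        m.add_section("a", (0, 0, 0), (10, 0, 0), 1.0, 1.0, "soma")
        m.add_section("b", (10, 0, 0), (20, 0, 0), 1.0, 1.0, "dendrite",
                      parent="a")
        m.add_section("c", (10, 0, 0), (10, 10, 0), 1.0, 1.0, "dendrite",
                      parent="a")
        ids = [s.id for s in m]
        assert sorted(ids) == ["a", "b", "c"]
        assert len(ids) == len(set(ids))


class TestSWC:
    def _write(self, tmp_path, text):
        p = tmp_path / "cell.swc"
        p.write_text(text)
        return p

    def test_three_point_type_change(self, tmp_path):
        p = self._write(tmp_path, """
# comment
1 1 0 0 0 5 -1
2 3 10 0 0 2 1
3 3 20 0 0 1 2
""".strip())
        m = read_swc(p)
        assert len(m) == 2
        regions = [s.region for s in m]
        assert regions == ["soma", "dendrite"]
        # soma sample becomes a sphere-equivalent cylinder, L = d = 2r
        soma = m.root
        assert soma.spherical
        assert soma.length == pytest.approx(10.0)

    def test_single_sample_sphere(self, tmp_path):
        p = self._write(tmp_path, "1 1 0 0 0 7.5 -1")
        m = read_swc(p)
        assert len(m) == 1
        sec = m.root
        assert sec.length == pytest.approx(15.0)
        assert sec.proximal_radius == pytest.approx(7.5)
        # area equals that of a sphere of the same radius
        assert sec.lateral_area == pytest.approx(4 * math.pi * 7.5**2)

    def test_missing_parent_is_format_error(self, tmp_path):
        p = self._write(tmp_path, "1 1 0 0 0 5 -1\n2 3 1 0 0 1 99")
        with pytest.raises(MorphologyError, match=":2"):
            read_swc(p)

    def test_multiple_roots_rejected(self, tmp_path):
        p = self._write(tmp_path, "1 1 0 0 0 5 -1\n2 1 9 0 0 5 -1")
        with pytest.raises(MorphologyError, match="one root"):
            read_swc(p)

    def test_nonpositive_radius_rejected(self, tmp_path):
        p = self._write(tmp_path, "1 1 0 0 0 0 -1")
        with pytest.raises(MorphologyError, match=":1"):
            read_swc(p)

    def test_wrong_column_count(self, tmp_path):
        p = self._write(tmp_path, "1 1 0 0 0 5")
        with pytest.raises(MorphologyError, match="7 columns"):
            read_swc(p)

    def test_same_type_chain_keeps_geometry(self, tmp_path):
        p = self._write(tmp_path, """
1 3 0 0 0 2 -1
2 3 10 0 0 2 1
3 3 20 5 0 1 2
""".strip())
        m = read_swc(p)
        assert len(m) == 2
        assert np.allclose(m.sections[0].proximal, [0, 0, 0])
        assert np.allclose(m.sections[1].distal, [20, 5, 0])

    def test_write_read_round_trip(self, tmp_path):
        p = self._write(tmp_path, """
1 1 0 0 0 5 -1
2 3 10 0 0 2 1
3 3 20 0 0 1 2
4 3 20 10 0 1 3
5 2 -5 0 0 1 1
""".strip())
        m1 = read_swc(p)
        out = tmp_path / "rt.swc"
        write_swc(m1, out)
        m2 = read_swc(out)
        assert len(m1) == len(m2)
        for a, b in zip(m1, m2):
            assert a.region == b.region
            assert np.allclose(a.proximal, b.proximal, atol=1e-6)
            assert np.allclose(a.distal, b.distal, atol=1e-6)
            assert a.proximal_radius == pytest.approx(b.proximal_radius,
                                                      abs=1e-6)
            assert a.distal_radius == pytest.approx(b.distal_radius, abs=1e-6)
            assert (a.parent is None) == (b.parent is None)

    def test_branched_dendrites_attach_to_soma(self, tmp_path):
        p = self._write(tmp_path, """
1 1 0 0 0 5 -1
2 3 10 0 0 2 1
3 3 20 0 0 1 2
4 3 10 10 0 2 1
5 3 10 20 0 1 4
""".strip())
        m = read_swc(p)
        root = m.root
        assert root.region == "soma"
        children = m.children_of(root)
        assert len(children) == 2
        assert all(c.region == "dendrite" for c in children)


class TestResolveLocation:
    def _loc(self, frac):
        m = build_soma_from_area(1000)
        return MorphLocation(m.root, frac)

    def test_single_segment(self):
        assert resolve_location(self._loc(0.5), 1) == (0, pytest.approx(0.5))

    def test_middle_of_three(self):
        idx, local = resolve_location(self._loc(0.5), 3)
        assert idx == 1
        assert local == pytest.approx(0.5)

    def test_boundary_folds_into_last(self):
        idx, local = resolve_location(self._loc(1.0), 3)
        assert idx == 2
        assert local == pytest.approx(1.0)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            self._loc(1.5)

    def test_bad_nseg(self):
        with pytest.raises(DomainError):
            resolve_location(self._loc(0.5), 0)


@given(
    r1=st.floats(min_value=0.1, max_value=10),
    r2=st.floats(min_value=0.1, max_value=10),
    length=st.floats(min_value=0.5, max_value=100),
    split=st.floats(min_value=0.05, max_value=0.95),
)
@settings(max_examples=200, deadline=None)
def test_area_additive_under_subdivision(r1, r2, length, split):
    """Splitting a frustum at any interior point conserves lateral area."""
    whole = frustum_lateral_area(r1, r2, length)
    rm = r1 + split * (r2 - r1)
    part1 = frustum_lateral_area(r1, rm, split * length)
    part2 = frustum_lateral_area(rm, r2, (1 - split) * length)
    assert part1 + part2 == pytest.approx(whole, rel=1e-9)
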