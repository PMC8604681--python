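import dataclasses
import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aromstack import (
    beta_angle,
    central_plane,
    dihedral_alpha,
    extract_rings,
    fit_plane,
    pair_geometry,
    read_structure,
    shift_d,
    template_phe,
)
from aromstack.reference_enumeration import _ry, place_pair, random_rotations
from aromstack.ring_geometry import transform_ring
from aromstack.synthetic_fixtures import expected_pair_alpha

from conftest import make_ring


def hexagon(radius=1.39):
    ang = np.radians(60.0 * np.arange(6))
    return radius * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])


class TestFitPlane:
    def test_ideal_hexagon(self):
        center, normal = fit_plane(hexagon())
        np.testing.assert_allclose(center, 0.0, atol=1e-12)
        assert abs(abs(normal[2]) - 1.0) < 1e-12

    def test_three_symmetric_points(self):
        center, normal = fit_plane(np.eye(3))
        expected = np.ones(3) / math.sqrt(3)
        assert min(np.linalg.norm(normal - expected), np.linalg.norm(normal + expected)) < 1e-12

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError):
            fit_plane(pts)

    def test_noise_robustness(self):
        # out-of-plane noise sigma = 0.01 Å: fitted normal within 1 degree
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = hexagon()
            pts[:, 2] += rng.normal(scale=0.01, size=6)
            _, normal = fit_plane(pts)
            ang = math.degrees(math.acos(min(1.0, abs(normal[2]))))
            assert ang < 1.0


class TestExtractRings:
    def test_single_phe_centroid(self):
        ring = make_ring()
        coords = np.array(list(ring.ring_atoms.values()))
        np.testing.assert_allclose(ring.center, coords.mean(axis=0), atol=1e-12)

    def test_missing_atom_skips_with_warning(self, caplog):
        from aromstack.synthetic_fixtures import PairSpec, make_pair_structure

        text = make_pair_structure(PairSpec(alpha0=30, h=3))
        st = read_structure(text)
        # remove CZ from the first Phe
        del st.chains[0].residues[0].atoms["CZ"]
        with caplog.at_level(logging.WARNING, logger="aromstack.ring_geometry"):
            rings = extract_rings(st)
        assert len(rings) == 1
        assert any("CZ" in rec.message for rec in caplog.records)

    def test_template_normal_and_guide(self):
        t = template_phe()
        assert abs(abs(t.normal[2]) - 1.0) < 1e-12
        np.testing.assert_allclose(t.guide, [1, 0, 0], atol=1e-12)  # center -> CG


class TestDihedralAlpha:
    def test_coplanar_parallel_rings(self):
        r1 = make_ring()
        r2 = make_ring(t=(4.0, 1.0, 0.0), seq_index=5)
        assert dihedral_alpha(r1, r2) == pytest.approx(0.0, abs=1e-9)

    def test_acute_to_obtuse_switch_at_50_degrees(self):
        h = 2.0
        boundary = -h / math.tan(math.radians(50.0))
        r1, r2 = place_pair(_ry(math.radians(50.0)), [boundary + 1.0, 0.0, h])
        assert dihedral_alpha(r1, r2) == pytest.approx(50.0, abs=1e-9)
        r1, r2 = place_pair(_ry(math.radians(50.0)), [boundary - 1.0, 0.0, h])
        assert dihedral_alpha(r1, r2) == pytest.approx(130.0, abs=1e-9)

    def test_closed_form_rule_over_construction_grid(self):
        for a0 in range(10, 90, 10):
            cot = 1.0 / math.tan(math.radians(a0))
            for h in (0.5, 1.0, 2.0, 4.0):
                for dx in np.arange(-10.0, 10.01, 0.5):
                    if abs(dx + h * cot) < 1e-3:  # switching boundary
                        continue
                    for dy in (0.0, 3.0):
                        r1, r2 = place_pair(_ry(math.radians(a0)), [dx, dy, h])
                        assert dihedral_alpha(r1, r2) == pytest.approx(
                            expected_pair_alpha(a0, h, dx), abs=1e-6
                        )

    def test_alpha_is_theta_or_its_supplement(self, rng):
        for _ in range(300):
            R = random_rotations(1, rng).matrices[0]
            v = rng.uniform(-6, 6, size=3)
            r1, r2 = place_pair(R, v)
            theta = math.degrees(math.acos(min(1.0, abs(float(r1.normal @ r2.normal)))))
            alpha = dihedral_alpha(r1, r2)
            assert min(abs(alpha - theta), abs(alpha - (180.0 - theta))) < 1e-8

    def test_sine_law_limits_under_uniform_rotation(self):
        # plane angle theta has density sin(theta) on [0, 90]
        mats = random_rotations(1_000_000, 7).matrices
        theta = np.degrees(np.arccos(np.clip(np.abs(mats[:, 2, 2]), 0, 1)))
        p_parallel = float((theta < 15.0).mean())
        p_perp = float((theta >= 75.0).mean())
        assert p_parallel == pytest.approx(1 - math.cos(math.radians(15)), abs=1e-3)
        assert p_perp == pytest.approx(math.cos(math.radians(75)), abs=2e-3)


class TestCentralPlane:
    def test_parallel_rings_midplane(self):
        r1 = make_ring()
        r2 = make_ring(t=(0, 0, 4.0), seq_index=5)
        point, normal = central_plane(r1, r2)
        assert point[2] == pytest.approx(2.0)
        assert abs(abs(normal[2]) - 1.0) < 1e-12

    def test_perpendicular_construction(self):
        # ring 2 in the x = 5 plane, center (5, 0, 2): the central plane must
        # contain the line {x = 5, z = 0} and the midpoint (2.5, 0, 1)
        r1 = make_ring()
        r2 = make_ring(R=_ry(math.radians(90.0)), t=(5.0, 0.0, 2.0), seq_index=5)
        point, normal = central_plane(r1, r2)
        for probe in ([5.0, 0.0, 0.0], [5.0, 3.0, 0.0], [2.5, 0.0, 1.0]):
            assert abs(float((np.array(probe) - point) @ normal)) < 1e-9

    def test_swap_gives_same_plane(self):
        r1 = make_ring(R=_ry(0.3), t=(0.5, 0.2, 1.0))
        r2 = make_ring(R=_ry(1.1), t=(2.0, -1.0, 3.0), seq_index=5)
        p12, n12 = central_plane(r1, r2)
        p21, n21 = central_plane(r2, r1)
        assert abs(float((p21 - p12) @ n12)) < 1e-9
        assert abs(abs(float(n12 @ n21)) - 1.0) < 1e-9


class TestBetaAndShift:
    def test_beta_cis_trans(self):
        r1 = make_ring()
        r2 = make_ring(t=(0, 0, 2.0), seq_index=5)
        assert beta_angle(r1, r2) == pytest.approx(0.0, abs=1e-9)  # both guides +x
        r2_trans = dataclasses.replace(r2, guide=np.array([-1.0, 0.0, 0.0]))
        assert beta_angle(r1, r2_trans) == pytest.approx(180.0, abs=1e-9)

    def test_beta_in_plane_angle_preserved(self):
        r1 = make_ring()
        g = np.array([math.cos(math.radians(40)), math.sin(math.radians(40)), 0.0])
        r2 = dataclasses.replace(make_ring(t=(0, 0, 2.0), seq_index=5), guide=g)
        assert beta_angle(r1, r2) == pytest.approx(40.0, abs=1e-9)

    def test_shift_parallel_offset(self):
        r1 = make_ring()
        r2 = make_ring(t=(3.0, 0.0, 4.0), seq_index=5)
        assert shift_d(r1, r2) == pytest.approx(3.0, abs=1e-9)

    def test_shift_stacked_is_zero(self):
        r1 = make_ring()
        r2 = make_ring(t=(0.0, 0.0, 3.4), seq_index=5)
        assert shift_d(r1, r2) == pytest.approx(0.0, abs=1e-9)

    def test_shift_never_exceeds_center_distance(self, rng):
        for _ in range(1000):
            R = random_rotations(1, rng).matrices[0]
            v = rng.uniform(-6, 6, size=3)
            r1, r2 = place_pair(R, v)
            assert shift_d(r1, r2) <= np.linalg.norm(v) + 1e-6


class TestPairGeometry:
    def test_parameter_recovery(self):
        r1, r2 = place_pair(_ry(math.radians(60.0)), [1.0, 0.0, 3.0])
        g = pair_geometry(r1, r2)
        assert g.alpha == pytest.approx(60.0, abs=1e-6)
        assert g.center_distance == pytest.approx(math.sqrt(10.0))

    def test_swap_and_rigid_motion_invariance(self, rng):
        for _ in range(1000):
            R = random_rotations(1, rng).matrices[0]
            v = rng.uniform(-6, 6, size=3)
            if np.linalg.norm(v) < 0.5:
                continue
            r1, r2 = place_pair(R, v)
            g = pair_geometry(r1, r2)
            gs = pair_geometry(r2, r1)
            Q = random_rotations(1, rng).matrices[0]
            t = rng.uniform(-20, 20, size=3)
            gt = pair_geometry(transform_ring(r1, Q, t), transform_ring(r2, Q, t))
            for other in (gs, gt):
                assert other.alpha == pytest.approx(g.alpha, abs=1e-6)
                assert other.d == pytest.approx(g.d, abs=1e-6)
                assert other.center_distance == pytest.approx(g.center_distance, abs=1e-6)
                if not (math.isnan(g.beta) or math.isnan(other.beta)):
                    assert other.beta == pytest.approx(g.beta, abs=1e-6)

    @given(
        a0=st.floats(5, 175),
        h=st.floats(0.5, 6.0),
        dx=st.floats(-6, 6),
        dy=st.floats(-4, 4),
    )
    @settings(max_examples=100, deadline=None)
    def test_descriptor_ranges(self, a0, h, dx, dy):
        r1, r2 = place_pair(_ry(math.radians(a0)), [dx, dy, h])
        g = pair_geometry(r1, r2)
        assert 0.0 <= g.alpha <= 180.0
        assert g.d >= 0.0
        assert g.d <= g.center_distance + 1e-6
        if not math.isnan(g.beta):
            assert 0.0 <= g.beta <= 180.0
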