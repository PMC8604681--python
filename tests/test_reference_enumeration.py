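import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from aromstack import (
    BallModel,
    bin_fractions,
    dihedral_alpha,
    enumerate_reference,
    overlap_allowed_total,
    overlap_test,
    place_pair,
    random_rotations,
    sift_rotations,
    sphere_points,
    template_phe,
    translation_grid,
)
from aromstack.reference_enumeration import (
    RotationSet,
    _ry,
    euler_rotation_grid,
)


def nn_angles_deg(points):
    d, _ = cKDTree(points).query(points, k=2)
    return np.degrees(2.0 * np.arcsin(np.clip(d[:, 1] / 2.0, 0.0, 1.0)))


class TestSpherePoints:
    def test_fine_spacing_point_count(self):
        # 2.5 degree spacing: on the order of the canonical 6600 points
        assert 5500 <= len(sphere_points(2.5)) <= 7500

    def test_median_spacing_tracks_request(self):
        for spacing in (2.5, 5.0, 10.0):
            nn = nn_angles_deg(sphere_points(spacing))
            assert abs(np.median(nn) - spacing) < 0.15 * spacing

    def test_coarse_limit_covers_axes(self):
        pts = sphere_points(90.0)
        assert len(pts) >= 6
        axes = np.vstack([np.eye(3), -np.eye(3)])
        d, _ = cKDTree(pts).query(axes)
        ang = np.degrees(2.0 * np.arcsin(np.clip(d / 2.0, 0.0, 1.0)))
        assert ang.max() <= 45.0

    def test_points_not_clumped(self):
        nn = nn_angles_deg(sphere_points(10.0))
        assert nn.min() > 0.4 * 10.0


class TestEulerGrid:
    def test_count_formula(self):
        assert sum(1 for _ in euler_rotation_grid(120.0)) == 27
        assert sum(1 for _ in euler_rotation_grid(90.0)) == 64

    def test_axis_aligned_entries(self):
        for m in euler_rotation_grid(90.0):
            assert np.all(np.isin(np.round(m, 12), [-1.0, 0.0, 1.0]))

    def test_all_proper_rotations(self):
        for m in euler_rotation_grid(90.0):
            np.testing.assert_allclose(m @ m.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(m) == pytest.approx(1.0, abs=1e-12)

    def test_step_must_divide_360(self):
        with pytest.raises(ValueError):
            next(euler_rotation_grid(7.0))


class TestSiftRotations:
    def test_octahedral_rotations_all_distinguished(self):
        # the 64 products at 90 deg step collapse onto the 24 proper
        # octahedral rotations, all separable at 45 deg point spacing
        rs = sift_rotations(euler_rotation_grid(90.0), sphere_points(45.0))
        assert 24 <= len(rs) <= 64
        rs.validate()

    def test_identity_survives(self):
        rs = sift_rotations(euler_rotation_grid(90.0), sphere_points(45.0))
        assert any(np.allclose(m, np.eye(3), atol=1e-9) for m in rs.matrices)

    def test_dedup_only_shrinks(self):
        grid = list(euler_rotation_grid(120.0))
        rs = sift_rotations(iter(grid), sphere_points(60.0))
        assert len(rs) <= len(grid)


class TestTranslationGrid:
    def test_strict_boundary_single_vector(self):
        grid = translation_grid(step=7.0, rmax=7.0)
        assert len(grid) == 1
        np.testing.assert_array_equal(grid.vectors[0], [0.0, 0.0, 0.0])

    def test_full_grid_close_to_continuum_volume(self):
        grid = translation_grid(step=0.5, rmax=7.0)
        continuum = 4.0 / 3.0 * math.pi * 14.0**3
        assert abs(len(grid) - continuum) / continuum < 0.01

    def test_lattice_symmetry_and_uniqueness(self):
        grid = translation_grid(step=1.0, rmax=4.0)
        vecs = {tuple(v) for v in grid.vectors}
        assert len(vecs) == len(grid)
        assert all(tuple(-np.array(v)) in vecs for v in vecs)


class TestTemplate:
    def test_ideal_hexagon_geometry(self):
        t = template_phe()
        np.testing.assert_allclose(t.center, 0.0, atol=1e-12)
        np.testing.assert_allclose(t.cgamma, [1.39, 0.0, 0.0], atol=1e-12)
        coords = np.array(list(t.ring_atoms.values()))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        nearest = np.sort(d, axis=1)[:, 1]
        np.testing.assert_allclose(nearest, 1.39, atol=1e-9)

    def test_placed_pair_center_distance_is_shift_length(self, rng):
        for _ in range(20):
            R = random_rotations(1, rng).matrices[0]
            v = rng.uniform(-7, 7, size=3)
            r1, r2 = place_pair(R, v)
            assert np.linalg.norm(r2.center - r1.center) == pytest.approx(
                np.linalg.norm(v), abs=1e-9
            )

    def test_pure_stack(self):
        r1, r2 = place_pair(np.eye(3), [0.0, 0.0, 3.4])
        assert dihedral_alpha(r1, r2) == pytest.approx(0.0, abs=1e-9)

    def test_tilted_placement_recovers_angle(self):
        r1, r2 = place_pair(_ry(math.radians(60.0)), [2.0, 0.0, 2.0])
        assert dihedral_alpha(r1, r2) == pytest.approx(60.0, abs=1e-9)


class TestOverlap:
    def test_close_stack_clashes(self):
        assert overlap_test(place_pair(np.eye(3), [0.0, 0.0, 1.0])) is True

    def test_distant_stack_is_clear(self):
        # ring-ring 6.9 Å > 3.5; the backbone balls sit at z separation 6.9 > 6
        assert overlap_test(place_pair(np.eye(3), [0.0, 0.0, 6.9])) is False

    def test_touching_spheres_do_not_overlap(self):
        # backbone balls exactly at the 6 Å radius sum: the strict rule keeps
        # the conformation (all other ball pairs are clear at this offset)
        assert overlap_test(place_pair(np.eye(3), [0.0, 0.0, 6.0])) is False

    def test_stacked_pair_backbone_clash(self):
        # face-to-face rings at 3.5 Å just clear each other, but the aligned
        # stems put ring 2's backbone ball 4.61 Å from ring 1's C-beta (< 4.75)
        assert overlap_test(place_pair(np.eye(3), [0.0, 0.0, 3.5])) is True


class TestEnumeration:
    def test_identity_only_rotation_set_is_all_parallel(self):
        rs = RotationSet(matrices=np.eye(3)[None])
        grid = translation_grid(step=2.0, rmax=7.0)
        hist = enumerate_reference(rs, grid)
        fr = bin_fractions(hist)
        assert fr["parallel"] == 1.0
        assert hist.total == len(grid)

    def test_filtering_is_monotone_per_bin(self):
        rs = random_rotations(50, 11)
        grid = translation_grid(step=2.0, rmax=7.0)
        h_all = enumerate_reference(rs, grid, filter_overlap=False)
        h_keep = enumerate_reference(rs, grid, filter_overlap=True)
        assert h_keep.total <= h_all.total
        for label, count in h_keep.class_counts.items():
            assert count <= h_all.class_counts[label]

    def test_fractions_sum_to_one(self):
        rs = random_rotations(20, 5)
        grid = translation_grid(step=2.5, rmax=7.0)
        fr = bin_fractions(enumerate_reference(rs, grid))
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)

    def test_parallel_fraction_is_translation_independent(self):
        # parallel membership depends only on the plane angle, so the fraction
        # over matrices alone equals the fraction over all conformations
        rs = random_rotations(200, 3)
        theta = np.degrees(np.arccos(np.clip(np.abs(rs.matrices[:, 2, 2]), 0, 1)))
        from_matrices = float((theta < 15.0).mean())
        grid = translation_grid(step=2.0, rmax=7.0)
        fr = bin_fractions(enumerate_reference(rs, grid))
        assert fr["parallel"] == pytest.approx(from_matrices, abs=1e-12)

    def test_overlap_allowed_total_shortcut(self):
        grid = translation_grid(step=2.0, rmax=7.0)
        rs = random_rotations(7, 1)
        hist = enumerate_reference(rs, grid)
        assert overlap_allowed_total(len(rs), grid) == hist.total

    def test_beta_d_histograms_accumulate(self):
        rs = random_rotations(10, 9)
        grid = translation_grid(step=2.5, rmax=7.0)
        hist = enumerate_reference(rs, grid, collect_beta_d=True)
        assert hist.beta_counts is not None and hist.d_counts is not None
        assert hist.beta_counts.sum() <= hist.total  # undefined betas excluded
        assert hist.d_counts.sum() == hist.total

    def test_empty_rotation_set_rejected(self):
        grid = translation_grid(step=2.0, rmax=7.0)
        with pytest.raises(ValueError):
            enumerate_reference(
                RotationSet(matrices=np.empty((0, 3, 3))), grid
            )
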