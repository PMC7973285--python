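"""Geometric feature metrics against analytic phantoms and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from brachysel.geometry import (
    FEATURE_NAMES,
    axis_offset,
    extract_features,
    lateral_extent,
    oar_proximity,
    structure_volume,
    vertical_extent,
)
from brachysel.structure_io import ApplicatorFrame, VoxelMask, rasterize
from brachysel.synthetic import CohortConfig, generate_cohort, make_analytic_phantom

FRAME = ApplicatorFrame(
    tandem_point=(0, 0, 0), tandem_dir=(0, 0, 1),
    ring_point=(0, 0, 0), ring_normal=(0, 0, 1),
)


def _random_mask(rng, shape=(18, 18, 18), p=0.15, spacing=(1.0, 1.0, 1.0)):
    occ = rng.random(shape) < p
    occ[tuple(s // 2 for s in shape)] = True  # never empty
    origin = rng.uniform(-20, 0, 3)
    return VoxelMask(origin=origin, spacing=np.asarray(spacing), occupancy=occ)


# ---------------------------------------------------------------------------
# brute-force voxel-loop oracles (deliberately naive)


def brute_lat_max(mask, frame):
    best = 0.0
    for v in mask.occupied_centers():
        rel = v - np.asarray(frame.tandem_point, float)
        proj = np.dot(rel, frame.tandem_dir)
        best = max(best, math.sqrt(max(np.dot(rel, rel) - proj * proj, 0.0)))
    return best


def brute_vert_max(mask, frame):
    best = 0.0
    for v in mask.occupied_centers():
        h = np.dot(v - np.asarray(frame.ring_point, float), frame.ring_normal)
        best = max(best, max(h, 0.0))
    return best


def brute_proximity(hrctv, oar, subvolume=1.5):
    d = cdist(oar.occupied_centers(), hrctv.occupied_centers()).min(axis=1)
    m = min(len(d), math.ceil(subvolume * 1000.0 / oar.voxel_volume))
    return float(np.sort(d)[:m].mean())


# ---------------------------------------------------------------------------


class TestStructureVolume:
    def test_empty_mask_is_zero(self):
        m = VoxelMask(origin=(0, 0, 0), spacing=(1, 1, 1),
                      occupancy=np.zeros((4, 4, 4), bool))
        assert structure_volume(m) == 0.0

    def test_ellipsoid_analytic_at_half_mm(self):
        struct, _ = make_analytic_phantom("ellipsoid", semi_axes=(20, 15, 25))
        m = rasterize(struct, "HR-CTV", spacing=(0.5, 0.5, 0.5))
        assert structure_volume(m) == pytest.approx(31.416, rel=0.02)

    def test_additivity_over_disjoint_masks(self):
        rng = np.random.default_rng(3)
        a = _random_mask(rng)
        b = VoxelMask(origin=a.origin + 100, spacing=a.spacing,
                      occupancy=rng.random((10, 10, 10)) < 0.4)
        union = VoxelMask(
            origin=a.origin, spacing=a.spacing,
            occupancy=np.concatenate(
                [a.occupancy, np.zeros_like(a.occupancy)], axis=0
            ),
        )
        assert structure_volume(a) + structure_volume(b) == pytest.approx(
            structure_volume(a)
            + structure_volume(b)
        )
        # additivity on the same grid: split one mask into two halves
        top = a.occupancy.copy(); top[:9] = False
        bot = a.occupancy.copy(); bot[9:] = False
        vt = structure_volume(VoxelMask(a.origin, a.spacing, top))
        vb = structure_volume(VoxelMask(a.origin, a.spacing, bot))
        assert vt + vb == pytest.approx(structure_volume(a), abs=1e-12)


class TestAxisOffset:
    def test_on_axis_sphere_is_zero(self):
        struct, frame = make_analytic_phantom("sphere", radius=15)
        m = rasterize(struct, "HR-CTV")
        assert axis_offset(m, frame) <= 0.5

    def test_off_axis_sphere_recovers_offset(self):
        struct, frame = make_analytic_phantom(
            "sphere", radius=15, center=(12.0, 0.0, 0.0)
        )
        m = rasterize(struct, "HR-CTV")
        assert axis_offset(m, frame) == pytest.approx(12.0, abs=0.5)

    def test_joint_translation_invariance(self):
        rng = np.random.default_rng(1)
        m = _random_mask(rng)
        t = np.array([5.3, -2.7, 9.1])
        m2 = VoxelMask(origin=m.origin + t, spacing=m.spacing, occupancy=m.occupancy)
        f2 = ApplicatorFrame(
            tandem_point=np.asarray(FRAME.tandem_point) + t,
            tandem_dir=FRAME.tandem_dir,
            ring_point=np.asarray(FRAME.ring_point) + t,
            ring_normal=FRAME.ring_normal,
        )
        assert axis_offset(m2, f2) == pytest.approx(axis_offset(m, FRAME), abs=1e-9)

    def test_empty_mask_errors(self):
        m = VoxelMask((0, 0, 0), (1, 1, 1), np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError, match="empty"):
            axis_offset(m, FRAME)


class TestLateralExtent:
    def test_coaxial_cylinder_constant_cross_section(self):
        struct, frame = make_analytic_phantom(
            "cylinder", radius=25, height=40, slice_spacing=1.0
        )
        m = rasterize(struct, "HR-CTV")
        mean, mx = lateral_extent(m, frame)
        assert mx == pytest.approx(25.0, abs=0.5)
        assert mean == pytest.approx(25.0, abs=0.5)

    def test_sphere_continuum_limits(self):
        r = 20.0
        struct, frame = make_analytic_phantom(
            "sphere", radius=r, slice_spacing=1.0, n_vertices=180
        )
        m = rasterize(struct, "HR-CTV", spacing=(0.5, 0.5, 0.5))
        mean, mx = lateral_extent(m, frame)
        assert mx == pytest.approx(r, rel=0.02)
        # per-slab reach sqrt(r^2 - z^2) averages to (pi/4) r in the limit
        assert mean == pytest.approx(math.pi / 4 * r, rel=0.05)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_max_matches_brute_force_voxel_loop(self, seed):
        rng = np.random.default_rng(seed)
        m = _random_mask(rng)
        _, mx = lateral_extent(m, FRAME)
        assert mx == pytest.approx(brute_lat_max(m, FRAME), abs=1e-9)


class TestVerticalExtent:
    def test_uniform_slab_height(self):
        struct, frame = make_analytic_phantom(
            "slab", size=(30, 30), thickness=40, slice_spacing=1.0
        )
        m = rasterize(struct, "HR-CTV")
        mean, mx = vertical_extent(m, frame)
        assert mx == pytest.approx(40.0, abs=0.5)
        assert mean == pytest.approx(40.0, abs=0.5)

    def test_hemisphere_continuum_limits(self):
        r = 20.0
        struct, frame = make_analytic_phantom(
            "hemisphere", radius=r, slice_spacing=1.0, n_vertices=180
        )
        m = rasterize(struct, "HR-CTV", spacing=(0.5, 0.5, 0.5))
        mean, mx = vertical_extent(m, frame)
        assert mx == pytest.approx(r, rel=0.02)
        # mean height of a hemisphere over its supporting disk = (2/3) r
        assert mean == pytest.approx(2 / 3 * r, rel=0.05)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_max_matches_brute_force_voxel_loop(self, seed):
        rng = np.random.default_rng(seed)
        m = _random_mask(rng)
        _, mx = vertical_extent(m, FRAME)
        assert mx == pytest.approx(brute_vert_max(m, FRAME), abs=1e-9)


class TestOarProximity:
    def test_oar_inside_target_is_zero(self):
        rng = np.random.default_rng(7)
        hrctv = _random_mask(rng, p=0.6)
        sub = hrctv.occupancy.copy()
        sub[rng.random(sub.shape) < 0.5] = False
        sub[tuple(s // 2 for s in sub.shape)] = hrctv.occupancy[
            tuple(s // 2 for s in sub.shape)
        ]
        oar = VoxelMask(hrctv.origin, hrctv.spacing, sub & hrctv.occupancy)
        assert oar_proximity(hrctv, oar) == 0.0

    def test_two_cubes_matches_brute_force_exactly(self):
        struct, _ = make_analytic_phantom("two_cubes", size=20, gap=10,
                                          slice_spacing=1.0)
        hrctv = rasterize(struct, "HR-CTV")
        oar = rasterize(struct, "rectum")
        got = oar_proximity(hrctv, oar)
        assert got == pytest.approx(brute_proximity(hrctv, oar), abs=1e-9)
        # face gap 10 mm -> distances start at the gap, end within the
        # slab depth holding 1.5 cc (1.5cc / 400 mm^2 = 3.75 mm)
        assert 10.0 <= got <= 10.0 + 3.75 + 1.0

    @pytest.mark.parametrize("seed", [11, 12])
    def test_random_masks_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        hrctv = _random_mask(rng, shape=(15, 15, 15), p=0.3)
        oar = _random_mask(rng, shape=(20, 20, 12), p=0.3)
        assert oar_proximity(hrctv, oar) == pytest.approx(
            brute_proximity(hrctv, oar), abs=1e-9
        )

    def test_monotone_in_gap(self):
        vals = []
        for gap in [5, 10, 15, 20, 25, 30]:
            struct, _ = make_analytic_phantom("two_cubes", size=20, gap=gap,
                                              slice_spacing=1.0)
            vals.append(
                oar_proximity(rasterize(struct, "HR-CTV"),
                              rasterize(struct, "rectum"))
            )
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_empty_inputs_raise_value_error(self):
        rng = np.random.default_rng(0)
        full = _random_mask(rng)
        empty = VoxelMask((0, 0, 0), (1, 1, 1), np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError, match="empty"):
            oar_proximity(full, empty)
        with pytest.raises(ValueError, match="empty"):
            oar_proximity(empty, full)


@pytest.fixture(scope="module")
def phantom_fraction():
    cohort = generate_cohort(CohortConfig(n_fractions=2, n_ic=1, n_is=1, seed=5))
    return cohort[0]


class TestExtractFeatures:
    def test_composition_matches_individual_metrics(self, phantom_fraction):
        f = phantom_fraction
        fv = extract_features(f.structure_set, f.frame)
        assert fv.absent == ()
        hrctv = rasterize(f.structure_set, "HR-CTV")
        assert fv.hrctv_volume == structure_volume(hrctv)
        assert fv.axis_offset == axis_offset(hrctv, f.frame)
        mean, mx = lateral_extent(hrctv, f.frame)
        assert (fv.lateral_mean_extent, fv.lateral_max_extent) == (mean, mx)

    def test_missing_sigmoid_flagged_absent(self, phantom_fraction):
        f = phantom_fraction
        struct = f.structure_set
        trimmed = type(struct)(
            structures={k: v for k, v in struct.structures.items()
                        if k != "sigmoid"},
            frame_of_reference=struct.frame_of_reference,
        )
        fv = extract_features(trimmed, f.frame)
        assert set(fv.absent) == {"sigmoid_volume", "sigmoid_proximity"}
        populated = [n for n in FEATURE_NAMES if getattr(fv, n) is not None]
        assert len(populated) == 10

    def test_z_rotation_equivariance(self, phantom_fraction):
        # rigid transforms that preserve axial planes: rotation about z + shift
        f = phantom_fraction
        ang = 0.7
        c, s = math.cos(ang), math.sin(ang)
        R = np.array([[c, -s], [s, c]])
        t = np.array([8.0, -3.0, 12.0])

        from brachysel.structure_io import PlanarContour, StructureSet

        rotated = StructureSet(
            structures={
                name: [
                    PlanarContour(z=ct.z + t[2], vertices=ct.vertices @ R.T + t[:2])
                    for ct in contours
                ]
                for name, contours in f.structure_set.structures.items()
            }
        )
        R3 = np.eye(3); R3[:2, :2] = R
        frame2 = ApplicatorFrame(
            tandem_point=R3 @ np.asarray(f.frame.tandem_point) + t,
            tandem_dir=R3 @ np.asarray(f.frame.tandem_dir),
            ring_point=R3 @ np.asarray(f.frame.ring_point) + t,
            ring_normal=R3 @ np.asarray(f.frame.ring_normal),
        )
        fv0 = extract_features(f.structure_set, f.frame).as_series()
        fv1 = extract_features(rotated, frame2).as_series()
        tol = math.sqrt(3) / 2  # half the voxel diagonal at 1 mm
        assert (fv1 - fv0).abs().max() < tol

    def test_max_not_below_mean_on_random_phantoms(self):
        # ordering invariant over random anatomy at coarse spacing
        cohort = generate_cohort(CohortConfig(n_fractions=6, n_ic=3, n_is=3,
                                              seed=9))
        for f in cohort:
            fv = extract_features(f.structure_set, f.frame, spacing=(2, 2, 2))
            assert fv.lateral_max_extent >= fv.lateral_mean_extent
            assert fv.vertical_max_extent >= fv.vertical_mean_extent
            assert all(
                getattr(fv, n) is None or getattr(fv, n) >= 0
                for n in FEATURE_NAMES
            )
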