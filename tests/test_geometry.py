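"""Chord-length geometry: analytic ellipsoid intersections vs brute force."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from biopsim.geometry import (
    BiopsyCore,
    Ellipsoid,
    chord_length_ellipsoid,
    core_cancer_length,
    merge_interval_lengths,
    segment_in_gland_length,
)
from biopsim.reconstruct import VoxelModel

from conftest import make_model, spherical_lesion


def dense_length(core, predicate, step=0.05):
    """Brute-force inside-length by dense point sampling along the segment."""
    half = core.effective_length / 2
    n = int(np.ceil(core.effective_length / step)) + 1
    t = np.linspace(-half, half, n)
    pts = core.realized_midpoint + t[:, None] * core.direction
    return float(np.count_nonzero(predicate(pts))) * (t[1] - t[0])


def random_core(rng, effective_length=17.0):
    mid = rng.uniform(-8, 8, 3)
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    return BiopsyCore.aimed(mid - 30 * d, d, mid, effective_length)


def random_ellipsoid(rng):
    axes = rng.uniform(2.0, 9.0, 3)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    return Ellipsoid(rng.uniform(-4, 4, 3), axes, q * np.sign(np.linalg.det(q)))


class TestChordLengthEllipsoid:
    def test_diameter_chord_through_sphere(self):
        sphere = Ellipsoid([0, 0, 0], [5, 5, 5])
        core = BiopsyCore.aimed([-20, 0, 0], [1, 0, 0], [0, 0, 0], 17.0)
        assert chord_length_ellipsoid(core, sphere) == pytest.approx(10.0)

    def test_disjoint_segment_gives_zero(self):
        sphere = Ellipsoid([0, 0, 0], [5, 5, 5])
        core = BiopsyCore.aimed([-20, 30, 0], [1, 0, 0], [0, 30, 0], 17.0)
        assert chord_length_ellipsoid(core, sphere) == 0.0

    def test_segment_clipping_limits_chord(self):
        # a 4 mm notch through a 10 mm-diameter sphere samples only 4 mm
        sphere = Ellipsoid([0, 0, 0], [5, 5, 5])
        core = BiopsyCore.aimed([-20, 0, 0], [1, 0, 0], [0, 0, 0], 4.0)
        assert chord_length_ellipsoid(core, sphere) == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_dense_sampling(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            ell = random_ellipsoid(rng)
            core = random_core(rng)
            exact = chord_length_ellipsoid(core, ell)
            approx = dense_length(core, lambda p: ell.contains(p))
            assert exact == pytest.approx(approx, abs=0.11)

    @given(st.integers(0, 500))
    def test_chord_bounded_by_effective_length(self, seed):
        rng = np.random.default_rng(seed)
        ell = random_ellipsoid(rng)
        core = random_core(rng, effective_length=float(rng.uniform(1, 25)))
        c = chord_length_ellipsoid(core, ell)
        assert 0.0 <= c <= core.effective_length + 1e-12


class TestCoreCancerLength:
    def test_union_not_sum_for_overlapping_lesions(self):
        a = spherical_lesion([0, 0, 0], 5.0, "A")
        b = spherical_lesion([4, 0, 0], 5.0, "B", is_index=False)
        model = make_model([a, b])
        core = BiopsyCore.aimed([-30, 0, 0], [1, 0, 0], [2, 0, 0], 25.0)
        res = core_cancer_length(core, model)
        per_sum = sum(res.per_lesion_lengths.values())
        assert res.cancer_length == pytest.approx(14.0)  # union [-5, 9]
        assert res.cancer_length < per_sum
        union = dense_length(
            core, lambda p: a.ellipsoid.contains(p) | b.ellipsoid.contains(p)
        )
        assert res.cancer_length == pytest.approx(union, abs=0.11)

    def test_false_target_contributes_no_cancer(self):
        benign = spherical_lesion([0, 0, 0], 5.0, "B1", is_false_target=True)
        model = make_model([benign])
        core = BiopsyCore.aimed([-30, 0, 0], [1, 0, 0], [0, 0, 0], 17.0)
        res = core_cancer_length(core, model)
        assert res.cancer_length == 0.0
        assert not res.positive
        assert res.per_lesion_lengths["B1"] == pytest.approx(10.0)

    def test_gland_miss_flagged(self):
        model = make_model([spherical_lesion([0, 0, 0], 5.0)])
        core = BiopsyCore.aimed([100, 100, 0], [1, 0, 0], [120, 100, 0], 17.0)
        res = core_cancer_length(core, model)
        assert res.gland_miss and res.cancer_length == 0.0

    def test_rigid_equivariance(self):
        rng = np.random.default_rng(3)
        lesion = spherical_lesion([2.0, -3.0, 1.0], 4.0)
        model = make_model([lesion])
        core = random_core(rng)
        base = core_cancer_length(core, model).cancer_length
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        q *= np.sign(np.linalg.det(q))
        t = rng.uniform(-10, 10, 3)
        moved_core = BiopsyCore.aimed(
            q @ core.entry + t, q @ core.direction, q @ core.realized_midpoint + t,
            core.effective_length,
        )
        assert chord_length_ellipsoid(
            moved_core, lesion.ellipsoid.transformed(q, t)
        ) == pytest.approx(base, abs=1e-9)

    def test_monotone_in_lesion_size(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            center = rng.uniform(-3, 3, 3)
            axes = rng.uniform(2, 6, 3)
            small = Ellipsoid(center, axes)
            big = Ellipsoid(center, axes * rng.uniform(1.0, 2.0))
            core = random_core(rng)
            assert chord_length_ellipsoid(core, big) >= chord_length_ellipsoid(
                core, small
            ) - 1e-12


class TestVoxelRoute:
    @staticmethod
    def voxelize(ell: Ellipsoid, spacing=0.5, pad=3.0):
        lo = ell.center - ell.semi_axes.max() - pad
        n = int(np.ceil((2 * (ell.semi_axes.max() + pad)) / spacing)) + 1
        xs = lo[0] + spacing * np.arange(n)
        ys = lo[1] + spacing * np.arange(n)
        zs = lo[2] + spacing * np.arange(n)
        Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        mask = ell.contains(pts).reshape(n, n, n)
        return VoxelModel(origin=lo, spacing=spacing, gland_mask=mask,
                          lesion_masks={"L": mask.copy()})

    def test_analytic_and_voxel_paths_agree(self):
        rng = np.random.default_rng(5)
        ell = Ellipsoid([0, 0, 0], [9, 6, 4])
        vm = self.voxelize(ell)
        for _ in range(15):
            core = random_core(rng)
            exact = chord_length_ellipsoid(core, ell)
            res = core_cancer_length(core, vm)
            tol = max(0.02 * exact, 0.45)  # voxelisation + sampling quantum
            assert res.cancer_length == pytest.approx(exact, abs=tol)

    def test_gland_chord_on_voxel_sphere(self):
        ell = Ellipsoid([0, 0, 0], [8, 8, 8])
        vm = self.voxelize(ell)
        core = BiopsyCore.aimed([-30, 0, 0], [1, 0, 0], [0, 0, 0], 25.0)
        # nearest-voxel lookup dilates the surface by up to one voxel overall
        assert segment_in_gland_length(core, vm) == pytest.approx(16.0, abs=1.0)


class TestSegmentInGland:
    def test_through_centre_positive(self, sphere_target_model):
        core = BiopsyCore.aimed([0, 0, -60], [0, 0, 1], [0, 0, 0], 17.0)
        assert segment_in_gland_length(core, sphere_target_model) == pytest.approx(17.0)

    def test_far_outside_zero(self, sphere_target_model):
        core = BiopsyCore.aimed([200, 0, 0], [0, 0, 1], [200, 0, 0], 17.0)
        assert segment_in_gland_length(core, sphere_target_model) == 0.0

    def test_diameter_chord(self):
        model = make_model([], gland_semi=(20, 20, 20))
        core = BiopsyCore.aimed([-60, 0, 0], [1, 0, 0], [0, 0, 0], 60.0)
        assert segment_in_gland_length(core, model) == pytest.approx(40.0)


class TestMergeIntervals:
    @pytest.mark.parametrize(
        "starts,ends,total,longest",
        [
            ([[0, 2]], [[1, 3]], 2.0, 1.0),
            ([[0, 0.5]], [[1, 2]], 2.0, 2.0),
            ([[0, np.nan]], [[1, np.nan]], 1.0, 1.0),
            ([[np.nan, np.nan]], [[np.nan, np.nan]], 0.0, 0.0),
            ([[0, 1, 5]], [[2, 3, 6]], 4.0, 3.0),
        ],
    )
    def test_known_unions(self, starts, ends, total, longest):
        tot, lon = merge_interval_lengths(np.array(starts), np.array(ends))
        assert tot[0] == pytest.approx(total)
        assert lon[0] == pytest.approx(longest)

    @given(st.integers(0, 300))
    def test_union_bounds(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 8)
        s = rng.uniform(-10, 10, (1, m))
        e = s + rng.uniform(0, 5, (1, m))
        tot, lon = merge_interval_lengths(s, e)
        assert lon[0] <= tot[0] + 1e-12
        assert tot[0] <= (e - s).sum() + 1e-12
        assert tot[0] <= e.max() - s.min() + 1e-12


class TestBiopsyCore:
    def test_rejects_non_unit_direction(self):
        with pytest.raises(ValueError):
            BiopsyCore([0, 0, 0], [1, 1, 0], 17.0, [0, 0, 0], [0, 0, 0])

    def test_rejects_non_positive_length(self):
        with pytest.raises(ValueError):
            BiopsyCore.aimed([0, 0, 0], [1, 0, 0], [0, 0, 0], 0.0)

    def test_segment_spans_effective_length(self):
        core = BiopsyCore.aimed([0, 0, -30], [0, 0, 1], [1, 2, 3], 17.0)
        a, b = core.segment
        assert np.allclose(b - a, [0, 0, 17.0])
        assert np.allclose(0.5 * (a + b), [1, 2, 3])
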