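import numpy as np
import pytest
from scipy.interpolate import RBFInterpolator

from fukomys.errors import DegenerateShapeError, FormatError
from fukomys.shape import (
    LandmarkConfig,
    average_replicates,
    gpa,
    procrustes_distance,
    read_tps,
    relative_warps,
    tps_deformation,
    write_tps,
)
from fukomys.simulate import sim_landmarks


def rotation(theta):
    return np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )


def two_shape_procrustes_reference(a, b):
    """Closed-form partial Procrustes distance (unit size, rotation only,
    reflections excluded), via the SVD of the cross-product matrix."""
    def pre(x):
        c = x - x.mean(axis=0)
        return c / np.sqrt((c ** 2).sum())

    x, y = pre(a), pre(b)
    m = x.T @ y
    u, s, vt = np.linalg.svd(m)
    sign = np.sign(np.linalg.det(m))
    trace = s[0] + sign * s[1]
    return np.sqrt(max(2 - 2 * trace, 0.0))


@pytest.fixture
def triangle_rng():
    return np.random.default_rng(99)


class TestTPSFormat:
    def test_single_block(self, tmp_path):
        p = tmp_path / "x.tps"
        p.write_text("LM=3\n1.0 2.0\n3.0 4.0\n5.0 6.0\nID=spec1\n")
        cfgs = read_tps(p)
        assert len(cfgs) == 1
        assert cfgs[0].specimen == "spec1"
        assert cfgs[0].coords.shape == (3, 2)

    def test_scale_applied(self, tmp_path):
        p = tmp_path / "x.tps"
        p.write_text("LM=2\n2.0 4.0\n6.0 8.0\nSCALE=0.5\n")
        cfgs = read_tps(p)
        assert np.allclose(cfgs[0].coords, [[1, 2], [3, 4]])

    def test_roundtrip_dorsal_blocks(self, tmp_path, triangle_rng):
        coords = [triangle_rng.normal(0, 1, size=(15, 2)) for _ in range(4)]
        cfgs = [
            LandmarkConfig(coords=c, specimen=f"sp{i}", view="dorsal")
            for i, c in enumerate(coords)
        ]
        p = tmp_path / "d.tps"
        write_tps(cfgs, p)
        back = read_tps(p, view="dorsal")
        assert len(back) == 4
        for orig, rt in zip(cfgs, back):
            assert np.allclose(orig.coords, rt.coords, atol=1e-9)
            assert rt.specimen == orig.specimen

    def test_landmark_count_mismatch_rejected(self, tmp_path):
        p = tmp_path / "x.tps"
        p.write_text("LM=3\n1 2\n3 4\n")
        with pytest.raises(FormatError):
            read_tps(p)

    def test_view_count_enforced(self):
        with pytest.raises(FormatError):
            LandmarkConfig(coords=np.zeros((10, 2)), view="dorsal")


class TestGPA:
    def test_identical_shapes_zero_distance(self, triangle_rng):
        t = triangle_rng.normal(0, 1, (6, 2))
        assert procrustes_distance(t, t.copy()) == pytest.approx(0, abs=1e-12)

    def test_similarity_transform_invariance(self, triangle_rng):
        t = triangle_rng.normal(0, 1, (6, 2))
        moved = (t @ rotation(1.1)) * 2.7 + np.array([10.0, -4.0])
        assert procrustes_distance(t, moved) < 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_pairwise_distance_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (3, 2))
        b = rng.normal(0, 1, (3, 2))
        assert procrustes_distance(a, b) == pytest.approx(
            two_shape_procrustes_reference(a, b), abs=1e-10
        )

    def test_aligned_configs_unit_size_centered(self, triangle_rng):
        shapes = [triangle_rng.normal(0, 1, (8, 2)) for _ in range(5)]
        res = gpa(np.stack(shapes))
        for i in range(res.n):
            assert np.allclose(res.coords[i].mean(axis=0), 0, atol=1e-9)
            assert np.sqrt((res.coords[i] ** 2).sum()) == pytest.approx(
                1.0, abs=1e-9
            )
        assert np.allclose(
            res.consensus, res.coords.mean(axis=0)
            / np.sqrt((res.coords.mean(axis=0) ** 2).sum()),
            atol=1e-6,
        )

    def test_result_invariant_to_input_pretransforms(self, triangle_rng):
        shapes = np.stack([triangle_rng.normal(0, 1, (8, 2)) for _ in range(4)])
        res1 = gpa(shapes.copy())
        shapes2 = shapes.copy()
        shapes2[2] = (shapes2[2] @ rotation(0.8)) * 3.0 + np.array([4.0, 4.0])
        res2 = gpa(shapes2)
        # the rotated/translated/rescaled copy aligns to the same shape
        d = procrustes_distance(res1.coords[2], res2.coords[2])
        assert d < 1e-7

    def test_degenerate_config_rejected(self):
        with pytest.raises(DegenerateShapeError):
            gpa(np.zeros((3, 5, 2)))


class TestReplicates:
    def test_identical_replicates_return_shape(self, triangle_rng):
        base = triangle_rng.normal(0, 1, (7, 2))
        cfgs = [
            LandmarkConfig(coords=base.copy(), specimen="s1", replicate=r)
            for r in range(3)
        ] + [
            LandmarkConfig(
                coords=triangle_rng.normal(0, 1, (7, 2)),
                specimen="s2", replicate=0,
            )
        ]
        aligned = gpa(cfgs)
        per_spec = average_replicates(aligned)
        assert per_spec.n == 2
        assert procrustes_distance(per_spec.coords[0], base) < 1e-6

    def test_symmetric_perturbation_cancels(self, triangle_rng):
        base = triangle_rng.normal(0, 1, (7, 2))
        pert = triangle_rng.normal(0, 0.01, (7, 2))
        cfgs = [
            LandmarkConfig(coords=base + pert, specimen="s1", replicate=0),
            LandmarkConfig(coords=base - pert, specimen="s1", replicate=1),
            LandmarkConfig(
                coords=triangle_rng.normal(0, 1, (7, 2)), specimen="s2"
            ),
        ]
        aligned = gpa(cfgs)
        per_spec = average_replicates(aligned)
        assert procrustes_distance(per_spec.coords[0], base) < 1e-3

    def test_mean_scores_close_to_score_of_mean(self):
        """In the small-noise regime the warp score of the averaged config
        matches the average of replicate scores (linearization)."""
        rng = np.random.default_rng(5)
        mean = rng.normal(0, 1, (10, 2))
        cfgs = sim_landmarks(
            mean, {"A": 6, "B": 6},
            {"B": np.full((10, 2), 0.02)}, noise_sd=0.005,
            seed=3, n_replicates=3,
        )
        aligned = gpa(cfgs)
        warps_all = relative_warps(aligned)
        per_spec = average_replicates(aligned)
        warps_mean = relative_warps(per_spec)
        spec_ids = [lab[0] for lab in warps_all.labels]
        for i, spec in enumerate(per_spec.labels):
            rows = [j for j, s in enumerate(spec_ids) if s == spec]
            avg_score = warps_all.scores[rows, 0].mean()
            assert warps_mean.scores[i, 0] == pytest.approx(
                avg_score, abs=2e-3
            )


class TestRelativeWarps:
    def test_single_axis_of_variation(self):
        base = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1], [0.5, 2]])
        direction = np.zeros((5, 2))
        direction[4, 1] = 1.0
        shapes = np.stack([base + t * direction for t in
                           (-0.02, -0.01, 0.0, 0.01, 0.02)])
        warps = relative_warps(gpa(shapes))
        assert warps.variance_fractions[0] == pytest.approx(1.0, abs=1e-4)

    def test_variance_fractions_sum_to_one(self, triangle_rng):
        shapes = np.stack(
            [triangle_rng.normal(0, 1, (9, 2)) * 0.05
             + np.linspace(0, 1, 18).reshape(9, 2) for _ in range(8)]
        )
        warps = relative_warps(gpa(shapes))
        assert warps.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_axes_orthogonal(self, triangle_rng):
        shapes = np.stack([triangle_rng.normal(0, 1, (9, 2)) for _ in range(6)])
        warps = relative_warps(gpa(shapes))
        gram = warps.axes @ warps.axes.T
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-9)

    def test_planted_group_displacement_recovered(self):
        from fukomys.experiments import landmark_displacement_recovery

        res = landmark_displacement_recovery(seed=7)
        assert res["relative_error"] < 0.05

    def test_sign_convention_largest_loading_positive(self, triangle_rng):
        shapes = np.stack([triangle_rng.normal(0, 1, (9, 2)) for _ in range(6)])
        warps = relative_warps(gpa(shapes))
        for axis in warps.axes:
            assert axis[np.argmax(np.abs(axis))] > 0


class TestThinPlateSpline:
    def test_identity_map_identity_grid(self, triangle_rng):
        ref = triangle_rng.normal(0, 1, (8, 2))
        tps = tps_deformation(ref, ref.copy(), grid_resolution=6)
        lattice = tps.grid.reshape(-1, 2)
        # mapping is the identity, so the grid equals the undeformed lattice
        span = ref.max(axis=0) - ref.min(axis=0)
        lo = ref.min(axis=0) - 0.1 * span
        hi = ref.max(axis=0) + 0.1 * span
        gx, gy = np.meshgrid(np.linspace(lo[0], hi[0], 6),
                             np.linspace(lo[1], hi[1], 6))
        want = np.stack([gx, gy], axis=-1).reshape(-1, 2)
        assert np.allclose(lattice, want, atol=1e-9)
        assert tps.bending_energy == pytest.approx(0, abs=1e-9)

    def test_affine_target_zero_bending(self, triangle_rng):
        ref = triangle_rng.normal(0, 1, (8, 2))
        target = ref @ np.array([[1.3, 0.2], [-0.1, 0.8]]) + np.array([2.0, 1.0])
        tps = tps_deformation(ref, target)
        assert tps.bending_energy == pytest.approx(0, abs=1e-9)

    def test_exact_interpolation_at_landmarks(self, triangle_rng):
        ref = triangle_rng.normal(0, 1, (10, 2))
        target = ref + triangle_rng.normal(0, 0.2, (10, 2))
        tps = tps_deformation(ref, target)
        assert np.allclose(tps.transform(ref), target, atol=1e-9)

    def test_matches_scipy_rbf_thin_plate(self, triangle_rng):
        """Independent check: scipy's thin-plate RBF interpolant (degree-1
        polynomial tail) gives the same map at off-landmark points."""
        ref = triangle_rng.normal(0, 1, (12, 2))
        target = ref + triangle_rng.normal(0, 0.15, (12, 2))
        tps = tps_deformation(ref, target)
        rbf = RBFInterpolator(ref, target, kernel="thin_plate_spline", degree=1)
        pts = triangle_rng.normal(0, 1, (30, 2))
        assert np.allclose(tps.transform(pts), rbf(pts), atol=1e-7)

    def test_collinear_reference_rejected(self):
        ref = np.stack([np.linspace(0, 1, 6), np.linspace(0, 2, 6)], axis=1)
        with pytest.raises(DegenerateShapeError):
            tps_deformation(ref, ref + 0.1)
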