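import numpy as np
import pytest

from reefstruct import (
    CorrespondencePairs,
    PointCloud3D,
    SimilarityTransform,
    apply_transform,
    estimate_similarity,
    icp_scaled,
    rasterize_heights,
    read_cloud,
    volume_change,
    write_cloud,
)
from reefstruct.clouds import CloudFormatError, DegenerateCorrespondenceError
from conftest import random_rotation, rotation_about


def stratified_plane_points(extent=2.0, spacing=0.005, z_fn=None, seed=0):
    """Dense, evenly covering sample of a z = f(x, y) surface."""
    rng = np.random.default_rng(seed)
    g = np.arange(0.0, extent, spacing)
    xx, yy = np.meshgrid(g, g)
    x = (xx + rng.uniform(0, spacing, xx.shape)).ravel()
    y = (yy + rng.uniform(0, spacing, yy.shape)).ravel()
    z = np.zeros_like(x) if z_fn is None else z_fn(x, y)
    return np.column_stack([x, y, z])


class TestCloudIO:
    def test_xyz_roundtrip(self, tmp_path):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        write_cloud(PointCloud3D(pts), tmp_path / "c.xyz")
        back = read_cloud(tmp_path / "c.xyz")
        np.testing.assert_allclose(back.points, pts, rtol=1e-9)

    def test_ascii_ply_roundtrip(self, tmp_path):
        pts = np.random.default_rng(1).normal(size=(7, 3))
        write_cloud(PointCloud3D(pts), tmp_path / "c.ply")
        back = read_cloud(tmp_path / "c.ply")
        np.testing.assert_allclose(back.points, pts, rtol=1e-9)

    def test_ply_with_extra_properties_ignored(self, tmp_path):
        path = tmp_path / "c.ply"
        path.write_text(
            "ply\nformat ascii 1.0\nelement vertex 2\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property uchar red\nproperty uchar green\nproperty uchar blue\n"
            "end_header\n1 2 3 255 0 0\n4 5 6 0 255 0\n"
        )
        back = read_cloud(path)
        np.testing.assert_allclose(back.points, [[1, 2, 3], [4, 5, 6]])

    def test_binary_ply(self, tmp_path):
        pts = np.array([[0.5, 1.5, -2.0], [3.0, 4.0, 5.0]], dtype="<f4")
        path = tmp_path / "b.ply"
        header = (
            "ply\nformat binary_little_endian 1.0\nelement vertex 2\n"
            "property float x\nproperty float y\nproperty float z\nend_header\n"
        )
        path.write_bytes(header.encode() + pts.tobytes())
        back = read_cloud(path)
        np.testing.assert_allclose(back.points, pts, rtol=1e-6)

    def test_empty_and_unknown_files_error(self, tmp_path):
        empty = tmp_path / "e.xyz"
        empty.write_text("")
        with pytest.raises(CloudFormatError):
            read_cloud(empty)
        weird = tmp_path / "c.obj"
        weird.write_text("v 1 2 3\n")
        with pytest.raises(CloudFormatError):
            read_cloud(weird)


class TestSimilarity:
    def test_identity_pairs(self):
        P = np.random.default_rng(0).normal(size=(6, 3))
        T = estimate_similarity(CorrespondencePairs(P, P))
        assert T.scale == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, 0.0, atol=1e-12)

    def test_pure_scaling(self):
        P = np.random.default_rng(1).normal(size=(5, 3))
        T = estimate_similarity(CorrespondencePairs(P, 2.0 * P))
        assert T.scale == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_generate_and_recover_random_similarity(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.uniform(-1, 1, (10, 3))
        T = SimilarityTransform(
            scale=rng.uniform(0.5, 2.0),
            rotation=random_rotation(rng),
            translation=rng.uniform(-2, 2, 3),
        )
        est = estimate_similarity(CorrespondencePairs(P, T.apply(P)))
        assert est.scale == pytest.approx(T.scale, abs=1e-8)
        np.testing.assert_allclose(est.rotation, T.rotation, atol=1e-8)
        np.testing.assert_allclose(est.translation, T.translation, atol=1e-8)

    def test_exact_on_minimal_noncollinear_triple(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.5]], dtype=float)
        T = SimilarityTransform(
            scale=1.3, rotation=rotation_about([0, 0, 1], 0.4), translation=[1, 2, 3]
        )
        est = estimate_similarity(CorrespondencePairs(P, T.apply(P)))
        assert est.scale == pytest.approx(1.3, abs=1e-10)

    def test_collinear_source_raises(self):
        P = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], dtype=float)
        with pytest.raises(DegenerateCorrespondenceError):
            estimate_similarity(CorrespondencePairs(P, P + 1.0))

    def test_too_few_pairs_raises(self):
        P = np.array([[0, 0, 0], [1, 0, 0]], dtype=float)
        with pytest.raises(DegenerateCorrespondenceError):
            estimate_similarity(CorrespondencePairs(P, P))


class TestApplyTransform:
    def test_identity(self):
        cloud = PointCloud3D(np.random.default_rng(0).normal(size=(5, 3)))
        out = apply_transform(cloud, SimilarityTransform())
        np.testing.assert_array_equal(out.points, cloud.points)

    def test_composition_equals_sequential(self):
        rng = np.random.default_rng(3)
        cloud = PointCloud3D(rng.normal(size=(8, 3)))
        T1 = SimilarityTransform(1.2, random_rotation(rng), rng.normal(size=3))
        T2 = SimilarityTransform(0.8, random_rotation(rng), rng.normal(size=3))
        seq = apply_transform(apply_transform(cloud, T1), T2)
        one = apply_transform(cloud, T2.compose(T1))
        np.testing.assert_allclose(one.points, seq.points, atol=1e-12)

    def test_inverse_restores_original(self):
        rng = np.random.default_rng(4)
        cloud = PointCloud3D(rng.normal(size=(8, 3)))
        T = SimilarityTransform(1.7, random_rotation(rng), rng.normal(size=3))
        back = apply_transform(apply_transform(cloud, T), T.inverse())
        np.testing.assert_allclose(back.points, cloud.points, atol=1e-10)

    def test_to_from_array_roundtrip(self):
        rng = np.random.default_rng(5)
        T = SimilarityTransform(1.1, random_rotation(rng), rng.normal(size=3))
        T2 = SimilarityTransform.from_array(T.to_array())
        assert T2.scale == pytest.approx(T.scale)
        np.testing.assert_allclose(T2.rotation, T.rotation)


class TestICP:
    def test_identical_clouds_converge_immediately(self):
        pts = np.random.default_rng(0).uniform(0, 1, (500, 3))
        res = icp_scaled(PointCloud3D(pts), PointCloud3D(pts))
        assert res.converged
        assert res.rms_history[-1] == pytest.approx(0.0, abs=1e-12)
        assert res.transform.scale == pytest.approx(1.0, abs=1e-9)

    def test_recovers_small_similarity_under_noise(self):
        pts = stratified_plane_points(
            extent=2.0, spacing=0.01,
            z_fn=lambda x, y: 0.05 * np.sin(2 * np.pi * x / 0.4)
            + 0.05 * np.cos(2 * np.pi * y / 0.7),
            seed=6,
        )
        rng = np.random.default_rng(7)
        ref = PointCloud3D(pts + rng.normal(0, 0.001, pts.shape))
        angle = np.deg2rad(4.0)
        T_true = SimilarityTransform(
            scale=1.02,
            rotation=rotation_about([0.1, -0.2, 1.0], angle),
            translation=[0.02, -0.015, 0.01],
        )
        src = PointCloud3D(T_true.inverse().apply(ref.points))
        res = icp_scaled(src, ref)
        assert abs(res.transform.scale - 1.02) < 0.005
        relative = res.transform.compose(T_true.inverse())
        assert np.rad2deg(relative.rotation_angle) < 0.5
        diffs = np.diff(res.rms_history)
        assert np.all(diffs <= 1e-12)

    def test_rms_history_non_increasing_from_poor_init(self):
        rng = np.random.default_rng(8)
        ref = PointCloud3D(rng.uniform(0, 1, (800, 3)))
        T = SimilarityTransform(1.1, rotation_about([0, 0, 1], 0.2), [0.1, 0.1, 0.0])
        src = PointCloud3D(T.inverse().apply(ref.points))
        res = icp_scaled(src, ref, max_iter=30)
        assert np.all(np.diff(res.rms_history) <= 1e-12)

    def test_too_small_clouds_rejected(self):
        few = PointCloud3D(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            icp_scaled(few, few)


class TestRasterize:
    def test_mean_of_points_in_cell(self):
        pts = np.array([[0.005, 0.005, z] for z in (1.0, 2.0, 3.0, 4.0)])
        g = rasterize_heights(PointCloud3D(pts), 0.01, extent=(0, 0, 0.02, 0.02))
        # cell (0, 0) is the bottom-left => last row in north-up layout
        assert g.heights[-1, 0] == pytest.approx(2.5)
        assert g.nodata.sum() == 3

    def test_plane_recovered_at_cell_centres(self):
        pts = stratified_plane_points(
            extent=1.0, spacing=0.002, z_fn=lambda x, y: 0.2 * x + 0.1 * y, seed=9
        )
        g = rasterize_heights(PointCloud3D(pts), 0.01, extent=(0, 0, 1, 1))
        xc, yc = g.cell_centers()
        expected = 0.2 * xc + 0.1 * yc
        assert not g.nodata.any()
        np.testing.assert_allclose(g.heights, expected, atol=2e-3)

    def test_no_points_in_extent_errors(self):
        pts = np.zeros((5, 3))
        with pytest.raises(ValueError):
            rasterize_heights(PointCloud3D(pts), 0.01, extent=(10, 10, 11, 11))


class TestVolumeChange:
    def test_identical_clouds_zero_net(self):
        pts = stratified_plane_points(extent=1.0, spacing=0.004, seed=10)
        c = PointCloud3D(pts)
        vc = volume_change(c, c, cell_size=0.01)
        assert vc.net_volume == pytest.approx(0.0, abs=1e-12)
        assert vc.gain_volume == 0.0 and vc.loss_volume == 0.0

    def test_added_box_volume(self):
        def box(x, y):
            return np.where((x > 0.5) & (x < 1.5) & (y > 0.5) & (y < 1.5), 0.5, 0.0)

        before = PointCloud3D(stratified_plane_points(2.0, 0.004, seed=11))
        after = PointCloud3D(stratified_plane_points(2.0, 0.004, z_fn=box, seed=12))
        vc = volume_change(before, after, cell_size=0.01)
        assert vc.net_volume == pytest.approx(0.5, rel=0.02)
        assert vc.net_volume == pytest.approx(vc.gain_volume + vc.loss_volume)

    def test_removed_hemisphere_volume(self):
        r = 0.5

        def hemi(x, y):
            d2 = (x - 1.0) ** 2 + (y - 1.0) ** 2
            return np.where(d2 < r**2, np.sqrt(np.maximum(r**2 - d2, 0.0)), 0.0)

        before = PointCloud3D(stratified_plane_points(2.0, 0.004, z_fn=hemi, seed=13))
        after = PointCloud3D(stratified_plane_points(2.0, 0.004, seed=14))
        vc = volume_change(before, after, cell_size=0.01)
        expected = -(2.0 / 3.0) * np.pi * r**3
        assert vc.net_volume == pytest.approx(expected, rel=0.02)
        assert vc.loss_volume < 0 < vc.gain_volume + 1e-9

    def test_antisymmetry(self):
        rng = np.random.default_rng(15)
        a = PointCloud3D(stratified_plane_points(1.0, 0.005, seed=16))
        b = PointCloud3D(
            stratified_plane_points(
                1.0, 0.005, z_fn=lambda x, y: 0.1 * np.sin(3 * x) * np.cos(2 * y), seed=16
            )
        )
        ab = volume_change(a, b, cell_size=0.01)
        ba = volume_change(b, a, cell_size=0.01)
        assert ab.net_volume == pytest.approx(-ba.net_volume, abs=1e-9)

    def test_translation_invariance_of_net_volume(self):
        shift = np.array([5.0, -3.0, 2.0])
        a = PointCloud3D(stratified_plane_points(1.0, 0.005, seed=17))
        b = PointCloud3D(
            stratified_plane_points(1.0, 0.005, z_fn=lambda x, y: 0.05 + 0 * x, seed=18)
        )
        v1 = volume_change(a, b, cell_size=0.01)
        v2 = volume_change(
            PointCloud3D(a.points + shift), PointCloud3D(b.points + shift), cell_size=0.01
        )
        assert v2.net_volume == pytest.approx(v1.net_volume, abs=1e-6)

    def test_disjoint_clouds_error(self):
        a = PointCloud3D(stratified_plane_points(0.5, 0.01, seed=19))
        b = PointCloud3D(stratified_plane_points(0.5, 0.01, seed=20) + [10.0, 0, 0])
        with pytest.raises(ValueError, match="no comparable area"):
            volume_change(a, b, cell_size=0.01)
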