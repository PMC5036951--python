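import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse.csgraph import dijkstra

from hippoflat.layering import grow_layers
from hippoflat.synthetic import PhantomSpec, generate_phantom
from hippoflat.volume_io import SUBREGION_CODES, derive_gray_matter
from hippoflat import unfolding as uf

from conftest import measure_phantom


def line_graph(n=5, spacing=(1.0, 1.0, 1.0)):
    gm = np.zeros((n + 2, 3, 3), bool)
    gm[1:n + 1, 1, 1] = True
    return uf.build_manifold_graph(gm, None, spacing, "face")


class TestManifoldGraph:
    def test_path_graph_weights(self):
        g = line_graph(5)
        assert g.n_nodes == 5
        assert g.adjacency.nnz == 8  # 4 undirected edges
        assert np.allclose(g.adjacency.data, 1.0)

    def test_inplane_diagonal_weight(self):
        gm = np.zeros((4, 4, 4), bool)
        gm[1, 1, 1] = gm[2, 2, 1] = True
        g = uf.build_manifold_graph(gm, None, (0.39, 0.39, 3.0), "face+edge")
        assert g.adjacency.nnz == 2
        assert g.adjacency.data[0] == pytest.approx(0.39 * np.sqrt(2))

    def test_slab_graph_connected(self, slab_phantom):
        from scipy.sparse.csgraph import connected_components

        vol, _ = slab_phantom
        gm = derive_gray_matter(vol)
        la = grow_layers(gm, vol.wm_mask())
        g = uf.build_manifold_graph(gm, la, vol.spacing_mm)
        n, _ = connected_components(g.adjacency, directed=False)
        assert n == 1

    def test_empty_gm_errors(self):
        with pytest.raises(ValueError, match="empty"):
            uf.build_manifold_graph(np.zeros((3, 3, 3), bool), None, (1, 1, 1))


class TestGeodesics:
    def test_path_graph_end_to_end(self):
        g = line_graph(6)
        d = uf.geodesic_distance_matrix(g, [0, 5])
        assert d[0, 5] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_disconnected_landmark_errors(self):
        gm = np.zeros((6, 3, 3), bool)
        gm[1, 1, 1] = True
        gm[4, 1, 1] = True
        g = uf.build_manifold_graph(gm, None, (1, 1, 1), "face")
        with pytest.raises(ValueError, match="disconnected"):
            uf.geodesic_distance_matrix(g, [0])

    def test_shell_halfway_distance_is_pi_r(self):
        """Geodesic half-way around a shell approximates the arc length."""
        spec = PhantomSpec("cylindrical_shell", 1.6, (0.4, 0.4, 0.4), (52, 52, 16), 1, 0.0, 0)
        vol, _ = generate_phantom(spec)
        gm = derive_gray_matter(vol)
        la = grow_layers(gm, vol.wm_mask())
        g = uf.build_manifold_graph(gm, la, vol.spacing_mm)
        pos = g.voxel_indices * 0.4
        c = (52 - 1) / 2 * 0.4
        x, y = pos[:, 0] - c, pos[:, 1] - c
        r, theta = np.hypot(x, y), np.arctan2(y, x)
        zmid = int(np.median(g.voxel_indices[:, 2]))
        r_mid = r.mean()

        def nearest(target):
            score = (np.abs(theta - target) + np.abs(r - r_mid)
                     + 10 * np.abs(g.voxel_indices[:, 2] - zmid))
            return int(np.argmin(score))

        a, b = nearest(np.pi / 2), nearest(-np.pi / 2)
        d = dijkstra(g.adjacency, directed=False, indices=a)[b]
        arc = np.pi * (r[a] + r[b]) / 2
        assert d == pytest.approx(arc, rel=0.05)


class TestClassicalMDS:
    def test_collinear_points_exact(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        X = uf.classical_mds_embed(D)
        D2 = np.linalg.norm(X[:, None] - X[None], axis=-1)
        np.testing.assert_allclose(D2, D, atol=1e-7)
        # second dimension is degenerate
        assert np.abs(X[:, 1]).max() < 1e-6

    def test_unit_square_recovered(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        X = uf.classical_mds_embed(D)
        D2 = np.linalg.norm(X[:, None] - X[None], axis=-1)
        np.testing.assert_allclose(D2, D, atol=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 30))
    def test_planar_configurations_recovered_up_to_rigid_motion(self, seed, n):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(n, 2))
        D = np.linalg.norm(P[:, None] - P[None], axis=-1)
        X = uf.classical_mds_embed(D)
        D2 = np.linalg.norm(X[:, None] - X[None], axis=-1)
        np.testing.assert_allclose(D2, D, atol=1e-8)

    def test_orientation_is_deterministic(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(10, 2))
        D = np.linalg.norm(P[:, None] - P[None], axis=-1)
        np.testing.assert_array_equal(
            uf.classical_mds_embed(D), uf.classical_mds_embed(D))

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            uf.classical_mds_embed(np.array([[0, 1], [2, 0]], float))
        # strongly non-Euclidean: violates the triangle inequality badly
        D = np.array([[0, 10, 1], [10, 0, 1], [1, 1, 0]], float)
        with pytest.raises(uf.NonEuclideanError):
            uf.classical_mds_embed(D)


class TestExtendEmbedding:
    def test_coincident_node_lands_on_landmark(self):
        X = np.array([[0, 0], [2, 0], [0, 2]], float)
        d = np.linalg.norm(X - X[1], axis=1)[:, None]
        y = uf.extend_embedding(X, d)
        np.testing.assert_allclose(y[0], X[1], atol=1e-9)

    def test_equidistant_node_at_centroid(self):
        ang = np.array([0, 2 * np.pi / 3, 4 * np.pi / 3])
        X = np.column_stack([np.cos(ang), np.sin(ang)])
        d = np.full((3, 1), 1.0)
        y = uf.extend_embedding(X, d)
        np.testing.assert_allclose(y[0], X.mean(axis=0), atol=1e-9)

    def test_reproduces_direct_mds(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(40, 2))
        D = np.linalg.norm(P[:, None] - P[None], axis=-1)
        lm = np.arange(10)
        Xlm = uf.classical_mds_embed(D[np.ix_(lm, lm)])
        Xall = uf.extend_embedding(Xlm, D[lm, :])
        Dhat = np.linalg.norm(Xall[:, None] - Xall[None], axis=-1)
        assert np.sqrt(((Dhat - D) ** 2).mean()) < 1e-6

    def test_collinear_landmarks_rejected(self):
        X = np.array([[0, 0], [1, 0], [2, 0]], float)
        with pytest.raises(uf.ConditioningError, match="collinear"):
            uf.extend_embedding(X, np.ones((3, 2)))


class TestRasterize:
    def test_single_voxel_single_pixel(self):
        fm = uf.rasterize_flatmap(np.zeros((1, 2)), 0.4, np.zeros(1),
                                  np.zeros((1, 3), int))
        assert len(fm.occupied_pixels()) == 1

    def test_every_voxel_in_exactly_one_pixel(self, c_sheet_phantom):
        vol, _ = c_sheet_phantom
        _, fm = measure_phantom(vol)
        assert fm.node_pixel.shape[0] == fm.n_nodes
        assert fm.node_pixel.min() >= 0
        assert fm.node_pixel.max() < fm.grid_shape[0] * fm.grid_shape[1]

    def test_slab_occupied_pixels_match_sheet_area(self, slab_phantom):
        vol, _ = slab_phantom
        _, fm = measure_phantom(vol)
        sheet_cols = (40 - 4) * (40 - 4)  # in-sheet columns incl. flanks
        assert len(fm.occupied_pixels()) == pytest.approx(sheet_cols, rel=0.10)

    def test_invalid_pixel_size(self):
        with pytest.raises(ValueError, match="pixel size"):
            uf.rasterize_flatmap(np.zeros((2, 2)), 0.0, np.zeros(2),
                                 np.zeros((2, 3), int))


class TestLabelProjection:
    def test_single_band_label_everywhere(self):
        spec = PhantomSpec("flat_slab", 2.0, (0.4, 0.4, 0.4), (24, 30, 30), 1, 0.0, 0)
        vol, _ = generate_phantom(spec)
        res, fm = measure_phantom(vol)
        labels2d = uf.project_subregion_labels(vol.labels, fm)
        present = set(np.unique(labels2d)) - {0}
        assert present == {SUBREGION_CODES[0]}

    def test_tie_broken_by_precedence(self):
        labels3d = np.zeros((4, 1, 1), np.int16)
        labels3d[0:2] = 11  # CA1
        labels3d[2:4] = 10  # CA23DG
        coords = np.zeros((4, 2))
        vox = np.argwhere(labels3d > 0)
        fm = uf.rasterize_flatmap(coords, 1.0, np.zeros(4), vox)
        out = uf.project_subregion_labels(labels3d, fm)
        assert out.ravel()[0] == 10  # CA23DG wins the 2-2 tie

    def test_seven_bands_contiguous_in_order(self, c_sheet_phantom):
        """Flat-map band regions keep the anatomical ordering along the sheet."""
        vol, _ = c_sheet_phantom
        _, fm = measure_phantom(vol)
        labels2d = uf.project_subregion_labels(vol.labels, fm)
        assert set(np.unique(labels2d)) - {0} == set(SUBREGION_CODES)
        # adjacency oracle: each band must touch its neighbours in the
        # fixed order and never a band two or more steps away
        from scipy import ndimage

        adj = set()
        for code in SUBREGION_CODES:
            grown = ndimage.binary_dilation(labels2d == code, iterations=2)
            for other in set(np.unique(labels2d[grown])) - {0, code}:
                adj.add(tuple(sorted((code, int(other)))))
        expected = {(c, c + 1) for c in SUBREGION_CODES[:-1]}
        assert adj == expected


class TestDistortion:
    def test_exact_euclidean_input(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(15, 2))
        D = np.linalg.norm(P[:, None] - P[None], axis=-1)
        stress, corr = uf.distortion_report(P, D)
        assert stress == pytest.approx(0.0, abs=1e-12)
        assert corr == pytest.approx(1.0, abs=1e-12)

    def test_shuffled_distances_uncorrelated(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(60, 2))
        D = np.linalg.norm(P[:, None] - P[None], axis=-1)
        perm = rng.permutation(60)
        _, corr = uf.distortion_report(P[perm], D)
        assert abs(corr) < 0.2

    def test_developable_sheet_low_stress(self, c_sheet_phantom):
        vol, _ = c_sheet_phantom
        _, fm = measure_phantom(vol)
        assert fm.stress1 <= 0.05
        assert fm.distance_correlation >= 0.99

    def test_too_few_nodes(self):
        with pytest.raises(ValueError, match="3 nodes"):
            uf.distortion_report(np.zeros((2, 2)), np.zeros((2, 2)))


class TestRotationInvariance:
    def test_quarter_turn_leaves_subregion_means_unchanged(self):
        """90-degree in-plane rotation of a slab leaves thickness means intact."""
        spec = PhantomSpec("flat_slab", 2.0, (0.4, 0.4, 0.4), (24, 30, 30), 2, 0.0, 4)
        vol, _ = generate_phantom(spec)
        res, _ = measure_phantom(vol, seed=0)
        from hippoflat.volume_io import TissueLabelVolume

        rot = TissueLabelVolume(np.rot90(vol.labels, axes=(1, 2)).copy(), vol.spacing_mm)
        res_rot, _ = measure_phantom(rot, seed=0)
        for name, v in res.subregion_mean_mm.items():
            if np.isfinite(v):
                assert res_rot.subregion_mean_mm[name] == pytest.approx(v, abs=1e-6)
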