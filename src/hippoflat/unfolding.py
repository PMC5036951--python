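"""Flatten the layered gray-matter manifold to a 2D map by metric MDS.

The gray-matter sheet is treated as a discrete manifold: a graph over GM
voxels with spacing-aware Euclidean edge weights.  Geodesic (shortest-path)
distances on this graph approximate intrinsic distances along the sheet.
Classical (metric) multidimensional scaling of the geodesic distance matrix
yields 2D flat-map coordinates; for tractability the eigendecomposition runs
on a landmark subset (farthest-point sampled) and the remaining voxels are
placed by least-squares trilateration against the landmarks.  Voxels are then
binned into flat-map pixels, so each pixel corresponds to a column of GM
voxels across layers; subregion boundaries drawn in 3D are projected into
flat-map space by per-pixel majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra

from .layering import LayerAssignment
from .volume_io import LABEL_GM, SUBREGION_CODES

_NEIGHBOR_OFFSETS = {
    "face": [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    "face+edge": [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    ],
    "face+edge+corner": [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
}


class NonEuclideanError(ValueError):
    """Raised when the MDS input is too non-Euclidean to embed in 2D."""


class ConditioningError(ValueError):
    """Raised for degenerate (e.g. collinear) landmark configurations."""


@dataclass
class ManifoldGraph:
    """Weighted voxel-adjacency graph of the assigned gray matter."""

    voxel_indices: np.ndarray      # (n, 3) int, grid coordinates of each node
    adjacency: sparse.csr_matrix   # (n, n) symmetric, weights in mm
    spacing_mm: tuple[float, float, float]

    @property
    def n_nodes(self) -> int:
        return self.voxel_indices.shape[0]


def build_manifold_graph(
    gm_mask: np.ndarray,
    layers: LayerAssignment | None,
    spacing_mm,
    connectivity: str = "face+edge+corner",
) -> ManifoldGraph:
    """Graph over assigned GM voxels with anisotropic Euclidean edge weights.

    ``layers`` restricts nodes to layer-assigned voxels (unreachable GM is
    excluded); pass None to use the full mask.
    """
    mask = np.asarray(gm_mask, bool)
    if layers is not None:
        mask = mask & layers.assigned_mask()
    if not mask.any():
        raise ValueError("empty gray-matter mask: no nodes to build a graph on")
    if connectivity not in _NEIGHBOR_OFFSETS:
        raise ValueError(f"unknown connectivity {connectivity!r}")

    spacing = np.asarray(spacing_mm, float)
    idx_vol = np.full(mask.shape, -1, dtype=np.int64)
    vox = np.argwhere(mask)
    idx_vol[mask] = np.arange(vox.shape[0])

    rows, cols, wts = [], [], []
    for off in _NEIGHBOR_OFFSETS[connectivity]:
        off = np.asarray(off)
        # voxels whose neighbour at +off is inside the grid
        lo = np.maximum(-off, 0)
        hi = np.array(mask.shape) - np.maximum(off, 0)
        src = vox[
            np.all((vox >= lo) & (vox < hi), axis=1)
        ]
        if src.size == 0:
            continue
        dst_idx = idx_vol[tuple((src + off).T)]
        keep = dst_idx >= 0
        src_idx = idx_vol[tuple(src[keep].T)]
        dst_idx = dst_idx[keep]
        w = float(np.linalg.norm(off * spacing))
        rows.append(src_idx)
        cols.append(dst_idx)
        wts.append(np.full(src_idx.shape, w))

    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        w = np.concatenate(wts)
        adj = sparse.coo_matrix((w, (r, c)), shape=(vox.shape[0],) * 2)
        adj = (adj + adj.T).tocsr()
    else:
        adj = sparse.csr_matrix((vox.shape[0],) * 2)

    return ManifoldGraph(voxel_indices=vox, adjacency=adj, spacing_mm=tuple(spacing))


def geodesic_distance_matrix(graph: ManifoldGraph, landmark_nodes) -> np.ndarray:
    """Shortest-path distances (mm) from each landmark node to every node."""
    landmarks = np.asarray(landmark_nodes, dtype=np.int64)
    if landmarks.size == 0:
        raise ValueError("no landmark nodes given")
    if landmarks.min() < 0 or landmarks.max() >= graph.n_nodes:
        raise ValueError("landmark index out of range")
    dist = dijkstra(graph.adjacency, directed=False, indices=landmarks)
    bad = ~np.isfinite(dist).all(axis=1)
    if bad.any():
        raise ValueError(
            f"graph disconnected from landmark node(s) {landmarks[bad].tolist()}"
        )
    return dist


def farthest_point_landmarks(graph: ManifoldGraph, n_landmarks: int, seed: int = 0):
    """Farthest-point sampling of landmark nodes.

    Starts from a seeded random node and greedily adds the node with maximal
    graph distance to the chosen set.  Returns (landmark_indices,
    distances_to_all) so the Dijkstra runs are reused for the embedding.
    """
    n = min(int(n_landmarks), graph.n_nodes)
    if n < 1:
        raise ValueError("need at least one landmark")
    rng = np.random.default_rng(seed)
    first = int(rng.integers(graph.n_nodes))
    chosen = [first]
    dist_rows = [dijkstra(graph.adjacency, directed=False, indices=first)]
    min_dist = dist_rows[0].copy()
    for _ in range(n - 1):
        nxt = int(np.argmax(np.where(np.isfinite(min_dist), min_dist, -np.inf)))
        if nxt in chosen:
            break
        chosen.append(nxt)
        row = dijkstra(graph.adjacency, directed=False, indices=nxt)
        dist_rows.append(row)
        min_dist = np.minimum(min_dist, row)
    dist = np.vstack(dist_rows)
    if not np.isfinite(dist).all():
        raise ValueError("graph is disconnected; cannot landmark-sample all of it")
    return np.asarray(chosen, dtype=np.int64), dist


def classical_mds_embed(distance_matrix: np.ndarray, target_dim: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric MDS.

    Double-centers the squared-distance matrix, takes the top ``target_dim``
    eigenpairs and scales eigenvectors by square-rooted eigenvalues.  The
    orientation is made deterministic: axes ordered by eigenvalue, sign of
    each axis fixed so the first node with a nonzero coordinate on that axis
    has a positive one.
    """
    D = np.asarray(distance_matrix, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12) or np.any(D < 0):
        raise ValueError("distance matrix must be nonnegative with zero diagonal")
    m = D.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    top = evals[order[:target_dim]]
    # the discarded negative part must stay small relative to the retained
    # axes: a negative eigenvalue rivalling the 2nd axis means the metric has
    # no faithful 2D Euclidean representation
    neg = float(max(0.0, -evals.min()))
    if top[0] <= 0 or neg > max(top[-1], 1e-8 * top[0]):
        raise NonEuclideanError(
            "distance matrix is non-Euclidean beyond tolerance: "
            f"top eigenvalues {evals[order[:max(target_dim, 2)]].tolist()}, "
            f"most negative {evals[order[-1]]:.6g}"
        )
    top = np.clip(top, 0.0, None)
    coords = evecs[:, order[:target_dim]] * np.sqrt(top)
    # deterministic sign per axis
    for d in range(coords.shape[1]):
        col = coords[:, d]
        nz = np.flatnonzero(np.abs(col) > 1e-12 * (np.abs(col).max() or 1.0))
        if nz.size and col[nz[0]] < 0:
            coords[:, d] = -col
    return coords


def extend_embedding(
    landmark_coords: np.ndarray, node_to_landmark_distances: np.ndarray
) -> np.ndarray:
    """Place non-landmark nodes by least-squares trilateration.

    Given landmark flat-map coordinates ``x_j`` and each node's geodesic
    distances ``d_j`` to the landmarks, solves the linearised multilateration
    system obtained by differencing the squared-distance equations against
    their mean:  ``-2 (x_j - x̄)ᵀ y = (d_j² - ‖x_j‖²) - mean_j(...)``.
    Exact for distances consistent with a planar configuration.
    """
    X = np.asarray(landmark_coords, float)
    D = np.asarray(node_to_landmark_distances, float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ConditioningError("need at least 3 landmarks")
    if D.shape[0] != X.shape[0]:
        raise ValueError("distance rows must correspond to landmarks")
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc, tol=1e-9 * max(1.0, np.abs(Xc).max())) < X.shape[1]:
        raise ConditioningError("landmarks are collinear; trilateration is ill-conditioned")
    A = -2.0 * Xc
    B = (D ** 2) - (X ** 2).sum(axis=1)[:, None]
    B = B - B.mean(axis=0)
    sol, *_ = np.linalg.lstsq(A, B, rcond=None)
    return sol.T


@dataclass
class FlatMap:
    """Mapping of GM voxels to 2D flat-map coordinates and raster pixels."""

    voxel_indices: np.ndarray      # (n, 3) grid coordinates
    node_coords: np.ndarray        # (n, 2) flat-map coordinates, mm
    node_layer: np.ndarray         # (n,) layer index
    pixel_size_mm: float
    origin: np.ndarray             # (2,) lower corner of the pixel grid, mm
    grid_shape: tuple[int, int]
    node_pixel: np.ndarray         # (n,) flat pixel id = u * ncols + v
    stress1: float | None = None
    distance_correlation: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.voxel_indices.shape[0]

    def occupied_pixels(self) -> np.ndarray:
        return np.unique(self.node_pixel)

    def pixel_reduce_max(self, node_values: np.ndarray) -> np.ndarray:
        """Per-pixel max of a per-node value; NaN on empty pixels."""
        out = np.full(self.grid_shape[0] * self.grid_shape[1], -np.inf)
        np.maximum.at(out, self.node_pixel, np.asarray(node_values, float))
        out[np.isinf(out)] = np.nan
        return out.reshape(self.grid_shape)


def rasterize_flatmap(
    coords: np.ndarray,
    pixel_size_mm: float,
    layers: np.ndarray,
    voxel_indices: np.ndarray,
) -> FlatMap:
    """Bin flat-map coordinates into a pixel raster covering their bounding box.

    Every mapped voxel lands in exactly one pixel; a pixel aggregates the
    column of contributing 3D voxels across all layers.
    """
    coords = np.asarray(coords, float)
    if not np.isfinite(coords).all():
        raise ValueError("non-finite flat-map coordinates")
    if pixel_size_mm <= 0:
        raise ValueError(f"pixel size must be positive, got {pixel_size_mm}")
    origin = coords.min(axis=0)
    span = coords.max(axis=0) - origin
    shape = tuple(int(np.floor(s / pixel_size_mm)) + 1 for s in span)
    uv = np.floor((coords - origin) / pixel_size_mm).astype(np.int64)
    uv = np.minimum(uv, np.asarray(shape) - 1)
    pix = uv[:, 0] * shape[1] + uv[:, 1]
    return FlatMap(
        voxel_indices=np.asarray(voxel_indices),
        node_coords=coords,
        node_layer=np.asarray(layers),
        pixel_size_mm=float(pixel_size_mm),
        origin=origin,
        grid_shape=shape,
        node_pixel=pix,
    )


def project_subregion_labels(labels3d: np.ndarray, flatmap: FlatMap) -> np.ndarray:
    """Project 3D subregion labels to a 2D label raster by per-pixel majority.

    Ties are broken by the fixed anatomical precedence
    CA23DG > CA1 > SUB > ERC > PRC > PHC > FUS (ascending label code).
    Voxels carrying the plain-GM code do not vote; a pixel whose column is
    entirely unlabeled stays 0.
    """
    node_labels = np.asarray(labels3d)[tuple(flatmap.voxel_indices.T)]
    npix = flatmap.grid_shape[0] * flatmap.grid_shape[1]
    counts = np.zeros((len(SUBREGION_CODES), npix), dtype=np.int64)
    for i, code in enumerate(SUBREGION_CODES):
        sel = node_labels == code
        if sel.any():
            np.add.at(counts[i], flatmap.node_pixel[sel], 1)
    any_vote = counts.sum(axis=0) > 0
    # argmax returns the first (lowest-code) maximum: the stated tie rule
    winner = np.argmax(counts, axis=0)
    out = np.zeros(npix, dtype=np.int16)
    out[any_vote] = np.asarray(SUBREGION_CODES, dtype=np.int16)[winner[any_vote]]
    return out.reshape(flatmap.grid_shape)


def distortion_report(
    embedded_coords: np.ndarray, geodesic_distances: np.ndarray
) -> tuple[float, float]:
    """Stress-1 and Pearson correlation between geodesic and embedded distances.

    Computed over all unordered pairs of the supplied nodes (typically the
    landmark set).  Stress-1 is ``sqrt(Σ(d_g - d_e)² / Σ d_g²)``; 0 means a
    perfect metric embedding.
    """
    X = np.asarray(embedded_coords, float)
    Dg = np.asarray(geodesic_distances, float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 nodes for a distortion report")
    iu = np.triu_indices(X.shape[0], k=1)
    de = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)[iu]
    dg = Dg[iu]
    stress1 = float(np.sqrt(np.sum((dg - de) ** 2) / np.sum(dg ** 2)))
    corr = float(np.corrcoef(dg, de)[0, 1])
    return stress1, corr


def unfold(
    gm_mask: np.ndarray,
    layers: LayerAssignment,
    spacing_mm,
    n_landmarks: int = 500,
    geodesic_connectivity: str = "face+edge+corner",
    pixel_size_mm: float = 0.4,
    seed: int = 0,
) -> FlatMap:
    """Full flattening: graph → landmarks → geodesics → MDS → extension → raster.

    Landmark MDS keeps the eigenproblem small; all other assigned GM voxels
    are placed by trilateration against the landmark embedding.  Distortion
    diagnostics (over landmark pairs) are stored on the returned FlatMap.
    """
    graph = build_manifold_graph(gm_mask, layers, spacing_mm, geodesic_connectivity)
    lm, dist = farthest_point_landmarks(graph, n_landmarks, seed=seed)
    lm_coords = classical_mds_embed(dist[:, lm], target_dim=2)
    if lm.size >= 3:
        coords = extend_embedding(lm_coords, dist)
        coords[lm] = lm_coords
    else:
        coords = lm_coords  # degenerate tiny graphs: landmarks are all nodes
    stress1, corr = distortion_report(lm_coords, dist[:, lm])
    node_layers = layers.layer_index[tuple(graph.voxel_indices.T)]
    fm = rasterize_flatmap(coords, pixel_size_mm, node_layers, graph.voxel_indices)
    fm.stress1 = stress1
    fm.distance_correlation = corr
    return fm
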