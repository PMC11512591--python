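"""Spatial neighborhood graph over all spots of all slices.

Within a slice, spots are connected by K-nearest-neighbor (or fixed-radius)
edges on physical coordinates; across slices, by mutual-nearest-neighbor
(MNN) edges on expression.  The union is one symmetric 0/1 adjacency matrix
A over global spot indices, the support of the Potts label prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .data_io import MultiSliceDataset, PLATFORM_GRAPH_DEFAULTS, ValidationError

logger = logging.getLogger(__name__)

#: Graph defaults: spatial KNN for ST (K=4) and Visium (K=6), radius 50 for
#: Slide-seqV2 bead arrays, and K=2 for cross-slice expression MNN pairs.
DEFAULT_K_ST = 4
DEFAULT_K_VISIUM = 6
DEFAULT_RADIUS_SLIDESEQ = 50.0
DEFAULT_K_MNN = 2
MNN_N_PCS = 50


@dataclass
class NeighborGraph:
    """Symmetric unweighted adjacency with per-edge provenance.

    ``intra_edges`` never cross batches; ``inter_edges`` never stay within
    one.  ``adjacency`` is CSR with zero diagonal.
    """

    n: int
    intra_edges: set[tuple[int, int]]
    inter_edges: set[tuple[int, int]]
    adjacency: sp.csr_matrix

    @property
    def edges(self) -> set[tuple[int, int]]:
        return self.intra_edges | self.inter_edges

    def neighbor_lists(self) -> tuple[np.ndarray, np.ndarray]:
        """(indptr, indices) arrays of the CSR adjacency."""
        return self.adjacency.indptr, self.adjacency.indices


def _edges_to_adjacency(n: int, edges: set[tuple[int, int]]) -> sp.csr_matrix:
    if not edges:
        return sp.csr_matrix((n, n))
    rows, cols = zip(*edges)
    rows, cols = np.array(rows), np.array(cols)
    data = np.ones(2 * len(edges))
    A = sp.coo_matrix(
        (data, (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()
    A.data[:] = 1.0  # duplicates collapse to 1
    return A


def _canon(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def knn_edges(coords: np.ndarray, K: int) -> set[tuple[int, int]]:
    """Symmetrized K-nearest-neighbor edges under Euclidean distance.

    The directed KNN relation is symmetrized by union.  Distance ties break
    toward the lower spot index; self-neighbors are excluded.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if K < 1:
        raise ValidationError("K must be >= 1")
    if n < 2:
        logger.warning("knn_edges: fewer than 2 spots, empty edge set")
        return set()
    k_eff = min(K, n - 1)
    # lexicographic (distance, index) ordering makes tie-breaks deterministic
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1) if n <= 2048 else None
    edges: set[tuple[int, int]] = set()
    if d2 is not None:
        np.fill_diagonal(d2, np.inf)
        for i in range(n):
            order = np.lexsort((np.arange(n), d2[i]))
            for j in order[:k_eff]:
                edges.add(_canon(i, int(j)))
    else:
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(coords)
        _, idx = nn.kneighbors(coords)
        for i in range(n):
            for j in idx[i]:
                if j != i:
                    edges.add(_canon(i, int(j)))
        # trim possible extra neighbor when self not returned first
        # (kneighbors returns k_eff+1 including self except under exact ties)
    return edges


def radius_edges(coords: np.ndarray, r: float) -> set[tuple[int, int]]:
    """Edges between all pairs strictly closer than ``r``."""
    if r <= 0:
        raise ValidationError("radius must be positive")
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    nn = NearestNeighbors(radius=r).fit(coords)
    neigh = nn.radius_neighbors(coords, return_distance=True)
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        dists, idx = neigh[0][i], neigh[1][i]
        for dist, j in zip(dists, idx):
            if j != i and dist < r:  # strict inequality at the boundary
                edges.add(_canon(i, int(j)))
    return edges


def mnn_edges(
    expr_a: np.ndarray, expr_b: np.ndarray, K: int = DEFAULT_K_MNN
) -> set[tuple[int, int]]:
    """Mutual nearest neighbors between two expression matrices.

    Edge (i, j) iff j is among the K nearest rows of ``expr_b`` to row i of
    ``expr_a`` *and* vice versa, in Euclidean distance of the supplied
    representation.  Indices are local to each matrix.
    """
    expr_a = np.asarray(expr_a, float)
    expr_b = np.asarray(expr_b, float)
    if expr_a.shape[1] != expr_b.shape[1]:
        raise ValidationError(
            f"feature mismatch: {expr_a.shape[1]} vs {expr_b.shape[1]} columns"
        )
    if K < 1:
        raise ValidationError("K must be >= 1")
    ka = min(K, expr_b.shape[0])
    kb = min(K, expr_a.shape[0])
    nn_b = NearestNeighbors(n_neighbors=ka).fit(expr_b)
    _, a_to_b = nn_b.kneighbors(expr_a)
    nn_a = NearestNeighbors(n_neighbors=kb).fit(expr_a)
    _, b_to_a = nn_a.kneighbors(expr_b)
    b_sets = [set(row) for row in b_to_a]
    edges = set()
    for i in range(expr_a.shape[0]):
        for j in a_to_b[i]:
            if i in b_sets[j]:
                edges.add((i, int(j)))
    return edges


def _pair_pca(expr_a: np.ndarray, expr_b: np.ndarray, n_pcs: int) -> tuple[np.ndarray, np.ndarray]:
    """Joint principal components of a slice pair for expression MNN.

    Full-dimensional Euclidean KNN on thousands of genes is noise-dominated;
    a joint low-rank basis is the standard representation for MNN matching.
    """
    X = np.vstack([expr_a, expr_b])
    X = X - X.mean(axis=0)
    k = min(n_pcs, min(X.shape) - 1)
    if k < 1:
        return expr_a, expr_b
    # deterministic truncated SVD
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * s[:k]
    return scores[: expr_a.shape[0]], scores[expr_a.shape[0]:]


def assemble_adjacency(
    dataset: MultiSliceDataset,
    intra_cfg: dict | None = None,
    inter_cfg: dict | None = None,
) -> NeighborGraph:
    """Build the combined graph: per-slice spatial edges plus all pairwise
    cross-slice MNN edges, mapped to global spot indices.

    ``intra_cfg`` overrides the per-platform defaults (keys ``method``,
    ``K``, ``r``); ``inter_cfg`` takes ``K`` and ``n_pcs``.
    """
    inter_cfg = dict(inter_cfg or {})
    k_mnn = int(inter_cfg.get("K", DEFAULT_K_MNN))
    n_pcs = int(inter_cfg.get("n_pcs", MNN_N_PCS))

    offsets = np.cumsum([0] + [s.n_spots for s in dataset.slices])
    intra: set[tuple[int, int]] = set()
    for b, s in enumerate(dataset.slices):
        cfg = dict(PLATFORM_GRAPH_DEFAULTS[s.platform])
        cfg.update(intra_cfg or {})
        if cfg["method"] == "knn":
            e = knn_edges(s.coords, int(cfg["K"]))
        elif cfg["method"] == "radius":
            e = radius_edges(s.coords, float(cfg["r"]))
        else:
            raise ValidationError(f"unknown intra-slice method {cfg['method']!r}")
        if not e and s.n_spots > 1:
            logger.warning("slice %s produced no spatial edges", s.batch_id)
        off = offsets[b]
        intra |= {(i + off, j + off) for i, j in e}

    inter: set[tuple[int, int]] = set()
    B = len(dataset.slices)
    for a in range(B):
        for b in range(a + 1, B):
            ea, eb = dataset.slices[a].expr, dataset.slices[b].expr
            if ea is None or eb is None:
                raise ValidationError("assemble_adjacency needs normalized expression")
            ra, rb = _pair_pca(ea, eb, n_pcs)
            pairs = mnn_edges(ra, rb, k_mnn)
            if not pairs:
                logger.warning(
                    "no MNN pairs between slices %s and %s",
                    dataset.slices[a].batch_id,
                    dataset.slices[b].batch_id,
                )
            inter |= {
                _canon(i + offsets[a], j + offsets[b]) for i, j in pairs
            }

    n = dataset.n_total
    A = _edges_to_adjacency(n, intra | inter)
    deg = np.asarray(A.sum(axis=1)).ravel()
    batch = dataset.batch_of_spot()
    for b in range(B):
        logger.info(
            "batch %s: mean degree %.2f", dataset.slices[b].batch_id, deg[batch == b].mean()
        )
    return NeighborGraph(n=n, intra_edges=intra, inter_edges=inter, adjacency=A)
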