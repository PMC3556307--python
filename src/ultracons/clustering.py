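"""Similarity graph, Markov clustering, and minimum-curvilinear embedding.

UCRs (with flanks) are related pairwise by local-alignment score
density (bit-score per alignment column, best of both strands); edges
are gated on E-value.  The graph is partitioned with Markov clustering
(MCL): a column-stochastic walk matrix with self-loops is alternately
squared (expansion) and entrywise powered + renormalized (inflation)
until it converges to a union of attractor systems, which are read out
as clusters.

For visualization, each sequence is summarized by its 5-mer composition
and embedded by non-centered Minimum Curvilinear Embedding (MCE): the
pairwise-distance matrix is replaced by geodesic distances along the
minimum spanning tree (the minimum curvilinear kernel), which is then
decomposed by SVD *without centering*; coordinates are the top singular
vectors scaled by the square roots of their singular values.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree

from .align import best_strand_align
from .io import encode_dna

DEFAULT_INFLATION = 2.0
DEFAULT_PRUNE = 1e-5
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 200
DEFAULT_MAX_E = 1e-5


@dataclasses.dataclass(frozen=True)
class Cluster:
    cluster_id: int
    member_ids: tuple[str, ...]
    species_composition: Mapping[str, int]

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclasses.dataclass(frozen=True)
class EmbeddingResult:
    ids: tuple[str, ...]
    coordinates: np.ndarray  # n x d
    singular_values: np.ndarray  # nonincreasing


def build_graph(
    sequences: Mapping[str, str],
    min_density: float | None = None,
    max_e: float = DEFAULT_MAX_E,
    **align_kwargs,
) -> nx.Graph:
    """Weighted similarity graph over sequences.

    Every sequence is a node.  An edge is added when the best-strand
    local alignment reaches E-value <= max_e (and score density >=
    min_density when given); its weight is the score density.
    """
    if not sequences:
        raise ValueError("at least one sequence required")
    graph = nx.Graph()
    ids = list(sequences)
    graph.add_nodes_from(ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            res = best_strand_align(sequences[ids[i]], sequences[ids[j]], **align_kwargs)
            if res.e_value > max_e:
                continue
            density = res.score_density
            if min_density is not None and density < min_density:
                continue
            graph.add_edge(ids[i], ids[j], weight=density,
                           bit_score=res.bit_score,
                           alignment_length=res.alignment_length,
                           e_value=res.e_value)
    return graph


def mcl(
    graph: nx.Graph,
    inflation: float = DEFAULT_INFLATION,
    prune: float = DEFAULT_PRUNE,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    species_of: Mapping[str, str] | None = None,
) -> list[Cluster]:
    """Markov clustering of a weighted undirected graph.

    Self-loop weight is each node's maximum incident edge weight
    (1.0 for isolated nodes), the classic regularization that keeps the
    walk from oscillating.  Returns a partition of the node set; nodes
    attracted to several attractor systems go to the lowest-indexed
    cluster.  Non-convergence raises a warning and returns the current
    interpretation.
    """
    nodes = list(graph.nodes)
    if not nodes:
        raise ValueError("empty graph")
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        M[index[u], index[v]] = w
        M[index[v], index[u]] = w
    loop = M.max(axis=0)
    loop[loop <= 0] = 1.0
    M[np.diag_indices(n)] = loop
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = M**inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter; interpreting anyway")

    # clusters = weakly connected components of the nonzero structure
    comp = nx.Graph()
    comp.add_nodes_from(range(n))
    rows, cols = np.nonzero(M)
    comp.add_edges_from(zip(rows.tolist(), cols.tolist()))
    groups = sorted(
        (sorted(c) for c in nx.connected_components(comp)), key=lambda c: c[0]
    )
    clusters = []
    for cid, members in enumerate(groups):
        ids = tuple(nodes[i] for i in members)
        composition: dict[str, int] = {}
        if species_of:
            for m in ids:
                sp = species_of[m]
                composition[sp] = composition.get(sp, 0) + 1
        clusters.append(Cluster(cid, ids, composition))
    return clusters


def kmer_profile(sequence: str, k: int = 5) -> np.ndarray:
    """Normalized forward-strand k-mer frequency vector (length 4^k).

    Windows containing a non-ACGT symbol are skipped.  If no window is
    valid the zero vector is returned with a warning.
    """
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    s = encode_dna(sequence).astype(np.int64)
    n = len(sequence) - k + 1
    valid = s != 255
    window_valid = np.ones(n, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    for off in range(k):
        window_valid &= valid[off : off + n]
        codes = codes * 4 + np.where(valid[off : off + n], s[off : off + n], 0)
    counts = np.bincount(codes[window_valid], minlength=4**k).astype(float)
    total = counts.sum()
    if total == 0:
        warnings.warn("no valid k-mer window; returning zero profile")
        return counts
    return counts / total


def mst_geodesic_kernel(profiles: np.ndarray) -> np.ndarray:
    """Minimum curvilinear kernel: MST geodesic distances between rows."""
    from scipy.spatial.distance import squareform, pdist
    from scipy.sparse.csgraph import shortest_path

    dist = squareform(pdist(profiles, metric="euclidean"))
    mst = minimum_spanning_tree(csr_matrix(dist))
    kernel = shortest_path(mst, method="D", directed=False)
    return np.asarray(kernel)


def mce_embed(profiles: np.ndarray, d: int = 3, ids: Sequence[str] | None = None) -> EmbeddingResult:
    """Non-centered MCE of row-vector profiles into d dimensions."""
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    if n < 2:
        raise ValueError("need at least 2 profiles")
    if d > n:
        raise ValueError(f"d={d} exceeds number of samples {n}")
    kernel = mst_geodesic_kernel(profiles)
    u, s, _ = np.linalg.svd(kernel)  # no centering of the kernel
    coords = u[:, :d] * np.sqrt(s[:d])
    if ids is None:
        ids = tuple(str(i) for i in range(n))
    return EmbeddingResult(tuple(ids), coords, s)
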