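"""JTT maximum-likelihood distances, neighbor-joining, and bootstrap.

Pairwise distances between aligned protein sequences are
maximum-likelihood estimates under the JTT model: columns where either
sequence has a gap or ambiguous residue are dropped for that pair
(pairwise deletion), and t-hat maximizes sum over sites of
log(pi_a * P(a->b | t)) by bounded 1-D optimization on [0, t_max].
Rates are uniform across sites.

Trees are built with the Saitou–Nei neighbor-joining algorithm
(Q-criterion, ties broken by the lowest taxon-index pair).  Negative
branch-length estimates are clamped to zero with the excess moved to
the sibling branch.  Bootstrap support resamples supermatrix columns
with replacement and reports, per internal edge of the full-data tree,
the percentage of replicates whose NJ tree contains the same
bipartition.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from . import jtt
from ._seeds import stage_rng

DEFAULT_T_MAX = 10.0


@dataclasses.dataclass
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")


@dataclasses.dataclass
class TreeNode:
    name: str | None = None
    children: list["tuple[TreeNode, float]"] = dataclasses.field(default_factory=list)
    support: int | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self, length: float | None = None) -> str:
        if self.is_leaf():
            body = self.name
        else:
            inner = ",".join(c._newick_inner(bl) for c, bl in self.children)
            label = "" if self.support is None else str(self.support)
            body = f"({inner}){label}"
        if length is None:
            return body
        return f"{body}:{length:.6f}"


def pair_count_matrix(seq_a: str, seq_b: str) -> np.ndarray:
    """20x20 matrix of aligned residue-pair counts (pairwise deletion)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    a = jtt.encode_protein(seq_a)
    b = jtt.encode_protein(seq_b)
    ok = (a >= 0) & (b >= 0)
    if not ok.any():
        raise ValueError("no comparable columns between sequences")
    codes = a[ok] * 20 + b[ok]
    return np.bincount(codes, minlength=400).reshape(20, 20).astype(float)


def ml_distance_from_counts(
    counts: np.ndarray, t_max: float = DEFAULT_T_MAX
) -> float:
    """JTT ML distance for a residue-pair count matrix."""
    log_pi = np.log(jtt.EQUILIBRIUM)

    def neg_loglik(t: float) -> float:
        p = jtt.transition_matrix(t)
        with np.errstate(divide="ignore"):
            ll = np.log(np.where(p > 0, p, 1e-300)) + log_pi[:, None]
        return -float((counts * ll).sum())

    off_diagonal = counts.sum() - np.trace(counts)
    if off_diagonal == 0:
        return 0.0
    res = minimize_scalar(
        neg_loglik, bounds=(0.0, t_max), method="bounded",
        options={"xatol": 1e-8},
    )
    t_hat = float(res.x)
    if t_hat > t_max - 1e-3:
        warnings.warn("distance at saturation bound t_max; returning t_max")
        return t_max
    return t_hat


def jtt_distance(aligned_a: str, aligned_b: str, t_max: float = DEFAULT_T_MAX) -> float:
    """ML substitutions/site between two aligned protein sequences."""
    return ml_distance_from_counts(pair_count_matrix(aligned_a, aligned_b), t_max)


def distance_matrix(
    alignment: Mapping[str, str], t_max: float = DEFAULT_T_MAX
) -> DistanceMatrix:
    taxa = tuple(sorted(alignment))
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jtt_distance(
                alignment[taxa[i]], alignment[taxa[j]], t_max
            )
    return DistanceMatrix(taxa, d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor-joining; unrooted tree via a trifurcating root."""
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, None)
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] < best[0]:
                    best = (q[i, j], (i, j))
        i, j = best[1]
        vi = 0.5 * sub[i, j] + (totals[i] - totals[j]) / (2 * (m - 2))
        vj = sub[i, j] - vi
        if vi < 0:
            vj += -vi
            vi = 0.0
        if vj < 0:
            vi += -vj
            vj = 0.0
        gi, gj = active[i], active[j]
        parent = TreeNode(children=[(nodes[gi], vi), (nodes[gj], vj)])
        nodes.append(parent)
        new_idx = len(nodes) - 1
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in range(m):
            gk = active[k]
            if gk in (gi, gj):
                continue
            dist = 0.5 * (sub[i, k] + sub[j, k] - sub[i, j])
            d[new_idx, gk] = d[gk, new_idx] = max(dist, 0.0)
        active = [g for g in active if g not in (gi, gj)] + [new_idx]

    (ga, gb, gc) = active
    dab, dac, dbc = d[ga, gb], d[ga, gc], d[gb, gc]
    va = max(0.0, (dab + dac - dbc) / 2)
    vb = max(0.0, (dab + dbc - dac) / 2)
    vc = max(0.0, (dac + dbc - dab) / 2)
    return TreeNode(children=[(nodes[ga], va), (nodes[gb], vb), (nodes[gc], vc)])


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each as the smaller-or-canonical side."""
    all_leaves = frozenset(tree.leaves())
    parts: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            sub = walk(child)
            if 1 < len(sub) < len(all_leaves) - 1:
                parts.add(_canonical(sub, all_leaves))
            below = below | sub
        return below

    walk(tree)
    return parts


def _canonical(side: frozenset[str], universe: frozenset[str]) -> frozenset[str]:
    other = universe - side
    return min(side, other, key=lambda s: (len(s), sorted(s)))


def path_metric(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    leaves = sorted(tree.leaves())
    index = {t: i for i, t in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n))

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf():
            return {node.name: 0.0}
        acc: dict[str, float] = {}
        groups = []
        for child, bl in node.children:
            sub = {k: v + bl for k, v in walk(child).items()}
            groups.append(sub)
            acc.update(sub)
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for la, va in groups[gi].items():
                    for lb, vb in groups[gj].items():
                        d[index[la], index[lb]] = d[index[lb], index[la]] = va + vb
        return acc

    walk(tree)
    return DistanceMatrix(tuple(leaves), d)


def _concat_supermatrix(
    families: Sequence[Mapping[str, str]],
) -> dict[str, str]:
    taxa = sorted(families[0])
    for fam in families:
        if sorted(fam) != taxa:
            raise ValueError("all families must cover the same taxa")
    return {t: "".join(fam[t] for fam in families) for t in taxa}


def bootstrap_support(
    families: Sequence[Mapping[str, str]],
    n_reps: int = 500,
    seed: int = 0,
    t_max: float = DEFAULT_T_MAX,
) -> TreeNode:
    """NJ tree from the concatenated supermatrix with bootstrap support.

    Each replicate resamples alignment columns with replacement,
    recomputes all pairwise JTT distances and the NJ tree; an internal
    edge's support is the percentage of replicates containing its
    bipartition.  Deterministic for a fixed seed regardless of family
    input order (families are concatenated in sorted-taxon order and
    replicate seeds are drawn from one named stream).
    """
    if not families:
        raise ValueError("at least one family required")
    supermatrix = _concat_supermatrix(families)
    taxa = tuple(sorted(supermatrix))
    coded = {t: jtt.encode_protein(supermatrix[t]) for t in taxa}
    n_sites = len(next(iter(supermatrix.values())))

    def tree_from_weights(weights: np.ndarray) -> TreeNode:
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                a, b = coded[taxa[i]], coded[taxa[j]]
                ok = (a >= 0) & (b >= 0)
                codes = a[ok] * 20 + b[ok]
                counts = np.bincount(
                    codes, weights=weights[ok], minlength=400
                ).reshape(20, 20)
                d[i, j] = d[j, i] = ml_distance_from_counts(counts, t_max)
        return neighbor_joining(DistanceMatrix(taxa, d))

    base_tree = tree_from_weights(np.ones(n_sites))
    base_parts = tree_bipartitions(base_tree)
    hits = {part: 0 for part in base_parts}
    rng = stage_rng(seed, "bootstrap")
    for _ in range(n_reps):
        idx = rng.integers(0, n_sites, size=n_sites)
        weights = np.bincount(idx, minlength=n_sites).astype(float)
        rep_parts = tree_bipartitions(tree_from_weights(weights))
        for part in base_parts & rep_parts:
            hits[part] += 1

    universe = frozenset(taxa)

    def annotate(node: TreeNode, seen_root: bool) -> None:
        for child, _ in node.children:
            if not child.is_leaf():
                side = frozenset(child.leaves())
                if 1 < len(side) < len(universe) - 1:
                    part = _canonical(side, universe)
                    child.support = round(100 * hits[part] / n_reps)
            annotate(child, False)

    annotate(base_tree, True)
    return base_tree
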