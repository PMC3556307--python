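"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by a different route than the
implementation (quadratic dynamic programming, exhaustive enumeration,
a different library) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

from ultracons.io import encode_dna, revcomp


def mem_oracle(seq_a: str, seq_b: str, min_length: int):
    """All maximal exact matches >= min_length, by quadratic DP.

    Returns a set of (start_a, start_b, length, strand) with start_b on
    the forward strand of seq_b.
    """
    out = set()
    a = encode_dna(seq_a).astype(np.int64)

    def one_strand(bseq: str, strand: str):
        b = encode_dna(bseq).astype(np.int64)
        n, m = a.size, b.size
        prev = np.zeros(m, dtype=np.int64)
        for i in range(n):
            eq = (b == a[i]) & (b != 255) & (a[i] != 255)
            run = np.where(eq, 1, 0)
            run[1:] += np.where(eq[1:], prev[:-1], 0)
            # right-maximal at (i, j) if next chars differ or at an end
            if i + 1 < n:
                nxt_eq = np.zeros(m, dtype=bool)
                nxt_eq[:-1] = (b[1:] == a[i + 1]) & (b[1:] != 255) & (a[i + 1] != 255)
            else:
                nxt_eq = np.zeros(m, dtype=bool)
            for j in np.flatnonzero((run >= min_length) & ~nxt_eq):
                ell = int(run[j])
                sa_, sb_ = i - ell + 1, j - ell + 1
                # left-maximal?
                if sa_ > 0 and sb_ > 0 and seq_a[sa_ - 1] == bseq[sb_ - 1] \
                        and seq_a[sa_ - 1] in "ACGT":
                    continue
                if strand == "+":
                    out.add((sa_, sb_, ell, "+"))
                else:
                    out.add((sa_, len(bseq) - sb_ - ell, ell, "-"))
            prev = run
    one_strand(seq_b, "+")
    one_strand(revcomp(seq_b), "-")
    return out


def tandem_oracle(sequence: str, max_period: int, min_copies: float, min_span: int):
    """Quadratic scan over all (start, period) pairs; same output contract
    as the implementation (maximal intervals, containment-filtered)."""
    n = len(sequence)
    candidates = set()
    for p in range(1, max_period + 1):
        i = 0
        while i + p < n:
            if sequence[i] == sequence[i + p] and sequence[i] in "ACGT":
                j = i
                while (
                    j + p < n
                    and sequence[j] == sequence[j + p]
                    and sequence[j] in "ACGT"
                ):
                    j += 1
                span = (j - i) + p
                if span >= min_span and span / p >= min_copies:
                    candidates.add((i, j + p))
                i = j + 1
            else:
                i += 1
    final = []
    max_end = -1
    for a, b in sorted(candidates, key=lambda iv: (iv[0], -iv[1])):
        if b > max_end:
            final.append((a, b))
            max_end = b
    return set(final)


def entropy_window_oracle(sequence: str, window: int, threshold: float):
    """Per-position masked flags by direct window-entropy recomputation."""
    n = len(sequence)
    masked = np.zeros(n, dtype=bool)
    for i in range(n - window + 1):
        win = sequence[i : i + window]
        counts = [win.count(b) for b in "ACGT"]
        total = sum(counts)
        ent = 0.0
        for c in counts:
            if c and total:
                p = c / total
                ent -= p * np.log2(p)
        if ent < threshold:
            masked[i : i + window] = True
    return masked


def hypergeom_enum_oracle(G: int, g: int, D: int, d: int) -> float:
    """P(X >= d) by exhaustive enumeration of all C(G, g) draws."""
    total = 0
    hits = 0
    pool = [1] * D + [0] * (G - D)
    for draw in itertools.combinations(range(G), g):
        total += 1
        if sum(pool[i] for i in draw) >= d:
            hits += 1
    return hits / total


def binomial_enum_oracle(x: int, n: int, p: float) -> float:
    """P(X >= x) by summing the full outcome tree (2^n paths weighted)."""
    prob = 0.0
    for successes in range(x, n + 1):
        prob += comb(n, successes) * p**successes * (1 - p) ** (n - successes)
    return prob


def mst_geodesic_oracle(profiles: np.ndarray) -> np.ndarray:
    """Kruskal MST (networkx) + Dijkstra geodesics (networkx)."""
    import networkx as nx

    n = profiles.shape[0]
    g = nx.Graph()
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=float(np.linalg.norm(profiles[i] - profiles[j])))
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    kernel = np.zeros((n, n))
    lengths = dict(nx.all_pairs_dijkstra_path_length(mst))
    for i in range(n):
        for j in range(n):
            kernel[i, j] = lengths[i][j]
    return kernel
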