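"""Smith–Waterman local alignment with BLAST-style bit-scores.

Scoring follows classic blastn conventions: match +2, mismatch -3, and
affine gaps costing open + extend * length (defaults 5 + 2L).  Raw
scores are converted to bit-scores with Karlin–Altschul parameters
(bit = (lambda * raw - ln K) / ln 2) and to E-values as m * n * 2^-bit.
The score density — bit-score divided by alignment length (columns of
the optimal local alignment, gaps included) — is the similarity measure
used for clustering.

The DP is row-vectorized in numpy; the horizontal affine gap state is
resolved with a prefix-max scan, which is exact because a gap extended
through another gap state never beats the single-open formulation.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .io import encode_dna, revcomp

DEFAULT_LAMBDA = 0.625
DEFAULT_K = 0.41


@dataclasses.dataclass(frozen=True)
class AlignmentResult:
    raw_score: float
    bit_score: float
    alignment_length: int
    e_value: float

    @property
    def score_density(self) -> float:
        return self.bit_score / self.alignment_length


def _sw_matrix(a: np.ndarray, b: np.ndarray, match: float, mismatch: float,
               gap_open: float, gap_extend: float):
    """Full H and E matrices of the affine Smith–Waterman DP."""
    n, m = a.size, b.size
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    E = np.full((n + 1, m + 1), -np.inf)
    open_ext = gap_open + gap_extend
    jcost = gap_extend * np.arange(1, m + 1)
    valid_b = b != 255
    for i in range(1, n + 1):
        sub = np.where((b == a[i - 1]) & valid_b & (a[i - 1] != 255), match, mismatch)
        E[i, 1:] = np.maximum(H[i - 1, 1:] - open_ext, E[i - 1, 1:] - gap_extend)
        h0 = np.maximum(0.0, H[i - 1, :-1] + sub)
        h0 = np.maximum(h0, E[i, 1:])
        g = h0 + gap_extend * np.arange(1, m + 1)
        prefix = np.maximum.accumulate(g)
        f = np.full(m, -np.inf)
        if m > 1:
            f[1:] = prefix[:-1] - gap_open - jcost[1:]
        H[i, 1:] = np.maximum(h0, f)
    return H, E


def _traceback_length(a, b, H, E, match, mismatch, gap_open, gap_extend) -> int:
    """Column count of the optimal local alignment, by explicit traceback."""
    i, j = np.unravel_index(np.argmax(H), H.shape)
    i, j = int(i), int(j)
    length = 0
    open_ext = gap_open + gap_extend
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if (a[i - 1] == b[j - 1] and a[i - 1] != 255) else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            i, j = i - 1, j - 1
            length += 1
            continue
        if H[i, j] == E[i, j]:
            k = i - 1
            while k >= 1 and H[k, j] - open_ext - gap_extend * (i - 1 - k) != H[i, j]:
                k -= 1
            length += i - k
            i = k
            continue
        k = j - 1
        while k >= 1 and H[i, k] - open_ext - gap_extend * (j - 1 - k) != H[i, j]:
            k -= 1
        length += j - k
        j = k
    return max(length, 1)


def local_align(
    seq_a: str,
    seq_b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = 5.0,
    gap_extend: float = 2.0,
    lam: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
) -> AlignmentResult:
    """Optimal local alignment with Karlin–Altschul statistics."""
    if lam <= 0:
        raise ValueError("Karlin-Altschul lambda must be positive")
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a, b = encode_dna(seq_a), encode_dna(seq_b)
    H, E = _sw_matrix(a, b, match, mismatch, gap_open, gap_extend)
    raw = float(H.max())
    if raw <= 0:
        bit = (lam * 0.0 - math.log(K)) / math.log(2)
        return AlignmentResult(0.0, bit, 1, len(seq_a) * len(seq_b) * 2.0**-bit)
    length = _traceback_length(a, b, H, E, match, mismatch, gap_open, gap_extend)
    bit = (lam * raw - math.log(K)) / math.log(2)
    e_value = len(seq_a) * len(seq_b) * 2.0**-bit
    return AlignmentResult(raw, bit, length, e_value)


def best_strand_align(seq_a: str, seq_b: str, **kwargs) -> AlignmentResult:
    """Align forward-forward and forward-revcomp; keep the higher bit-score."""
    fwd = local_align(seq_a, seq_b, **kwargs)
    rev = local_align(seq_a, revcomp(seq_b), **kwargs)
    return fwd if fwd.bit_score >= rev.bit_score else rev
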