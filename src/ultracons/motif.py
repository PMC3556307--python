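"""8-mer overrepresentation in UCR clusters.

Each cluster gets a representative sequence (center-star consensus of
its members) and a 10 kb random background drawn from the unmasked
portions of the member genomes, each genome contributing in proportion
to its species' share of the cluster.  Every 8-mer occurring in the
representative is scored with the upper-tail binomial probability

    F(x | n, p) = 1 - sum_{i=0}^{x-1} C(n,i) p^i (1-p)^(n-i)

with n = L - k + 1 sliding-window trials and p estimated from the
background with add-one smoothing (a finite 10 kb background
undersamples the 65,536 possible 8-mers, and an unsmoothed zero count
would make F degenerate).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy.stats import binom

from .align import local_align
from .io import Genome, encode_dna

DEFAULT_K = 8
DEFAULT_BG_LENGTH = 10_000
DEFAULT_SEGMENT = 100
DEFAULT_THRESHOLD = 1e-4


@dataclasses.dataclass(frozen=True)
class BackgroundSpec:
    total_length: int = DEFAULT_BG_LENGTH
    segment_length: int = DEFAULT_SEGMENT
    seed: int = 0

    def __post_init__(self):
        if self.total_length < self.segment_length:
            raise ValueError("total_length must be >= segment_length")


def consensus_sequence(member_sequences: Sequence[str]) -> str:
    """Center-star majority consensus of a cluster.

    The center is the member with the highest summed pairwise local
    alignment score; every other member is globally aligned to it and
    votes per center column.  Columns where gap is the strict majority
    are dropped; base ties break alphabetically.  Insertions relative
    to the center are not represented.
    """
    seqs = [s.upper() for s in member_sequences]
    if not seqs:
        raise ValueError("empty cluster")
    if len(seqs) == 1:
        return seqs[0]
    scores = np.zeros(len(seqs))
    cache: dict[tuple[int, int], float] = {}
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            s = local_align(seqs[i], seqs[j]).raw_score
            scores[i] += s
            scores[j] += s
    center_idx = int(np.argmax(scores))
    center = seqs[center_idx]

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2

    votes = [dict() for _ in center]  # per center column: symbol -> count
    for col, base in enumerate(center):
        votes[col][base] = 1
    for idx, seq in enumerate(seqs):
        if idx == center_idx:
            continue
        aln = aligner.align(center, seq)[0]
        for (c_start, c_end), (s_start, s_end) in zip(*aln.aligned):
            for off in range(c_end - c_start):
                b = seq[s_start + off]
                votes[c_start + off][b] = votes[c_start + off].get(b, 0) + 1
        # center columns never touched by this member count as gaps
        covered = np.zeros(len(center), dtype=bool)
        for (c_start, c_end), _ in zip(*aln.aligned):
            covered[c_start:c_end] = True
        for col in np.flatnonzero(~covered):
            votes[col]["-"] = votes[col].get("-", 0) + 1

    out = []
    for col_votes in votes:
        gap = col_votes.get("-", 0)
        bases = sorted(
            ((cnt, b) for b, cnt in col_votes.items() if b != "-"),
            key=lambda t: (-t[0], t[1]),
        )
        if not bases or gap > bases[0][0]:
            continue
        out.append(bases[0][1])
    return "".join(out)


def build_background(
    species_fractions: Mapping[str, float],
    genomes: Mapping[str, Genome],
    spec: BackgroundSpec = BackgroundSpec(),
) -> str:
    """Species-proportional random background of exactly total_length bp.

    Per-species quotas follow largest-remainder rounding of
    fraction * total_length; each quota is filled with unmasked
    segments of segment_length (the final segment truncated to fit)
    sampled uniformly from that species' scaffolds.
    """
    fracs = {sp: f for sp, f in species_fractions.items() if f > 0}
    total = sum(fracs.values())
    if total <= 0:
        raise ValueError("species fractions must sum to a positive value")
    fracs = {sp: f / total for sp, f in fracs.items()}
    raw = {sp: f * spec.total_length for sp, f in fracs.items()}
    quota = {sp: int(np.floor(v)) for sp, v in raw.items()}
    shortfall = spec.total_length - sum(quota.values())
    for sp in sorted(raw, key=lambda s: (raw[s] - quota[s], s), reverse=True)[:shortfall]:
        quota[sp] += 1

    rng = np.random.default_rng(spec.seed)
    parts: list[str] = []
    for sp in sorted(quota):
        need = quota[sp]
        genome = genomes[sp]
        scaffolds = sorted(genome.scaffolds)
        lengths = np.array([len(genome.scaffolds[s]) for s in scaffolds], dtype=float)
        if lengths.max() < spec.segment_length:
            raise ValueError(f"genome {sp} shorter than segment_length")
        weights = lengths / lengths.sum()
        while need > 0:
            seg_len = min(spec.segment_length, need)
            for _ in range(1000):
                scaf = scaffolds[rng.choice(len(scaffolds), p=weights)]
                seq = genome.scaffolds[scaf]
                if len(seq) < seg_len:
                    continue
                start = int(rng.integers(0, len(seq) - seg_len + 1))
                segment = seq[start : start + seg_len]
                if "N" not in segment:
                    break
            else:
                raise ValueError(f"could not sample unmasked segment from {sp}")
            parts.append(segment)
            need -= seg_len
    return "".join(parts)


def binomial_upper(x: int, n: int, p: float) -> float:
    """Upper-tail binomial probability F = P(X >= x)."""
    if not (0 <= x <= n):
        raise ValueError(f"x={x} outside [0, n={n}]")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p={p} outside [0, 1]")
    if x == 0:
        return 1.0
    return float(binom.sf(x - 1, n, p))


def _count_kmers(sequence: str, k: int) -> dict[str, int]:
    s = encode_dna(sequence).astype(np.int64)
    n = len(sequence) - k + 1
    if n <= 0:
        return {}
    valid = s != 255
    window_valid = np.ones(n, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    for off in range(k):
        window_valid &= valid[off : off + n]
        codes = codes * 4 + np.where(valid[off : off + n], s[off : off + n], 0)
    counts: dict[str, int] = {}
    alphabet = "ACGT"
    for code, cnt in zip(*np.unique(codes[window_valid], return_counts=True)):
        mer = "".join(alphabet[(int(code) >> (2 * (k - 1 - i))) & 3] for i in range(k))
        counts[mer] = int(cnt)
    return counts


def oligomer_enrichment(
    representative: str,
    background: str,
    k: int = DEFAULT_K,
    report_threshold: float = DEFAULT_THRESHOLD,
    cluster_id: int | None = None,
) -> pd.DataFrame:
    """Score every k-mer of the representative against the background.

    x counts overlapping forward-strand occurrences; n = L - k + 1; the
    background probability is add-one smoothed, p = (c+1)/(N-k+2).
    Rows are sorted by p_value; `flagged` marks p_value < threshold.
    """
    L = len(representative)
    if L < k:
        raise ValueError("representative shorter than k")
    if len(background) < k:
        raise ValueError("background shorter than k")
    rep_counts = _count_kmers(representative, k)
    bg_counts = _count_kmers(background, k)
    n = L - k + 1
    denom = len(background) - k + 2
    rows = []
    for mer, x in rep_counts.items():
        p = (bg_counts.get(mer, 0) + 1) / denom
        pv = binomial_upper(x, n, p)
        rows.append(
            {
                "cluster_id": cluster_id,
                "oligomer": mer,
                "x": x,
                "n": n,
                "p": p,
                "p_value": pv,
                "flagged": pv < report_threshold,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["cluster_id", "oligomer", "x", "n", "p", "p_value", "flagged"],
    )
    return df.sort_values(["p_value", "oligomer"], kind="stable").reset_index(drop=True)
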