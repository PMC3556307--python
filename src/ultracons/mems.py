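"""Maximal exact match (MEM) discovery between two hard-masked genomes.

A MEM is an exact match that cannot be extended by one base on either
side *in both genomes simultaneously*; all occurrences are reported
regardless of uniqueness (`maxmatch` semantics).  Both strands are
searched; a minus-strand record carries the forward-strand interval of
genome b whose reverse complement equals the genome-a substring.

Algorithm: one generalized suffix array over

    scaffolds(a) | scaffolds(b) | revcomp(scaffolds(b))

with a unique integer symbol at every separator and at every non-ACGT
base (so 'N' never matches anything, and matches never span scaffold
boundaries).  The suffix array is built by numpy prefix doubling
(O(n log n) lexsort rounds), the LCP array by Kasai's algorithm.  Every
pair of suffixes (p from a, q from b/revcomp-b) whose pairwise LCP is
>= the length threshold and whose preceding symbols differ is exactly
one MEM, so MEMs are enumerated by scanning maximal runs of the suffix
array where consecutive LCP >= threshold.  On repeat-masked genomes
these runs are short and enumeration is output-bound; an unmasked
high-copy repeat would make the containing run quadratic, which is the
reason masking precedes discovery.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import masking
from .io import Genome

_A_FWD, _B_FWD, _B_REV = 0, 1, 2


@dataclasses.dataclass(frozen=True)
class MatchRecord:
    """One maximal exact match between two species.

    Coordinates are 0-based on the forward strand of each genome; a
    minus-strand match means revcomp(b[start_b0:start_b0+length]) equals
    a[start_a0:start_a0+length].
    """

    species_a: str
    species_b: str
    scaffold_a: str
    scaffold_b: str
    start_a0: int
    start_b0: int
    length: int
    strand: str  # '+' or '-'

    @property
    def end_a0(self) -> int:
        return self.start_a0 + self.length

    @property
    def end_b0(self) -> int:
        return self.start_b0 + self.length


def suffix_array(symbols: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence by prefix doubling."""
    n = symbols.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    _, rank = np.unique(symbols, return_inverse=True)
    rank = rank.astype(np.int64)
    k = 1
    idx = np.arange(n)
    order = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1 = rank[order]
        r2 = key2[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        if n > 1:
            changed[1:] = np.cumsum((r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1]))
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = changed
        rank = new_rank
        if changed[-1] == n - 1:
            break
        k *= 2
    return order.astype(np.int64)


def lcp_array(symbols: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai LCP array: lcp[i] = LCP(suffix sa[i-1], suffix sa[i]); lcp[0]=0."""
    n = symbols.size
    lcp = np.zeros(n, dtype=np.int64)
    if n == 0:
        return lcp
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    sym = symbols.tolist()
    sa_l = sa.tolist()
    rank_l = rank.tolist()
    h = 0
    out = [0] * n
    for i in range(n):
        r = rank_l[i]
        if r > 0:
            j = sa_l[r - 1]
            while i + h < n and j + h < n and sym[i + h] == sym[j + h]:
                h += 1
            out[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return np.asarray(out, dtype=np.int64)


def _build_text(genome_a: Genome, genome_b: Genome):
    """Integer text with unique symbols at separators and non-ACGT bases."""
    base_code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        base_code[b] = i
    comp = {0: 3, 1: 2, 2: 1, 3: 0}

    chunks: list[np.ndarray] = []
    meta: list[tuple[int, str, int]] = []  # (source, scaffold, seq_length)
    unique_counter = [4]

    def encode(seq: str, reverse_complement: bool) -> np.ndarray:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        codes = base_code[raw]
        if reverse_complement:
            codes = codes[::-1].copy()
            acgt = codes >= 0
            codes[acgt] = np.array([comp[c] for c in codes[acgt].tolist()])
        bad = np.flatnonzero(codes < 0)
        if bad.size:
            codes[bad] = unique_counter[0] + np.arange(bad.size)
            unique_counter[0] += bad.size
        return codes

    def add(source: int, scaffold: str, seq: str, rc: bool) -> None:
        chunks.append(encode(seq, rc))
        meta.append((source, scaffold, len(seq)))
        sep = np.array([unique_counter[0]], dtype=np.int64)
        unique_counter[0] += 1
        chunks.append(sep)
        meta.append((-1, "", 1))

    for name, seq in genome_a.scaffolds.items():
        add(_A_FWD, name, seq, rc=False)
    for name, seq in genome_b.scaffolds.items():
        add(_B_FWD, name, seq, rc=False)
    for name, seq in genome_b.scaffolds.items():
        add(_B_REV, name, seq, rc=True)

    text = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
    n = text.size
    source = np.full(n, -1, dtype=np.int8)
    scaffold_idx = np.full(n, -1, dtype=np.int32)
    offset = np.zeros(n, dtype=np.int64)
    scaffold_names: list[str] = []
    pos = 0
    for src, name, length in meta:
        if src >= 0:
            scaffold_names.append(name)
            sid = len(scaffold_names) - 1
            source[pos : pos + length] = src
            scaffold_idx[pos : pos + length] = sid
            offset[pos : pos + length] = np.arange(length)
        pos += length
    return text, source, scaffold_idx, offset, scaffold_names


def find_mems(
    genome_a: Genome, genome_b: Genome, min_length: int
) -> list[MatchRecord]:
    """All maximal exact matches >= min_length between two genomes."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if genome_a.total_length == 0 or genome_b.total_length == 0:
        return []
    text, source, scaf_idx, offset, scaf_names = _build_text(genome_a, genome_b)
    sa = suffix_array(text)
    lcp = lcp_array(text, sa)
    b_lengths = genome_b.scaffold_lengths()
    self_cmp = genome_a.species == genome_b.species

    matches: list[MatchRecord] = []
    n = sa.size
    # maximal runs of consecutive suffix-array entries with lcp >= min_length
    ge = lcp >= min_length
    i = 1
    while i < n:
        if not ge[i]:
            i += 1
            continue
        j = i
        while j < n and ge[j]:
            j += 1
        block = sa[i - 1 : j]  # suffixes in this run
        block_lcp = lcp[i : j]  # pairwise neighbours within run
        m = block.size
        srcs = source[block]
        a_members = np.flatnonzero(srcs == _A_FWD)
        b_members = np.flatnonzero(srcs >= _B_FWD)
        if a_members.size and b_members.size:
            for ai in a_members.tolist():
                p = int(block[ai])
                left_p = text[p - 1] if p > 0 else -1
                for bi in b_members.tolist():
                    q = int(block[bi])
                    left_q = text[q - 1] if q > 0 else -2
                    if left_p == left_q:
                        continue  # left-extendable: not a MEM
                    lo, hi = (ai, bi) if ai < bi else (bi, ai)
                    ell = int(block_lcp[lo:hi].min())
                    if ell < min_length:
                        continue
                    scaffold_b = scaf_names[scaf_idx[q]]
                    if source[q] == _B_FWD:
                        strand = "+"
                        start_b = int(offset[q])
                    else:
                        strand = "-"
                        start_b = b_lengths[scaffold_b] - int(offset[q]) - ell
                    scaffold_a = scaf_names[scaf_idx[p]]
                    start_a = int(offset[p])
                    if self_cmp:
                        if (
                            scaffold_a == scaffold_b
                            and start_a == start_b
                        ):
                            # identity / palindromic self-match
                            continue
                    matches.append(
                        MatchRecord(
                            species_a=genome_a.species,
                            species_b=genome_b.species,
                            scaffold_a=scaffold_a,
                            scaffold_b=scaffold_b,
                            start_a0=start_a,
                            start_b0=start_b,
                            length=ell,
                            strand=strand,
                        )
                    )
        i = j
    matches.sort(
        key=lambda m: (m.scaffold_a, m.start_a0, m.scaffold_b, m.start_b0, m.strand)
    )
    return matches


def remask_matches(
    matches: list[MatchRecord],
    genome_a: Genome,
    min_length: int,
    **mask_params,
) -> list[MatchRecord]:
    """Second-round masking of discovered elements.

    Each match's genome-a sequence is re-scanned by both repeat
    detectors; the match is trimmed to its longest unmasked run and
    dropped when that run falls below min_length.  Coordinates are
    updated consistently on both sides (strand-aware on b).
    """
    out: list[MatchRecord] = []
    for m in matches:
        seq = genome_a.fetch(m.scaffold_a, m.start_a0, m.end_a0)
        off, run = masking.longest_unmasked_run(seq, **mask_params)
        if run < min_length:
            continue
        if run == m.length:
            out.append(m)
            continue
        if m.strand == "+":
            new_b = m.start_b0 + off
        else:
            new_b = m.start_b0 + (m.length - off - run)
        out.append(
            dataclasses.replace(
                m, start_a0=m.start_a0 + off, start_b0=new_b, length=run
            )
        )
    return out


def matches_to_tsv(matches: list[MatchRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "species_a": m.species_a,
                "scaffold_a": m.scaffold_a,
                "start_a": m.start_a0,
                "end_a": m.end_a0,
                "species_b": m.species_b,
                "scaffold_b": m.scaffold_b,
                "start_b": m.start_b0,
                "end_b": m.end_b0,
                "strand": m.strand,
                "length": m.length,
            }
            for m in matches
        ]
    ).to_csv(path, sep="\t", index=False)
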