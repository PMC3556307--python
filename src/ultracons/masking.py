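"""Hard-masking of tandem repeats and low-complexity sequence.

Exact-match discovery must never run through repetitive DNA: a single
microsatellite shared by chance between two genomes would otherwise
flood the match set.  Masking is *hard* — masked bases become 'N',
which matches nothing downstream (not even another 'N').

Two detectors are provided:

* an exact tandem-repeat finder (period <= ``max_period``, at least
  ``min_copies`` copies, spanning >= ``min_span`` bp; the last copy may
  be partial), and
* a sliding-window mononucleotide Shannon-entropy filter for
  low-complexity runs (homopolymers, skewed composition).

Both detectors are deterministic and oracle-checkable; users with
external repeat annotations (RepeatMasker/CENSOR/TRF output) can load
them as BED and stack them on top.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .io import Genome, encode_dna

DEFAULT_MAX_PERIOD = 6
DEFAULT_MIN_COPIES = 4.0
DEFAULT_MIN_SPAN = 24
DEFAULT_WINDOW = 64
DEFAULT_ENTROPY = 1.5


@dataclasses.dataclass(frozen=True)
class MaskInterval:
    """A half-open masked interval on one scaffold."""

    scaffold: str
    start0: int
    end0: int
    kind: str  # tandem | low_complexity | external

    def __post_init__(self):
        if self.end0 <= self.start0:
            raise ValueError(
                f"empty mask interval {self.scaffold}:{self.start0}-{self.end0}"
            )


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True in a boolean vector."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def find_tandem_repeats(
    sequence: str,
    max_period: int = DEFAULT_MAX_PERIOD,
    min_copies: float = DEFAULT_MIN_COPIES,
    min_span: int = DEFAULT_MIN_SPAN,
    scaffold: str = "seq",
) -> list[MaskInterval]:
    """All maximal exact tandem arrays with unit length <= max_period.

    An interval [a, b) is reported when some period p <= max_period has
    s[i] == s[i+p] for every i in [a, b-p), the span b-a is >= min_span,
    and (b-a)/p >= min_copies.  Intervals contained in a longer reported
    interval are dropped, so the output is the set of maximal repeat
    loci.  Non-ACGT symbols never participate in a repeat.
    """
    if max_period < 1:
        raise ValueError("max_period must be >= 1")
    n = len(sequence)
    if n == 0:
        return []
    s = encode_dna(sequence)
    valid = s != 255
    candidates: set[tuple[int, int]] = set()
    for p in range(1, max_period + 1):
        if n <= p:
            break
        eq = (s[:-p] == s[p:]) & valid[:-p] & valid[p:]
        for a, b in _runs_of_true(eq):
            span = (b - a) + p
            if span >= min_span and span / p >= min_copies:
                candidates.add((a, b + p))
    # drop intervals contained in another candidate
    kept: list[tuple[int, int]] = []
    max_end = -1
    for a, b in sorted(candidates, key=lambda iv: (iv[0], -iv[1])):
        if b > max_end:
            kept.append((a, b))
            max_end = b
    return [MaskInterval(scaffold, a, b, "tandem") for a, b in kept]


def find_low_complexity(
    sequence: str,
    window: int = DEFAULT_WINDOW,
    entropy_threshold: float = DEFAULT_ENTROPY,
    scaffold: str = "seq",
) -> list[MaskInterval]:
    """Union of windows whose mononucleotide entropy is below threshold.

    Entropy is Shannon entropy (bits) of the ACGT composition inside
    each sliding window; random DNA sits near 2 bits, homopolymers at 0.
    """
    if window < 4:
        raise ValueError("window must be >= 4")
    n = len(sequence)
    if n < window:
        return []
    s = encode_dna(sequence)
    onehot = np.zeros((4, n), dtype=np.int32)
    for base in range(4):
        onehot[base] = s == base
    csum = np.concatenate(
        [np.zeros((4, 1), dtype=np.int64), np.cumsum(onehot, axis=1)], axis=1
    )
    counts = csum[:, window:] - csum[:, :-window]  # 4 x (n-window+1)
    totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / np.where(totals == 0, 1, totals)
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    entropy = terms.sum(axis=0)
    low = entropy < entropy_threshold
    mask = np.zeros(n, dtype=bool)
    for a, b in _runs_of_true(low):
        mask[a : b - 1 + window] = True
    return [
        MaskInterval(scaffold, a, b, "low_complexity") for a, b in _runs_of_true(mask)
    ]


def apply_mask(genome: Genome, intervals: list[MaskInterval]) -> Genome:
    """Hard-mask intervals with 'N'. Length-preserving and idempotent."""
    arrays = {
        name: np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        for name, seq in genome.scaffolds.items()
    }
    for iv in intervals:
        if iv.scaffold not in arrays:
            raise ValueError(f"mask interval on unknown scaffold: {iv}")
        arr = arrays[iv.scaffold]
        if iv.start0 < 0 or iv.end0 > arr.size:
            raise ValueError(f"mask interval out of bounds: {iv}")
        arr[iv.start0 : iv.end0] = ord("N")
    return Genome(
        genome.species,
        {name: arr.tobytes().decode("ascii") for name, arr in arrays.items()},
    )


def load_external_mask(path: str | Path) -> list[MaskInterval]:
    """Read a 3+ column BED file (0-based half-open) as external masks."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}") from exc
            if end0 <= start0:
                raise ValueError(
                    f"{path}: BED line {lineno} has end <= start"
                )
            out.append(MaskInterval(parts[0], start0, end0, "external"))
    return out


def mask_genome(
    genome: Genome,
    max_period: int = DEFAULT_MAX_PERIOD,
    min_copies: float = DEFAULT_MIN_COPIES,
    min_span: int = DEFAULT_MIN_SPAN,
    window: int = DEFAULT_WINDOW,
    entropy_threshold: float = DEFAULT_ENTROPY,
    external: list[MaskInterval] | None = None,
) -> tuple[Genome, list[MaskInterval]]:
    """Run both detectors on every scaffold and hard-mask the genome."""
    intervals: list[MaskInterval] = list(external or [])
    for name, seq in genome.scaffolds.items():
        intervals.extend(
            find_tandem_repeats(seq, max_period, min_copies, min_span, scaffold=name)
        )
        intervals.extend(
            find_low_complexity(seq, window, entropy_threshold, scaffold=name)
        )
    return apply_mask(genome, intervals), intervals


def longest_unmasked_run(
    sequence: str,
    max_period: int = DEFAULT_MAX_PERIOD,
    min_copies: float = DEFAULT_MIN_COPIES,
    min_span: int = DEFAULT_MIN_SPAN,
    window: int = DEFAULT_WINDOW,
    entropy_threshold: float = DEFAULT_ENTROPY,
) -> tuple[int, int]:
    """Second-round masking of one element.

    Re-runs both detectors on the element's own sequence and returns the
    (offset, length) of the longest run untouched by either detector
    (leftmost on ties).  Length 0 means the element is repeat through
    and through.
    """
    n = len(sequence)
    masked = np.zeros(n, dtype=bool)
    for iv in find_tandem_repeats(sequence, max_period, min_copies, min_span):
        masked[iv.start0 : iv.end0] = True
    for iv in find_low_complexity(sequence, window, entropy_threshold):
        masked[iv.start0 : iv.end0] = True
    best = (0, 0)
    for a, b in _runs_of_true(~masked):
        if b - a > best[1]:
            best = (a, b - a)
    return best
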