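"""Projection of pairwise matches onto species and merging into UCRs.

An ultraconserved region (UCR) is the non-overlapping union of
overlapping conserved elements within one species, pooled across all
its pairwise comparisons, carrying the set of partner species it is
conserved with and up to 50 bp of flanking sequence on each side.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

from .io import Genome
from .mems import MatchRecord

DEFAULT_FLANK = 50


@dataclasses.dataclass(frozen=True)
class LabeledInterval:
    scaffold: str
    start0: int
    end0: int
    partner: str
    match_id: int


@dataclasses.dataclass(frozen=True)
class UCR:
    species: str
    scaffold: str
    start0: int
    end0: int
    conserved_with: frozenset[str]
    source_match_ids: tuple[int, ...]
    flank_left: str
    flank_right: str
    sequence_with_flanks: str

    @property
    def ucr_id(self) -> str:
        return f"{self.species}:{self.scaffold}:{self.start0}-{self.end0}"

    @property
    def length(self) -> int:
        return self.end0 - self.start0


def project_matches(
    all_pair_matches: Mapping[tuple[str, str], Sequence[MatchRecord]],
    species: str,
) -> list[LabeledInterval]:
    """Intervals contributed to one species by every pairwise match set.

    A match between (a, b) contributes its a-side interval to species a
    labeled with partner b, and its b-side interval (forward-strand
    coordinates) to species b labeled with partner a.
    """
    out: list[LabeledInterval] = []
    mid = 0
    for (_, _), matches in sorted(all_pair_matches.items()):
        for m in matches:
            if m.species_a == species:
                out.append(
                    LabeledInterval(m.scaffold_a, m.start_a0, m.end_a0, m.species_b, mid)
                )
            if m.species_b == species:
                out.append(
                    LabeledInterval(m.scaffold_b, m.start_b0, m.end_b0, m.species_a, mid)
                )
            mid += 1
    return out


def merge_to_ucrs(
    intervals: Iterable[LabeledInterval],
    genome: Genome,
    flank: int = DEFAULT_FLANK,
) -> list[UCR]:
    """Merge overlapping intervals into UCRs and attach flanks.

    Overlap means sharing at least one base; book-ended intervals stay
    separate.  The merge is the connected-component closure, so the
    result is a fixpoint: no two output intervals overlap.  Flanks are
    truncated (not discarded) at scaffold ends.
    """
    by_scaffold: dict[str, list[LabeledInterval]] = {}
    for iv in intervals:
        if iv.end0 <= iv.start0:
            raise ValueError(f"empty interval {iv}")
        by_scaffold.setdefault(iv.scaffold, []).append(iv)

    ucrs: list[UCR] = []
    for scaffold in sorted(by_scaffold):
        seq = genome.scaffolds[scaffold]
        ivs = sorted(by_scaffold[scaffold], key=lambda iv: (iv.start0, iv.end0))
        i = 0
        while i < len(ivs):
            start, end = ivs[i].start0, ivs[i].end0
            partners = {ivs[i].partner}
            ids = [ivs[i].match_id]
            j = i + 1
            while j < len(ivs) and ivs[j].start0 < end:
                end = max(end, ivs[j].end0)
                partners.add(ivs[j].partner)
                ids.append(ivs[j].match_id)
                j += 1
            if end > len(seq) or start < 0:
                raise ValueError(
                    f"interval {scaffold}:{start}-{end} outside genome"
                )
            fl = seq[max(0, start - flank) : start]
            fr = seq[end : end + flank]
            core = seq[start:end]
            ucrs.append(
                UCR(
                    species=genome.species,
                    scaffold=scaffold,
                    start0=start,
                    end0=end,
                    conserved_with=frozenset(partners),
                    source_match_ids=tuple(sorted(ids)),
                    flank_left=fl,
                    flank_right=fr,
                    sequence_with_flanks=fl + core + fr,
                )
            )
            i = j
    return ucrs


def ucrs_to_tables(ucrs: Sequence[UCR]):
    """(BED rows, TSV DataFrame) for a UCR track."""
    import pandas as pd

    bed = [(u.scaffold, u.start0, u.end0) for u in ucrs]
    df = pd.DataFrame(
        [
            {
                "ucr_id": u.ucr_id,
                "species": u.species,
                "scaffold": u.scaffold,
                "start0": u.start0,
                "end0": u.end0,
                "length": u.length,
                "conserved_with": ",".join(sorted(u.conserved_with)),
                "n_source_matches": len(u.source_match_ids),
            }
            for u in ucrs
        ]
    )
    return bed, df
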