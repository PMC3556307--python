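"""Genome container and text-format I/O (FASTA, BED, GFF3, TSV).

Coordinates are 0-based half-open everywhere in memory.  GFF3 output
follows the GFF3 standard (1-based inclusive); BED is 0-based half-open.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclasses.dataclass
class Genome:
    """Named scaffold sequences for one species.

    Hard-masked positions carry 'N'; everything downstream treats 'N'
    as a base that matches nothing, including another 'N'.
    """

    species: str
    scaffolds: dict[str, str]

    def scaffold_lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.scaffolds.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())

    def fetch(self, scaffold: str, start0: int, end0: int) -> str:
        return self.scaffolds[scaffold][start0:end0]

    def masked_fraction(self) -> float:
        total = self.total_length
        if total == 0:
            return 0.0
        n = sum(s.count("N") for s in self.scaffolds.values())
        return n / total

    def copy(self) -> "Genome":
        return Genome(self.species, dict(self.scaffolds))

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.scaffolds.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, species: str | None = None) -> "Genome":
        species = species or Path(path).stem
        scaffolds = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(species, scaffolds)


# --- small table I/O helpers -------------------------------------------------

def write_bed(path: str | Path, rows: Iterable[tuple[str, int, int]]) -> None:
    with open(path, "w") as fh:
        for scaffold, start0, end0 in rows:
            fh.write(f"{scaffold}\t{start0}\t{end0}\n")


def write_gff3(path: str | Path, genes: Iterable) -> None:
    """Write GeneRecord-like objects (scaffold, start0, end0, strand, gene_id)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold}\tultracons\tgene\t{g.start0 + 1}\t{g.end0}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_gff3_genes(path: str | Path, species: str) -> list:
    """Parse gene features from a GFF3 file into GeneRecords (no domains)."""
    from .enrichment import GeneRecord

    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}")
            scaffold, _, ftype, start1, end1, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            gene_id = ""
            for field in attrs.split(";"):
                if field.startswith("ID="):
                    gene_id = field[3:]
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    species=species,
                    scaffold=scaffold,
                    start0=int(start1) - 1,
                    end0=int(end1),
                    strand=strand if strand in "+-" else "+",
                    domains=frozenset(),
                )
            )
    return genes


def read_domain_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Two-column TSV gene_id -> domain accession (one pair per line)."""
    acc: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed domain-map line {lineno}")
            acc.setdefault(parts[0], set()).add(parts[1])
    return {k: frozenset(v) for k, v in acc.items()}


def encode_dna(seq: str) -> np.ndarray:
    """Map ACGT to 0..3 and anything else to 255 (uint8)."""
    table = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        table[b] = i
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return table[raw]
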