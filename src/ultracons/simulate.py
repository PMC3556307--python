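"""Synthetic multi-species genomes with planted ground truth.

The generator emulates the study design end to end: i.i.d. background
genomes with a per-species GC content, conserved elements written at
known coordinates into chosen species subsets (optionally mutated or
reverse-complemented per copy), tandem repeats for the masking stage,
gene annotations with protein-domain labels at controlled distances
from planted elements, and aligned protein families evolved along a
known tree under the JTT model.

Planted elements are written *over* the background (replacement, not
insertion) so all coordinates stay fixed, and substitutions are the
only mutation type, matching the gap-free exact-match discovery model.
By default the planter also writes distinct boundary bases around each
copy (strand-aware, in the element's frame) so that a planted exact
pair is also the *maximal* exact match — without this, a 1-in-4 chance
per side would let matches extend beyond the planted coordinates and
the truth table could not promise exact coordinates.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import stage_rng
from .io import Genome, revcomp
from .masking import MaskInterval

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclasses.dataclass(frozen=True)
class SpeciesSpec:
    species_id: str
    n_scaffolds: int
    scaffold_length: int
    gc_content: float = 0.5

    def __post_init__(self):
        if self.n_scaffolds < 1 or self.scaffold_length < 1:
            raise ValueError(f"non-positive genome dimensions for {self.species_id}")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError(f"gc_content outside [0,1] for {self.species_id}")


@dataclasses.dataclass(frozen=True)
class PlantSpec:
    """One conserved element and where each species carries it.

    placements: species_id -> (scaffold, start0, strand); mutations:
    species_id -> substitution count (0 when omitted).  A pair of
    species is an *exact* pair only when both copies carry zero
    mutations.
    """

    element_id: str
    length: int
    placements: Mapping[str, tuple[str, int, str]]
    mutations: Mapping[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"{self.element_id}: length must be >= 1")
        if len(self.placements) < 2:
            raise ValueError(f"{self.element_id}: needs >= 2 species")
        for sp, count in self.mutations.items():
            if count >= self.length:
                raise ValueError(f"{self.element_id}: mutation count >= length in {sp}")


@dataclasses.dataclass
class TruthTable:
    """Planted-copy coordinates plus the exact-pair relation."""

    placements: pd.DataFrame  # element_id, species_id, scaffold, start0, end0, strand, n_mutations

    def exact_pairs(self) -> list[tuple[str, str, str]]:
        """(element_id, species_i, species_j) for pairs exact in both copies."""
        out = []
        for eid, grp in self.placements.groupby("element_id", sort=True):
            clean = sorted(grp.loc[grp.n_mutations == 0, "species_id"])
            for a, b in itertools.combinations(clean, 2):
                out.append((eid, a, b))
        return out

    def to_tsv(self, path) -> None:
        self.placements.to_csv(path, sep="\t", index=False)


def generate_genome(spec: SpeciesSpec, seed: int) -> Genome:
    """i.i.d. background genome with the requested GC fraction."""
    rng = stage_rng(seed, f"genome:{spec.species_id}")
    gc = spec.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    scaffolds = {}
    for i in range(spec.n_scaffolds):
        draws = rng.choice(4, size=spec.scaffold_length, p=probs)
        scaffolds[f"{spec.species_id}_scaf{i}"] = (
            BASES[draws].tobytes().decode("ascii")
        )
    return Genome(spec.species_id, scaffolds)


def _check_collisions(plants: Sequence[PlantSpec]) -> None:
    by_loc: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for plant in plants:
        for sp, (scaf, start, _) in plant.placements.items():
            by_loc.setdefault((sp, scaf), []).append(
                (start, start + plant.length, plant.element_id)
            )
    for (sp, scaf), ivs in by_loc.items():
        ivs.sort()
        for (s1, e1, id1), (s2, e2, id2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping placements on {sp}/{scaf}: {id1} and {id2}"
                )


def plant_elements(
    genomes: Mapping[str, Genome],
    plants: Sequence[PlantSpec],
    seed: int,
    sharp_boundaries: bool = True,
) -> tuple[dict[str, Genome], TruthTable]:
    """Write planted elements into the genomes and return the truth table."""
    _check_collisions(plants)
    arrays = {
        sp: {
            name: bytearray(seq, "ascii") for name, seq in g.scaffolds.items()
        }
        for sp, g in genomes.items()
    }
    rng = stage_rng(seed, "plant_elements")
    rows = []
    for plant in sorted(plants, key=lambda p: p.element_id):
        master = BASES[rng.integers(0, 4, size=plant.length)].tobytes().decode()
        boundary_letters = list("ACGT")
        rng.shuffle(boundary_letters)
        for copy_idx, sp in enumerate(sorted(plant.placements)):
            scaf, start, strand = plant.placements[sp]
            if sp not in arrays:
                raise ValueError(f"{plant.element_id}: unknown species {sp}")
            target = arrays[sp][scaf]
            end = start + plant.length
            if start < 0 or end > len(target):
                raise ValueError(
                    f"{plant.element_id}: placement outside scaffold in {sp}"
                )
            seq = master
            n_mut = plant.mutations.get(sp, 0)
            if n_mut:
                pos = rng.choice(plant.length, size=n_mut, replace=False)
                chars = list(seq)
                for p in sorted(pos.tolist()):
                    alternatives = [b for b in "ACGT" if b != chars[p]]
                    chars[p] = alternatives[int(rng.integers(0, 3))]
                seq = "".join(chars)
            written = revcomp(seq) if strand == "-" else seq
            target[start:end] = written.encode("ascii")
            if sharp_boundaries:
                left_b = boundary_letters[copy_idx % 4]
                right_b = boundary_letters[(copy_idx + 2) % 4]
                _write_boundary(target, start, end, strand, left_b, right_b)
            rows.append(
                {
                    "element_id": plant.element_id,
                    "species_id": sp,
                    "scaffold": scaf,
                    "start0": start,
                    "end0": end,
                    "strand": strand,
                    "n_mutations": n_mut,
                }
            )
    out = {
        sp: Genome(sp, {name: bytes(arr).decode() for name, arr in scafs.items()})
        for sp, scafs in arrays.items()
    }
    return out, TruthTable(pd.DataFrame(rows))


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _write_boundary(
    target: bytearray, start: int, end: int, strand: str, left_b: str, right_b: str
) -> None:
    """Write element-frame boundary bases (strand-aware) around a copy."""
    if strand == "+":
        if start > 0:
            target[start - 1] = ord(left_b)
        if end < len(target):
            target[end] = ord(right_b)
    else:
        # element-frame left precedes the master; on '-' that is the base
        # after the written copy, complemented (and vice versa).
        if end < len(target):
            target[end] = ord(_COMP[left_b])
        if start > 0:
            target[start - 1] = ord(_COMP[right_b])


def plant_repeats(
    genome: Genome,
    n_tandem: int,
    unit_length: int,
    copies: int,
    seed: int,
    positions: Sequence[tuple[str, int]] | None = None,
    units: Sequence[str] | None = None,
    avoid: Sequence[tuple[str, int, int]] = (),
) -> tuple[Genome, list[MaskInterval]]:
    """Write tandem repeat arrays and return their truth intervals.

    Repeats are placed at the given positions, or sampled uniformly
    avoiding `avoid` intervals and each other.  Collisions with avoid
    intervals raise an error naming the repeat.
    """
    if n_tandem == 0:
        return genome.copy(), []
    rng = stage_rng(seed, f"repeats:{genome.species}")
    arrays = {name: bytearray(seq, "ascii") for name, seq in genome.scaffolds.items()}
    span = unit_length * copies
    occupied: dict[str, list[tuple[int, int]]] = {}
    for scaf, a, b in avoid:
        occupied.setdefault(scaf, []).append((a, b))

    def collides(scaf: str, a: int, b: int) -> bool:
        return any(a < e and s < b for s, e in occupied.get(scaf, []))

    truth: list[MaskInterval] = []
    names = sorted(arrays)
    for r in range(n_tandem):
        unit = (
            units[r]
            if units is not None
            else BASES[rng.integers(0, 4, size=unit_length)].tobytes().decode()
        )
        if positions is not None:
            scaf, start = positions[r]
            if collides(scaf, start, start + span):
                raise ValueError(f"repeat {r} collides with an existing plant")
        else:
            for _ in range(1000):
                scaf = names[int(rng.integers(0, len(names)))]
                limit = len(arrays[scaf]) - span
                if limit <= 0:
                    continue
                start = int(rng.integers(0, limit))
                if not collides(scaf, start, start + span):
                    break
            else:
                raise ValueError(f"could not place repeat {r} without collision")
        arr = arrays[scaf]
        if start < 0 or start + span > len(arr):
            raise ValueError(f"repeat {r} outside scaffold {scaf}")
        arr[start : start + span] = (unit * copies).encode("ascii")
        occupied.setdefault(scaf, []).append((start, start + span))
        truth.append(MaskInterval(scaf, start, start + span, "tandem"))
    out = Genome(genome.species, {n: bytes(a).decode() for n, a in arrays.items()})
    return out, truth


def generate_annotations(
    genome: Genome,
    n_genes: int,
    domain_vocab: Sequence[str],
    placement_rule: str = "uniform",
    seed: int = 0,
    elements: Sequence[tuple[str, int, int]] = (),
    near_distance: int = 1_000,
    near_fraction: float = 1.0,
    near_domain: str | None = None,
    gene_length: int = 500,
    domains_per_gene: int = 1,
):
    """Non-overlapping gene annotations with domain labels.

    placement_rule 'near-elements' puts a `near_fraction` share of the
    genes within `near_distance` bp of the given element intervals (one
    per element, cycling); those genes carry `near_domain` when given.
    The rest (and everything under 'uniform') is placed uniformly with
    domains drawn from the vocabulary.
    """
    from .enrichment import GeneRecord

    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if domains_per_gene > 0 and not domain_vocab and near_domain is None:
        raise ValueError("domain vocabulary empty while domains requested")
    rng = stage_rng(seed, f"genes:{genome.species}")
    names = sorted(genome.scaffolds)
    lengths = {n: len(genome.scaffolds[n]) for n in names}
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}

    def free(scaf: str, a: int, b: int) -> bool:
        return 0 <= a and b <= lengths[scaf] and not any(
            a < e and s < b for s, e in occupied[scaf]
        )

    n_near = 0
    if placement_rule == "near-elements":
        if not elements:
            raise ValueError("near-elements placement requires element intervals")
        n_near = int(round(near_fraction * n_genes))
    elif placement_rule != "uniform":
        raise ValueError(f"unknown placement rule {placement_rule!r}")

    genes = []
    for g in range(n_genes):
        for _ in range(2000):
            if g < n_near:
                scaf, es, ee = elements[g % len(elements)]
                lo = max(0, es - near_distance - gene_length)
                hi = min(lengths[scaf] - gene_length, ee + near_distance)
                if hi < lo:
                    continue
                start = int(rng.integers(lo, hi + 1))
            else:
                scaf = names[int(rng.integers(0, len(names)))]
                if lengths[scaf] <= gene_length:
                    continue
                start = int(rng.integers(0, lengths[scaf] - gene_length))
            end = start + gene_length
            if free(scaf, start, end):
                break
        else:
            raise ValueError(f"could not place gene {g} without overlap")
        occupied[scaf].append((start, end))
        if g < n_near and near_domain is not None:
            domains = frozenset([near_domain])
        elif domain_vocab and domains_per_gene > 0:
            picks = rng.choice(len(domain_vocab), size=domains_per_gene)
            domains = frozenset(domain_vocab[i] for i in picks)
        else:
            domains = frozenset()
        genes.append(
            GeneRecord(
                gene_id=f"{genome.species}_g{g:04d}",
                species=genome.species,
                scaffold=scaf,
                start0=start,
                end0=end,
                strand="+" if rng.integers(0, 2) == 0 else "-",
                domains=domains,
            )
        )
    return genes


def random_plants(
    genomes: Mapping[str, Genome],
    n_elements: int,
    seed: int,
    length_range: tuple[int, int] = (50, 300),
    margin: int = 200,
    strands: str = "+-",
) -> list[PlantSpec]:
    """Random non-overlapping PlantSpecs over mixed species subsets.

    Each element gets a random length in `length_range` (inclusive), a
    random species subset of size >= 2, one random placement per species
    (kept `margin` bp away from other plants and scaffold ends) and a
    random strand per copy.  All copies are exact (no mutations).
    """
    rng = stage_rng(seed, "random_plants")
    species = sorted(genomes)
    used: dict[tuple[str, str], list[tuple[int, int]]] = {}
    plants = []
    for e in range(n_elements):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        k = int(rng.integers(2, len(species) + 1))
        subset = sorted(rng.choice(species, size=k, replace=False))
        placements = {}
        for sp in subset:
            names = sorted(genomes[sp].scaffolds)
            for _ in range(1000):
                scaf = names[int(rng.integers(0, len(names)))]
                limit = len(genomes[sp].scaffolds[scaf]) - length - margin
                if limit <= margin:
                    continue
                start = int(rng.integers(margin, limit))
                taken = used.setdefault((sp, scaf), [])
                if all(
                    start >= e0 + margin or start + length <= s0 - margin
                    for s0, e0 in taken
                ):
                    taken.append((start, start + length))
                    break
            else:
                raise ValueError(f"could not place element {e} in {sp}")
            strand = strands[int(rng.integers(0, len(strands)))]
            placements[sp] = (scaf, start, strand)
        plants.append(PlantSpec(f"el{e:03d}", length, placements))
    return plants


def three_species_study(
    seed: int,
    scaffold_length: int = 250_000,
    n_scaffolds: int = 4,
    n_elements: int = 50,
    n_repeats_per_species: int = 20,
    repeat_unit: int = 3,
    repeat_copies: int = 12,
):
    """The canonical three-species synthetic benchmark.

    Three 1 Mb genomes (4 x 250 kb scaffolds by default) carrying 50
    exact conserved elements of 50-300 bp over mixed strands and
    species subsets, plus tandem-repeat arrays per species that the
    masking stage must remove.  Returns (genomes, element truth table,
    repeat truth intervals per species).
    """
    specs = {
        sp: SpeciesSpec(sp, n_scaffolds, scaffold_length)
        for sp in ("sp1", "sp2", "sp3")
    }
    genomes = {sp: generate_genome(spec, seed) for sp, spec in specs.items()}
    plants = random_plants(genomes, n_elements, seed)
    genomes, truth = plant_elements(genomes, plants, seed)
    repeat_truth: dict[str, list[MaskInterval]] = {}
    for sp in sorted(genomes):
        rows = truth.placements[truth.placements.species_id == sp]
        avoid = [
            (r.scaffold, r.start0 - 1, r.end0 + 1) for _, r in rows.iterrows()
        ]
        genomes[sp], repeat_truth[sp] = plant_repeats(
            genomes[sp], n_repeats_per_species, repeat_unit, repeat_copies,
            seed, avoid=avoid,
        )
    return genomes, truth, repeat_truth


def evolve_protein_families(
    tree,
    n_families: int,
    sites_per_family: int,
    seed: int,
):
    """Aligned protein families evolved under JTT along a known tree.

    `tree` is a newick string or a dendropy Tree with branch lengths in
    substitutions/site (zero allowed, negative rejected).  Sites evolve
    independently; returns (families, tree) where families is a list of
    dicts leaf_label -> sequence.
    """
    import dendropy

    from . import jtt

    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("tree must have at least 3 leaves")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")

    rng = stage_rng(seed, "evolve_families")
    transition_cache: dict[float, np.ndarray] = {}

    def transition(bl: float) -> np.ndarray:
        if bl not in transition_cache:
            transition_cache[bl] = jtt.transition_matrix(bl)
        return transition_cache[bl]

    families = []
    for _ in range(n_families):
        states: dict = {}
        root = tree.seed_node
        states[root] = rng.choice(20, size=sites_per_family, p=jtt.EQUILIBRIUM)
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            bl = node.edge.length or 0.0
            parent_states = states[node.parent_node]
            if bl == 0.0:
                states[node] = parent_states.copy()
            else:
                p = transition(bl)
                child = np.empty_like(parent_states)
                for a in range(20):
                    idx = parent_states == a
                    k = int(idx.sum())
                    if k:
                        child[idx] = rng.choice(20, size=k, p=p[a] / p[a].sum())
                states[node] = child
        fam = {}
        for leaf in tree.leaf_node_iter():
            seq = states[leaf]
            fam[leaf.taxon.label] = "".join(jtt.AA_ORDER[i] for i in seq)
        families.append(fam)
    return families, tree
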