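"""Synthetic-data generator: determinism, truth-model guarantees."""

import numpy as np
import pytest

from ultracons import jtt, simulate
from ultracons.io import revcomp


def test_genome_determinism_and_boundaries():
    spec = simulate.SpeciesSpec("sp", 1, 10_000, gc_content=0.5)
    g1 = simulate.generate_genome(spec, seed=7)
    g2 = simulate.generate_genome(spec, seed=7)
    assert g1.scaffolds == g2.scaffolds
    at_only = simulate.generate_genome(
        simulate.SpeciesSpec("sp", 1, 5_000, gc_content=0.0), seed=7
    )
    assert set(next(iter(at_only.scaffolds.values()))) <= {"A", "T"}


def test_genome_gc_within_binomial_error():
    spec = simulate.SpeciesSpec("sp", 1, 100_000, gc_content=0.5)
    seq = next(iter(simulate.generate_genome(spec, seed=3).scaffolds.values()))
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    se = np.sqrt(0.25 / 100_000)
    assert abs(gc - 0.5) < 3 * se


def test_invalid_species_spec():
    with pytest.raises(ValueError):
        simulate.SpeciesSpec("sp", 0, 100)
    with pytest.raises(ValueError):
        simulate.SpeciesSpec("sp", 1, 100, gc_content=1.5)


@pytest.fixture
def two_genomes():
    return {
        s: simulate.generate_genome(simulate.SpeciesSpec(s, 1, 5_000), seed=1)
        for s in ("A", "B")
    }


def test_plant_exact_pair_and_strand(two_genomes):
    plant = simulate.PlantSpec(
        "el0", 60,
        {"A": ("A_scaf0", 100, "+"), "B": ("B_scaf0", 900, "-")},
    )
    genomes, truth = simulate.plant_elements(two_genomes, [plant], seed=2)
    assert truth.exact_pairs() == [("el0", "A", "B")]
    a_copy = genomes["A"].fetch("A_scaf0", 100, 160)
    b_copy = genomes["B"].fetch("B_scaf0", 900, 960)
    assert b_copy == revcomp(a_copy)


def test_plant_mutation_breaks_exact_run(two_genomes):
    plant = simulate.PlantSpec(
        "el0", 60,
        {"A": ("A_scaf0", 100, "+"), "B": ("B_scaf0", 900, "+")},
        mutations={"B": 1},
    )
    genomes, truth = simulate.plant_elements(two_genomes, [plant], seed=2)
    assert truth.exact_pairs() == []
    a_copy = genomes["A"].fetch("A_scaf0", 100, 160)
    b_copy = genomes["B"].fetch("B_scaf0", 900, 960)
    assert a_copy != b_copy
    # brute-force longest common substring must be < 60
    longest = 0
    for i in range(60):
        for j in range(60):
            k = 0
            while i + k < 60 and j + k < 60 and a_copy[i + k] == b_copy[j + k]:
                k += 1
            longest = max(longest, k)
    assert longest < 60


def test_overlapping_placements_rejected(two_genomes):
    plants = [
        simulate.PlantSpec(
            "el0", 60, {"A": ("A_scaf0", 100, "+"), "B": ("B_scaf0", 100, "+")}
        ),
        simulate.PlantSpec(
            "el1", 60, {"A": ("A_scaf0", 130, "+"), "B": ("B_scaf0", 900, "+")}
        ),
    ]
    with pytest.raises(ValueError, match="el0.*el1"):
        simulate.plant_elements(two_genomes, plants, seed=0)


def test_plant_repeats_truth_and_determinism(two_genomes):
    g = two_genomes["A"]
    out, truth = simulate.plant_repeats(
        g, 1, 3, 10, seed=5, positions=[("A_scaf0", 100)], units=["AGT"]
    )
    assert [(t.scaffold, t.start0, t.end0) for t in truth] == [("A_scaf0", 100, 130)]
    assert out.fetch("A_scaf0", 100, 130) == "AGT" * 10
    same, _ = simulate.plant_repeats(
        g, 1, 3, 10, seed=5, positions=[("A_scaf0", 100)], units=["AGT"]
    )
    assert same.scaffolds == out.scaffolds
    unchanged, mask = simulate.plant_repeats(g, 0, 3, 10, seed=5)
    assert unchanged.scaffolds == g.scaffolds and mask == []


def test_annotations_near_elements(two_genomes):
    g = two_genomes["A"]
    elements = [("A_scaf0", 1000, 1100), ("A_scaf0", 3000, 3080)]
    genes = simulate.generate_annotations(
        g, 6, ["D1", "D2"], placement_rule="near-elements", seed=4,
        elements=elements, near_distance=1_000, near_fraction=1.0,
        gene_length=200,
    )
    assert len(genes) == 6
    for scaf, es, ee in elements:
        assert any(
            max(0, g0.start0 - ee, es - g0.end0) <= 1_000
            for g0 in genes if g0.scaffold == scaf
        )
    starts = sorted((g0.scaffold, g0.start0, g0.end0) for g0 in genes)
    for (s1, a1, b1), (s2, a2, b2) in zip(starts, starts[1:]):
        assert s1 != s2 or a2 >= b1  # non-overlapping
    assert simulate.generate_annotations(g, 0, ["D1"], seed=1) == []
    with pytest.raises(ValueError):
        simulate.generate_annotations(g, 3, [], seed=1)


def test_evolution_zero_branches_identical():
    fams, _ = simulate.evolve_protein_families(
        "(A:0.0,B:0.0,C:0.0);", 2, 50, seed=9
    )
    for fam in fams:
        assert len(set(fam.values())) == 1


def test_evolution_matches_jtt_p_distance():
    fams, _ = simulate.evolve_protein_families(
        "(A:0.25,B:0.25,C:0.1);", 1, 10_000, seed=5
    )
    fam = fams[0]
    p_obs = sum(a != b for a, b in zip(fam["A"], fam["B"])) / 10_000
    p_exp = jtt.expected_p_distance(0.5)
    se = np.sqrt(p_exp * (1 - p_exp) / 10_000)
    assert abs(p_obs - p_exp) < 3 * se


def test_evolution_deterministic_and_rejects_negative():
    a, _ = simulate.evolve_protein_families("(A:0.1,B:0.1,C:0.1);", 2, 30, seed=1)
    b, _ = simulate.evolve_protein_families("(A:0.1,B:0.1,C:0.1);", 2, 30, seed=1)
    assert a == b
    with pytest.raises(ValueError, match="negative"):
        simulate.evolve_protein_families("(A:-0.1,B:0.1,C:0.1);", 1, 10, seed=1)
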