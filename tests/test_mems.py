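"""Maximal-exact-match discovery vs the quadratic DP oracle."""

import numpy as np
import pytest

from ultracons import mems
from ultracons.io import Genome, revcomp

from conftest import random_dna
from oracles import mem_oracle


def as_tuples(matches):
    return {(m.start_a0, m.start_b0, m.length, m.strand) for m in matches}


def test_identity_match(rng):
    s = random_dna(rng, 200)
    got = mems.find_mems(Genome("A", {"a": s}), Genome("B", {"b": s}), 50)
    assert as_tuples(got) >= {(0, 0, 200, "+")}
    assert as_tuples(got) == mem_oracle(s, s, 50)


def test_reverse_complement_match(rng):
    s = random_dna(rng, 200)
    got = mems.find_mems(
        Genome("A", {"a": s}), Genome("B", {"b": revcomp(s)}), 50
    )
    assert as_tuples(got) == mem_oracle(s, revcomp(s), 50)
    assert (0, 0, 200, "-") in as_tuples(got)


def test_length_threshold_is_inclusive(rng):
    """A shared 49 bp segment is invisible at 50 but found at 30."""
    seg = random_dna(rng, 49)
    a = random_dna(rng, 2_000)
    b = random_dna(rng, 2_000)
    # distinct boundary bases so the shared segment is exactly 49 bp
    ga = Genome("A", {"a": a[:699] + "A" + seg + "A" + a[750:]})
    gb = Genome("B", {"b": b[:299] + "C" + seg + "C" + b[350:]})
    at50 = mems.find_mems(ga, gb, 50)
    assert not any(m.length >= 49 and m.start_a0 <= 700 <= m.end_a0 for m in at50)
    at30 = mems.find_mems(ga, gb, 30)
    assert any(
        m.start_a0 <= 700 and m.end_a0 >= 749 and m.start_b0 <= 300 for m in at30
    )


@pytest.mark.parametrize("seed", range(8))
def test_matches_equal_oracle_on_planted_instances(seed):
    rng = np.random.default_rng(seed)
    a = random_dna(rng, 1_500)
    b = random_dna(rng, 1_500)
    for length, pa, pb, minus in ((60, 100, 400, False), (80, 600, 900, True),
                                  (120, 1_000, 100, False)):
        seg = random_dna(rng, length)
        a = a[:pa] + seg + a[pa + length:]
        ins = revcomp(seg) if minus else seg
        b = b[:pb] + ins + b[pb + length:]
    got = mems.find_mems(Genome("A", {"a": a}), Genome("B", {"b": b}), 50)
    assert as_tuples(got) == mem_oracle(a, b, 50)


def test_symmetry_of_roles(rng):
    a = random_dna(rng, 800)
    b = random_dna(rng, 800)
    seg = random_dna(rng, 70)
    a = a[:100] + seg + a[170:]
    b = b[:500] + revcomp(seg) + b[570:]
    ga, gb = Genome("A", {"a": a}), Genome("B", {"b": b})
    ab = {(m.start_a0, m.start_b0, m.length, m.strand) for m in mems.find_mems(ga, gb, 50)}
    ba = {(m.start_b0, m.start_a0, m.length, m.strand) for m in mems.find_mems(gb, ga, 50)}
    assert ab == ba


def test_n_breaks_matches(rng):
    s = random_dna(rng, 200)
    broken = s[:100] + "N" + s[101:]
    got = mems.find_mems(Genome("A", {"a": s}), Genome("B", {"b": broken}), 50)
    for m in got:
        assert "N" not in broken[m.start_b0 : m.end_b0]
    assert as_tuples(got) == mem_oracle(s, broken, 50)


def test_multi_scaffold_and_empty():
    assert mems.find_mems(Genome("A", {}), Genome("B", {"b": "ACGT"}), 1) == []
    rng = np.random.default_rng(0)
    seg = random_dna(rng, 60)
    ga = Genome("A", {"a1": random_dna(rng, 300) + seg, "a2": random_dna(rng, 200)})
    gb = Genome("B", {"b1": seg + random_dna(rng, 300)})
    got = mems.find_mems(ga, gb, 50)
    assert any(m.scaffold_a == "a1" and m.start_b0 == 0 for m in got)
    # matches never span the scaffold boundary
    for m in got:
        assert m.end_a0 <= len(ga.scaffolds[m.scaffold_a])


def test_remask_drops_pure_tandem(rng):
    seq = "AT" * 30
    g = Genome("A", {"a": seq + random_dna(rng, 100)})
    m = mems.MatchRecord("A", "B", "a", "b", 0, 0, 60, "+")
    assert mems.remask_matches([m], g, 50) == []


def test_remask_trims_internal_tandem(rng):
    flank_a = random_dna(rng, 40)
    tandem = "CA" * 15
    rest = random_dna(rng, 30)
    seq = flank_a + tandem + rest
    g = Genome("A", {"a": seq})
    m = mems.MatchRecord("A", "B", "a", "b", 0, 10, len(seq), "+")
    out = mems.remask_matches([m], g, 30)
    assert len(out) == 1
    t = out[0]
    assert t.length == 40 and t.start_a0 == 0 and t.start_b0 == 10
    # below the threshold the trimmed match is dropped entirely
    assert mems.remask_matches([m], g, 45) == []


def test_remask_minus_strand_coordinates(rng):
    flank = "GG" + random_dna(rng, 48)  # break the AT period at the joint
    seq = "AT" * 20 + flank  # mask at the left, keep the right 50
    g = Genome("A", {"a": seq})
    m = mems.MatchRecord("A", "B", "a", "b", 0, 200, len(seq), "-")
    out = mems.remask_matches([m], g, 40)
    assert len(out) == 1
    t = out[0]
    assert t.start_a0 == 40 and t.length == 50
    # b interval shifts from the other end on the minus strand
    assert t.start_b0 == 200 + (len(seq) - 40 - 50)


def test_remask_identity(rng):
    seq = random_dna(rng, 120)
    g = Genome("A", {"a": seq})
    m = mems.MatchRecord("A", "B", "a", "b", 0, 0, 120, "+")
    assert mems.remask_matches([m], g, 50) == [m]
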