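"""Consensus building, background sampling, binomial motif statistic."""

import numpy as np
import pytest

from ultracons import motif
from ultracons.io import Genome

from conftest import random_dna
from oracles import binomial_enum_oracle


# --- consensus --------------------------------------------------------------

def test_consensus_identical_and_singleton(rng):
    s = random_dna(rng, 120)
    assert motif.consensus_sequence([s, s, s]) == s
    assert motif.consensus_sequence([s]) == s
    with pytest.raises(ValueError):
        motif.consensus_sequence([])


def test_consensus_majority_and_tie_break(rng):
    s = random_dna(rng, 100)
    pos = 50
    variant = list(s)
    variant[pos] = "A" if s[pos] != "A" else "C"
    out = motif.consensus_sequence([s, "".join(variant)])
    # two sequences differing at one site: alphabetical tie-break there
    expect = list(s)
    expect[pos] = min(s[pos], variant[pos])
    assert out == "".join(expect)


def test_consensus_majority_vote(rng):
    s = random_dna(rng, 90)
    mutated = list(s)
    mutated[30] = "A" if s[30] != "A" else "G"
    out = motif.consensus_sequence([s, s, "".join(mutated)])
    assert out == s  # 2-vs-1 majority keeps the original base


# --- background -------------------------------------------------------------

@pytest.fixture
def genomes(rng):
    return {
        sp: Genome(sp, {f"{sp}_s": random_dna(rng, 30_000)})
        for sp in ("A", "B", "C")
    }


def test_background_single_species(genomes):
    bg = motif.build_background(
        {"A": 1.0}, genomes, motif.BackgroundSpec(seed=1)
    )
    assert len(bg) == 10_000
    assert all(bg[i : i + 100] in genomes["A"].scaffolds["A_s"]
               for i in range(0, 10_000, 2_500))


def test_background_fractions_largest_remainder(genomes):
    spec = motif.BackgroundSpec(total_length=10_000, segment_length=100, seed=2)
    bg = motif.build_background({"A": 0.5, "B": 0.5}, genomes, spec)
    assert len(bg) == 10_000
    # thirds do not divide 10,000 evenly; largest remainder fixes the sum
    bg3 = motif.build_background({"A": 1 / 3, "B": 1 / 3, "C": 1 / 3}, genomes, spec)
    assert len(bg3) == 10_000


def test_background_deterministic(genomes):
    spec = motif.BackgroundSpec(seed=7)
    one = motif.build_background({"A": 0.4, "B": 0.6}, genomes, spec)
    two = motif.build_background({"A": 0.4, "B": 0.6}, genomes, spec)
    assert one == two


def test_background_avoids_masked_bases(genomes):
    masked = Genome("A", {"A_s": "N" * 15_000 + genomes["A"].scaffolds["A_s"][15_000:]})
    bg = motif.build_background(
        {"A": 1.0}, {"A": masked}, motif.BackgroundSpec(seed=3)
    )
    assert "N" not in bg


def test_background_too_short_genome():
    tiny = {"A": Genome("A", {"s": "ACGT" * 10})}
    with pytest.raises(ValueError):
        motif.build_background({"A": 1.0}, tiny, motif.BackgroundSpec(seed=1))


# --- binomial statistic ------------------------------------------------------

def test_binomial_examples():
    assert motif.binomial_upper(0, 10, 0.3) == 1.0
    assert motif.binomial_upper(1, 1, 0.5) == pytest.approx(0.5)
    expect = 1 - sum(
        binomial_enum_oracle(i, 10, 0.1) - binomial_enum_oracle(i + 1, 10, 0.1)
        for i in range(0, 3)
    )
    assert motif.binomial_upper(3, 10, 0.1) == pytest.approx(0.0702, abs=5e-5)
    assert motif.binomial_upper(3, 10, 0.1) == pytest.approx(expect)
    with pytest.raises(ValueError):
        motif.binomial_upper(5, 3, 0.1)
    with pytest.raises(ValueError):
        motif.binomial_upper(1, 3, 1.5)


@pytest.mark.parametrize("n", [1, 4, 9, 12])
def test_binomial_matches_enumeration(n):
    for p in (0.05, 0.3, 0.7):
        for x in range(n + 1):
            assert motif.binomial_upper(x, n, p) == pytest.approx(
                binomial_enum_oracle(x, n, p), abs=1e-12
            )


def test_binomial_nonincreasing_in_x():
    vals = [motif.binomial_upper(x, 20, 0.2) for x in range(21)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))


# --- oligomer table ----------------------------------------------------------

def test_trial_count_and_row_filtering(rng):
    rep = random_dna(rng, 100)
    bg = random_dna(rng, 10_000)
    table = motif.oligomer_enrichment(rep, bg, k=8)
    assert (table.n == 93).all()  # L - k + 1
    assert (table.x >= 1).all()  # absent 8-mers are not reported
    assert table.p_value.is_monotonic_increasing


def test_planted_oligomer_flagged(rng):
    mer = "ACGTACGT"
    rep = "".join(mer + random_dna(rng, 12) for _ in range(10))
    bg = random_dna(rng, 10_000)
    table = motif.oligomer_enrichment(rep, bg, k=8, report_threshold=1e-4)
    row = table[table.oligomer == mer].iloc[0]
    assert row.x >= 10 - 1 and row.flagged and row.p_value < 1e-4


def test_null_representative_rarely_flagged(rng):
    """Calibration: same-distribution representative and background."""
    flagged = total = 0
    for seed in range(50):
        r = np.random.default_rng(seed)
        rep = random_dna(r, 200)
        bg = random_dna(r, 10_000)
        table = motif.oligomer_enrichment(rep, bg, k=8, report_threshold=1e-4)
        flagged += int(table.flagged.sum())
        total += len(table)
    assert flagged / total <= 1e-3
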