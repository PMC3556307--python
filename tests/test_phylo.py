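"""JTT distances, neighbor-joining, bootstrap support."""

import dendropy
import numpy as np
import pytest

from ultracons import jtt, phylo, simulate


def test_three_taxon_closed_form():
    dm = phylo.DistanceMatrix(
        ("t1", "t2", "t3"), np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], float)
    )
    tree = phylo.neighbor_joining(dm)
    lengths = {child.name: bl for child, bl in tree.children}
    assert lengths == pytest.approx({"t1": 0.0, "t2": 2.0, "t3": 4.0})


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        phylo.neighbor_joining(
            phylo.DistanceMatrix(("a", "b"), np.array([[0, 1], [1, 0]], float))
        )


def _additive_matrix(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(t.label for t in tree.taxon_namespace)
    tx = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = pdm.distance(tx[taxa[i]], tx[taxa[j]])
    return phylo.DistanceMatrix(tuple(taxa), d)


NEWICK6 = "((A:0.11,B:0.07):0.09,(C:0.05,(D:0.12,E:0.06):0.08):0.10,F:0.20);"


def test_nj_recovers_additive_tree_exactly():
    dm = _additive_matrix(NEWICK6)
    tree = phylo.neighbor_joining(dm)
    recovered = phylo.path_metric(tree)
    assert recovered.taxa == dm.taxa
    assert np.abs(recovered.d - dm.d).max() < 1e-10
    assert phylo.tree_bipartitions(tree) == {
        frozenset({"A", "B"}),
        frozenset({"D", "E"}),
        frozenset({"A", "B", "F"}),  # canonical side of {C,D,E}
    }


def test_nj_invariant_to_taxon_order():
    dm = _additive_matrix(NEWICK6)
    perm = [3, 0, 5, 1, 4, 2]
    dm2 = phylo.DistanceMatrix(
        tuple(dm.taxa[i] for i in perm), dm.d[np.ix_(perm, perm)]
    )
    t1 = phylo.neighbor_joining(dm)
    t2 = phylo.neighbor_joining(dm2)
    assert phylo.tree_bipartitions(t1) == phylo.tree_bipartitions(t2)
    assert np.abs(phylo.path_metric(t2).d - phylo.path_metric(t1).d).max() < 1e-10


def test_nj_agrees_with_biopython_topology():
    from Bio.Phylo.TreeConstruction import DistanceMatrix as BioDM
    from Bio.Phylo.TreeConstruction import DistanceTreeConstructor

    dm = _additive_matrix(NEWICK6)
    lower = [[float(dm.d[i, j]) for j in range(i + 1)] for i in range(len(dm.taxa))]
    bio_tree = DistanceTreeConstructor().nj(BioDM(list(dm.taxa), lower))
    bio_parts = set()
    universe = frozenset(dm.taxa)
    for clade in bio_tree.get_nonterminals():
        side = frozenset(t.name for t in clade.get_terminals())
        if 1 < len(side) < len(universe) - 1:
            bio_parts.add(phylo._canonical(side, universe))
    assert phylo.tree_bipartitions(phylo.neighbor_joining(dm)) == bio_parts


def test_jtt_distance_identical_is_zero():
    seq = "ACDEFGHIKLMNPQRSTVWY" * 5
    assert phylo.jtt_distance(seq, seq) == 0.0


def test_jtt_distance_symmetric_and_gap_handling():
    a = "ACDEFGHIKL-MNPQRSTVW"
    b = "ACDEFGHIKLYMNPQRSTVW"
    assert phylo.jtt_distance(a, b) == pytest.approx(phylo.jtt_distance(b, a))
    with pytest.raises(ValueError):
        phylo.jtt_distance("---", "AC-")


def test_jtt_distance_saturation_warns():
    with pytest.warns(UserWarning, match="saturation"):
        d = phylo.jtt_distance("A", "R")
    assert d == phylo.DEFAULT_T_MAX


def test_jtt_distance_recovers_simulated_t():
    fams, _ = simulate.evolve_protein_families(
        "(A:0.25,B:0.25,C:0.10);", 1, 10_000, seed=5
    )
    fam = fams[0]
    t_hat = phylo.jtt_distance(fam["A"], fam["B"])
    # asymptotic SE from observed Fisher information via finite differences
    eps = 1e-4
    counts = phylo.pair_count_matrix(fam["A"], fam["B"])

    def nll(t):
        p = jtt.transition_matrix(t)
        return -(counts * (np.log(p + 1e-300) + np.log(jtt.EQUILIBRIUM)[:, None])).sum()

    info = (nll(t_hat + eps) - 2 * nll(t_hat) + nll(t_hat - eps)) / eps**2
    se = 1.0 / np.sqrt(info)
    assert abs(t_hat - 0.5) < 3 * se


def test_bootstrap_contract_and_support():
    nwk = "((A:0.1,B:0.1):0.15,(C:0.1,D:0.1):0.15,(E:0.1,F:0.1):0.15);"
    fams, _ = simulate.evolve_protein_families(nwk, 5, 400, seed=11)
    tree = phylo.bootstrap_support(fams, n_reps=50, seed=2)
    supports = []

    def collect(node):
        for child, _ in node.children:
            if child.support is not None:
                supports.append(child.support)
            collect(child)

    collect(tree)
    assert supports and all(0 <= s <= 100 for s in supports)
    assert all(isinstance(s, int) for s in supports)
    # deterministic under a fixed seed and family order
    again = phylo.bootstrap_support(fams, n_reps=50, seed=2)
    assert again.to_newick() == tree.to_newick()
    # family order must not matter
    reordered = phylo.bootstrap_support(list(reversed(fams)), n_reps=50, seed=2)
    assert phylo.tree_bipartitions(reordered) == phylo.tree_bipartitions(tree)
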