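"""Similarity graph, MCL partitioning, 5-mer profiles, MCE kernel."""

import networkx as nx
import numpy as np
import pytest

from ultracons import clustering
from ultracons.io import revcomp

from conftest import random_dna
from oracles import mst_geodesic_oracle


# --- graph building ---------------------------------------------------------

def test_identical_sequences_get_maximal_edge(rng):
    s = random_dna(rng, 150)
    g = clustering.build_graph({"u1": s, "u2": s})
    assert g.has_edge("u1", "u2")
    # the density of a perfect match is bit/length of the self-alignment
    from ultracons.align import local_align

    self_res = local_align(s, s)
    assert g["u1"]["u2"]["weight"] == pytest.approx(self_res.score_density)


def test_unrelated_sequences_stay_disconnected(rng):
    g = clustering.build_graph(
        {"u1": random_dna(rng, 150), "u2": random_dna(rng, 150)}, max_e=1e-5
    )
    assert g.number_of_edges() == 0 and g.number_of_nodes() == 2


def test_single_node_graph(rng):
    g = clustering.build_graph({"u1": random_dna(rng, 100)})
    assert list(g.nodes) == ["u1"]


def test_reverse_complement_pairs_connect(rng):
    s = random_dna(rng, 150)
    g = clustering.build_graph({"u1": s, "u2": revcomp(s)})
    assert g.has_edge("u1", "u2")


# --- MCL --------------------------------------------------------------------

def clique(g, members, weight=1.0):
    for i, u in enumerate(members):
        for v in members[i + 1:]:
            g.add_edge(u, v, weight=weight)


def test_mcl_disconnected_components_never_merge():
    g = nx.Graph()
    clique(g, [0, 1, 2])
    clique(g, [3, 4, 5])
    clusters = clustering.mcl(g)
    assert sorted(sorted(c.member_ids) for c in clusters) == [[0, 1, 2], [3, 4, 5]]


def test_mcl_singleton():
    g = nx.Graph()
    g.add_node("only")
    (c,) = clustering.mcl(g)
    assert c.member_ids == ("only",)


def test_mcl_bridged_cliques_split():
    g = nx.Graph()
    clique(g, list(range(5)))
    clique(g, list(range(5, 10)))
    g.add_edge(0, 5, weight=0.01)
    clusters = clustering.mcl(g, inflation=2.0)
    assert sorted(sorted(c.member_ids) for c in clusters) == [
        list(range(5)), list(range(5, 10))
    ]


@pytest.mark.parametrize("seed", range(10))
def test_mcl_partition_and_component_confinement(seed):
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    n_comp = rng.integers(2, 5)
    node = 0
    comps = []
    for _ in range(n_comp):
        size = int(rng.integers(2, 8))
        members = list(range(node, node + size))
        node += size
        # random connected graph: a path plus extra edges
        for u, v in zip(members, members[1:]):
            g.add_edge(u, v, weight=float(rng.uniform(0.5, 1.5)))
        for _ in range(size):
            u, v = rng.choice(members, 2, replace=False)
            g.add_edge(int(u), int(v), weight=float(rng.uniform(0.5, 1.5)))
        comps.append(set(members))
    clusters = clustering.mcl(g)
    # exact partition of the node set
    seen = [m for c in clusters for m in c.member_ids]
    assert sorted(seen) == sorted(g.nodes)
    # clusters never span disconnected components
    for c in clusters:
        assert any(set(c.member_ids) <= comp for comp in comps)


def test_mcl_invariant_to_node_insertion_order():
    def build(order):
        g = nx.Graph()
        g.add_nodes_from(order)
        clique(g, [0, 1, 2, 3, 4])
        clique(g, [5, 6, 7, 8, 9])
        g.add_edge(0, 5, weight=0.01)
        return g

    a = clustering.mcl(build(range(10)))
    b = clustering.mcl(build(reversed(range(10))))
    assert {frozenset(c.member_ids) for c in a} == {
        frozenset(c.member_ids) for c in b
    }


# --- k-mer profiles ---------------------------------------------------------

def test_kmer_profile_contract(rng):
    v = clustering.kmer_profile("AAAAA", k=5)
    assert v[0] == 1.0 and v.sum() == 1.0
    s = random_dna(rng, 500)
    v = clustering.kmer_profile(s, k=5)
    assert v.sum() == pytest.approx(1.0) and v.shape == (1024,)
    with_n = "AANAA" + s
    v2 = clustering.kmer_profile(with_n, k=5)
    assert v2.sum() == pytest.approx(1.0)  # N windows skipped, rest valid
    with pytest.warns(UserWarning):
        z = clustering.kmer_profile("ANANA", k=5)
    assert z.sum() == 0.0
    with pytest.raises(ValueError):
        clustering.kmer_profile("ACG", k=5)


# --- MCE --------------------------------------------------------------------

def test_mce_path_kernel():
    profiles = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
    kernel = clustering.mst_geodesic_kernel(profiles)
    assert kernel == pytest.approx(
        np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
    )


@pytest.mark.parametrize("seed", range(5))
def test_mce_kernel_equals_dijkstra_oracle(seed):
    rng = np.random.default_rng(seed)
    profiles = rng.normal(size=(int(rng.integers(5, 50)), 8))
    kernel = clustering.mst_geodesic_kernel(profiles)
    assert kernel == pytest.approx(mst_geodesic_oracle(profiles), rel=1e-9)
    assert np.allclose(kernel, kernel.T) and np.all(np.diag(kernel) == 0)


def test_mce_embedding_contract(rng):
    profiles = rng.normal(size=(20, 16))
    emb = clustering.mce_embed(profiles, d=3)
    assert emb.coordinates.shape == (20, 3)
    sv = emb.singular_values
    assert np.all(np.diff(sv) <= 1e-12)  # nonincreasing
    with pytest.raises(ValueError):
        clustering.mce_embed(profiles[:2], d=3)


def test_two_families_separate_in_embedding(rng):
    """Planted 5-mer families split along the top MCE dimensions."""
    masters = [random_dna(rng, 200), random_dna(rng, 200)]
    seqs, labels = [], []
    for fam, master in enumerate(masters):
        for _ in range(8):
            chars = list(master)
            for pos in rng.choice(200, size=6, replace=False):
                chars[pos] = "ACGT"[rng.integers(0, 4)]
            seqs.append("".join(chars))
            labels.append(fam)
    profiles = np.array([clustering.kmer_profile(s, k=5) for s in seqs])
    emb = clustering.mce_embed(profiles, d=3)
    from sklearn.metrics import silhouette_score

    assert silhouette_score(emb.coordinates, labels) > 0
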