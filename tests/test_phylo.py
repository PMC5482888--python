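"""Supermatrix assembly, block filtering, NJ trees and bootstrap support."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from mitocomp.phylo import (Supermatrix, bipartitions, bootstrap_support,
                            concatenate_supermatrix, filter_conserved_blocks,
                            is_sister_pair, nj_tree, p_distance_matrix)
from mitocomp.synthetic import simulate_alignment_on_tree

from oracles import best_topology_splits, random_tree_distances


def _dm(dist, taxa):
    n = len(taxa)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        m[i, j] = m[j, i] = dist[frozenset((taxa[i], taxa[j]))]
    return DistanceMatrix(m, ids=taxa)


def _tree_splits(tree):
    return bipartitions(tree)


# ---------------------------------------------------------------------------
# supermatrix

def test_concatenation_widths_and_gap_fill():
    genes = {
        "cox1": {"t1": "A" * 30, "t2": "C" * 30, "t3": "G" * 30},
        "cob": {"t1": "T" * 60, "t3": "A" * 60},
    }
    m = concatenate_supermatrix(genes)
    assert m.n_columns == 90
    assert m.partitions == {"cox1": (0, 30), "cob": (30, 90)}
    assert m.row("t2") == "C" * 30 + "-" * 60  # absent taxon gap-filled


def test_duplicate_taxon_within_gene_rejected():
    with pytest.raises(ValueError, match="duplicate taxon"):
        concatenate_supermatrix({"g": [("t1", "AAA"), ("t1", "CCC")]})


def test_gene_order_permutation_leaves_distances_unchanged():
    rng = np.random.default_rng(4)
    taxa = ["a", "b", "c", "d"]
    genes = {f"g{k}": {t: "".join(rng.choice(list("ACGT"), 40))
                       for t in taxa} for k in range(3)}
    d1 = p_distance_matrix(concatenate_supermatrix(genes))
    shuffled = dict(reversed(list(genes.items())))
    d2 = p_distance_matrix(concatenate_supermatrix(shuffled))
    np.testing.assert_allclose(d1.data, d2.data)


# ---------------------------------------------------------------------------
# block filtering

def test_identical_alignment_passes_filter_unchanged():
    m = Supermatrix(taxa=["a", "b", "c"], sequences=["ACGT" * 10] * 3,
                    partitions={"g": (0, 40)})
    out = filter_conserved_blocks(m)
    assert out.sequences == m.sequences
    assert out.partitions == {"g": (0, 40)}


def test_gap_columns_removed_at_default_settings():
    base = "A" * 30
    m = Supermatrix(taxa=["a", "b", "c"],
                    sequences=[base, base[:15] + "-" + base[16:], base])
    out = filter_conserved_blocks(m)
    assert out.n_columns < 30
    assert all("-" not in s for s in out.sequences)


def test_stricter_conservation_never_keeps_more_columns():
    rng = np.random.default_rng(11)
    seqs = ["".join(rng.choice(list("ACGT"), 400, p=[0.7, 0.1, 0.1, 0.1]))
            for _ in range(6)]
    m = Supermatrix(taxa=[f"t{i}" for i in range(6)], sequences=seqs)
    widths = []
    for min_cons in (0.3, 0.5, 0.7, 0.9):
        try:
            widths.append(filter_conserved_blocks(
                m, min_block_len=5, min_conservation=min_cons).n_columns)
        except ValueError:
            widths.append(0)
    assert widths == sorted(widths, reverse=True)


def test_all_columns_removed_is_an_error():
    m = Supermatrix(taxa=["a", "b", "c"],
                    sequences=["A-A", "C-C", "G-G"])
    with pytest.raises(ValueError, match="no columns retained"):
        filter_conserved_blocks(m)


# ---------------------------------------------------------------------------
# distances

def test_identical_rows_have_zero_distance():
    m = Supermatrix(taxa=["a", "b", "c"], sequences=["ACGT" * 5] * 3)
    assert np.allclose(p_distance_matrix(m).data, 0.0)


def test_p_distance_is_a_metric_on_gap_free_alignments():
    rng = np.random.default_rng(21)
    seqs = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(5)]
    d = p_distance_matrix(
        Supermatrix(taxa=list("abcde"), sequences=seqs)).data
    for i, j, k in itertools.permutations(range(5), 3):
        assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


def test_all_gap_overlap_is_an_error():
    m = Supermatrix(taxa=["a", "b", "c"],
                    sequences=["AAA---", "---CCC", "GGGGGG"])
    with pytest.raises(ValueError, match="no.*gap-free columns"):
        p_distance_matrix(m)


def test_fewer_than_three_taxa_rejected():
    m = Supermatrix(taxa=["a", "b"], sequences=["AAAA", "CCCC"])
    with pytest.raises(ValueError, match="at least 3"):
        p_distance_matrix(m)


# ---------------------------------------------------------------------------
# neighbor-joining vs oracles

def test_nj_recovers_four_taxon_additive_tree_with_branch_lengths():
    # ((a:1,b:2):3,(c:4,d:5)) -> pairwise path lengths
    dist = {frozenset("ab"): 3, frozenset("ac"): 8, frozenset("ad"): 9,
            frozenset("bc"): 9, frozenset("bd"): 10, frozenset("cd"): 9}
    taxa = list("abcd")
    tree = nj_tree(_dm(dist, taxa))
    assert _tree_splits(tree) == {frozenset((frozenset("ab"),
                                             frozenset("cd")))}
    tips = {t.name: t.length for t in tree.tips()}
    assert tips["a"] == pytest.approx(1.0)
    assert tips["d"] == pytest.approx(5.0)
    # path a..b = 3 exactly
    assert tree.find("a").distance(tree.find("b")) == pytest.approx(3.0)


@pytest.mark.parametrize("n_taxa", [4, 5, 6])
def test_nj_matches_exhaustive_least_squares_oracle(n_taxa):
    rng = np.random.default_rng(100 + n_taxa)
    taxa = [f"t{i}" for i in range(n_taxa)]
    for _ in range(10):
        true_splits, dist = random_tree_distances(taxa, rng)
        assert _tree_splits(nj_tree(_dm(dist, taxa))) == true_splits
        assert best_topology_splits(dist, taxa) == true_splits


@pytest.mark.parametrize("n_taxa", [7, 8])
def test_nj_recovers_larger_additive_trees(n_taxa):
    rng = np.random.default_rng(200 + n_taxa)
    taxa = [f"t{i}" for i in range(n_taxa)]
    for _ in range(10):
        true_splits, dist = random_tree_distances(taxa, rng)
        assert _tree_splits(nj_tree(_dm(dist, taxa))) == true_splits


def test_nj_agrees_with_skbio_reference_implementation():
    rng = np.random.default_rng(77)
    taxa = [f"t{i}" for i in range(7)]
    for _ in range(10):
        _, dist = random_tree_distances(taxa, rng)
        dm = _dm(dist, taxa)
        assert _tree_splits(nj_tree(dm)) == _tree_splits(skbio_nj(dm))


# ---------------------------------------------------------------------------
# bootstrap and sister pairs

def test_bootstrap_supports_are_100_for_zero_column_variance():
    # every column identical -> every replicate rebuilds the same tree
    m = Supermatrix(taxa=list("abcd"),
                    sequences=["A" * 50, "A" * 50, "C" * 50, "G" * 50])
    tree = bootstrap_support(m, replicates=20, seed=0)
    sup = [n.bootstrap for n in tree.non_tips(include_self=False)
           if hasattr(n, "bootstrap")]
    assert sup and all(s == 100.0 for s in sup)


def test_strong_signal_simulation_supports_every_true_split():
    newick = ("((A:0.05,B:0.05):0.15,(C:0.05,D:0.05):0.15,"
              "(E:0.05,F:0.25):0.10);")
    aln = simulate_alignment_on_tree(newick, 10_000, seed=1234)
    m = Supermatrix(taxa=sorted(aln), sequences=[aln[t] for t in sorted(aln)])
    tree = bootstrap_support(m, replicates=100, seed=4321)
    supports = [n.bootstrap for n in tree.non_tips(include_self=False)
                if hasattr(n, "bootstrap")]
    assert len(supports) == 3  # 6 taxa -> 3 internal edges
    assert all(0 <= s <= 100 for s in supports)
    assert min(supports) >= 95.0
    true_splits = {
        frozenset((frozenset("AB"), frozenset("CDEF"))),
        frozenset((frozenset("CD"), frozenset("ABEF"))),
        frozenset((frozenset("EF"), frozenset("ABCD"))),
    }
    assert _tree_splits(tree) == true_splits


def test_is_sister_pair_on_four_taxon_tree():
    dist = {frozenset("ab"): 2, frozenset("ac"): 6, frozenset("ad"): 6,
            frozenset("bc"): 6, frozenset("bd"): 6, frozenset("cd"): 2}
    tree = nj_tree(_dm(dist, list("abcd")))
    assert is_sister_pair(tree, "a", "b")[0]
    assert not is_sister_pair(tree, "a", "c")[0]
    with pytest.raises(KeyError):
        is_sister_pair(tree, "a", "zz")
    with pytest.raises(ValueError, match="outgroup"):
        is_sister_pair(tree, "a", "b", outgroup="a")


def test_sesarmid_cherry_recovered_end_to_end():
    """Two sesarmid taxa simulated as a cherry are reported as sisters."""
    newick = ("((Csinensis:0.03,Ssinensis:0.03):0.12,"
              "((Hlatimera:0.05,Ejaponica:0.05):0.08,"
              "(Pcrassipes:0.10,Adistinguendus:0.25):0.04):0.05);")
    aln = simulate_alignment_on_tree(newick, 8_000, seed=555)
    m = Supermatrix(taxa=sorted(aln), sequences=[aln[t] for t in sorted(aln)])
    tree = bootstrap_support(m, replicates=100, seed=556)
    sister, support = is_sister_pair(tree, "Csinensis", "Ssinensis",
                                     outgroup="Adistinguendus")
    assert sister
    assert support is not None and support >= 95.0
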