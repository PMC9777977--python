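"""ORF finding, protein parameters, identity and neighbor joining."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from Bio.SeqUtils.ProtParamData import DIWV

from candsnp import (
    find_orfs,
    identity_matrix,
    nj_tree,
    percent_identity,
    protein_params,
    simulate_coding_sequence,
)


class TestFindOrfs:
    def test_minimal_orf_and_translation(self):
        orfs = find_orfs("ATGAAATAA", min_len=6)
        assert len(orfs) == 1
        orf = orfs[0]
        assert (orf.start, orf.end, orf.length, orf.protein) == (0, 9, 9, "MK")

    @pytest.mark.parametrize(
        "orf_nt,aa", [(1398, 465), (1404, 467), (1278, 425)]
    )
    def test_planted_cds_recovered_with_expected_protein_length(self, orf_nt, aa):
        seq, start = simulate_coding_sequence(orf_nt, seed=13)
        hits = [o for o in find_orfs(seq, min_len=300) if o.length == orf_nt]
        assert len(hits) == 1
        orf = hits[0]
        assert orf.start == start
        assert len(orf.protein) == aa == orf.length // 3 - 1

    def test_no_start_codon_gives_empty_list(self):
        assert find_orfs("CCCCCCTAACCC", min_len=6) == []

    def test_nested_starts_each_reported(self):
        orfs = find_orfs("ATGATGAAATAA", min_len=6)
        assert sorted(o.length for o in orfs) == [9, 12]

    def test_reverse_strand_orf_found_only_with_flag(self):
        from Bio.Seq import Seq

        fwd = "ATGAAATAA"
        seq = str(Seq(fwd).reverse_complement())
        assert find_orfs(seq, min_len=6) == []
        rev = find_orfs(seq, min_len=6, both_strands=True)
        assert len(rev) == 1 and rev[0].strand == -1 and rev[0].protein == "MK"

    def test_bad_characters_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            find_orfs("ATGXXXTAA")


class TestProteinParams:
    def test_poly_isoleucine_has_maximum_gravy(self):
        assert protein_params("IIIIII").gravy == pytest.approx(4.5)

    def test_poly_alanine_aliphatic_index_is_100(self):
        assert protein_params("AAAAAAA").aliphatic_index == pytest.approx(100.0)

    def test_instability_index_matches_dipeptide_weight_oracle(self):
        seq = "MKWVT"
        expected = (10 / len(seq)) * sum(
            DIWV[a][b] for a, b in zip(seq, seq[1:])
        )
        assert protein_params(seq).instability_index == pytest.approx(expected)

    def test_charged_residue_counts(self):
        p = protein_params("DEDERKRKH")
        assert (p.n_negative, p.n_positive) == (4, 4)

    def test_classification_flags(self):
        # glutamine-proline rich sequences are classic high-instability cases
        p = protein_params("QPPQPPQPPQPP")
        assert p.instability_index > 40 and p.stability == "unstable"
        assert p.gravy < 0 and p.hydropathy_class == "hydrophilic"

    def test_nonstandard_residue_named_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            protein_params("MKXVT")


class TestIdentity:
    def test_identical_sequences_are_100_percent(self):
        assert percent_identity("MKWVT", "MKWVT") == 100.0

    def test_three_quarters_identity(self):
        assert percent_identity("AAAA", "AAAT") == 75.0

    def test_gap_columns_excluded(self):
        assert percent_identity("A-CD", "ABCD") == 100.0

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="aligned"):
            percent_identity("AA", "AAA")

    def test_random_pair_matches_column_count_oracle(self):
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(list("ACDEFG-"), size=200))
        b = "".join(rng.choice(list("ACDEFG-"), size=200))
        cols = [(x, y) for x, y in zip(a, b) if "-" not in (x, y)]
        expected = 100.0 * sum(x == y for x, y in cols) / len(cols)
        assert percent_identity(a, b) == pytest.approx(expected)

    def test_matrix_diagonal_and_symmetry(self):
        m = identity_matrix({"s1": "MKWVT", "s2": "MKWVA", "s3": "MKAVT"})
        assert (np.diag(m.to_numpy()) == 100.0).all()
        np.testing.assert_allclose(m.to_numpy(), m.to_numpy().T)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def _tree_from_newick(newick, taxa):
    tns = dendropy.TaxonNamespace(taxa)
    return dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)


def _rf(newick_a, newick_b, taxa):
    tns = dendropy.TaxonNamespace(taxa)
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns,
                           rooting="force-unrooted")
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns,
                           rooting="force-unrooted")
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


def _additive_distances_4taxon(pair, lengths):
    """Distance matrix of the unrooted 4-taxon tree with sibling ``pair``.

    ``lengths`` = (la, lb, lc, ld, internal) for taxa A-D in the order
    (pair[0], pair[1], other[0], other[1]).
    """
    taxa = list("ABCD")
    others = [t for t in taxa if t not in pair]
    order = [pair[0], pair[1], others[0], others[1]]
    la, lb, lc, ld, mid = lengths
    leaf = dict(zip(order, [la, lb, lc, ld]))
    D = np.zeros((4, 4))
    for i, x in enumerate(taxa):
        for j, y in enumerate(taxa):
            if i == j:
                continue
            same_side = {x, y} == set(pair) or {x, y} == set(others)
            D[i, j] = leaf[x] + leaf[y] + (0 if same_side else mid)
    return D


def _min_evolution_topology(D):
    """Exhaustive oracle: OLS branch lengths for all 3 topologies, pick the
    one with the smallest total length (ties by fit error)."""
    taxa = list("ABCD")
    best = None
    for pair in (("A", "B"), ("A", "C"), ("A", "D")):
        others = tuple(t for t in taxa if t not in pair)
        order = [pair[0], pair[1], others[0], others[1]]
        idx = [taxa.index(t) for t in order]
        # rows: pairs (0,1),(0,2),(0,3),(1,2),(1,3),(2,3) in `order` indexing
        pairs = list(itertools.combinations(range(4), 2))
        X = np.zeros((6, 5))
        y = np.zeros(6)
        for r, (i, j) in enumerate(pairs):
            X[r, i] = X[r, j] = 1.0
            same_side = {i, j} in ({0, 1}, {2, 3})
            if not same_side:
                X[r, 4] = 1.0
            y[r] = D[idx[i], idx[j]]
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        fit_err = float(((X @ beta - y) ** 2).sum())
        total = float(np.clip(beta, 0, None).sum())
        key = (round(total, 10), round(fit_err, 10))
        if best is None or key < best[0]:
            best = (key, pair)
    return best[1]


def _sibling_pair_of_A(newick, taxa=("A", "B", "C", "D")):
    """The 4-taxon topology, reported as the sorted pair grouped with A."""
    tree = _tree_from_newick(newick, list(taxa))
    tree.encode_bipartitions()
    for bip in tree.bipartition_encoding:
        names = {t.label for t in bip.leafset_taxa(tree.taxon_namespace)}
        if len(names) == 2:
            if "A" in names:
                return tuple(sorted(names))
            rest = set(taxa) - names
            if "A" in rest:
                return tuple(sorted(rest))
    raise AssertionError("no pair split found")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        newick = nj_tree(D, ["A", "B", "C"])
        tree = _tree_from_newick(newick, ["A", "B", "C"])
        lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_additive_five_taxon_matrix_recovered_exactly(self):
        true_newick = "((A:2,B:3):1,(C:4,D:1):2,E:5);"
        taxa = list("ABCDE")
        tns = dendropy.TaxonNamespace(taxa)
        true_tree = dendropy.Tree.get(data=true_newick, schema="newick",
                                      taxon_namespace=tns)
        pdm = true_tree.phylogenetic_distance_matrix()
        D = np.array(
            [[pdm.distance(tns.get_taxon(a), tns.get_taxon(b)) for b in taxa]
             for a in taxa]
        )
        newick = nj_tree(D, taxa)
        assert _rf(newick, true_newick, taxa) == 0
        # total branch length is preserved for an additive matrix
        est = _tree_from_newick(newick, taxa)
        assert est.length() == pytest.approx(true_tree.length())

    def test_matches_minimum_evolution_oracle_on_random_additive_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            pair = [("A", "B"), ("A", "C"), ("A", "D")][rng.integers(3)]
            lengths = rng.uniform(0.5, 5.0, size=5)
            D = _additive_distances_4taxon(pair, lengths)
            newick = nj_tree(D, list("ABCD"))
            cherry = _sibling_pair_of_A(newick)
            assert cherry == tuple(sorted(pair))                   # generating topology
            assert cherry == tuple(sorted(_min_evolution_topology(D)))  # ME oracle

    def test_ultrametric_matrices_recover_generating_topology(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            taxa = [f"t{i}" for i in range(n)]
            tns = dendropy.TaxonNamespace(taxa)
            import random

            true_tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
                taxon_namespace=tns, rng=random.Random(int(rng.integers(1 << 30))),
            )
            pdm = true_tree.phylogenetic_distance_matrix()
            D = np.array(
                [[pdm.distance(tns.get_taxon(a), tns.get_taxon(b)) for b in taxa]
                 for a in taxa]
            )
            newick = nj_tree(D, taxa)
            assert _rf(newick, true_tree.as_string(schema="newick"), taxa) == 0

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.1, 0, 3], [2, 3, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(D, ["A", "B", "C"])
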