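"""Receptor curation, similarity, neighbor joining, clade extraction."""

import random

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare
from dendropy.simulate import treesim

from lrrpockets.simulate import (
    LRR_UNIT_PATTERN,
    SimConfig,
    curation_reference_receptor,
)
from lrrpockets.receptors import (
    DistanceMatrix,
    PhyloTree,
    curation_filter,
    detect_lrr_repeats,
    extract_clade,
    nj_tree,
    similarity_matrix,
)


def _unit(rng):
    return "".join(
        c if c != "x" else rng.choice("ACDEFGHIKMNPQRSTVWY")
        for c in LRR_UNIT_PATTERN
    )


class TestDetectRepeats:
    def test_curation_reference_reports_24_repeats(self):
        _, seq = curation_reference_receptor(SimConfig(seed=1))
        assert detect_lrr_repeats(seq).n_repeats == 24

    def test_family_members_keep_the_reference_count(self, receptor_family):
        for _, seq in receptor_family.records:
            assert detect_lrr_repeats(seq).n_repeats == 24

    def test_poly_alanine_has_no_repeats(self):
        assert detect_lrr_repeats("A" * 200).n_repeats == 0

    def test_middle_unit_with_three_anchor_mismatches_skipped(self):
        rng = random.Random(0)
        units = [_unit(rng) for _ in range(3)]
        broken = list(units[1])
        anchor_positions = [i for i, c in enumerate(LRR_UNIT_PATTERN)
                            if c != "x"][:3]
        for pos in anchor_positions:
            broken[pos] = "W"
        seq = units[0] + "".join(broken) + units[2]
        ann = detect_lrr_repeats(seq)
        # regex-with-mismatch oracle: only windows with <=2 anchor errors
        anchors = [(i, c) for i, c in enumerate(LRR_UNIT_PATTERN) if c != "x"]
        oracle = [
            i for i in range(len(seq) - 24 + 1)
            if sum(seq[i + off] != c for off, c in anchors) <= 2
        ]
        assert ann.n_repeats == 2
        assert [s for s, _ in ann.repeats] == oracle

    def test_two_mismatches_still_match(self):
        rng = random.Random(1)
        unit = list(_unit(rng))
        anchor_positions = [i for i, c in enumerate(LRR_UNIT_PATTERN)
                            if c != "x"][:2]
        for pos in anchor_positions:
            unit[pos] = "W"
        assert detect_lrr_repeats("".join(unit)).n_repeats == 1


class TestCurationFilter:
    def test_partition_and_reasons(self):
        rng = random.Random(2)
        good = "".join(_unit(rng) for _ in range(24))
        short = "".join(_unit(rng) for _ in range(23))
        kept, ann, rejected = curation_filter({"ok": good, "short": short},
                                              expected_repeats=24)
        assert kept == ["ok"]
        assert rejected["short"].startswith("repeat_count")
        assert set(kept) | set(rejected) == {"ok", "short"}
        assert ann["ok"].n_repeats == 24

    def test_gap_outside_repeats_rejected(self):
        rng = random.Random(3)
        seq = "MKTWSPQE" + "".join(_unit(rng) for _ in range(24))
        row_ok = seq
        row_gap = "MKTW-PQE" + seq[8:]          # gap in the cap segment
        kept, _, rejected = curation_filter(
            {"a": seq, "b": seq}, expected_repeats=24,
            alignment={"a": row_ok, "b": row_gap},
        )
        assert kept == ["a"]
        assert rejected["b"] == "gap_outside_repeats"

    def test_gap_inside_repeat_not_flagged_by_outside_rule(self):
        rng = random.Random(4)
        seq = "".join(_unit(rng) for _ in range(24))
        row = seq[:10] + "-" + seq[10:]         # gap column inside repeat 1
        kept, _, rejected = curation_filter(
            {"a": seq}, expected_repeats=24, alignment={"a": row})
        assert kept == ["a"] and rejected == {}


class TestSimilarityMatrix:
    def test_identical_pair(self):
        dm, report = similarity_matrix({"a": "ACDEFGHIKL",
                                        "b": "ACDEFGHIKL"})
        assert dm.matrix[0, 1] == pytest.approx(0.0)
        assert report[("a", "b")] == pytest.approx(100.0)

    def test_hand_alignment_identity(self):
        dm, _ = similarity_matrix({"a": "ACDE", "b": "ACDK"})
        assert dm.matrix[0, 1] == pytest.approx(0.25)   # identity 0.75

    def test_symmetric_and_order_invariant(self):
        seqs = {"a": "ACDEFGHIKL", "b": "ACDEFGHIKW", "c": "MNPQRSTVWY"}
        dm1, _ = similarity_matrix(seqs)
        dm2, _ = similarity_matrix(dict(reversed(list(seqs.items()))))
        assert np.allclose(dm1.matrix, dm1.matrix.T)
        assert dm1.taxa == dm2.taxa
        assert np.allclose(dm1.matrix, dm2.matrix)

    def test_invariant_checks(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.2, 0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[0.1, 0.2], [0.2, 0]]))


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        t = nj_tree(DistanceMatrix(["A", "B"],
                                   np.array([[0, 0.3], [0.3, 0]])))
        assert "A:0.300000" in t.newick

    def test_three_taxa_closed_form(self):
        d = np.array([[0, .2, .4], [.2, 0, .5], [.4, .5, 0]])
        t = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        # v_A = (d_AB + d_AC - d_BC) / 2 = 0.05
        assert "A:0.050000" in t.newick
        assert "B:0.150000" in t.newick

    def test_four_taxa_additive_topology(self):
        # distances additive on ((A,B),(C,D))
        d = np.array([[0, .2, .6, .7], [.2, 0, .6, .7],
                      [.6, .6, 0, .3], [.7, .7, .3, 0]])
        t = nj_tree(DistanceMatrix(list("ABCD"), d))
        tns = dendropy.TaxonNamespace(list("ABCD"))
        got = dendropy.Tree.get(data=t.newick, schema="newick",
                                taxon_namespace=tns,
                                preserve_underscores=True)
        want = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick",
                                 taxon_namespace=tns)
        got.encode_bipartitions()
        want.encode_bipartitions()
        assert treecompare.symmetric_difference(got, want) == 0

    def test_matches_independent_skbio_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(0)
        n = 7
        taxa = [f"t{i}" for i in range(n)]
        base = rng.uniform(0.1, 0.9, size=(n, n))
        m = np.clip((base + base.T) / 2, 0, 1)
        np.fill_diagonal(m, 0)
        mine = nj_tree(DistanceMatrix(taxa, m))
        theirs = skbio_nj(SkbioDM(m, ids=taxa))
        tns = dendropy.TaxonNamespace(taxa)
        t1 = dendropy.Tree.get(data=mine.newick, schema="newick",
                               taxon_namespace=tns,
                               preserve_underscores=True)
        t2 = dendropy.Tree.get(data=str(theirs).strip(), schema="newick",
                               taxon_namespace=tns,
                               preserve_underscores=True)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert treecompare.symmetric_difference(t1, t2) == 0


def random_binary_tree_distances(n, seed):
    """Seeded random binary tree with positive branch lengths and its
    patristic distance matrix (the additive case)."""
    tns = dendropy.TaxonNamespace([f"t{i:02d}" for i in range(n)])
    rng = random.Random(seed)
    tree = treesim.pure_kingman_tree(taxon_namespace=tns, pop_size=1,
                                     rng=rng)
    for e in tree.edges():
        if e.length is not None:
            e.length = max(float(e.length), 0.02)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tns, key=lambda t: t.label)
    m = np.array([[pdm.patristic_distance(a, b) for b in taxa]
                  for a in taxa])
    m = m / (m.max() * 1.05)
    return tree, tns, [t.label for t in taxa], m


class TestCladeExtraction:
    @pytest.fixture(scope="class")
    def tree(self):
        d = np.array([
            [0, .2, .6, .7, .9],
            [.2, 0, .6, .7, .9],
            [.6, .6, 0, .3, .9],
            [.7, .7, .3, 0, .9],
            [.9, .9, .9, .9, 0],
        ])
        return nj_tree(DistanceMatrix(["A", "B", "C", "D", "OUT"], d))

    def test_all_ingroup_seeds_return_whole_ingroup(self, tree):
        got = extract_clade(tree, outgroup="OUT", seeds=["A", "B", "C", "D"])
        assert got == {"A", "B", "C", "D"}

    def test_single_seed_returns_that_leaf(self, tree):
        assert extract_clade(tree, outgroup="OUT", seeds=["C"]) == {"C"}

    def test_seeds_in_one_subtree_return_exactly_it(self, tree):
        assert extract_clade(tree, outgroup="OUT",
                             seeds=["A", "B"]) == {"A", "B"}
        assert extract_clade(tree, outgroup="OUT",
                             seeds=["C", "D"]) == {"C", "D"}

    def test_missing_outgroup_or_seed_raises(self, tree):
        with pytest.raises(KeyError, match="outgroup"):
            extract_clade(tree, outgroup="nope", seeds=["A"])
        with pytest.raises(KeyError, match="seed"):
            extract_clade(tree, outgroup="OUT", seeds=["nope"])

    def test_planted_subtree_recovered_from_generated_distances(self):
        tree, tns, taxa, m = random_binary_tree_distances(9, seed=5)
        nj = nj_tree(DistanceMatrix(taxa, m))
        # truth: leaves of one child of the root, rooted at another leaf
        outgroup = taxa[0]
        t = dendropy.Tree.get(data=nj.newick, schema="newick",
                              taxon_namespace=tns,
                              preserve_underscores=True)
        og = next(lf for lf in t.leaf_node_iter()
                  if lf.taxon.label == outgroup)
        t.to_outgroup_position(og, update_bipartitions=True)
        ingroup = [lf.taxon.label for lf in t.leaf_node_iter()
                   if lf.taxon.label != outgroup]
        sub = extract_clade(nj, outgroup=outgroup, seeds=ingroup[:3])
        # the extracted clade is the smallest rooted clade holding the seeds
        assert set(ingroup[:3]) <= sub <= set(ingroup)
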