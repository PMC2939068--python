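import tempfile
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylodiag.errors import (
    AlignmentShapeError,
    FormatError,
    ValidationError,
)
from phylodiag.seqio import (
    Alignment,
    TaxonPartition,
    concatenate,
    is_rooted,
    read_fasta,
    read_newick,
    read_nexus_alignment,
    read_taxon_table,
    read_tree_sample,
    root_with_outgroup,
    write_fasta,
    write_newick,
    write_nexus_alignment,
    write_taxon_table,
)

from helpers import random_tree_newick


class TestAlignment:
    def test_basic_construction(self):
        aln = Alignment(("a", "b"), ("ACGT", "ACGA"))
        assert aln.n_taxa == 2
        assert aln.column_count == 4
        assert aln.partitions == {"default": (1, 4)}

    def test_ragged_rows_rejected(self):
        with pytest.raises(AlignmentShapeError):
            Alignment(("a", "b"), ("ACGT", "ACGTA"))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError):
            Alignment(("a", "a"), ("ACGT", "ACGT"))

    def test_overlapping_partitions_rejected(self):
        with pytest.raises(ValidationError):
            Alignment(("a",), ("ACGTACGT",), {"p1": (1, 5), "p2": (4, 8)})

    def test_column_addressing_is_one_based(self):
        aln = Alignment(("a", "b"), ("ACGT", "TGCA"))
        assert aln.column(1) == {"a": "A", "b": "T"}
        assert aln.column(4) == {"a": "T", "b": "A"}
        with pytest.raises(ValidationError):
            aln.column(0)


class TestFasta:
    def test_round_trip(self, tmp_path):
        aln = Alignment(("x1", "x2", "x3"), ("AC-T", "ACGT", "A??T"))
        p = tmp_path / "a.fasta"
        write_fasta(aln, p)
        back = read_fasta(p)
        assert back.taxon_labels == aln.taxon_labels
        assert back.matrix == aln.matrix

    def test_record_order_preserved(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">z\nACGT\n>a\nTTTT\n")
        assert read_fasta(p).taxon_labels == ("z", "a")

    def test_ragged_input_is_shape_error(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n>b\nACGTA\n")
        with pytest.raises(AlignmentShapeError):
            read_fasta(p)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n_taxa=st.integers(2, 6),
        ncols=st.integers(1, 30),
        seed=st.integers(0, 10**6),
    )
    def test_round_trip_property(self, n_taxa, ncols, seed):
        rng = np.random.default_rng(seed)
        chars = np.array(list("ACGTN-?"))
        labels = tuple(f"tax{i}" for i in range(n_taxa))
        seqs = tuple(
            "".join(rng.choice(chars, size=ncols)) for _ in range(n_taxa)
        )
        aln = Alignment(labels, seqs)
        with tempfile.TemporaryDirectory() as d:
            p = Path(d) / "x.fasta"
            write_fasta(aln, p)
            back = read_fasta(p)
        assert back.matrix == aln.matrix
        assert back.taxon_labels == aln.taxon_labels


class TestNexus:
    def test_charsets_become_partitions(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2 NCHAR=5;\n"
            "FORMAT DATATYPE=DNA MISSING=? GAP=-;\nMATRIX\n"
            "a ACGTA\nb ACGTT\n;\nEND;\n"
            "BEGIN SETS;\nCHARSET p1 = 1-3;\nEND;\n"
        )
        aln = read_nexus_alignment(p)
        assert aln.partitions["p1"] == (1, 3)
        assert aln.partitions["unassigned"] == (4, 5)

    def test_no_charsets_single_default(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2 NCHAR=4;\n"
            "FORMAT DATATYPE=DNA;\nMATRIX\na ACGT\nb ACGA\n;\nEND;\n"
        )
        assert read_nexus_alignment(p).partitions == {"default": (1, 4)}

    def test_interleaved_equals_sequential(self, tmp_path):
        seq = tmp_path / "s.nex"
        inter = tmp_path / "i.nex"
        seq.write_text(
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2 NCHAR=8;\n"
            "FORMAT DATATYPE=DNA;\nMATRIX\na ACGTACGT\nb ACGAACGA\n;\nEND;\n"
        )
        inter.write_text(
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2 NCHAR=8;\n"
            "FORMAT DATATYPE=DNA INTERLEAVE;\nMATRIX\n"
            "a ACGT\nb ACGA\n\na ACGT\nb ACGA\n;\nEND;\n"
        )
        assert read_nexus_alignment(seq).matrix == read_nexus_alignment(inter).matrix

    def test_round_trip(self, tmp_path):
        aln = Alignment(("a", "b"), ("ACGTACGT", "ACGAAC-A"), {"m": (1, 5), "n": (6, 8)})
        p = tmp_path / "w.nex"
        write_nexus_alignment(aln, p)
        back = read_nexus_alignment(p)
        assert back.matrix == aln.matrix
        assert back.partitions == aln.partitions

    def test_missing_data_block_is_format_error(self, tmp_path):
        p = tmp_path / "bad.nex"
        p.write_text("#NEXUS\nBEGIN TREES;\nTREE t = (a,b);\nEND;\n")
        with pytest.raises(FormatError):
            read_nexus_alignment(p)


class TestConcatenate:
    def test_study_scale_partition_arithmetic(self):
        # mitochondrial-like 1348 columns + nuclear-like 481 -> 1829
        a = Alignment(("x", "y"), ("A" * 1348, "C" * 1348))
        b = Alignment(("x", "y"), ("G" * 481, "T" * 481))
        cat = concatenate([a, b], ["mito", "nuclear"])
        assert cat.column_count == 1829
        assert cat.partitions == {"mito": (1, 1348), "nuclear": (1349, 1829)}

    def test_single_input_is_identity(self):
        a = Alignment(("x", "y"), ("ACGT", "TGCA"))
        cat = concatenate([a], ["only"])
        assert cat.matrix == a.matrix

    def test_rows_aligned_by_label_not_position(self):
        a = Alignment(("x", "y"), ("AA", "CC"))
        b = Alignment(("y", "x"), ("GG", "TT"))
        cat = concatenate([a, b])
        assert cat.sequence("x") == "AATT"
        assert cat.sequence("y") == "CCGG"

    def test_mismatch_without_fill_is_error(self):
        a = Alignment(("x", "y"), ("AA", "CC"))
        b = Alignment(("x", "z"), ("GG", "TT"))
        with pytest.raises(ValidationError):
            concatenate([a, b])
        cat = concatenate([a, b], fill_missing=True)
        assert cat.sequence("z") == "??TT"

    def test_associativity_of_matrix_and_boundaries(self):
        parts = [
            Alignment(("x", "y"), ("AC", "GT")),
            Alignment(("x", "y"), ("CA", "TG")),
            Alignment(("x", "y"), ("GG", "AA")),
        ]
        left = concatenate(
            [concatenate(parts[:2], ["a", "b"]), parts[2]], ["ab", "c"]
        )
        flat = concatenate(parts, ["a", "b", "c"])
        assert left.matrix == flat.matrix
        assert flat.partitions["c"] == (5, 6)

    def test_column_offset_identity(self):
        a = Alignment(("x", "y"), ("ACGT", "TGCA"))
        b = Alignment(("x", "y"), ("CCC", "GGG"))
        cat = concatenate([a, b], ["p", "q"])
        start = cat.partitions["q"][0]
        for i in range(1, 4):
            assert cat.column(start + i - 1) == b.column(i)


class TestTrees:
    def test_parse_small_tree(self):
        tree = read_newick("(A:1,(B:1,C:1):1);")
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        assert sorted(leaves) == ["A", "B", "C"]
        assert len(tree.seed_node.child_nodes()) == 2

    def test_unbalanced_parens_rejected(self):
        with pytest.raises(FormatError):
            read_newick("((A,B);")

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(ValidationError):
            read_newick("(A:1,A:1);")

    def test_internal_labels_become_support(self):
        tree = read_newick("((A:1,B:1)95:1,C:1);")
        supports = [
            n.support
            for n in tree.preorder_node_iter()
            if getattr(n, "support", None) is not None
        ]
        assert supports == [95.0]

    def test_node_ids_are_preorder_and_stable(self):
        tree = read_newick("((A:1,B:1):1,C:1);")
        ids = [n.node_id for n in tree.preorder_node_iter()]
        assert ids == list(range(len(ids)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(2, 12), seed=st.integers(0, 10**6))
    def test_newick_round_trip_property(self, n, seed):
        rng = np.random.default_rng(seed)
        nwk = random_tree_newick(rng, n)
        tree = read_newick(nwk)
        back = read_newick(write_newick(tree))
        clades = lambda t: {
            frozenset(l.taxon.label for l in nd.leaf_iter())
            for nd in t.preorder_node_iter()
        }
        assert clades(tree) == clades(back)

    def test_tree_sample_one_per_line(self, tmp_path):
        p = tmp_path / "trees.nwk"
        p.write_text("(A:1,(B:1,C:1):1);\n" * 100)
        sample = read_tree_sample(p)
        assert len(sample) == 100
        assert sample.leaf_labels == frozenset("ABC")

    def test_tree_sample_leafset_mismatch_rejected(self, tmp_path):
        p = tmp_path / "trees.nwk"
        p.write_text("(A:1,B:1);\n(A:1,C:1);\n")
        with pytest.raises(ValidationError):
            read_tree_sample(p)

    def test_unrooted_input_detected(self):
        tree = read_newick("(A:1,B:1,C:1);")
        assert not is_rooted(tree)
        assert is_rooted(read_newick("(A:1,(B:1,C:1):1);"))

    def test_outgroup_rooting(self):
        tree = read_newick("(A:1,B:1,(og1:1,og2:1):1);")
        rooted = root_with_outgroup(tree, ["og1", "og2"])
        assert is_rooted(rooted)
        kids = [
            frozenset(l.taxon.label for l in c.leaf_iter())
            for c in rooted.seed_node.child_nodes()
        ]
        assert frozenset(["og1", "og2"]) in kids


class TestTaxonTable:
    def test_round_trip(self, tmp_path):
        tp = TaxonPartition(
            {"s1": "spA", "s2": "spA", "s3": "spB", "o1": "out"},
            {"spA": "g1", "spB": "g1"},
            {"o1"},
        )
        p = tmp_path / "taxa.tsv"
        write_taxon_table(tp, p)
        back = read_taxon_table(p)
        assert back.species_of == tp.species_of
        assert back.group_of == tp.group_of
        assert back.outgroups == tp.outgroups

    def test_outgroup_in_group_rejected(self):
        with pytest.raises(ValidationError):
            TaxonPartition({"o1": "out"}, {"out": "g1"}, {"o1"})

    def test_members_and_ingroup(self):
        tp = TaxonPartition(
            {"a": "sp1", "b": "sp1", "o": "outsp"}, {}, {"o"}
        )
        assert tp.members("sp1") == ["a", "b"]
        assert tp.ingroup_species == ["sp1"]
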