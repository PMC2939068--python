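import numpy as np

from phylodiag.diagnostics import (
    COMBINATION,
    EMBEDDED_DERIVED,
    UNIQUE_UNIFORM,
    diagnose_all,
    fingerprint,
    fitch_reconstruct,
)
from phylodiag.seqio import Alignment, TaxonPartition, read_newick
from phylodiag.synthetic_data import (
    ParaphylySpec,
    SimConfig,
    simulate_dataset,
    zero_rate_config,
)

from helpers import brute_force_min_changes, random_rooted_tree


def _aln(cols_by_taxon):
    labels = tuple(cols_by_taxon)
    return Alignment(labels, tuple(cols_by_taxon[t] for t in labels))


class TestFitchReconstruct:
    def test_monomorphic_column_has_zero_changes(self):
        tree = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        aln = _aln({"a": "A", "b": "A", "c": "A", "d": "A"})
        rec = fitch_reconstruct(tree, aln, 1)
        assert rec.change_count == 0
        assert all(s == frozenset("A") for s in rec.final_sets.values())

    def test_two_leaf_tree_single_difference(self):
        tree = read_newick("(a:1,b:1);")
        rec = fitch_reconstruct(tree, _aln({"a": "A", "b": "C"}), 1)
        assert rec.change_count == 1
        assert rec.down_sets[0] == frozenset("AC")

    def test_missing_tips_contribute_full_set(self):
        tree = read_newick("((a:1,b:1):1,c:1);")
        rec = fitch_reconstruct(tree, _aln({"a": "A", "b": "-", "c": "?"}), 1)
        assert rec.change_count == 0

    def test_matches_brute_force_on_random_instances(self, rng):
        """Exhaustive-enumeration oracle on random 6-leaf trees/columns."""
        chars = np.array(list("ACGTRYN-"))
        for _ in range(60):
            tree = random_rooted_tree(rng, 6)
            column = {
                l.taxon.label: str(rng.choice(chars))
                for l in tree.leaf_node_iter()
            }
            if all(c in "RYN-" for c in column.values()):
                continue
            aln = _aln({t: c for t, c in column.items()})
            rec = fitch_reconstruct(tree, aln, 1)
            assert rec.change_count == brute_force_min_changes(tree, column)

    def test_change_count_bounded_by_state_diversity(self, rng):
        for _ in range(30):
            tree = random_rooted_tree(rng, 7)
            column = {
                l.taxon.label: str(rng.choice(list("ACGT")))
                for l in tree.leaf_node_iter()
            }
            rec = fitch_reconstruct(tree, _aln(column), 1)
            # lower bound: each extra observed state needs a change;
            # upper bound: label every internal node with the majority state
            counts = [list(column.values()).count(s) for s in set(column.values())]
            assert len(counts) - 1 <= rec.change_count <= len(column) - max(counts)


class TestDiagnoseAll:
    def test_planted_sites_fully_recovered_at_zero_background(self, clean_bundle):
        table = diagnose_all(
            clean_bundle.tree, clean_bundle.alignment, clean_bundle.taxa
        )
        found = {
            (s.species, s.column, s.state)
            for s in table.all_sites()
            if s.category == UNIQUE_UNIFORM
        }
        assert found == set(clean_bundle.truth.planted)

    def test_no_false_positives_at_zero_background(self, clean_bundle):
        table = diagnose_all(
            clean_bundle.tree, clean_bundle.alignment, clean_bundle.taxa
        )
        planted = set(clean_bundle.truth.planted)
        for s in table.all_sites():
            if s.category == UNIQUE_UNIFORM:
                assert (s.species, s.column, s.state) in planted

    def test_monomorphic_alignment_gives_empty_table(self, default_config):
        cfg = zero_rate_config(default_config)
        cfg = type(cfg)(**{**cfg.__dict__, "planted_per_species": 0})
        bundle = simulate_dataset(cfg)
        table = diagnose_all(bundle.tree, bundle.alignment, bundle.taxa)
        assert table.all_sites() == []

    def test_deterministic_across_tip_permutation(self, clean_bundle):
        aln = clean_bundle.alignment
        perm = tuple(reversed(range(aln.n_taxa)))
        aln2 = Alignment(
            tuple(aln.taxon_labels[i] for i in perm),
            tuple(aln.matrix[i] for i in perm),
            dict(aln.partitions),
        )
        t1 = diagnose_all(clean_bundle.tree, aln, clean_bundle.taxa)
        t2 = diagnose_all(clean_bundle.tree, aln2, clean_bundle.taxa)
        key = lambda t: [
            (s.species, s.column, s.state, s.category) for s in t.all_sites()
        ]
        assert key(t1) == key(t2)

    def test_shared_state_demotes_to_combination(self):
        # state T uniform in species A (3 tips, unambiguous stem change)
        # but also carried by the single distant tip c2
        tree = read_newick(
            "(((a1:1,(a2:1,a3:1):1):1,(b1:1,b2:1):1):1,"
            "((c1:1,c2:1):1,(d1:1,d2:1):1):1);"
        )
        aln = _aln(
            {"a1": "T", "a2": "T", "a3": "T", "b1": "A", "b2": "A",
             "c1": "A", "c2": "T", "d1": "A", "d2": "A"}
        )
        taxa = TaxonPartition(
            {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B",
             "c1": "C", "c2": "C", "d1": "D", "d2": "D"}
        )
        table = diagnose_all(tree, aln, taxa)
        cats = {(s.species, s.column): s.category for s in table.all_sites()}
        assert cats[("A", 1)] == COMBINATION

    def test_polymorphic_species_yields_nothing(self):
        tree = read_newick("(((a1:1,a2:1):1,b1:1):1,c1:1);")
        aln = _aln({"a1": "T", "a2": "G", "b1": "A", "c1": "A"})
        taxa = TaxonPartition({"a1": "A", "a2": "A", "b1": "B", "c1": "C"})
        table = diagnose_all(tree, aln, taxa)
        assert table.sites["A"] == []

    def test_embedded_derived_sites_for_budding_pair(self):
        cfg = SimConfig(
            seed=101,
            paraphyly=ParaphylySpec(host="sp1", embedded="sp2"),
            planted_per_species=2,
        )
        bundle = simulate_dataset(zero_rate_config(cfg))
        table = diagnose_all(bundle.tree, bundle.alignment, bundle.taxa)
        emb_cats = {s.category for s in table.sites["sp2"]}
        assert EMBEDDED_DERIVED in emb_cats
        planted_sp2 = {
            (c, st) for sp, c, st in bundle.truth.planted if sp == "sp2"
        }
        got_sp2 = {
            (s.column, s.state)
            for s in table.sites["sp2"]
            if s.category == EMBEDDED_DERIVED
        }
        assert planted_sp2 <= got_sp2

    def test_monotonic_demotion_when_state_appears_elsewhere(self, clean_bundle):
        """Adding the diagnostic state outside the species can only demote
        unique_uniform to combination, never create a new unique site."""
        aln = clean_bundle.alignment
        sp, col, state = clean_bundle.truth.planted[0]
        outsider = next(
            t for t in aln.taxon_labels
            if clean_bundle.taxa.species_of.get(t) not in (sp,)
            and not clean_bundle.taxa.is_outgroup_specimen(t)
        )
        i = aln.taxon_labels.index(outsider)
        rows = list(aln.matrix)
        rows[i] = rows[i][: col - 1] + state + rows[i][col:]
        aln2 = Alignment(aln.taxon_labels, tuple(rows), dict(aln.partitions))
        t2 = diagnose_all(clean_bundle.tree, aln2, clean_bundle.taxa)
        cats = {
            (s.species, s.column): s.category for s in t2.all_sites()
        }
        assert cats.get((sp, col)) in (COMBINATION, None)


class TestFingerprint:
    def test_monomorphic_alignment_renders_no_columns(self, tmp_path):
        aln = _aln({"a": "AAA", "b": "AAA"})
        taxa = TaxonPartition({"a": "A", "b": "B"})
        order, cols, rows = fingerprint(aln, taxa, tsv_path=tmp_path / "f.tsv")
        assert cols == []

    def test_tsv_round_trip_equals_submatrix(self, tmp_path):
        aln = _aln({"a": "ACGT", "b": "ACCA", "c": "ACGA"})
        taxa = TaxonPartition({"a": "sp1", "b": "sp1", "c": "sp2"})
        p = tmp_path / "fp.tsv"
        order, cols, rows = fingerprint(aln, taxa, tsv_path=p)
        lines = p.read_text().strip().split("\n")
        header = lines[0].split("\t")[1:]
        assert [int(h) for h in header] == cols
        for line, lab, row in zip(lines[1:], order, rows):
            fields = line.split("\t")
            assert fields[0] == lab
            assert "".join(fields[1:]) == row
            assert row == "".join(aln.sequence(lab)[c - 1] for c in cols)

    def test_svg_written_with_distinct_state_colors(self, tmp_path):
        from phylodiag.diagnostics import STATE_COLORS

        core = [STATE_COLORS[s] for s in "ACGT"] + [STATE_COLORS["-"]]
        assert len(set(core)) == 5
        aln = _aln({"a": "ACGT", "b": "ACCA"})
        taxa = TaxonPartition({"a": "sp1", "b": "sp2"})
        svg = tmp_path / "fp.svg"
        fingerprint(aln, taxa, svg_path=svg)
        assert svg.exists() and svg.stat().st_size > 0
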