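"""Core data model and readers/writers for alignments, trees and taxon tables.

Alignments are immutable-ish dataclasses holding one character string per
taxon plus named, non-overlapping column partitions.  Column coordinates are
1-based and inclusive throughout the package, matching the convention used
for published molecular diagnoses ("position 108" means column 108 of the
concatenated matrix).

Trees are :class:`dendropy.Tree` objects.  After reading, every node carries
a stable ``node_id`` attribute (its preorder index) and internal newick
labels are stored as ``node.support`` rather than as names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
from Bio import SeqIO
from Bio.Nexus import Nexus as BioNexus

from .errors import (
    AlignmentShapeError,
    FormatError,
    UnrootedTreeError,
    ValidationError,
)

DNA_ALPHABET = set("ACGTUMRWSYKVHDBN-?")

#: IUPAC nucleotide codes expanded to their unambiguous state sets.  Gaps,
#: '?' and 'N' all expand to the full set; downstream modules decide how to
#: treat them semantically.
IUPAC_SETS: Mapping[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "M": frozenset("AC"),
    "R": frozenset("AG"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "V": frozenset("ACG"),
    "H": frozenset("ACT"),
    "D": frozenset("AGT"),
    "B": frozenset("CGT"),
    "N": frozenset("ACGT"),
    "-": frozenset("ACGT"),
    "?": frozenset("ACGT"),
}


def state_set(ch: str) -> frozenset:
    """Unambiguous state set for one alignment character (case-insensitive)."""
    try:
        return IUPAC_SETS[ch.upper()]
    except KeyError:
        raise ValidationError(f"unknown alignment character {ch!r}") from None


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A taxa x columns character matrix with named column partitions.

    Parameters
    ----------
    taxon_labels:
        Ordered, unique, non-empty taxon names.
    matrix:
        One sequence string per taxon, all of equal length.
    partitions:
        Mapping of partition name to (start, end), 1-based inclusive; ranges
        must be disjoint and lie within the matrix.
    """

    taxon_labels: tuple
    matrix: tuple
    partitions: dict = field(default_factory=dict)

    def __post_init__(self):
        self.taxon_labels = tuple(self.taxon_labels)
        self.matrix = tuple(s.upper() for s in self.matrix)
        if len(self.taxon_labels) != len(self.matrix):
            raise ValidationError("taxon_labels and matrix differ in length")
        if len(set(self.taxon_labels)) != len(self.taxon_labels):
            raise ValidationError("duplicate taxon labels")
        if any(not lab for lab in self.taxon_labels):
            raise ValidationError("empty taxon label")
        lengths = {len(s) for s in self.matrix}
        if len(lengths) > 1:
            raise AlignmentShapeError(f"ragged sequence lengths: {sorted(lengths)}")
        if not self.partitions:
            self.partitions = {"default": (1, self.column_count)}
        self._validate_partitions()

    def _validate_partitions(self):
        covered = []
        for name, (start, end) in self.partitions.items():
            if not (1 <= start <= end <= self.column_count):
                raise ValidationError(
                    f"partition {name!r} range ({start},{end}) outside "
                    f"[1,{self.column_count}]"
                )
            covered.append((start, end, name))
        covered.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(covered, covered[1:]):
            if s2 <= e1:
                raise ValidationError(f"partitions {n1!r} and {n2!r} overlap")

    @property
    def column_count(self) -> int:
        return len(self.matrix[0]) if self.matrix else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_labels)

    def sequence(self, label: str) -> str:
        try:
            return self.matrix[self.taxon_labels.index(label)]
        except ValueError:
            raise ValidationError(f"taxon {label!r} not in alignment") from None

    def column(self, i: int) -> dict:
        """Mapping taxon -> character at 1-based column ``i``."""
        if not 1 <= i <= self.column_count:
            raise ValidationError(f"column {i} out of range 1..{self.column_count}")
        return {lab: seq[i - 1] for lab, seq in zip(self.taxon_labels, self.matrix)}

    def columns(self, start: int, end: int) -> "Alignment":
        """Sub-alignment over 1-based inclusive column range."""
        if not (1 <= start <= end <= self.column_count):
            raise ValidationError(f"range ({start},{end}) out of bounds")
        return Alignment(
            self.taxon_labels,
            tuple(s[start - 1 : end] for s in self.matrix),
            {"default": (1, end - start + 1)},
        )

    def partition_of(self, column: int) -> Optional[str]:
        """Name of the partition containing a 1-based column, if any."""
        for name, (s, e) in self.partitions.items():
            if s <= column <= e:
                return name
        return None

    def variable_columns(self) -> list:
        """1-based indices of columns with >1 distinct unambiguous state."""
        out = []
        for i in range(1, self.column_count + 1):
            states = {
                seq[i - 1].upper()
                for seq in self.matrix
                if seq[i - 1].upper() in "ACGT"
            }
            if len(states) > 1:
                out.append(i)
        return out


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    A single partition named ``default`` spans all columns.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    labels = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    return Alignment(tuple(labels), tuple(seqs))


def write_fasta(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for lab, seq in zip(alignment.taxon_labels, alignment.matrix):
            fh.write(f">{lab}\n{seq}\n")


def read_nexus_alignment(path) -> Alignment:
    """Read a NEXUS DATA/CHARACTERS block; charsets become partitions.

    Columns not covered by any charset form implicit ``unassigned`` partitions
    (one per maximal uncovered run) so that the representation is lossless.
    Charsets must be contiguous ranges.
    """
    try:
        nex = BioNexus.Nexus(str(path))
    except Exception as exc:  # Bio.Nexus raises bare NexusError subclasses
        raise FormatError(f"cannot parse NEXUS file {path}: {exc}") from exc
    if not nex.matrix:
        raise FormatError(f"no DATA/CHARACTERS matrix in {path}")
    labels = list(nex.taxlabels) if nex.taxlabels else sorted(nex.matrix)
    seqs = [str(nex.matrix[lab]) for lab in labels]
    ncols = len(seqs[0])
    partitions: dict = {}
    covered = [False] * (ncols + 1)
    for name, positions in (nex.charsets or {}).items():
        pos = sorted(positions)  # 0-based in Bio.Nexus
        if not pos:
            continue
        if pos != list(range(pos[0], pos[-1] + 1)):
            raise FormatError(
                f"charset {name!r} is not a contiguous range; only contiguous "
                "charsets are supported as partitions"
            )
        partitions[name] = (pos[0] + 1, pos[-1] + 1)
        for p in pos:
            covered[p + 1] = True
    if partitions:
        # implicit partitions for uncovered runs
        run_start = None
        n_un = 0
        for i in range(1, ncols + 2):
            in_run = i <= ncols and not covered[i]
            if in_run and run_start is None:
                run_start = i
            elif not in_run and run_start is not None:
                n_un += 1
                name = "unassigned" if n_un == 1 else f"unassigned_{n_un}"
                partitions[name] = (run_start, i - 1)
                run_start = None
    return Alignment(tuple(labels), tuple(seqs), partitions)


def write_nexus_alignment(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(
            f"  DIMENSIONS NTAX={alignment.n_taxa} "
            f"NCHAR={alignment.column_count};\n"
        )
        fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        width = max(len(l) for l in alignment.taxon_labels)
        for lab, seq in zip(alignment.taxon_labels, alignment.matrix):
            safe = f"'{lab}'" if " " in lab else lab
            fh.write(f"    {safe:<{width + 2}} {seq}\n")
        fh.write("  ;\nEND;\n")
        sets = [
            f"  CHARSET {name} = {s}-{e};\n"
            for name, (s, e) in alignment.partitions.items()
        ]
        if sets:
            fh.write("BEGIN SETS;\n")
            fh.writelines(sets)
            fh.write("END;\n")


def concatenate(
    alignments: Sequence[Alignment],
    names: Optional[Sequence[str]] = None,
    fill_missing: bool = False,
) -> Alignment:
    """Concatenate alignments column-wise, aligning rows by taxon label.

    Each input becomes one named partition of the result.  Taxa missing from
    a locus are filled with '?' only when ``fill_missing`` is set; otherwise
    a taxon-set mismatch is an error.
    """
    if not alignments:
        raise ValidationError("nothing to concatenate")
    if names is None:
        names = [f"locus{i + 1}" for i in range(len(alignments))]
    if len(names) != len(alignments) or len(set(names)) != len(names):
        raise ValidationError("partition names must be unique, one per alignment")
    base = list(alignments[0].taxon_labels)
    all_taxa = set(base)
    for aln in alignments[1:]:
        extra = set(aln.taxon_labels) - all_taxa
        if extra and not fill_missing:
            raise ValidationError(f"taxon set mismatch: {sorted(extra)}")
        for t in aln.taxon_labels:
            if t not in all_taxa:
                base.append(t)
                all_taxa.add(t)
    if not fill_missing:
        for aln in alignments:
            missing = all_taxa - set(aln.taxon_labels)
            if missing:
                raise ValidationError(f"taxon set mismatch: {sorted(missing)}")
    parts: dict = {}
    offset = 0
    rows = {t: [] for t in base}
    for name, aln in zip(names, alignments):
        n = aln.column_count
        parts[name] = (offset + 1, offset + n)
        offset += n
        for t in base:
            if t in aln.taxon_labels:
                rows[t].append(aln.sequence(t))
            else:
                rows[t].append("?" * n)
    return Alignment(tuple(base), tuple("".join(rows[t]) for t in base), parts)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _finalize_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Validate a freshly parsed tree and attach stable node identifiers.

    Internal newick labels are treated as support values (node metadata),
    never as taxon names.  Node identifiers are preorder indices.
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate leaf labels in tree")
    for node in tree.preorder_node_iter():
        if node.edge.length is not None and node.edge.length < 0:
            raise ValidationError("negative branch length")
        if not node.is_leaf() and node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                node.support = node.label
            node.label = None
    assign_node_ids(tree)
    return tree


def assign_node_ids(tree: dendropy.Tree) -> None:
    """(Re)assign ``node_id`` = preorder index to every node."""
    for i, node in enumerate(tree.preorder_node_iter()):
        node.node_id = i


def read_newick(text: str) -> dendropy.Tree:
    """Parse a single newick string into a rooted-as-written dendropy tree."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        if "Duplicate taxon" in str(exc):
            raise ValidationError("duplicate leaf labels in tree") from exc
        raise FormatError(f"cannot parse newick: {exc}") from exc
    return _finalize_tree(tree)


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def read_tree_file(path) -> dendropy.Tree:
    with open(path) as fh:
        return read_newick(fh.read())


@dataclass
class TreeSample:
    """An ordered sample of trees over one shared leaf set (e.g. a posterior)."""

    trees: list
    generation_stride: Optional[int] = None
    burnin_applied: bool = False

    def __post_init__(self):
        if not self.trees:
            raise ValidationError("empty tree sample")
        ref = frozenset(l.taxon.label for l in self.trees[0].leaf_node_iter())
        for t in self.trees[1:]:
            if frozenset(l.taxon.label for l in t.leaf_node_iter()) != ref:
                raise ValidationError("trees in sample differ in leaf set")

    def __len__(self):
        return len(self.trees)

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(l.taxon.label for l in self.trees[0].leaf_node_iter())


def read_tree_sample(path, **metadata) -> TreeSample:
    """Read trees from a NEXUS TREES block or a one-newick-per-line file."""
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().upper().startswith("#NEXUS"):
        try:
            tl = dendropy.TreeList.get(
                data=text,
                schema="nexus",
                rooting="force-rooted",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:
            raise FormatError(f"cannot parse NEXUS trees: {exc}") from exc
        trees = [_finalize_tree(t) for t in tl]
    else:
        trees = [
            read_newick(line)
            for line in text.splitlines()
            if line.strip() and not line.lstrip().startswith("#")
        ]
    return TreeSample(trees, **metadata)


def is_rooted(tree: dendropy.Tree) -> bool:
    """A tree is treated as rooted when its root node is bifurcating."""
    return len(tree.seed_node.child_nodes()) == 2


def require_rooted(tree: dendropy.Tree) -> None:
    if not is_rooted(tree):
        raise UnrootedTreeError(
            "operation requires a rooted (bifurcating-root) tree; "
            "use root_with_outgroup() first"
        )


def root_with_outgroup(tree: dendropy.Tree, outgroup_labels: Iterable[str]) -> dendropy.Tree:
    """Root a tree on the branch subtending the outgroup taxa (in place)."""
    labels = list(outgroup_labels)
    taxa = [tree.taxon_namespace.get_taxon(l) for l in labels]
    if any(t is None for t in taxa):
        raise ValidationError(f"outgroup label(s) not in tree: {labels}")
    mrca = tree.mrca(taxa=taxa)
    if mrca is tree.seed_node:
        raise ValidationError(
            "outgroup spans the current root; cannot root on its stem"
        )
    edge = mrca.edge
    if edge.length is not None:
        tree.reroot_at_edge(edge, length1=edge.length / 2, length2=edge.length / 2)
    else:
        tree.reroot_at_edge(edge)
    assign_node_ids(tree)
    return tree


def leaf_set(node) -> frozenset:
    return frozenset(l.taxon.label for l in node.leaf_iter())


# ---------------------------------------------------------------------------
# Taxon assignment tables
# ---------------------------------------------------------------------------

@dataclass
class TaxonPartition:
    """Specimen -> species and species -> species-group assignments."""

    species_of: dict
    group_of: dict = field(default_factory=dict)
    outgroups: frozenset = frozenset()

    def __post_init__(self):
        self.outgroups = frozenset(self.outgroups)
        unknown = self.outgroups - set(self.species_of)
        if unknown:
            raise ValidationError(f"outgroup flag for unknown specimen: {sorted(unknown)}")
        grouped = set(self.group_of)
        for sp in self.outgroups:
            if self.species_of[sp] in grouped:
                raise ValidationError(
                    f"outgroup specimen {sp!r} maps to a grouped species"
                )

    @property
    def species(self) -> list:
        seen: dict = {}
        for sp in self.species_of.values():
            seen.setdefault(sp, None)
        return list(seen)

    @property
    def ingroup_species(self) -> list:
        out_sp = {self.species_of[s] for s in self.outgroups}
        return [s for s in self.species if s not in out_sp]

    def members(self, species: str) -> list:
        return [s for s, sp in self.species_of.items() if sp == species]

    def is_outgroup_specimen(self, specimen: str) -> bool:
        return specimen in self.outgroups


def read_taxon_table(path) -> TaxonPartition:
    """Read a tab-separated table with columns specimen, species,
    species_group, outgroup (0/1)."""
    species_of: dict = {}
    group_of: dict = {}
    outgroups = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("specimen", "species"):
            if col not in idx:
                raise FormatError(f"taxon table missing column {col!r}")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            spm = fields[idx["specimen"]]
            if spm in species_of:
                raise ValidationError(f"duplicate specimen {spm!r}")
            species_of[spm] = fields[idx["species"]]
            if "species_group" in idx and len(fields) > idx["species_group"]:
                grp = fields[idx["species_group"]]
                if grp:
                    group_of[fields[idx["species"]]] = grp
            if "outgroup" in idx and len(fields) > idx["outgroup"]:
                if fields[idx["outgroup"]].strip() == "1":
                    outgroups.add(spm)
    return TaxonPartition(species_of, group_of, outgroups)


def write_taxon_table(partition: TaxonPartition, path) -> None:
    with open(path, "w") as fh:
        fh.write("specimen\tspecies\tspecies_group\toutgroup\n")
        for spm, sp in partition.species_of.items():
            grp = partition.group_of.get(sp, "")
            og = "1" if spm in partition.outgroups else "0"
            fh.write(f"{spm}\t{sp}\t{grp}\t{og}\n")
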