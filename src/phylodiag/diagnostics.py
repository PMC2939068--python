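"""Character-based DNA diagnostics.

Each variable alignment column is reconstructed on the tree with unordered
unit-cost parsimony, and sites are sorted into three diagnosis categories
per species:

``unique_uniform``
    the species' tips all carry state *s*, a change to *s* is reconstructed
    on the branch subtending the species' MRCA, and *s* is observed in no
    tip outside that subtree (conventionally printed in italics);
``combination``
    as above, but *s* also occurs elsewhere on the tree, so it is diagnostic
    only in combination with other such sites;
``embedded_derived``
    for a paraphyletic host with an embedded daughter species: sites whose
    derived state arose on the branch subtending the embedded species'
    MRCA with no second origin inside the host clade (printed in bold).

"Change on a branch" is judged conservatively: a change is counted only
when the parent's and child's all-MPR state sets are disjoint, i.e. the
change is unambiguous under every most-parsimonious reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from ._parsimony import fitch_down_pass, sankoff_summary, tip_state_sets
from .errors import ValidationError
from .exclusivity import (
    embedded_pairs,
    mrca,
    species_exclusivity_report,
)
from .seqio import (
    Alignment,
    TaxonPartition,
    leaf_set,
    require_rooted,
    state_set,
)

NUCLEOTIDES = ("A", "C", "G", "T")

UNIQUE_UNIFORM = "unique_uniform"
COMBINATION = "combination"
EMBEDDED_DERIVED = "embedded_derived"


@dataclass
class ColumnReconstruction:
    """Parsimony reconstruction of one alignment column on the tree."""

    column: int
    down_sets: dict  # node_id -> frozenset (Fitch preliminary sets)
    final_sets: dict  # node_id -> frozenset (states over all MPRs)
    change_count: int
    #: node_ids whose subtending branch carries an unambiguous change
    change_branches: frozenset


@dataclass
class DiagnosticSite:
    species: str
    column: int  # 1-based, concatenated matrix
    state: str
    category: str

    def __post_init__(self):
        if self.state not in NUCLEOTIDES:
            raise ValidationError(f"diagnostic state must be ACGT, got {self.state!r}")
        if self.category not in (UNIQUE_UNIFORM, COMBINATION, EMBEDDED_DERIVED):
            raise ValidationError(f"unknown category {self.category!r}")


@dataclass
class DiagnosticTable:
    sites: dict  # species -> ordered list of DiagnosticSite
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for sp, lst in self.sites.items():
            cols = [s.column for s in lst]
            if cols != sorted(set(cols)) and len(cols) != len(set(cols)):
                raise ValidationError(f"duplicate columns for species {sp!r}")

    def all_sites(self) -> list:
        out = []
        for sp in sorted(self.sites):
            out.extend(self.sites[sp])
        return out


def _column_tip_sets(alignment: Alignment, column: int) -> dict:
    col = alignment.column(column)
    return {lab: state_set(ch) for lab, ch in col.items()}


def fitch_reconstruct(tree, alignment: Alignment, column: int) -> ColumnReconstruction:
    """Reconstruct one column: Fitch down-pass count + exact MPR state sets.

    Missing/gap tips contribute the full {A,C,G,T} set; IUPAC ambiguity its
    code's set.  Requires a rooted bifurcating tree.
    """
    require_rooted(tree)
    tip_values = _column_tip_sets(alignment, column)
    leaf_sets = tip_state_sets(tree, tip_values)
    down, changes = fitch_down_pass(tree, leaf_sets)
    summary = sankoff_summary(tree, leaf_sets, NUCLEOTIDES)
    assert summary.min_changes == changes, "Fitch and Sankoff counts disagree"
    change_branches = frozenset(
        node.node_id
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
        and not (
            summary.mpr_sets[node.node_id]
            & summary.mpr_sets[node.parent_node.node_id]
        )
    )
    return ColumnReconstruction(
        column=column,
        down_sets=down,
        final_sets=summary.mpr_sets,
        change_count=changes,
        change_branches=change_branches,
    )


def _species_state(
    alignment: Alignment,
    column: int,
    members: Iterable[str],
    strict: bool = False,
) -> Optional[str]:
    """The single unambiguous state shared by a species at a column, if any.

    Default mode tolerates missing data: at least one member must show the
    state unambiguously and no member may show a conflicting unambiguous
    state.  Strict mode requires every member unambiguous.
    """
    col = alignment.column(column)
    observed = set()
    n_unambig = 0
    members = list(members)
    for m in members:
        ch = col[m].upper()
        if ch in "ACGT":
            observed.add(ch)
            n_unambig += 1
    if len(observed) != 1:
        return None
    if strict and n_unambig != len(members):
        return None
    return observed.pop()


def classify_site(
    tree,
    alignment: Alignment,
    partition: TaxonPartition,
    species: str,
    column: int,
    reconstruction: ColumnReconstruction,
    strict: bool = False,
) -> Optional[DiagnosticSite]:
    """Classify one column for one species, or return None.

    The homoplasy check for ``unique_uniform`` uses observed unambiguous tip
    states outside the species' subtree, not reconstructed internal states.
    """
    members = [
        m
        for m in partition.members(species)
        if tree.taxon_namespace.get_taxon(m) is not None
    ]
    if not members:
        raise ValidationError(f"species {species!r} has no tips on the tree")
    s = _species_state(alignment, column, members, strict=strict)
    if s is None:
        return None
    node = mrca(tree, members)
    if node.parent_node is None:
        return None  # species spans the root: no subtending branch
    if node.node_id not in reconstruction.change_branches:
        return None
    if s not in reconstruction.final_sets[node.node_id]:
        return None
    inside = leaf_set(node)
    col = alignment.column(column)
    outside_states = {
        col[lab].upper()
        for lab in alignment.taxon_labels
        if lab not in inside and col[lab].upper() in "ACGT"
    }
    category = UNIQUE_UNIFORM if s not in outside_states else COMBINATION
    return DiagnosticSite(species, column, s, category)


def classify_embedded(
    tree,
    alignment: Alignment,
    partition: TaxonPartition,
    host: str,
    embedded: str,
    columns: Iterable[int],
    reconstructions: Mapping[int, ColumnReconstruction],
    strict: bool = False,
) -> list:
    """Diagnostic sites uniquely derived on the embedded species' stem.

    Requires the embedded species to be nested inside the host's MRCA.
    A site qualifies when an unambiguous change to a state uniform in the
    embedded species occurs on the branch subtending its MRCA and no second
    unambiguous origin of that state exists inside the host clade.
    """
    host_members = partition.members(host)
    emb_members = partition.members(embedded)
    host_node = mrca(tree, host_members + emb_members)
    emb_node = mrca(tree, emb_members)
    if not leaf_set(emb_node) <= leaf_set(host_node) or emb_node is host_node:
        raise ValidationError(
            f"{embedded!r} is not nested within the MRCA of {host!r}"
        )
    host_clade_ids = {n.node_id for n in host_node.preorder_iter()}
    out = []
    for column in columns:
        rec = reconstructions[column]
        if emb_node.node_id not in rec.change_branches:
            continue
        s = _species_state(alignment, column, emb_members, strict=strict)
        if s is None or s not in rec.final_sets[emb_node.node_id]:
            continue
        second_origin = any(
            nid in host_clade_ids
            and nid != emb_node.node_id
            and s in rec.final_sets[nid]
            for nid in rec.change_branches
        )
        if not second_origin:
            out.append(DiagnosticSite(embedded, column, s, EMBEDDED_DERIVED))
    return out


def diagnose_all(
    tree,
    alignment: Alignment,
    partition: TaxonPartition,
    strict: bool = False,
) -> DiagnosticTable:
    """Full molecular-diagnosis table for every ingroup species.

    Only variable columns are reconstructed.  Embedded-derived sites are
    added for each (paraphyletic host, embedded monophyletic species) pair
    detected by the exclusivity module.  Output ordering is deterministic:
    species by name, sites by column.
    """
    require_rooted(tree)
    on_tree = {l.taxon.label for l in tree.leaf_node_iter()}
    if not on_tree <= set(alignment.taxon_labels):
        missing = sorted(on_tree - set(alignment.taxon_labels))
        raise ValidationError(f"tree tips missing from alignment: {missing}")
    variable = alignment.variable_columns()
    recs = {c: fitch_reconstruct(tree, alignment, c) for c in variable}
    report = species_exclusivity_report(tree, partition)
    sites: dict = {sp: [] for sp in sorted(partition.ingroup_species)}
    for sp in sites:
        for c in variable:
            hit = classify_site(tree, alignment, partition, sp, c, recs[c], strict)
            if hit is not None:
                sites[sp].append(hit)
    for host, emb in embedded_pairs(report, partition):
        hits = classify_embedded(
            tree, alignment, partition, host, emb, variable, recs, strict
        )
        merged = {s.column: s for s in sites[emb]}
        for h in hits:
            merged[h.column] = h  # embedded_derived supersedes
        sites[emb] = [merged[c] for c in sorted(merged)]
    for sp in sites:
        sites[sp].sort(key=lambda s: s.column)
    return DiagnosticTable(
        sites,
        provenance={
            "n_variable_columns": len(variable),
            "strict": strict,
            "n_taxa": alignment.n_taxa,
        },
    )


def write_diagnostic_table(table: DiagnosticTable, alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tcolumn\tstate\tcategory\tpartition\n")
        for site in table.all_sites():
            part = alignment.partition_of(site.column) or ""
            fh.write(
                f"{site.species}\t{site.column}\t{site.state}\t"
                f"{site.category}\t{part}\n"
            )


STATE_COLORS = {
    "A": "#2ca02c",
    "C": "#1f77b4",
    "G": "#111111",
    "T": "#d62728",
    "-": "#bbbbbb",
    "other": "#f0e442",
}


def fingerprint(
    alignment: Alignment,
    partition: TaxonPartition,
    columns: Optional[Iterable[int]] = None,
    svg_path=None,
    tsv_path=None,
):
    """Per-specimen "DNA fingerprint" grid over variable (or given) columns.

    Specimens are grouped by species; each cell is colored by state.
    Returns (ordered specimen labels, ordered columns, sub-matrix rows).
    """
    cols = list(columns) if columns is not None else alignment.variable_columns()
    order = []
    for sp in sorted(set(partition.species_of.values())):
        order.extend(
            m for m in partition.members(sp) if m in alignment.taxon_labels
        )
    rows = [
        "".join(alignment.sequence(lab)[c - 1] for c in cols) for lab in order
    ]
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("specimen\t" + "\t".join(str(c) for c in cols) + "\n")
            for lab, row in zip(order, rows):
                fh.write(lab + "\t" + "\t".join(row) + "\n")
    if svg_path is not None and cols:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.patches import Patch

        fig, ax = plt.subplots(
            figsize=(max(4, len(cols) * 0.12), max(3, len(order) * 0.18))
        )
        for yi, row in enumerate(rows):
            for xi, ch in enumerate(row):
                color = STATE_COLORS.get(ch.upper(), STATE_COLORS["other"])
                ax.add_patch(
                    plt.Rectangle((xi, len(rows) - 1 - yi), 1, 1, color=color)
                )
        ax.set_xlim(0, len(cols))
        ax.set_ylim(0, len(rows))
        ax.set_yticks([len(rows) - 0.5 - i for i in range(len(order))])
        ax.set_yticklabels(order, fontsize=5)
        ax.set_xticks([])
        ax.set_title("variable-site fingerprint")
        ax.legend(
            handles=[
                Patch(color=c, label=s)
                for s, c in STATE_COLORS.items()
                if s != "other"
            ],
            loc="upper right",
            fontsize=5,
        )
        fig.savefig(svg_path, format="svg", bbox_inches="tight")
        plt.close(fig)
    return order, cols, rows
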