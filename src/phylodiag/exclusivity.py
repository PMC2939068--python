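"""Genealogical exclusivity: monophyly/paraphyly/polyphyly classification and
posterior clade support.

A species is *monophyletic* (genealogically exclusive) when its sampled tips
are exactly the leaf set of some node.  A non-exclusive species is called
*paraphyletic* when the intruding tips under its MRCA form exactly one
maximal clade (the typical "embedded daughter species" pattern), and
*polyphyletic* otherwise.  This tie-break is a convention — other usages
exist — and is applied uniformly here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import ValidationError
from .seqio import TaxonPartition, TreeSample, leaf_set, require_rooted

MONOPHYLETIC = "monophyletic"
PARAPHYLETIC = "paraphyletic"
POLYPHYLETIC = "polyphyletic"


@dataclass
class GroupStatus:
    status: str
    intruders: frozenset = frozenset()
    #: maximal intruder clades (each a frozenset of tips) under the MRCA
    intruder_clades: tuple = ()
    singleton: bool = False

    def __post_init__(self):
        if (self.status == MONOPHYLETIC) != (not self.intruders):
            raise ValidationError("status inconsistent with intruder set")


@dataclass
class MonophylyReport:
    """Per-species exclusivity classification on one tree."""

    statuses: dict  # species -> GroupStatus
    warnings: list = field(default_factory=list)

    def status(self, species: str) -> str:
        return self.statuses[species].status


def mrca(tree, tips: Iterable[str]):
    """Lowest node whose leaf set contains ``tips``."""
    tips = list(tips)
    if not tips:
        raise ValidationError("empty tip set")
    taxa = []
    for t in tips:
        taxon = tree.taxon_namespace.get_taxon(t)
        if taxon is None:
            raise ValidationError(f"tip {t!r} not in tree")
        taxa.append(taxon)
    if len(taxa) == 1:
        return tree.find_node_with_taxon_label(tips[0])
    node = tree.mrca(taxa=taxa)
    if node is None:
        raise ValidationError("no MRCA found")
    return node


def classify_group(tree, tips: Iterable[str]) -> GroupStatus:
    """Classify a tip set as monophyletic / paraphyletic / polyphyletic."""
    tips = frozenset(tips)
    if not tips:
        raise ValidationError("empty tip set")
    anc = mrca(tree, tips)
    anc_leaves = leaf_set(anc)
    intruders = anc_leaves - tips
    if not intruders:
        return GroupStatus(MONOPHYLETIC, singleton=len(tips) == 1)
    # decompose intruders into maximal intruder-only clades under the MRCA
    clades = []

    def descend(node):
        ls = leaf_set(node)
        if ls <= intruders:
            clades.append(ls)
            return
        if node.is_leaf():
            return
        for c in node.child_nodes():
            descend(c)

    descend(anc)
    status = PARAPHYLETIC if len(clades) == 1 else POLYPHYLETIC
    return GroupStatus(status, intruders=intruders, intruder_clades=tuple(clades))


def clade_posterior(sample: TreeSample, tips: Iterable[str]) -> float:
    """Fraction of sampled trees in which ``tips`` form a clade."""
    tips = frozenset(tips)
    if not tips:
        raise ValidationError("empty tip set")
    if not tips <= sample.leaf_labels:
        raise ValidationError("tips not in the sample's leaf set")
    count = 0
    for tree in sample.trees:
        for node in tree.preorder_node_iter():
            if leaf_set(node) == tips:
                count += 1
                break
    return count / len(sample)


def clade_support_table(sample: TreeSample, partition: TaxonPartition) -> dict:
    """Posterior frequency of each species' tip set forming a clade."""
    on_tree = sample.leaf_labels
    return {
        sp: clade_posterior(
            sample, [m for m in partition.members(sp) if m in on_tree]
        )
        for sp in partition.ingroup_species
        if any(m in on_tree for m in partition.members(sp))
    }


def species_exclusivity_report(
    tree, partition: TaxonPartition, species: Optional[Iterable[str]] = None
) -> MonophylyReport:
    """Classify every ingroup species' tips on the tree.

    Single-tip species are monophyletic by definition and flagged as
    singletons.  Outgroup tips falling inside an ingroup MRCA are counted as
    intruders and additionally raise a rooting-anomaly warning.
    """
    require_rooted(tree)
    on_tree = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    targets = list(species) if species is not None else partition.ingroup_species
    statuses: dict = {}
    notes: list = []
    for sp in targets:
        members = [m for m in partition.members(sp) if m in on_tree]
        if not members:
            raise ValidationError(f"species {sp!r} has no tips on the tree")
        st = classify_group(tree, members)
        og_intruders = {
            t for t in st.intruders if partition.is_outgroup_specimen(t)
        }
        if og_intruders:
            msg = (
                f"outgroup tip(s) {sorted(og_intruders)} fall inside the MRCA "
                f"of {sp!r}: possible rooting anomaly"
            )
            notes.append(msg)
            warnings.warn(msg)
        statuses[sp] = st
    return MonophylyReport(statuses, notes)


def embedded_pairs(report: MonophylyReport, partition: TaxonPartition) -> list:
    """(host, embedded) species pairs: host paraphyletic with all intruders
    belonging to one monophyletic ingroup species."""
    pairs = []
    for host, st in report.statuses.items():
        if st.status != PARAPHYLETIC:
            continue
        owners = {partition.species_of.get(t) for t in st.intruders}
        if len(owners) != 1:
            continue
        emb = owners.pop()
        if emb is None or emb == host:
            continue
        emb_status = report.statuses.get(emb)
        if emb_status is not None and emb_status.status == MONOPHYLETIC:
            pairs.append((host, emb))
    return sorted(pairs)
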