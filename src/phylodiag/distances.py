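"""Uncorrected pairwise distances, category partitioning, and the
barcoding-gap report.

Distances are p-distances with pairwise deletion: each pair is compared
over only the columns where both sequences carry an unambiguous A/C/G/T
state.  A Jukes-Cantor correction is available as an alternative output;
no model-corrected distance beyond JC is offered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError
from .seqio import Alignment, TaxonPartition

INTRA = "intraspecies"
INTER = "interspecies"
OUTGROUP = "outgroup"

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class DistanceMatrix:
    labels: tuple
    values: np.ndarray  # p-distances, NaN where undefined
    compared_sites: np.ndarray  # per-pair counts of jointly unambiguous sites

    def __post_init__(self):
        n = len(self.labels)
        if self.values.shape != (n, n) or self.compared_sites.shape != (n, n):
            raise ValidationError("matrix shape mismatch")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def jukes_cantor(self) -> np.ndarray:
        """JC69-corrected distances: -3/4 ln(1 - 4p/3); NaN when p >= 0.75."""
        with np.errstate(invalid="ignore", divide="ignore"):
            arg = 1.0 - 4.0 * self.values / 3.0
            out = np.where(arg > 0, -0.75 * np.log(np.where(arg > 0, arg, 1.0)), np.nan)
        return out


@dataclass
class SpeciesGap:
    species: str
    max_intra: Optional[float]
    min_inter: Optional[float]
    gap: Optional[bool]

    def __post_init__(self):
        if self.gap is not None and (self.max_intra is None or self.min_inter is None):
            raise ValidationError("gap flag requires both extrema")


@dataclass
class GapReport:
    per_species: dict  # species -> SpeciesGap
    global_gap: bool
    n_excluded_singletons: int


def p_distance_matrix(
    alignment: Alignment, columns: Optional[tuple] = None
) -> DistanceMatrix:
    """Pairwise p-distance matrix with pairwise deletion.

    ``columns`` restricts to a 1-based inclusive (start, end) range.  A pair
    with zero jointly unambiguous sites gets distance NaN (undefined).
    """
    if alignment.n_taxa < 2:
        raise ValidationError("need at least two taxa")
    aln = alignment if columns is None else alignment.columns(*columns)
    enc = np.full((aln.n_taxa, aln.column_count), -1, dtype=np.int8)
    for i, seq in enumerate(aln.matrix):
        for j, ch in enumerate(seq):
            enc[i, j] = _CODE.get(ch.upper(), -1)
    valid = enc >= 0
    n = aln.n_taxa
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            counts[i, j] = counts[j, i] = m
            if m == 0:
                values[i, j] = values[j, i] = math.nan
            else:
                d = float((enc[i, both] != enc[j, both]).sum()) / m
                values[i, j] = values[j, i] = d
    np.fill_diagonal(counts, valid.sum(axis=1))
    return DistanceMatrix(tuple(alignment.taxon_labels), values, counts)


def partition_pairs(
    matrix: DistanceMatrix, partition: TaxonPartition, scheme: str = "species"
) -> dict:
    """Bin each unordered taxon pair's distance into exactly one category.

    scheme 'species': intraspecies / interspecies / outgroup (any pair
    involving an outgroup specimen).  scheme 'groups': one category per
    unordered species-group pair (e.g. 'A|B'), 'within:G' for pairs inside
    one group, plus 'outgroup'.
    """
    if scheme not in ("species", "groups"):
        raise ValidationError(f"unknown scheme {scheme!r}")
    for lab in matrix.labels:
        if lab not in partition.species_of:
            raise ValidationError(f"taxon {lab!r} unassigned in partition")
    out: dict = {}
    labels = matrix.labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            d = float(matrix.values[i, j])
            if partition.is_outgroup_specimen(a) or partition.is_outgroup_specimen(b):
                cat = OUTGROUP
            elif scheme == "species":
                cat = INTRA if partition.species_of[a] == partition.species_of[b] else INTER
            else:
                ga = partition.group_of.get(partition.species_of[a])
                gb = partition.group_of.get(partition.species_of[b])
                if ga is None or gb is None:
                    raise ValidationError(
                        f"species of {a!r} or {b!r} lacks a species-group"
                    )
                cat = f"within:{ga}" if ga == gb else "|".join(sorted((ga, gb)))
            out.setdefault(cat, []).append(d)
    return out


def gap_report(matrix: DistanceMatrix, partition: TaxonPartition) -> GapReport:
    """Per-species barcoding-gap assessment on ingroup taxa.

    A species shows a gap when its smallest distance to any other ingroup
    taxon exceeds its largest intraspecific distance.  Singleton species
    have an undefined intraspecific maximum and are excluded from the
    global verdict; the global gap exists iff every assessable species'
    flag is true.
    """
    ingroup = [
        l for l in matrix.labels
        if l in partition.species_of and not partition.is_outgroup_specimen(l)
    ]
    species = sorted({partition.species_of[l] for l in ingroup})
    if len(species) < 2:
        raise ValidationError("need at least two ingroup species")
    idx = {l: i for i, l in enumerate(matrix.labels)}
    per: dict = {}
    n_singleton = 0
    flags = []
    for sp in species:
        members = [l for l in ingroup if partition.species_of[l] == sp]
        others = [l for l in ingroup if partition.species_of[l] != sp]
        inter = [
            matrix.values[idx[m], idx[o]]
            for m in members
            for o in others
            if not math.isnan(matrix.values[idx[m], idx[o]])
        ]
        min_inter = float(min(inter)) if inter else None
        if len(members) < 2:
            per[sp] = SpeciesGap(sp, None, min_inter, None)
            n_singleton += 1
            continue
        intra = [
            matrix.values[idx[a], idx[b]]
            for ii, a in enumerate(members)
            for b in members[ii + 1 :]
            if not math.isnan(matrix.values[idx[a], idx[b]])
        ]
        max_intra = float(max(intra)) if intra else None
        if max_intra is None or min_inter is None:
            per[sp] = SpeciesGap(sp, max_intra, min_inter, None)
            continue
        flag = min_inter > max_intra
        per[sp] = SpeciesGap(sp, max_intra, min_inter, flag)
        flags.append(flag)
    return GapReport(per, global_gap=bool(flags) and all(flags), n_excluded_singletons=n_singleton)


def write_phylip_matrix(matrix: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.labels)}\n")
        for i, lab in enumerate(matrix.labels):
            row = " ".join(
                "NA" if math.isnan(v) else f"{v:.6f}" for v in matrix.values[i]
            )
            fh.write(f"{lab:<12} {row}\n")


def histogram_svg(categories: dict, path, bins: int = 30) -> None:
    """Overlaid per-category histogram of pairwise distances."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    palette = {"intraspecies": "#1f77b4", "interspecies": "#2ca02c",
               "outgroup": "#d62728"}
    for i, (cat, vals) in enumerate(sorted(categories.items())):
        vals = [v for v in vals if not math.isnan(v)]
        if not vals:
            continue
        ax.hist(vals, bins=bins, alpha=0.55,
                color=palette.get(cat), label=f"{cat} (n={len(vals)})")
    ax.set_xlabel("uncorrected p-distance")
    ax.set_ylabel("pair count")
    ax.legend(fontsize=8)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
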