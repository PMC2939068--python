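"""Base-composition summaries, chi-square homogeneity, harmonic-mean marginal
likelihoods and Bayes-factor monophyly assessment.

The Bayes factor follows the raw-difference convention used with MrBayes
harmonic means:  B10 = HM(-lnL | constrained H1) - HM(-lnL | unconstrained
H0), with values of 10 or greater read as strong evidence against the
constraint.  The conventional 2*delta-lnL is reported as an auxiliary field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2 as chi2_dist

from .errors import FormatError, ValidationError
from .seqio import Alignment

STRONG_THRESHOLD = 10.0


@dataclass
class BaseCompositionTable:
    per_taxon: dict  # taxon -> {A, C, G, T} counts (non-ACGT excluded)
    pooled: dict  # base -> frequency

    def __post_init__(self):
        total = sum(self.pooled.values())
        if self.pooled and abs(total - 1.0) > 1e-9:
            raise ValidationError("pooled frequencies do not sum to 1")


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    taxa_included: tuple
    taxa_excluded: tuple

    def __post_init__(self):
        if self.statistic < 0:
            raise ValidationError("negative chi-square statistic")
        if self.df != 3 * (len(self.taxa_included) - 1):
            raise ValidationError("df inconsistent with included taxa")


@dataclass
class LnLTrace:
    """Ordered per-generation log-likelihood values from an MCMC run."""

    values: np.ndarray  # natural-log likelihoods (large-magnitude negatives)
    generation_stride: Optional[int] = None
    burnin_applied: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValidationError("trace must be a non-empty 1-D array")

    def __len__(self):
        return int(self.values.size)


@dataclass
class BayesFactorResult:
    hm_constrained: float
    hm_unconstrained: float
    b10: float = field(init=False)
    two_delta: float = field(init=False)
    interpretation: str = field(init=False)

    def __post_init__(self):
        self.b10 = self.hm_constrained - self.hm_unconstrained
        self.two_delta = 2.0 * self.b10
        self.interpretation = (
            "strong" if self.b10 >= STRONG_THRESHOLD else "not strong"
        )


def base_composition(
    alignment: Alignment, columns: Optional[tuple] = None
) -> BaseCompositionTable:
    """Per-taxon A/C/G/T counts and pooled frequencies.

    Gaps, '?', 'N' and ambiguity codes are excluded from the counts.
    """
    aln = alignment if columns is None else alignment.columns(*columns)
    per: dict = {}
    totals = {b: 0 for b in "ACGT"}
    for lab, seq in zip(aln.taxon_labels, aln.matrix):
        counts = {b: 0 for b in "ACGT"}
        for ch in seq.upper():
            if ch in counts:
                counts[ch] += 1
        per[lab] = counts
        for b in "ACGT":
            totals[b] += counts[b]
    grand = sum(totals.values())
    pooled = {b: (totals[b] / grand if grand else 0.0) for b in "ACGT"}
    return BaseCompositionTable(per, pooled if grand else {})


def chi2_homogeneity(
    alignment: Alignment,
    columns: Optional[tuple] = None,
    min_sites: int = 100,
) -> Chi2Result:
    """Contingency chi-square test of base-frequency homogeneity across taxa.

    Expected counts come from the pooled base frequencies (the standard
    R x C construction); df = 3 * (n_included - 1).  Taxa with fewer than
    ``min_sites`` counted sites are excluded and listed, since sparse rows
    distort the statistic.
    """
    table = base_composition(alignment, columns)
    included, excluded = [], []
    for lab, counts in table.per_taxon.items():
        (included if sum(counts.values()) >= min_sites else excluded).append(lab)
    if len(included) < 2:
        raise ValidationError("need >= 2 taxa above min_sites for the test")
    obs = np.array(
        [[table.per_taxon[lab][b] for b in "ACGT"] for lab in included],
        dtype=float,
    )
    col_sums = obs.sum(axis=0)
    for b, s in zip("ACGT", col_sums):
        if s == 0:
            raise ValidationError(
                f"expected count zero for base {b}: test undefined"
            )
    row_sums = obs.sum(axis=1, keepdims=True)
    expected = row_sums * (col_sums / col_sums.sum())
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = 3 * (len(included) - 1)
    p = float(chi2_dist.sf(stat, df))
    return Chi2Result(stat, df, p, tuple(included), tuple(excluded))


def harmonic_mean_lnl(trace: LnLTrace, burnin_fraction: float = 0.25) -> float:
    """Harmonic-mean marginal-likelihood estimate as a -log-likelihood.

    The first floor(n * burnin_fraction) samples are discarded; the result
    is -log of the harmonic mean of the likelihoods, computed entirely in
    log space (log-sum-exp with max shift), so traces near lnL = -12,000
    neither overflow nor underflow.  The returned value is the positive
    magnitude directly comparable across runs.
    """
    if not 0 <= burnin_fraction < 1:
        raise ValidationError("burnin_fraction must be in [0, 1)")
    n = len(trace)
    post = trace.values[int(math.floor(n * burnin_fraction)) :]
    if post.size == 0:
        raise ValidationError("empty trace after burn-in")
    # -log HM = logsumexp(-lnL_i) - log m
    return float(logsumexp(-post) - math.log(post.size))


def arithmetic_mean_lnl(trace: LnLTrace, burnin_fraction: float = 0.25) -> float:
    """Descriptive arithmetic mean of -lnL after burn-in (not used in B10)."""
    n = len(trace)
    post = trace.values[int(math.floor(n * burnin_fraction)) :]
    if post.size == 0:
        raise ValidationError("empty trace after burn-in")
    return float(-post.mean())


def bayes_factor(hm_constrained: float, hm_unconstrained: float) -> BayesFactorResult:
    """B10 from two harmonic-mean -log-likelihoods (raw difference)."""
    if not (math.isfinite(hm_constrained) and math.isfinite(hm_unconstrained)):
        raise ValidationError("harmonic means must be finite")
    return BayesFactorResult(hm_constrained, hm_unconstrained)


def read_lnl_trace(path, generation_stride: Optional[int] = None) -> LnLTrace:
    """Read a trace from a MrBayes-style .p file or a bare list of numbers.

    The .p layout is a title line, then a tab-separated header containing
    'Gen' and 'LnL' columns, then one row per sample.
    """
    with open(path) as fh:
        lines = [l.strip() for l in fh if l.strip()]
    if not lines:
        raise FormatError(f"empty trace file {path}")
    header_idx = None
    for i, line in enumerate(lines[:3]):
        fields = line.split("\t")
        if "LnL" in fields and "Gen" in fields:
            header_idx = i
            break
    if header_idx is not None:
        fields = lines[header_idx].split("\t")
        gen_col, lnl_col = fields.index("Gen"), fields.index("LnL")
        gens, vals = [], []
        for line in lines[header_idx + 1 :]:
            parts = line.split("\t")
            gens.append(float(parts[gen_col]))
            vals.append(float(parts[lnl_col]))
        stride = generation_stride
        if stride is None and len(gens) > 1:
            stride = int(gens[1] - gens[0])
        return LnLTrace(np.array(vals), generation_stride=stride)
    try:
        vals = [float(l) for l in lines]
    except ValueError as exc:
        raise FormatError(f"cannot parse trace file {path}: {exc}") from exc
    return LnLTrace(np.array(vals), generation_stride=generation_stride)
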