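# Methods

This note documents the models, conventions and numerical choices behind
each analysis, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one defensible convention
exists.

## Data model and coordinates

Alignment columns are addressed 1-based and inclusive everywhere, matching
how molecular diagnoses cite positions ("G at position 108" means column
108 of the concatenated matrix). `?`, `N` and `-` are preserved verbatim at
parse time; each downstream analysis decides their semantics (parsimony
expands them to the full {A,C,G,T} set, distances and base-composition
counts exclude them). NEXUS charsets become named partitions; columns not
covered by any charset are kept in implicit `unassigned` partitions so the
representation is lossless. Trees are treated as rooted only when the root
is bifurcating; operations that need rooting (diagnostics, ancestral
states) refuse unrooted input rather than silently midpoint-rooting, and a
separate utility roots on a designated outgroup. Internal newick labels are
read as support values (node metadata), never as taxon names. Leading or
trailing `?` runs — truncated sequences — are accepted anywhere.

## Exclusivity classification

A species is monophyletic iff its tips are exactly the leaf set of a node.
For a non-exclusive species the intruders are `leafset(MRCA) \ tips`;
the species is called **paraphyletic** when the intruders form exactly one
maximal clade under the MRCA and **polyphyletic** otherwise. This tie-break
is stated prominently because other conventions exist: it matches the
field usage in which a single embedded daughter species renders its host
paraphyletic while a species scattered in two or more places is
polyphyletic. Polytomies need no special handling — a group is a clade iff
it is the complete leaf set of some node. Outgroup tips inside an ingroup
MRCA are counted as intruders and additionally raise a rooting-anomaly
warning. Single-tip species are monophyletic by definition and flagged as
singletons. Clade posterior support is the exact count/sample-size
fraction over a posterior tree sample.

## Parsimony machinery

Column reconstructions combine two computations. The classic Fitch
down-pass (intersection-else-union on bifurcating trees) provides the
minimum change count; an inside/outside unit-cost Sankoff dynamic program
provides, for every node, the exact set of states it takes across **all**
most-parsimonious reconstructions (MPRs), and for every branch whether a
change occurs in all, some, or no MPRs. The two engines are cross-checked
against each other on every column and against exhaustive enumeration in
the tests. Ambiguity codes contribute their IUPAC sets; missing data and
gaps contribute the full set. The Fitch pass requires strictly bifurcating
internal nodes (simulated and empirical consensus trees here are binary);
the Sankoff program itself handles multifurcations.

"Change on a branch" is judged conservatively throughout the diagnostics:
a change is counted only when the parent's and child's all-MPR state sets
are **disjoint**, i.e. the change is unambiguous under every MPR. This is
deliberately stricter than "changed in every MPR" (which can hold even
with overlapping marginal state sets) and mirrors how unambiguous changes
are reported by classic parsimony GUIs.

ACCTRAN/DELTRAN single maps are produced by a preorder walk using the
exact subtree costs: each node takes a cost-minimizing state, with ties
broken toward a change (ACCTRAN) or toward the parent state (DELTRAN),
and remaining ties by fixed state order — every resolved map is a true MPR
and the output is deterministic. Claims about gain/loss counts (e.g. the
Dollo pattern) are asserted only under the all-MPR summary, where
`always`/`sometimes`/`never` branch statuses are resolution-free.

## Diagnosis categories

For species S with MRCA node v and candidate state s:

* the site is a candidate iff every member of S carries s or missing data,
  at least one member carries s unambiguously, and an unambiguous change to
  s is reconstructed on the branch subtending v (a `--strict` mode requires
  all members unambiguous);
* **unique_uniform** if s is observed in no tip outside v's subtree — the
  homoplasy check uses observed tip states, not reconstructed internal
  states, so it cannot be fooled by ambiguous internal reconstructions;
* **combination** if s also occurs elsewhere on the tree;
* **embedded_derived** (for a paraphyletic host with embedded species E):
  an unambiguous change on E's stem to a state uniform in E, with no second
  unambiguous origin of that state anywhere inside the host clade.

Missing data within a species is tolerated by default because truncated
sequences are routine in the target data; the strict mode exists for
conservative use. A deliberate consequence of the MRCA-based rule: a
paraphyletic host species generally has few or no unique sites — its MRCA
subtends the embedded species too, so host-private states do not change on
that branch. This mirrors the empirical situation the category system was
designed for. Only ingroup species are diagnosed; outgroups serve to
polarize reconstructions. An optional parent-node search depth (one node
deeper than the species MRCA) is exposed through `classify_embedded`'s
machinery but off by default, since its generality is unclear.

## Mk model

The binary character evolves under the symmetric 1-parameter Mk model
(equal forward and backward rates), with closed-form transition
probabilities `P_same(t) = 1/2 + 1/2 e^{-2qt}` and a flat (1/2, 1/2) root
prior — the stationary distribution, which also makes the likelihood
invariant to root placement along a branch (verified numerically).
Likelihoods use Felsenstein pruning with per-node rescaling, so ~500-tip
trees do not underflow. Impossible data (e.g. q = 0 with both states
observed) yield −∞, which propagates through optimization as a rejected
point rather than an exception; zero-length branches give identity
transition matrices. The rate is estimated by bounded scalar maximization
over q ∈ [1e−8, 1e3] with tolerance 1e−8 on q; an invariant character
pins the estimate at the lower bound with a warning rather than an error.
Marginal ancestral probabilities combine downward (subtree) partials with
outside partials on a preorder sweep; they match brute-force enumeration
to ≤1e−8 on small trees, and observed tips get probability 1. An
asymmetric 2-rate extension is out of scope; symmetric Mk with an
ML-estimated rate is stated as an assumption.

## Distances and the barcoding gap

Distances are uncorrected p-distances under pairwise deletion: each pair is
compared over the columns where both sequences have unambiguous A/C/G/T
states, and the compared-site count is recorded. Pairwise deletion is used
because truncated sequences would make complete deletion wasteful; a
Jukes-Cantor correction is available as an alternative output but no
model-based correction beyond JC is offered. A pair with zero comparable
sites has an undefined (NaN) distance. Each unordered pair falls in exactly
one category (intra-/inter-specific/outgroup, or per species-group pair).
A species shows a barcoding gap when its minimum distance to any other
ingroup taxon exceeds its maximum intraspecific distance; the global gap
exists iff every assessable species gaps. Singleton species (undefined
intraspecific maximum) are listed but excluded from the global verdict.

## Harmonic means and Bayes factors

The harmonic-mean marginal-likelihood estimate is computed wholly in log
space: after discarding the first ⌊n·b⌋ samples (default burn-in b = 0.25),
`HM(−lnL) = logsumexp(−lnL_i) − log m`, which is exact under max-shift
stabilization and safe for magnitudes up to at least 1e5 (property-tested).
The Bayes factor follows the raw-difference convention,
`B10 = HM(−lnL | constrained) − HM(−lnL | unconstrained)`, with ≥ 10 read
as strong; the conventional `2·ΔlnL` is carried as an auxiliary field.
The output always lies within the [min, max] range of the per-sample −lnL
values. The arithmetic mean is reported as a descriptive extra only and
never enters B10. The harmonic-mean estimator's well-known instability is
a property of the estimator itself, not of this implementation; no
stepping-stone or thermodynamic-integration alternative is provided.

## χ² homogeneity

Per-taxon A/C/G/T counts (ambiguity and gaps excluded) form an R×4
contingency table; expected counts come from pooled frequencies and
df = 3(R−1). Because published runs do not state their taxon-inclusion
rule, taxa with fewer than `min_sites` (default 100) counted sites are
excluded and listed rather than guessed at; a base with zero pooled count
makes the test undefined and raises an error naming the base.

## Synthetic-data generator

The default profile mirrors the target study system so tests run at
realistic scale in seconds: 9 ingroup species with 4–6 tips each (44
ingroup tips), 2 outgroups (46 total), partitions of 1348 and 481 columns,
HKY+Γ substitution with an AT-rich mitochondrial-like partition
(π = 0.389/0.140/0.142/0.329, κ = 4) and a near-uniform nuclear-like one
(κ = 2), gamma shape 0.5 with 4 discrete categories. Category rates use
the equal-probability quantile **mean** method (closed form via the
regularized incomplete gamma function), and every transition matrix is
checked stochastic to 1e−12. Depths are in expected substitutions per
site: ingroup crown 0.06, within-species crown 0.004, root (outgroup)
0.15 — a shallow radiation with substantially deeper outgroups.

Trees are pure-birth (Yule) backbones whose species leaves are replaced by
shallow within-species Yule clades; paraphyly is produced by **grafting**
the embedded species' clade onto a branch inside the host clade (never by
relabeling), so branch lengths stay coherent and positive. Outgroups
attach below the ingroup root. All simulators are pure functions of
(inputs, seed); random streams are split per component and per partition
with distinct spawn keys, so adding a partition does not perturb earlier
output.

Planted diagnostics overwrite disjoint columns so each species carries a
state absent from every other taxon at that column; ground truth records
the exact (species, column, state) triples. The Dollo simulator places one
gain and Poisson losses below it with no regains; for controlled
experiments, loss branches can be fixed explicitly, and a helper screens
candidate placements so that the planted history is also the unique MPR
(the planted branches come out `always`-changed) — without screening, an
unlucky placement can admit a cheaper reconstruction and the truth would
not be recoverable by any parsimony method.

What the generator does **not** emulate: coalescent gene-tree discordance,
indels and alignment error, codon structure, rate variation across
lineages, and sequencing error. Passing tests therefore demonstrate the
correctness of the algorithms under the stated generative model, not
robustness to those real-data complications.

## Problem sizes used in validation

Oracle comparisons run at sizes where exhaustive enumeration is exact and
fast: Fitch vs. enumeration on 1,000 random trees of ≤8 leaves; Mk
likelihood vs. state-summation on 200 trees of ≤6 leaves; marginals on
5-leaf trees. Recovery experiments use the default 46-tip/1829-column
profile (diagnostics, exclusivity over 100 replicates, Dollo over 20
replicates) and ~500-tip trees over 100 replicates for rate estimation,
where the median relative error of q̂ is ~12% (a single binary character
carries limited information; the 20% budget reflects that, not a model
claim).

## Known limitations

* The Fitch pass requires bifurcating trees; soft polytomies must be
  resolved upstream (the Sankoff engine itself does not care).
* The harmonic-mean estimator has high variance as a marginal-likelihood
  estimator; B10 values inherit that property.
* Diagnosis categories depend on taxon sampling: adding a taxon carrying a
  species' diagnostic state can only demote unique sites to combination
  sites (tested as a monotonicity property), so diagnoses should be read
  as relative to the sampled matrix.
* The Mk machinery is strictly 2-state; multi-state characters are covered
  only by the parsimony engine.
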