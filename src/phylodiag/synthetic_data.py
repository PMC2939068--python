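"""Synthetic data with the statistical structure the analyses assume.

The default profile emulates a shallow spider radiation sampled for
population-level species delimitation: 9 ingroup species with multiple
specimens each (44 ingroup tips), 2 outgroup taxa, a 1348-column
mitochondrial-like partition plus a 481-column nuclear-like partition
(1829 concatenated columns), HKY+Gamma substitution, optional species
paraphyly produced by grafting an embedded daughter species inside a host
("budding" speciation), planted species-diagnostic columns, a binary
character following a Dollo-style one-gain/several-losses history, and
MCMC-like log-likelihood traces.

All simulators are pure functions of (inputs, seed).  Random streams are
derived from the configuration seed with distinct spawn keys per component
and per partition, so adding a partition never perturbs earlier output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._parsimony import sankoff_summary, tip_state_sets
from .errors import ConfigError
from .seqio import Alignment, TaxonPartition, read_newick
from .stats import LnLTrace

NUC = "ACGT"

#: per-species ingroup tip counts of the default profile (sums to 44; with
#: 2 outgroups the tree has 46 tips)
DEFAULT_TIP_COUNTS = (6, 6, 5, 5, 5, 5, 4, 4, 4)

#: stationary frequencies of the two default partitions (mitochondrial-like
#: AT-rich vs. near-uniform nuclear-like)
MITO_FREQS = (0.38938, 0.13952, 0.14214, 0.32895)
NUCLEAR_FREQS = (0.23891, 0.26716, 0.21862, 0.27531)


@dataclass
class SubstitutionModel:
    """HKY or GTR with discrete-gamma rate variation.

    ``exchangeabilities`` are GTR rates in order (AC, AG, AT, CG, CT, GT);
    for HKY the single ``kappa`` is the transition/transversion rate ratio.
    The rate matrix is normalized to one expected substitution per unit
    branch length at stationarity.
    """

    kind: str = "HKY"
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    kappa: float = 4.0
    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    gamma_shape: Optional[float] = 0.5
    n_categories: int = 4

    def __post_init__(self):
        if self.kind not in ("HKY", "GTR"):
            raise ConfigError(f"unknown model kind {self.kind!r}")
        total = sum(self.base_freqs)
        if abs(total - 1.0) > 1e-3:
            raise ConfigError("base frequencies must sum to 1")
        # printed frequencies are often rounded; renormalize exactly
        self.base_freqs = tuple(f / total for f in self.base_freqs)
        if any(f <= 0 for f in self.base_freqs):
            raise ConfigError("base frequencies must be positive")
        if self.n_categories < 1:
            raise ConfigError("need at least one rate category")

    def rate_matrix(self) -> np.ndarray:
        pi = np.asarray(self.base_freqs)
        if self.kind == "HKY":
            s = np.ones((4, 4))
            s[0, 2] = s[2, 0] = self.kappa  # A<->G
            s[1, 3] = s[3, 1] = self.kappa  # C<->T
        else:
            ac, ag, at, cg, ct, gt = self.exchangeabilities
            s = np.array(
                [
                    [0, ac, ag, at],
                    [ac, 0, cg, ct],
                    [ag, cg, 0, gt],
                    [at, ct, gt, 0],
                ],
                dtype=float,
            )
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        return q / scale

    def category_rates(self) -> np.ndarray:
        """Mean rate of each equal-probability discrete-gamma category.

        With shape a and mean 1, category i's rate is the conditional mean
        of the gamma density between the i/k and (i+1)/k quantiles, which
        integrates in closed form via the regularized incomplete gamma
        function with shape a+1.
        """
        if self.gamma_shape is None:
            return np.ones(1)
        a = self.gamma_shape
        k = self.n_categories
        bounds = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        upper = gammainc(a + 1, a * bounds[1:])
        lower = gammainc(a + 1, a * bounds[:-1])
        return k * (upper - lower)

    def transition_matrix(self, t: float) -> np.ndarray:
        """Stochastic matrix P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ConfigError("negative branch length")
        return expm(self.rate_matrix() * t)


@dataclass
class ParaphylySpec:
    host: str
    embedded: str
    #: tips in the host sub-clade the embedded species becomes sister to
    n_host_sister_tips: int = 1


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic generator."""

    seed: int
    n_species: int = 9
    tips_per_species: Sequence[int] = DEFAULT_TIP_COUNTS
    outgroups: int = 2
    paraphyly: Optional[ParaphylySpec] = None
    partition_lengths: tuple = (1348, 481)
    partition_names: tuple = ("mito", "nuclear")
    models: tuple = (
        SubstitutionModel(kind="HKY", base_freqs=MITO_FREQS),
        SubstitutionModel(kind="HKY", base_freqs=NUCLEAR_FREQS, kappa=2.0),
    )
    planted_per_species: int = 0
    #: ingroup crown height, expected substitutions/site (shallow radiation)
    crown_depth: float = 0.06
    #: within-species crown height
    within_depth: float = 0.004
    #: root (outgroup divergence) height
    outgroup_depth: float = 0.15

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if isinstance(self.tips_per_species, int):
            self.tips_per_species = (self.tips_per_species,) * self.n_species
        self.tips_per_species = tuple(self.tips_per_species)
        if len(self.tips_per_species) != self.n_species:
            raise ConfigError("tips_per_species length != n_species")
        if any(k < 1 for k in self.tips_per_species) or self.n_species < 1:
            raise ConfigError("all counts must be positive")
        if len(self.partition_lengths) != len(self.partition_names):
            raise ConfigError("partition names/lengths mismatch")
        if any(n <= 0 for n in self.partition_lengths):
            raise ConfigError("zero-length partition requested")
        if len(self.models) == 1:
            self.models = tuple(self.models) * len(self.partition_lengths)
        if len(self.models) != len(self.partition_lengths):
            raise ConfigError("one model per partition required")
        if self.paraphyly is not None:
            names = set(self.species_names)
            if (
                self.paraphyly.host not in names
                or self.paraphyly.embedded not in names
                or self.paraphyly.host == self.paraphyly.embedded
            ):
                raise ConfigError("paraphyly spec names unknown species")

    @property
    def species_names(self) -> list:
        return [f"sp{i + 1}" for i in range(self.n_species)]

    def rng(self, *spawn_key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=spawn_key)
        )


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data."""

    newick: str = ""
    #: (species, 1-based column, state) triples planted as diagnostics
    planted: list = field(default_factory=list)
    #: binary-character truth: node_id -> state, plus change branches
    binary_states: dict = field(default_factory=dict)
    gain_branches: list = field(default_factory=list)
    loss_branches: list = field(default_factory=list)
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

class _N:
    __slots__ = ("children", "length", "label")

    def __init__(self, length=0.0, label=None):
        self.children = []
        self.length = length
        self.label = label

    def tips(self):
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.tips())
        return out

    def newick(self):
        if not self.children:
            return f"{self.label}:{self.length:.8f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.8f}"


def _yule_clade(labels: Sequence[str], depth: float, rng) -> _N:
    """Ultrametric pure-birth clade over the given tip labels."""
    n = len(labels)
    if n == 1:
        return _N(length=depth, label=labels[0])
    birth = {}
    root = _N()
    a, b = _N(), _N()
    root.children = [a, b]
    birth[a] = birth[b] = 0.0
    alive = [a, b]
    t = 0.0
    while len(alive) < n:
        t += rng.exponential(1.0 / len(alive))
        i = int(rng.integers(len(alive)))
        node = alive[i]
        c1, c2 = _N(), _N()
        node.children = [c1, c2]
        node.length = t - birth[node]
        birth[node] = t  # reuse: node's split time
        birth[c1] = birth[c2] = t
        alive[i] = c1
        alive.append(c2)
    t_end = t + rng.exponential(1.0 / n)
    for leaf in alive:
        leaf.length = t_end - birth[leaf]
    scale = depth / t_end if t_end > 0 else 1.0

    def rescale(node):
        node.length *= scale
        for c in node.children:
            rescale(c)

    for c in root.children:
        rescale(c)
    order = rng.permutation(n)
    for leaf, k in zip(root.tips(), order):
        leaf.label = labels[int(k)]
    return root


def _find_parent(root: _N, target: _N):
    for node in _iter_nodes(root):
        if target in node.children:
            return node
    return None


def _iter_nodes(root: _N):
    yield root
    for c in root.children:
        yield from _iter_nodes(c)


def simulate_tree(config: SimConfig):
    """Simulate the study tree: Yule species backbone, shallow within-species
    clades, optional paraphyly grafting, outgroups below the ingroup root.

    Returns (tree, TaxonPartition, SimTruth).  Deterministic given the seed.
    """
    rng = config.rng(0)
    species = config.species_names
    backbone = _yule_clade(species, config.crown_depth, rng)
    clade_of = {}
    for leaf in list(backbone.tips()):
        sp = leaf.label
        k = config.tips_per_species[species.index(sp)]
        tips = [f"{sp}_t{j + 1}" for j in range(k)]
        sub = _yule_clade(tips, config.within_depth, rng)
        sub.length = max(leaf.length - config.within_depth,
                         0.1 * config.within_depth)
        parent = _find_parent(backbone, leaf)
        if parent is None:  # single-species tree
            backbone = sub
        else:
            parent.children[parent.children.index(leaf)] = sub
        clade_of[sp] = sub

    if config.paraphyly is not None:
        backbone = _graft_embedded(backbone, clade_of, config, rng)

    root = _N()
    ingroup_stem = max(config.outgroup_depth - config.crown_depth,
                       0.1 * config.outgroup_depth)
    backbone.length = ingroup_stem
    og_labels = [f"og{i + 1}" for i in range(config.outgroups)]
    if config.outgroups == 0:
        raise ConfigError("at least one outgroup is required for rooting")
    if config.outgroups == 1:
        og = _N(length=config.outgroup_depth, label=og_labels[0])
    else:
        og = _yule_clade(og_labels, config.crown_depth, rng)
        og.length = ingroup_stem
    root.children = [backbone, og]
    newick = root.newick().rsplit(":", 1)[0] + ";"
    tree = read_newick(newick)

    species_of = {}
    outgroups = set()
    for sp in species:
        for j in range(config.tips_per_species[species.index(sp)]):
            species_of[f"{sp}_t{j + 1}"] = sp
    for i, lab in enumerate(og_labels):
        species_of[lab] = f"outsp{i + 1}"
        outgroups.add(lab)
    group_of = {
        sp: ("groupA" if i < min(3, config.n_species) else "groupB")
        for i, sp in enumerate(species)
    }
    partition = TaxonPartition(species_of, group_of, outgroups)
    truth = SimTruth(newick=newick, params={"config": config})
    return tree, partition, truth


def _graft_embedded(backbone: _N, clade_of: dict, config: SimConfig, rng) -> _N:
    """Detach the embedded species' clade and re-attach it inside the host
    clade, making the host paraphyletic and the embedded species
    monophyletic.  Grafting preserves coherent positive branch lengths."""
    spec = config.paraphyly
    emb = clade_of[spec.embedded]
    host = clade_of[spec.host]
    if sum(1 for _ in host.tips()) < 2:
        raise ConfigError("host species needs >= 2 tips for paraphyly")
    parent = _find_parent(backbone, emb)
    if parent is None:
        raise ConfigError("embedded clade cannot be the whole ingroup")
    sibling = next(c for c in parent.children if c is not emb)
    grandparent = _find_parent(backbone, parent)
    sibling.length += parent.length
    if grandparent is None:
        backbone = sibling
    else:
        grandparent.children[grandparent.children.index(parent)] = sibling
    # candidate attachment points: proper sub-clades of the host clade
    candidates = [
        n for n in _iter_nodes(host)
        if n is not host and len(n.tips()) == spec.n_host_sister_tips
    ]
    if not candidates:
        candidates = [n for n in _iter_nodes(host) if n is not host]
    target = candidates[int(rng.integers(len(candidates)))]
    tparent = _find_parent(host, target)
    joint = _N(length=target.length / 2)
    target.length /= 2
    tparent.children[tparent.children.index(target)] = joint
    emb.length = max(config.within_depth, target.length)
    joint.children = [target, emb]
    return backbone


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def simulate_alignment(tree, config: SimConfig) -> Alignment:
    """Evolve sequences along the tree, one partition at a time.

    Per partition: per-site gamma-category rates, root states drawn from the
    model's stationary frequencies, and child states sampled from exp(Q t r)
    transition rows down the tree.  Deterministic given the seed.
    """
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    parts = {}
    offset = 0
    chunks = {lab: [] for lab in labels}
    for p_idx, (name, length, model) in enumerate(
        zip(config.partition_names, config.partition_lengths, config.models)
    ):
        rng = config.rng(1, p_idx)
        rates = model.category_rates()
        cats = rng.integers(0, len(rates), size=length)
        pi = np.asarray(model.base_freqs)
        states = {}  # node -> int array of site states
        root = tree.seed_node
        states[root] = rng.choice(4, size=length, p=pi)
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            t = node.edge.length if node.edge.length is not None else 0.0
            parent_states = states[node.parent_node]
            child = np.empty(length, dtype=np.int64)
            for ci, r in enumerate(rates):
                pmat = model.transition_matrix(t * r)
                in_cat = cats == ci
                for s in range(4):
                    idx = np.flatnonzero(in_cat & (parent_states == s))
                    if idx.size:
                        child[idx] = rng.choice(4, size=idx.size, p=pmat[s])
            states[node] = child
        leaf_states = {
            l.taxon.label: states[l] for l in tree.leaf_node_iter()
        }
        for lab in labels:
            chunks[lab].append(
                "".join(NUC[s] for s in leaf_states[lab])
            )
        parts[name] = (offset + 1, offset + length)
        offset += length
    return Alignment(
        tuple(labels), tuple("".join(chunks[lab]) for lab in labels), parts
    )


def plant_diagnostics(
    alignment: Alignment, partition: TaxonPartition, config: SimConfig
):
    """Overwrite columns so each ingroup species carries a private state.

    For each species, ``planted_per_species`` columns are selected (disjoint
    across species) and every member's character is replaced with a state
    absent from all other taxa at that column.  Returns (new alignment,
    list of (species, column, state) truth triples).
    """
    k = config.planted_per_species
    if k == 0:
        return alignment, []
    rng = config.rng(2)
    rows = {lab: list(seq) for lab, seq in
            zip(alignment.taxon_labels, alignment.matrix)}
    used: set = set()
    truth = []
    all_cols = np.arange(1, alignment.column_count + 1)
    for sp in sorted(partition.ingroup_species):
        members = set(partition.members(sp)) & set(alignment.taxon_labels)
        others = [lab for lab in alignment.taxon_labels if lab not in members]
        planted = 0
        for col in rng.permutation(all_cols):
            if planted == k:
                break
            col = int(col)
            if col in used:
                continue
            other_states = {rows[lab][col - 1].upper() for lab in others}
            free = [b for b in NUC if b not in other_states]
            if not free:
                continue
            state = free[int(rng.integers(len(free)))]
            for m in members:
                rows[m][col - 1] = state
            used.add(col)
            truth.append((sp, col, state))
            planted += 1
        if planted < k:
            raise ConfigError(
                f"not enough columns with a free state to plant {k} "
                f"diagnostics for {sp!r}"
            )
    new = Alignment(
        alignment.taxon_labels,
        tuple("".join(rows[lab]) for lab in alignment.taxon_labels),
        dict(alignment.partitions),
    )
    return new, sorted(truth)


# ---------------------------------------------------------------------------
# binary character and trace simulation
# ---------------------------------------------------------------------------

def simulate_binary_character(
    tree,
    mode: str,
    seed: int,
    q: float = 1.0,
    gain_branch: Optional[int] = None,
    loss_rate: float = 0.0,
    loss_branches: Optional[Sequence[int]] = None,
):
    """Simulate one binary character; modes 'mk' and 'dollo'.

    mk: symmetric two-state Markov walk at rate ``q`` from a uniform root.
    dollo: state 1 arises exactly once on ``gain_branch`` (a node_id); below
    it, losses occur as Poisson events at ``loss_rate`` per unit branch
    length with no regains.  ``loss_branches`` fixes loss placements exactly
    (for controlled experiments) instead of drawing them.

    Returns (tip_states: {label: 0/1}, SimTruth with node states and the
    gain/loss branches).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    node_by_id = {n.node_id: n for n in tree.preorder_node_iter()}
    states: dict = {}
    truth = SimTruth(params={"mode": mode, "q": q, "loss_rate": loss_rate})
    if mode == "mk":
        root = tree.seed_node
        states[root.node_id] = int(rng.integers(2))
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            t = node.edge.length if node.edge.length is not None else 0.0
            p_diff = 0.5 - 0.5 * np.exp(-2.0 * q * t)
            s = states[node.parent_node.node_id]
            flip = rng.random() < p_diff
            states[node.node_id] = 1 - s if flip else s
            if flip:
                (truth.gain_branches if s == 0 else truth.loss_branches).append(
                    node.node_id
                )
    elif mode == "dollo":
        if gain_branch is None or gain_branch not in node_by_id:
            raise ConfigError(f"gain_branch {gain_branch!r} not in tree")
        gain_node = node_by_id[gain_branch]
        fixed_losses = set(loss_branches or ())
        unknown = fixed_losses - set(node_by_id)
        if unknown:
            raise ConfigError(f"loss branches not in tree: {sorted(unknown)}")
        for node in tree.preorder_node_iter():
            states[node.node_id] = 0
        truth.gain_branches.append(gain_node.node_id)

        def walk(node, state):
            states[node.node_id] = state
            for c in node.child_nodes():
                s = state
                if s == 1 and c.node_id != gain_node.node_id:
                    if loss_branches is not None:
                        lost = c.node_id in fixed_losses
                    else:
                        t = c.edge.length if c.edge.length is not None else 0.0
                        lost = rng.random() < 1.0 - np.exp(-loss_rate * t)
                    if lost:
                        s = 0
                        truth.loss_branches.append(c.node_id)
                walk(c, s)

        walk(gain_node, 1)
    else:
        raise ConfigError(f"unknown mode {mode!r}")
    truth.binary_states = dict(states)
    tips = {
        l.taxon.label: states[l.node_id] for l in tree.leaf_node_iter()
    }
    return tips, truth


def pick_dollo_branches(tree, seed: int, n_losses: int = 2):
    """Choose a gain branch and non-adjacent loss branches whose planted
    history is also the unique most-parsimonious reconstruction.

    The gain clade must exclude some tips (so the ancestral state is
    identifiable) and retain tips in state 1 after the losses; candidate
    placements are screened so every planted branch is an 'always' change
    across all MPRs.  Returns (gain_node_id, [loss_node_ids]).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    internal = [
        n for n in tree.preorder_node_iter()
        if not n.is_leaf() and n.parent_node is not None
        and n_losses + 1 <= sum(1 for _ in n.leaf_iter()) <= n_leaves - 2
    ]
    rng.shuffle(internal)
    for gain in internal:
        leaves = [l for l in gain.leaf_iter()]
        for _ in range(30):
            chosen = rng.choice(len(leaves), size=n_losses, replace=False)
            losses = [leaves[int(i)] for i in chosen]
            if len({l.parent_node for l in losses}) < n_losses:
                continue
            tips, _ = simulate_binary_character(
                tree, "dollo", seed=0, gain_branch=gain.node_id,
                loss_branches=[l.node_id for l in losses],
            )
            sets = tip_state_sets(
                tree, {k: frozenset((v,)) for k, v in tips.items()}
            )
            summary = sankoff_summary(tree, sets, (0, 1))
            planted = {gain.node_id} | {l.node_id for l in losses}
            if summary.min_changes == n_losses + 1 and all(
                summary.edge_status[b] == "always" for b in planted
            ):
                return gain.node_id, [l.node_id for l in losses]
    raise ConfigError("no identifiable Dollo placement found on this tree")


def simulate_lnl_trace(n: int, level: float, spread: float, seed: int) -> LnLTrace:
    """MCMC-like log-likelihood trace: ``level`` plus Gaussian noise.

    Magnitudes near -12,000 are routine for the downstream harmonic-mean
    estimator and must not overflow it.
    """
    if n < 1:
        raise ConfigError("trace length must be >= 1")
    if spread < 0:
        raise ConfigError("spread must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(5,)))
    return LnLTrace(level + rng.normal(0.0, spread, size=n) if spread > 0
                    else np.full(n, float(level)))


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    tree: object
    taxa: TaxonPartition
    alignment: Alignment
    truth: SimTruth


def simulate_dataset(config: SimConfig) -> SimBundle:
    """Tree + taxon table + (optionally diagnostic-planted) alignment."""
    tree, taxa, truth = simulate_tree(config)
    aln = simulate_alignment(tree, config)
    aln, planted = plant_diagnostics(aln, taxa, config)
    truth.planted = planted
    return SimBundle(tree, taxa, aln, truth)


def zero_rate_config(config: SimConfig) -> SimConfig:
    """Copy of a config with all substitution silenced (depths set to 0),
    leaving only planted diagnostics as variation."""
    return replace(
        config, crown_depth=0.0, within_depth=0.0, outgroup_depth=0.0
    )
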