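"""Two-state Mk likelihood machinery and parsimony change mapping.

The symmetric 2-state Mk model (Lewis's Markov k model with k = 2 and equal
forward/backward rates) has closed-form transition probabilities

    P_same(t) = 1/2 + 1/2 * exp(-2 q t)
    P_diff(t) = 1/2 - 1/2 * exp(-2 q t)

with a single rate q in expected changes per unit branch length.  The root
prior is flat (1/2, 1/2).  Likelihoods are computed by Felsenstein pruning
with per-node rescaling so that large trees do not underflow; impossible
data at q = 0 yield -inf rather than an exception.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from ._parsimony import resolve_states, sankoff_summary, tip_state_sets
from .errors import ValidationError
from .seqio import require_rooted

MISSING = {None, "?", "-"}

Q_LOWER = 1e-8
Q_UPPER = 1e3
Q_TOL = 1e-8


@dataclass
class BinaryCharacter:
    """Tip -> {0, 1, missing} states plus a semantics label."""

    states: dict
    state_labels: tuple = ("state0", "state1")

    def __post_init__(self):
        for tip, s in self.states.items():
            if s not in (0, 1) and s not in MISSING:
                raise ValidationError(f"tip {tip!r} has invalid state {s!r}")

    def state_sets(self) -> dict:
        """Tip -> frozenset over {0,1}; missing expands to both states."""
        return {
            tip: frozenset((s,)) if s in (0, 1) else frozenset((0, 1))
            for tip, s in self.states.items()
        }

    def observed(self) -> set:
        return {s for s in self.states.values() if s in (0, 1)}


@dataclass
class MkFit:
    rate: float
    log_likelihood: float
    invariant_warning: bool = False
    optimizer: dict = field(default_factory=dict)


@dataclass
class NodeStateProbs:
    """node_id -> (p0, p1) marginal posterior state probabilities."""

    probs: dict

    def __post_init__(self):
        for nid, (p0, p1) in self.probs.items():
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise ValidationError(f"node {nid}: probabilities outside [0,1]")
            if abs(p0 + p1 - 1) > 1e-9:
                raise ValidationError(f"node {nid}: probabilities do not sum to 1")


@dataclass
class ChangeMap:
    min_changes: int
    #: node_id -> annotation; 'gain'/'loss' for single resolutions,
    #: 'always'/'sometimes'/'never' under all-MPR-summary
    branch_changes: dict
    resolution: str
    node_states: Optional[dict] = None  # node_id -> state (single resolutions)


def _edge_probs(q: float, t: float) -> np.ndarray:
    if t < 0:
        raise ValidationError("negative branch length")
    e = math.exp(-2.0 * q * t)
    same = 0.5 + 0.5 * e
    diff = 0.5 - 0.5 * e
    return np.array([[same, diff], [diff, same]])


def _tip_partial(state) -> np.ndarray:
    if state in MISSING:
        return np.ones(2)
    return np.array([1.0, 0.0]) if state == 0 else np.array([0.0, 1.0])


def _down_partials(tree, char: BinaryCharacter, q: float):
    """Postorder conditional likelihoods with per-node log-scale factors.

    Returns (partials: node -> length-2 array, log_scale: float or -inf).
    """
    partials: dict = {}
    log_scale = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            if lab not in char.states:
                raise ValidationError(f"tip {lab!r} absent from character data")
            partials[node] = _tip_partial(char.states[lab])
            continue
        p = np.ones(2)
        for c in node.child_nodes():
            t = c.edge.length if c.edge.length is not None else 0.0
            p = p * (_edge_probs(q, t) @ partials[c])
        m = p.max()
        if m == 0.0:
            return partials, -math.inf
        partials[node] = p / m
        log_scale += math.log(m)
    return partials, log_scale


def mk2_loglik(tree, char: BinaryCharacter, q: float) -> float:
    """Log-likelihood of a binary character under the symmetric Mk model.

    Flat (1/2, 1/2) root prior; missing tips contribute partials (1, 1).
    Returns -inf for data impossible under the given rate (e.g. q = 0 with
    both states observed) rather than raising.
    """
    require_rooted(tree)
    if q < 0:
        raise ValidationError("rate q must be non-negative")
    partials, log_scale = _down_partials(tree, char, q)
    if log_scale == -math.inf:
        return -math.inf
    root_like = 0.5 * partials[tree.seed_node].sum()
    if root_like <= 0.0:
        return -math.inf
    return math.log(root_like) + log_scale


def fit_mk2(tree, char: BinaryCharacter) -> MkFit:
    """Bounded 1-D maximum-likelihood estimate of the Mk rate.

    An invariant character drives the estimate to the lower bound; this is
    reported with a warning flag rather than an error.
    """
    require_rooted(tree)
    if len(char.observed()) < 2:
        warnings.warn("invariant character: rate estimate at lower bound")
        ll = mk2_loglik(tree, char, Q_LOWER)
        return MkFit(Q_LOWER, ll, invariant_warning=True,
                     optimizer={"bounds": (Q_LOWER, Q_UPPER), "evaluations": 1})

    def neg(q):
        ll = mk2_loglik(tree, char, q)
        return math.inf if ll == -math.inf else -ll

    res = minimize_scalar(
        neg, bounds=(Q_LOWER, Q_UPPER), method="bounded",
        options={"xatol": Q_TOL},
    )
    return MkFit(
        float(res.x),
        -float(res.fun),
        optimizer={
            "bounds": (Q_LOWER, Q_UPPER),
            "tolerance": Q_TOL,
            "evaluations": int(res.nfev),
        },
    )


def marginal_asr(tree, char: BinaryCharacter, q: float) -> NodeStateProbs:
    """Exact marginal posterior state probabilities at every node.

    Downward (subtree) partials are combined with outside partials computed
    on a preorder sweep under the flat root prior.  Observed tips get
    probability 1 on their state.
    """
    require_rooted(tree)
    partials, log_scale = _down_partials(tree, char, q)
    if log_scale == -math.inf:
        raise ValidationError("data impossible at this rate: marginals undefined")
    outside: dict = {tree.seed_node: np.array([0.5, 0.5])}
    probs: dict = {}
    for node in tree.preorder_node_iter():
        down = partials[node]
        joint = outside[node] * down
        tot = joint.sum()
        if tot <= 0:
            raise ValidationError("zero marginal normalization")
        p = joint / tot
        probs[node.node_id] = (float(p[0]), float(p[1]))
        if node.is_leaf():
            continue
        children = node.child_nodes()
        # outside partial for each child: everything except its own subtree
        contrib = []
        for c in children:
            t = c.edge.length if c.edge.length is not None else 0.0
            contrib.append(_edge_probs(q, t) @ partials[c])
        for i, c in enumerate(children):
            rest = outside[node].copy()
            for j, other in enumerate(contrib):
                if j != i:
                    rest = rest * other
            t = c.edge.length if c.edge.length is not None else 0.0
            out_c = _edge_probs(q, t).T @ rest
            m = out_c.max()
            outside[c] = out_c / m if m > 0 else out_c
    return NodeStateProbs(probs)


def parsimony_map(tree, char: BinaryCharacter, resolution: str = "ACCTRAN") -> ChangeMap:
    """Fitch minimum changes with branch annotations.

    ``resolution`` is 'ACCTRAN', 'DELTRAN', or 'all-MPR-summary'.  The
    summary mode reports each branch as always / sometimes / never changed
    across all most-parsimonious reconstructions; the single-map modes
    annotate branches as 'gain' (0 -> 1) or 'loss' (1 -> 0).
    """
    require_rooted(tree)
    leaf_sets = tip_state_sets(tree, char.state_sets())
    summary = sankoff_summary(tree, leaf_sets, (0, 1))
    if resolution == "all-MPR-summary":
        return ChangeMap(summary.min_changes, dict(summary.edge_status), resolution)
    states = resolve_states(tree, leaf_sets, (0, 1), strategy=resolution)
    branch_changes: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        sp, sc = states[parent.node_id], states[node.node_id]
        if sp != sc:
            branch_changes[node.node_id] = "gain" if (sp, sc) == (0, 1) else "loss"
    if len(branch_changes) != summary.min_changes:
        raise ValidationError("resolved map change count mismatch")  # pragma: no cover
    return ChangeMap(summary.min_changes, branch_changes, resolution, states)


def gains_and_losses(change_map: ChangeMap) -> tuple:
    """(n_gains, n_losses) for a single-resolution change map."""
    if change_map.node_states is None:
        raise ValidationError("gain/loss counts need a single-map resolution")
    gains = sum(1 for v in change_map.branch_changes.values() if v == "gain")
    losses = sum(1 for v in change_map.branch_changes.values() if v == "loss")
    return gains, losses


def write_asr_table(path, probs: Optional[NodeStateProbs] = None,
                    change_map: Optional[ChangeMap] = None) -> None:
    with open(path, "w") as fh:
        if probs is not None:
            fh.write("node_id\tp0\tp1\n")
            for nid, (p0, p1) in sorted(probs.probs.items()):
                fh.write(f"{nid}\t{p0:.6f}\t{p1:.6f}\n")
        if change_map is not None:
            fh.write(f"# min_changes={change_map.min_changes}\t"
                     f"resolution={change_map.resolution}\n")
            fh.write("node_id\tchange\n")
            for nid, ann in sorted(change_map.branch_changes.items()):
                fh.write(f"{nid}\t{ann}\n")
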