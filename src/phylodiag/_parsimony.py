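"""Unordered (Fitch/Sankoff, unit-cost) parsimony machinery on rooted trees.

Two complementary computations are provided:

* the classic Fitch down-pass (intersection-else-union) for the minimum
  change count on bifurcating trees, and
* an inside/outside Sankoff dynamic program that yields, for every node, the
  exact set of states it takes across *all* most-parsimonious reconstructions
  (MPRs), and for every branch whether a change occurs in all / some / no
  MPRs.  The DP handles multifurcations and ambiguous or missing tips.

States are arbitrary hashables; tip data are state *sets* so that IUPAC
ambiguity and missing data are uniform: a missing tip is simply the full set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

from .errors import ValidationError

INF = math.inf


def tip_state_sets(tree, tip_values: Mapping[str, frozenset]) -> dict:
    """Map leaf node -> state set, erroring on leaves without data."""
    out = {}
    for leaf in tree.leaf_node_iter():
        lab = leaf.taxon.label
        if lab not in tip_values:
            raise ValidationError(f"tip {lab!r} absent from character data")
        s = frozenset(tip_values[lab])
        if not s:
            raise ValidationError(f"tip {lab!r} has empty state set")
        out[leaf] = s
    return out


def fitch_down_pass(tree, leaf_sets: Mapping) -> tuple:
    """Fitch preliminary state sets and union-event count.

    Requires every internal node to be bifurcating (the root included).
    Returns (down_sets: {node_id: frozenset}, change_count).
    """
    down: dict = {}
    changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            down[node.node_id] = leaf_sets[node]
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValidationError(
                "Fitch pass requires a bifurcating tree "
                f"(node {node.node_id} has {len(children)} children)"
            )
        a, b = (down[c.node_id] for c in children)
        inter = a & b
        if inter:
            down[node.node_id] = inter
        else:
            down[node.node_id] = a | b
            changes += 1
    return down, changes


@dataclass
class ParsimonySummary:
    """Exact all-MPR summary of one character on one tree."""

    states: tuple
    min_changes: int
    #: node_id -> frozenset of states the node takes in at least one MPR
    mpr_sets: dict
    #: node_id (non-root) -> 'always' | 'sometimes' | 'never' (change on the
    #: branch subtending the node, across all MPRs)
    edge_status: dict
    #: inside Sankoff costs, node_id -> {state: cost} (kept for reuse)
    inside: dict


def sankoff_summary(tree, leaf_sets: Mapping, states: Sequence[Hashable]) -> ParsimonySummary:
    """Inside/outside unit-cost Sankoff DP with exact MPR summaries."""
    states = tuple(states)
    inside: dict = {}
    # child_min[node] = {state of parent: min over child state of cost+inside}
    child_min: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sset = leaf_sets[node]
            inside[node] = {s: (0 if s in sset else INF) for s in states}
        else:
            tot = {s: 0.0 for s in states}
            for c in node.child_nodes():
                cm = {
                    sp: min(
                        inside[c][sc] + (0 if sc == sp else 1) for sc in states
                    )
                    for sp in states
                }
                child_min[c] = cm
                for s in states:
                    tot[s] += cm[s]
            inside[node] = tot
    root = tree.seed_node
    min_changes = min(inside[root].values())
    if not math.isfinite(min_changes):
        raise ValidationError("character has no feasible reconstruction")

    outside: dict = {root: {s: 0.0 for s in states}}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        tot = {
            sp: sum(child_min[c][sp] for c in node.child_nodes())
            for sp in states
        }
        for c in node.child_nodes():
            out_c = {}
            for sc in states:
                out_c[sc] = min(
                    outside[node][sp]
                    + (tot[sp] - child_min[c][sp])
                    + (0 if sc == sp else 1)
                    for sp in states
                )
            outside[c] = out_c

    mpr_sets = {}
    for node in tree.preorder_node_iter():
        mpr_sets[node.node_id] = frozenset(
            s for s in states if inside[node][s] + outside[node][s] == min_changes
        )
    edge_status = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        tot_p = {
            sp: sum(child_min[c][sp] for c in parent.child_nodes())
            for sp in states
        }
        best_same = INF
        best_diff = INF
        for sp in states:
            base = outside[parent][sp] + tot_p[sp] - child_min[node][sp]
            for sc in states:
                cost = base + (0 if sc == sp else 1) + inside[node][sc]
                if sc == sp:
                    best_same = min(best_same, cost)
                else:
                    best_diff = min(best_diff, cost)
        if best_diff == min_changes and best_same > min_changes:
            edge_status[node.node_id] = "always"
        elif best_diff == min_changes:
            edge_status[node.node_id] = "sometimes"
        else:
            edge_status[node.node_id] = "never"
    return ParsimonySummary(
        states=states,
        min_changes=int(min_changes),
        mpr_sets=mpr_sets,
        edge_status=edge_status,
        inside={n.node_id: inside[n] for n in tree.preorder_node_iter()},
    )


def resolve_states(
    tree,
    leaf_sets: Mapping,
    states: Sequence[Hashable],
    strategy: str = "ACCTRAN",
) -> dict:
    """One most-parsimonious labeling, node_id -> state.

    Ties during the preorder assignment are broken toward a change
    (ACCTRAN, accelerating transformations) or toward the parent state
    (DELTRAN, delaying them); remaining ties fall to the configured state
    order, making the output deterministic.
    """
    if strategy not in ("ACCTRAN", "DELTRAN"):
        raise ValidationError(f"unknown resolution strategy {strategy!r}")
    states = tuple(states)
    inside: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sset = leaf_sets[node]
            inside[node] = {s: (0 if s in sset else INF) for s in states}
        else:
            inside[node] = {
                s: sum(
                    min(inside[c][sc] + (0 if sc == s else 1) for sc in states)
                    for c in node.child_nodes()
                )
                for s in states
            }
    assignment: dict = {}
    root = tree.seed_node
    best = min(inside[root].values())
    root_state = next(s for s in states if inside[root][s] == best)
    assignment[root.node_id] = root_state
    node_state = {root: root_state}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        sp = node_state[node.parent_node]
        costs = {
            sc: inside[node][sc] + (0 if sc == sp else 1) for sc in states
        }
        best = min(costs.values())
        ties = [s for s in states if costs[s] == best]
        if strategy == "DELTRAN" and sp in ties:
            chosen = sp
        elif strategy == "ACCTRAN":
            diff = [s for s in ties if s != sp]
            chosen = diff[0] if diff else ties[0]
        else:
            chosen = ties[0]
        node_state[node] = chosen
        assignment[node.node_id] = chosen
    return assignment
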