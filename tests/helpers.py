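"""Independent oracles and random-instance generators for the test suite.

Everything here is deliberately implemented by direct enumeration or the
naive formula, independent of the package's algorithms, so that agreement
is evidence of correctness rather than shared bugs.
"""

import itertools
import math

import numpy as np

from phylodiag.seqio import read_newick, state_set


def random_tree_newick(rng, n_leaves, labels=None, max_len=1.0):
    """Random rooted bifurcating tree with uniform random branch lengths."""
    if labels is None:
        labels = [f"t{i}" for i in range(n_leaves)]
    nodes = [f"{lab}:{rng.uniform(0.01, max_len):.6f}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.01, max_len):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0].rsplit(":", 1)[0] + ";"


def random_rooted_tree(rng, n_leaves, **kw):
    return read_newick(random_tree_newick(rng, n_leaves, **kw))


def brute_force_min_changes(tree, column, states=("A", "C", "G", "T")):
    """Exhaustive minimum change count over all internal-node labelings.

    ``column`` maps leaf label -> character (IUPAC/missing allowed).
    Vectorized over all |states|^n_internal assignments.
    """
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    pos = {n: i for i, n in enumerate(internal)}
    n_int = len(internal)
    grids = np.indices((k,) * n_int).reshape(n_int, -1)
    cost = np.zeros(grids.shape[1])
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_states = grids[pos[node.parent_node]]
        if node.is_leaf():
            allowed = np.array(
                [idx[s] for s in state_set(column[node.taxon.label])]
            )
            cost += ~np.isin(parent_states, allowed)
        else:
            cost += parent_states != grids[pos[node]]
    return int(cost.min())


def brute_force_mk2_loglik(tree, tip_states, q):
    """Sum over all internal binary labelings of the Mk2 joint probability."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        p = 0.5
        for n in tree.preorder_node_iter():
            if n.parent_node is None:
                continue
            sp = amap[n.parent_node]
            if n.is_leaf():
                sc = tip_states[n.taxon.label]
                if sc not in (0, 1):
                    continue  # missing: marginalized -> factor 1
            else:
                sc = amap[n]
            e = math.exp(-2.0 * q * (n.edge.length or 0.0))
            p *= (0.5 + 0.5 * e) if sp == sc else (0.5 - 0.5 * e)
        total += p
    return math.log(total) if total > 0 else -math.inf


def brute_force_mk2_marginal(tree, tip_states, q, target_node):
    """Marginal posterior (p0, p1) at one internal node by enumeration."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    num = {0: 0.0, 1: 0.0}
    for assign in itertools.product((0, 1), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        p = 0.5
        for n in tree.preorder_node_iter():
            if n.parent_node is None:
                continue
            sp = amap[n.parent_node]
            if n.is_leaf():
                sc = tip_states[n.taxon.label]
                if sc not in (0, 1):
                    continue
            else:
                sc = amap[n]
            e = math.exp(-2.0 * q * (n.edge.length or 0.0))
            p *= (0.5 + 0.5 * e) if sp == sc else (0.5 - 0.5 * e)
        num[amap[target_node]] += p
    z = num[0] + num[1]
    return num[0] / z, num[1] / z


def all_clades(tree):
    """Set of leaf-label frozensets, one per node."""
    out = set()
    for node in tree.preorder_node_iter():
        out.add(frozenset(l.taxon.label for l in node.leaf_iter()))
    return out


def oracle_classify(tree, tips):
    """First-principles monophyly classification via the clade list."""
    tips = frozenset(tips)
    clades = all_clades(tree)
    if tips in clades:
        return "monophyletic", frozenset()
    containing = min((c for c in clades if tips <= c), key=len)
    intruders = containing - tips
    status = "paraphyletic" if intruders in clades else "polyphyletic"
    return status, intruders
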