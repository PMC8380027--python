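"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own algorithms:
isomorphism is checked through canonical nested keys, parsimony cost by
exhaustive enumeration over all internal-state assignments, and
irreversible gain counts by the maximal all-parasitic-subtree closed
form.  Random trees for round-trip tests are built by a local
random-join independent of the simulator module.
"""

from __future__ import annotations

import itertools
import math
import random

import pytest

from copsynth.treeio import FREE_LIVING, PARASITIC, UNKNOWN, Node, RootedTree, StateCoding


# ---- canonical-form isomorphism oracle ------------------------------


def topology_key(tree: RootedTree):
    """Canonical key of a rooted tree: equal keys <=> isomorphic trees."""

    def key(node: Node):
        if node.is_leaf:
            return ("L", str(node.tip_key))
        return ("N", tuple(sorted(key(c) for c in node.children)))

    return key(tree.root)


def assert_isomorphic(a: RootedTree, b: RootedTree):
    assert topology_key(a) == topology_key(b)


# ---- independent random tree generator ------------------------------


def random_tree(rng: random.Random, labels) -> RootedTree:
    """Random binary rooted tree by sequential pair-joins (local copy,
    independent of the simulator)."""
    nodes = [Node(label=str(l)) for l in labels]
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        joint = Node()
        joint.add_child(a)
        joint.add_child(b)
        nodes.append(joint)
    return RootedTree(nodes[0])


def random_coding(rng: random.Random, tree: RootedTree, p_unknown: float = 0.0) -> StateCoding:
    coding = StateCoding()
    for leaf in tree.leaves():
        roll = rng.random()
        if roll < p_unknown:
            state = UNKNOWN
        else:
            state = PARASITIC if rng.random() < 0.5 else FREE_LIVING
        coding.set(leaf.tip_key, state, sampled=True)
    return coding


# ---- exhaustive parsimony oracle ------------------------------------


def brute_force_min_cost(tree: RootedTree, coding: StateCoding, model) -> float:
    """Minimum parsimony cost by enumerating every internal labeling."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    best = math.inf
    for bits in itertools.product((0, 1), repeat=len(internals)):
        states = {id(n): s for n, s in zip(internals, bits)}
        cost = 0.0
        if model.root_prior is not None:
            cost += model.c(model.root_prior, states[id(tree.root)])
        for node in internals:
            s = states[id(node)]
            for child in node.children:
                if child.is_leaf:
                    tip = coding.state_of(child.tip_key)
                    if tip is UNKNOWN:
                        cost += min(model.c(s, 0), model.c(s, 1))
                    else:
                        cost += model.c(s, tip)
                else:
                    cost += model.c(s, states[id(child)])
        best = min(best, cost)
    return best


# ---- irreversible closed form ---------------------------------------


def irreversible_gains_oracle(tree: RootedTree, coding: StateCoding) -> int:
    """Number of maximal subtrees whose known tips are all parasitic
    (and that contain at least one known parasitic tip)."""

    def scan(node: Node):
        # returns (clean: no known free-living below, any_parasitic)
        if node.is_leaf:
            s = coding.state_of(node.tip_key)
            return s != FREE_LIVING, s == PARASITIC
        clean, para = True, False
        for c in node.children:
            c_clean, c_para = scan(c)
            clean &= c_clean
            para |= c_para
        return clean, para

    count = 0
    stack = [tree.root]
    while stack:
        node = stack.pop()
        clean, para = scan(node)
        if clean and para:
            count += 1
        elif not node.is_leaf:
            stack.extend(node.children)
    return count


# ---- exhaustive mrca oracle ------------------------------------------


def brute_force_mrca(tree: RootedTree, tips: set) -> Node:
    """Scan every node; pick the smallest-tipset node containing tips."""
    best, best_size = None, None
    for node in tree.preorder():
        sub = tree.tipset_of(node)
        if tips <= sub and (best is None or len(sub) < best_size):
            best, best_size = node, len(sub)
    return best


@pytest.fixture(scope="session")
def copepod_dataset():
    from copsynth.synthetic_copepod import build_dataset

    return build_dataset()
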