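"""Binary-state parsimony ancestral-state reconstruction.

The engine is the Sankoff dynamic program, which handles multifurcating
trees and asymmetric cost matrices uniformly (Fitch parsimony is the
unordered special case and is not implemented separately).  Two cost
models are provided:

* ``unordered`` — both transitions cost 1; gains (free-living →
  parasitic) and losses (parasitic → free-living) are equally allowed.
* ``irreversible`` — Camin–Sokal parsimony: the loss 1→0 is forbidden
  (infinite cost) and the state above the root is fixed to free-living,
  so every parasitic tip must be explained by a gain.  On an
  all-parasitic tree the single gain falls on the (virtual) root edge
  and the root itself is reported as the gained clade.

Equally parsimonious reconstructions are resolved during the preorder
backtrace by a tie rule: ACCTRAN prefers a child state *different* from
its parent (accelerating changes toward the root, favoring reversals),
DELTRAN prefers a child state *equal* to its parent (delaying changes
toward the tips, favoring parallel gains).  The root state tie on
unordered reconstructions defaults to free-living — the analysed trees
are rooted with free-living outgroups and parasitism is the derived
condition — and every application of the rule is recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .treeio import FREE_LIVING, PARASITIC, UNKNOWN, Node, RootedTree, StateCoding

__all__ = [
    "CostModel",
    "UNORDERED",
    "IRREVERSIBLE",
    "Change",
    "Reconstruction",
    "TransitionClade",
    "min_cost",
    "reconstruct",
    "count_changes",
    "transition_clades",
]

INF = math.inf
STATES = (FREE_LIVING, PARASITIC)


@dataclass(frozen=True)
class CostModel:
    """2x2 transition cost matrix over {free-living, parasitic}.

    ``cost[a][b]`` is the price of an a→b change along an edge.
    ``root_prior`` optionally fixes the state above the root: the root's
    own state is then chosen through a virtual edge from that state, so a
    change at the root is counted (and reported) once.
    """

    name: str
    cost: tuple  # ((c00, c01), (c10, c11))
    root_prior: Optional[int] = None

    def __post_init__(self):
        if self.cost[0][0] != 0 or self.cost[1][1] != 0:
            raise ValueError("cost matrix diagonal must be zero")
        if any(c < 0 for row in self.cost for c in row):
            raise ValueError("costs must be nonnegative")

    def c(self, a: int, b: int) -> float:
        return self.cost[a][b]


UNORDERED = CostModel("unordered", ((0, 1), (1, 0)))
IRREVERSIBLE = CostModel("irreversible", ((0, 1), (INF, 0)), root_prior=FREE_LIVING)


@dataclass(frozen=True)
class Change:
    """A state change on the edge above ``node`` (gain 0→1, loss 1→0)."""

    node: Node
    from_state: int
    to_state: int

    @property
    def is_gain(self) -> bool:
        return self.from_state == FREE_LIVING and self.to_state == PARASITIC

    @property
    def is_loss(self) -> bool:
        return self.from_state == PARASITIC and self.to_state == FREE_LIVING


@dataclass
class Reconstruction:
    tree: RootedTree
    model: CostModel
    resolution: str  # "ACCTRAN" | "DELTRAN"
    states: dict = field(default_factory=dict)  # Node -> state
    changes: list = field(default_factory=list)  # list[Change]
    total_cost: float = 0.0
    root_tie_applied: bool = False

    @property
    def gains(self) -> int:
        return sum(1 for ch in self.changes if ch.is_gain)

    @property
    def losses(self) -> int:
        return sum(1 for ch in self.changes if ch.is_loss)


def _tip_costs(leaf: Node, coding: StateCoding) -> tuple:
    state = coding.state_of(leaf.tip_key)
    if state is UNKNOWN:
        return (0.0, 0.0)
    return (0.0, INF) if state == FREE_LIVING else (INF, 0.0)


def _sankoff_table(tree: RootedTree, coding: StateCoding, model: CostModel) -> dict:
    """Postorder DP: table[node][s] = min cost of node's subtree given state s."""
    table: dict = {}
    for node in tree.postorder():
        if node.is_leaf:
            table[node] = _tip_costs(node, coding)
        else:
            costs = []
            for s in STATES:
                total = 0.0
                for child in node.children:
                    total += min(model.c(s, t) + table[child][t] for t in STATES)
                costs.append(total)
            table[node] = tuple(costs)
    return table


def _root_costs(table, root, model: CostModel):
    if model.root_prior is None:
        return table[root]
    return tuple(model.c(model.root_prior, s) + table[root][s] for s in STATES)


def min_cost(tree: RootedTree, coding: StateCoding, model: CostModel = UNORDERED) -> float:
    """Minimum total parsimony cost of the tree under the cost model.

    Unknown-state tips contribute zero cost in either state.  Raises if a
    tip has no coding entry, or if no finite assignment exists (possible
    only with a constrained model).
    """
    table = _sankoff_table(tree, coding, model)
    best = min(_root_costs(table, tree.root, model))
    if best == INF:
        raise ValueError("infeasible: no state assignment has finite cost")
    return best


def reconstruct(
    tree: RootedTree,
    coding: StateCoding,
    model: CostModel = UNORDERED,
    resolution: str = "ACCTRAN",
    root_rule: int = FREE_LIVING,
) -> Reconstruction:
    """Assign minimum-cost states to every node and record the changes.

    ``resolution`` breaks ties during the preorder backtrace (see module
    docstring); ``root_rule`` breaks a tie between root states when the
    model has no root prior.
    """
    if resolution not in ("ACCTRAN", "DELTRAN"):
        raise ValueError("resolution must be 'ACCTRAN' or 'DELTRAN'")
    table = _sankoff_table(tree, coding, model)
    rec = Reconstruction(tree=tree, model=model, resolution=resolution)

    root_costs = _root_costs(table, tree.root, model)
    best = min(root_costs)
    if best == INF:
        raise ValueError("infeasible: no state assignment has finite cost")
    rec.total_cost = best

    optimal = [s for s in STATES if root_costs[s] == best]
    if len(optimal) == 1:
        root_state = optimal[0]
    elif model.root_prior is not None:
        # tie through the virtual root edge: same accelerate/delay logic
        prefer_change = resolution == "ACCTRAN"
        root_state = next(
            s for s in optimal if (s != model.root_prior) == prefer_change
        )
    else:
        root_state = root_rule
        rec.root_tie_applied = True
    rec.states[tree.root] = root_state
    if model.root_prior is not None and root_state != model.root_prior:
        rec.changes.append(Change(tree.root, model.root_prior, root_state))

    # preorder backtrace with the resolution's tie rule
    stack = [tree.root]
    while stack:
        node = stack.pop()
        ps = rec.states[node]
        for child in reversed(node.children):
            scores = tuple(model.c(ps, t) + table[child][t] for t in STATES)
            low = min(scores)
            opts = [t for t in STATES if scores[t] == low]
            if len(opts) == 1:
                cs = opts[0]
            elif resolution == "ACCTRAN":
                cs = next(t for t in opts if t != ps)
            else:
                cs = next(t for t in opts if t == ps)
            rec.states[child] = cs
            if cs != ps:
                rec.changes.append(Change(child, ps, cs))
            if not child.is_leaf:
                stack.append(child)

    edge_cost = sum(model.c(ch.from_state, ch.to_state) for ch in rec.changes)
    assert edge_cost == rec.total_cost, "backtrace does not achieve the DP bound"
    return rec


def count_changes(rec: Reconstruction) -> tuple[int, int]:
    """(gains, losses): edges 0→1 and 1→0 in the reconstruction."""
    return rec.gains, rec.losses


@dataclass
class TransitionClade:
    """One independent origin of parasitism: the subtree above which the
    gain occurred, with any reversals nested inside it."""

    node: Node
    tips: frozenset
    losses_within: list = field(default_factory=list)  # list[(Node, frozenset)]

    @property
    def n_tips(self) -> int:
        return len(self.tips)


def transition_clades(rec: Reconstruction) -> list[TransitionClade]:
    """One record per gain edge, in preorder, with nested-loss sub-records."""
    tree = rec.tree
    order = {node: i for i, node in enumerate(tree.preorder())}
    gain_nodes = [ch.node for ch in rec.changes if ch.is_gain]
    loss_nodes = [ch.node for ch in rec.changes if ch.is_loss]

    def is_within(node: Node, ancestor: Node) -> bool:
        cur = node
        while cur is not None:
            if cur is ancestor:
                return True
            cur = cur.parent
        return False

    clades = []
    for gnode in sorted(gain_nodes, key=order.get):
        losses = [
            (ln, frozenset(tree.tipset_of(ln)))
            for ln in sorted(loss_nodes, key=order.get)
            if ln is not gnode and is_within(ln, gnode)
        ]
        clades.append(
            TransitionClade(
                node=gnode,
                tips=frozenset(tree.tipset_of(gnode)),
                losses_within=losses,
            )
        )
    return clades
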