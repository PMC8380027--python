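"""Parsimony reconstruction: Sankoff DP, tie rules, change counting."""

import random

import pytest

from conftest import (
    brute_force_min_cost,
    irreversible_gains_oracle,
    random_coding,
    random_tree,
)
from copsynth.asr import (
    IRREVERSIBLE,
    UNORDERED,
    CostModel,
    count_changes,
    min_cost,
    reconstruct,
    transition_clades,
)
from copsynth.treeio import FREE_LIVING, PARASITIC, UNKNOWN, StateCoding, parse_newick


def coding_from(tree, mapping):
    coding = StateCoding()
    for leaf in tree.leaves():
        coding.set(leaf.tip_key, mapping[leaf.tip_key], sampled=True)
    return coding


def states_by_prefix(tree):
    """P* tips parasitic, FL* tips free-living, U* unknown."""
    mapping = {}
    for leaf in tree.leaves():
        name = str(leaf.tip_key)
        mapping[leaf.tip_key] = (
            PARASITIC if name.startswith("P")
            else UNKNOWN if name.startswith("U")
            else FREE_LIVING
        )
    return mapping


CATERPILLAR = "(FL0,(P1,(FLa,(P2,(FLb,P3)))));"
PECTINATE = "(FLout,(P1,(P2,(P3,(P4,(FLa,(P5,(P6,(P7,(P8,FLb))))))))));"


class TestMinCost:
    def test_single_change(self):
        tree = parse_newick("((P1,P2),FL);")
        assert min_cost(tree, coding_from(tree, states_by_prefix(tree))) == 1

    def test_constant_character(self):
        tree = parse_newick("((P1,P2),P3);")
        assert min_cost(tree, coding_from(tree, states_by_prefix(tree))) == 0

    def test_missing_tip_coding_named(self):
        tree = parse_newick("((P1,P2),FL);")
        coding = StateCoding()
        coding.set("P1", PARASITIC)
        coding.set("P2", PARASITIC)
        with pytest.raises(KeyError, match="FL"):
            min_cost(tree, coding)

    @pytest.mark.parametrize("model", [UNORDERED, IRREVERSIBLE], ids=["unordered", "irrev"])
    def test_matches_brute_force(self, model):
        # exhaustive oracle over every internal labeling, random instances
        for seed in range(100):
            rng = random.Random(seed)
            n = rng.randint(4, 12)
            tree = random_tree(rng, [f"t{i}" for i in range(n)])
            coding = random_coding(rng, tree, p_unknown=0.15)
            assert min_cost(tree, coding, model) == brute_force_min_cost(tree, coding, model)

    def test_unknown_tips_never_increase_cost(self):
        for seed in range(40):
            rng = random.Random(1000 + seed)
            tree = random_tree(rng, [f"t{i}" for i in range(10)])
            coding = random_coding(rng, tree)
            full = min_cost(tree, coding)
            victim = rng.choice(sorted(tree.tip_set()))
            coding.states[victim] = UNKNOWN
            assert min_cost(tree, coding) <= full

    def test_polytomy_cost_bounds_its_resolutions(self):
        # a soft polytomy is an upper bound: collapsing an internal edge
        # never decreases the DP cost, because any polytomy labeling
        # extends to the resolved tree at equal cost
        for seed in range(40):
            rng = random.Random(2000 + seed)
            tree = random_tree(rng, [f"t{i}" for i in range(10)])
            coding = random_coding(rng, tree)
            resolved = min_cost(tree, coding)
            internal = [
                n for n in tree.preorder()
                if not n.is_leaf and n.parent is not None
            ]
            victim = rng.choice(internal)
            parent = victim.parent
            idx = parent.children.index(victim)
            parent.children[idx:idx + 1] = victim.children
            for c in victim.children:
                c.parent = parent
            assert min_cost(tree, coding) >= resolved


class TestReconstruct:
    def test_caterpillar_acctran_vs_deltran(self):
        tree = parse_newick(CATERPILLAR)
        coding = coding_from(tree, states_by_prefix(tree))
        assert min_cost(tree, coding) == 3
        acc = reconstruct(tree, coding, UNORDERED, resolution="ACCTRAN")
        delt = reconstruct(tree, coding, UNORDERED, resolution="DELTRAN")
        assert count_changes(acc) == (1, 2)  # one gain, reversals accelerated
        assert count_changes(delt) == (3, 0)  # parallel gains delayed to tips
        assert acc.total_cost == delt.total_cost == 3

    def test_pectinate_unambiguous(self):
        # both resolutions agree: one gain with two nested reversals
        tree = parse_newick(PECTINATE)
        coding = coding_from(tree, states_by_prefix(tree))
        for resolution in ("ACCTRAN", "DELTRAN"):
            rec = reconstruct(tree, coding, UNORDERED, resolution=resolution)
            assert count_changes(rec) == (1, 2)

    def test_pectinate_irreversible_parallel_gains(self):
        tree = parse_newick(PECTINATE)
        coding = coding_from(tree, states_by_prefix(tree))
        rec = reconstruct(tree, coding, IRREVERSIBLE)
        assert count_changes(rec) == (8, 0)
        assert rec.total_cost == 8

    @pytest.mark.parametrize("model", [UNORDERED, IRREVERSIBLE], ids=["unordered", "irrev"])
    @pytest.mark.parametrize("resolution", ["ACCTRAN", "DELTRAN"])
    def test_both_resolutions_achieve_min_cost(self, model, resolution):
        for seed in range(60):
            rng = random.Random(3000 + seed)
            tree = random_tree(rng, [f"t{i}" for i in range(rng.randint(4, 12))])
            coding = random_coding(rng, tree, p_unknown=0.1)
            rec = reconstruct(tree, coding, model, resolution=resolution)
            assert rec.total_cost == min_cost(tree, coding, model)
            edge_cost = sum(
                model.c(ch.from_state, ch.to_state) for ch in rec.changes
            )
            assert edge_cost == rec.total_cost

    def test_irreversible_never_loses(self):
        for seed in range(40):
            rng = random.Random(4000 + seed)
            tree = random_tree(rng, [f"t{i}" for i in range(10)])
            coding = random_coding(rng, tree)
            rec = reconstruct(tree, coding, IRREVERSIBLE)
            assert rec.losses == 0

    def test_irreversible_gains_closed_form(self):
        # gains equal the number of maximal all-parasitic subtrees
        for seed in range(80):
            rng = random.Random(5000 + seed)
            tree = random_tree(rng, [f"t{i}" for i in range(rng.randint(4, 14))])
            coding = random_coding(rng, tree, p_unknown=0.1)
            rec = reconstruct(tree, coding, IRREVERSIBLE)
            assert rec.gains == irreversible_gains_oracle(tree, coding)

    def test_all_parasitic_tree_gains_once_at_root(self):
        tree = parse_newick("((P1,P2),(P3,P4));")
        coding = coding_from(tree, states_by_prefix(tree))
        rec = reconstruct(tree, coding, IRREVERSIBLE)
        assert count_changes(rec) == (1, 0)
        [clade] = transition_clades(rec)
        assert clade.node is tree.root and clade.tips == tree.tip_set()

    def test_root_tie_logged_and_configurable(self):
        tree = parse_newick("(P1,FL1);")
        coding = coding_from(tree, states_by_prefix(tree))
        rec = reconstruct(tree, coding, UNORDERED)
        assert rec.root_tie_applied
        assert rec.states[tree.root] == FREE_LIVING
        rec2 = reconstruct(tree, coding, UNORDERED, root_rule=PARASITIC)
        assert rec2.states[tree.root] == PARASITIC

    def test_invalid_resolution_rejected(self):
        tree = parse_newick("(P1,FL1);")
        coding = coding_from(tree, states_by_prefix(tree))
        with pytest.raises(ValueError, match="resolution"):
            reconstruct(tree, coding, UNORDERED, resolution="MAXTRAN")


class TestCostModel:
    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            CostModel("bad", ((1, 1), (1, 0)))

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            CostModel("bad", ((0, -1), (1, 0)))


class TestTransitionClades:
    def test_single_gain_clade(self):
        tree = parse_newick("((P1,P2),FL);")
        coding = coding_from(tree, states_by_prefix(tree))
        [clade] = transition_clades(reconstruct(tree, coding, UNORDERED))
        assert clade.tips == {"P1", "P2"}
        assert not clade.losses_within

    def test_nested_losses_recorded(self):
        tree = parse_newick(PECTINATE)
        coding = coding_from(tree, states_by_prefix(tree))
        [clade] = transition_clades(reconstruct(tree, coding, UNORDERED, resolution="ACCTRAN"))
        loss_tipsets = sorted(sorted(t) for _, t in clade.losses_within)
        assert loss_tipsets == [["FLa"], ["FLb"]]

    def test_irreversible_clades_are_singletons_here(self):
        tree = parse_newick(PECTINATE)
        coding = coding_from(tree, states_by_prefix(tree))
        clades = transition_clades(reconstruct(tree, coding, IRREVERSIBLE))
        assert len(clades) == 8
        assert all(c.n_tips == 1 for c in clades)
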