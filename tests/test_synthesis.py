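"""Ranked grouping extraction, conflict detection, and grafting."""

import itertools
import random

import pytest

from conftest import assert_isomorphic, topology_key
from copsynth import synthetic_data as sd
from copsynth.synthesis import (
    Grouping,
    SourceStudy,
    conflicts,
    extract_groupings,
    rank_studies,
    summarize_skips,
    synthesize,
    taxonomy_study,
)
from copsynth.treeio import Node, RootedTree, displays, parse_newick, write_newick


def study(newick, study_id="s", rank=1, **kw):
    return SourceStudy(study_id, parse_newick(newick), rank=rank, **kw)


def g(ing, exc):
    return Grouping(frozenset(ing), frozenset(exc))


class TestRankStudies:
    def make(self, sid, n_taxa=10, markers=2, method="BI_ML"):
        return SourceStudy(
            sid, parse_newick("(A,B);"), n_ingroup_taxa=n_taxa,
            n_markers=markers, method_class=method,
        )

    def test_method_class_orders_ml_first(self):
        nj = self.make("nj", method="NJ_ME")
        ml = self.make("ml", method="BI_ML")
        assert [s.study_id for s in rank_studies([nj, ml])] == ["ml", "nj"]

    def test_explicit_ranks_override_comparator(self):
        a = self.make("a", n_taxa=100)
        b = self.make("b", n_taxa=5)
        ordered = rank_studies([a, b], explicit_ranks={"a": 2, "b": 1})
        assert [s.study_id for s in ordered] == ["b", "a"]
        assert ordered[0].rank == 1

    def test_tie_broken_by_study_id(self):
        ordered = rank_studies([self.make("b"), self.make("a")])
        assert [s.study_id for s in ordered] == ["a", "b"]

    def test_duplicate_explicit_rank_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            rank_studies([self.make("a"), self.make("b")], {"a": 1, "b": 1})

    def test_more_taxa_then_more_markers(self):
        few = self.make("few", n_taxa=5, markers=9)
        many = self.make("many", n_taxa=50, markers=1)
        assert rank_studies([few, many])[0].study_id == "many"


class TestExtractGroupings:
    def test_single_internal_node(self):
        out = extract_groupings(study("((A,B),C);"))
        assert len(out) == 1
        assert out[0].ingroup == {"A", "B"} and out[0].exclude == {"C"}

    def test_balanced_tree_preorder(self):
        out = extract_groupings(study("((A,B),(C,D));"))
        assert [sorted(x.ingroup) for x in out] == [["A", "B"], ["C", "D"]]

    def test_star_tree_empty(self):
        assert extract_groupings(study("(A,B,C);")) == []


class TestConflicts:
    def test_incompatible_pair_by_enumeration(self):
        # no rooted tree on {A,B,C} displays both {A,B}|{C} and {B,C}|{A}
        trees = ["((A,B),C);", "((A,C),B);", "((B,C),A);", "(A,B,C);"]
        g1, g2 = g("AB", "C"), g("BC", "A")
        for nwk in trees:
            t = parse_newick(nwk)
            assert not (displays(t, g1) and displays(t, g2))
        assert conflicts(g1, g2)

    def test_nesting_is_compatible(self):
        g1, g2 = g("ABC", "D"), g("AB", "CD")
        t = parse_newick("(((A,B),C),D);")
        assert displays(t, g1) and displays(t, g2)
        assert not conflicts(g1, g2)

    def test_disjoint_taxa_compatible(self):
        assert not conflicts(g("AB", "C"), g("XY", "Z"))


class TestSynthesize:
    def test_single_study_identity(self):
        s = study("(((A,B),C),(D,E));")
        out = synthesize([s])
        assert_isomorphic(out.tree, s.tree)
        assert not out.skips

    def test_compatible_grafting(self):
        out = synthesize([study("((A,B),C);", "s1", 1), study("((B,D),C);", "s2", 2)])
        assert not out.skips
        for st in (study("((A,B),C);"), study("((B,D),C);")):
            for grouping in extract_groupings(st):
                assert displays(out.tree, grouping)
        assert out.tree.tip_set() == {"A", "B", "C", "D"}

    def test_conflicting_study_skipped(self):
        s1, s2 = study("((A,B),C);", "s1", 1), study("((B,C),A);", "s2", 2)
        out = synthesize([s1, s2])
        assert_isomorphic(out.tree, s1.tree)
        [skip] = out.skips
        assert skip.reason == "conflict-with-rank-1" and skip.winning_rank == 1

    def test_empty_study_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            synthesize([])

    def test_unplaced_material_attaches_at_root(self):
        out = synthesize([study("((A,B),C);", "s1", 1), study("((X,Y),Z);", "s2", 2)])
        assert out.tree.tip_set() == set("ABCXYZ")
        # the disjoint study's clade exists below the root
        assert displays(out.tree, g("XY", "Z"))

    def test_determinism(self):
        studies = lambda: [study("((A,B),C);", "s1", 1), study("((B,D),(C,E));", "s2", 2)]
        assert write_newick(synthesize(studies()).tree) == write_newick(
            synthesize(studies()).tree
        )

    def test_rank1_dominance_on_random_study_sets(self):
        # every rank-1 grouping is displayed regardless of later conflict
        for seed in range(100):
            cfg = sd.SimulationConfig(
                seed=seed, shape=sd.TaxonomyShape(3, 3, 2, 2), n_gains=2,
                n_reversals=0, n_studies=3, tips_per_study=14, overlap=0.4,
                n_perturbations=2, unknown_fraction=0.0,
            )
            truth = sd.generate_dataset(cfg)
            synth = synthesize(truth.studies)
            for grouping in extract_groupings(truth.studies[0]):
                assert displays(synth.tree, grouping)

    def test_compatibility_completeness_without_perturbation(self):
        # clean restrictions: zero skips and every grouping displayed
        for seed in range(20):
            cfg = sd.SimulationConfig(
                seed=seed, shape=sd.TaxonomyShape(4, 3, 2, 2), n_gains=2,
                n_reversals=0, n_studies=4, tips_per_study=20, overlap=0.5,
                n_perturbations=0, unknown_fraction=0.0,
            )
            truth = sd.generate_dataset(cfg)
            synth = synthesize(truth.studies, taxonomy=truth.taxonomy)
            assert not synth.skips
            for st in truth.studies:
                for grouping in extract_groupings(st):
                    assert displays(synth.tree, grouping)

    def test_monotonic_damage(self):
        # appending a lower-ranked conflicting study never changes whether
        # previously accepted groupings are displayed
        for seed in range(20):
            cfg = sd.SimulationConfig(
                seed=seed, shape=sd.TaxonomyShape(3, 3, 2, 2), n_gains=2,
                n_reversals=0, n_studies=3, tips_per_study=14, overlap=0.5,
                n_perturbations=0, unknown_fraction=0.0,
            )
            truth = sd.generate_dataset(cfg)
            base = synthesize(truth.studies)
            perturbed = truth.studies[1].tree.copy()
            rng = random.Random(seed)
            sd._sibling_regraft(perturbed, rng)
            extra = SourceStudy("bad", perturbed, rank=len(truth.studies) + 1)
            bigger = synthesize(truth.studies + [extra])
            for a in base.accepted:
                assert displays(bigger.tree, a)


class TestSkipLog:
    def test_conflict_row(self):
        out = synthesize([study("((A,B),C);", "s1", 1), study("((B,C),A);", "s2", 2)])
        df = summarize_skips(out)
        assert list(df.reason) == ["conflict-with-rank-1"]
        assert list(df.study_id) == ["s2"]

    def test_all_compatible_empty(self):
        out = synthesize([study("((A,B),C);", "s1", 1), study("((A,B),D);", "s2", 2)])
        assert summarize_skips(out).empty

    def test_mixed_reasons_partition(self):
        # pairwise-compatible groupings can still be jointly unsatisfiable:
        # this frozen trio produces both skip categories
        out = synthesize(
            [
                study("((c,a),(b,d));", "s1", 1),
                study("((c,(e,d)),b);", "s2", 2),
                study("((b,(a,e)),d);", "s3", 3),
            ]
        )
        reasons = set(summarize_skips(out).reason)
        assert reasons == {"conflict-with-rank-1", "unresolvable"}
        for a in out.accepted:
            assert displays(out.tree, a)


class TestTaxonomyAsSource:
    def test_taxonomy_groupings_resolve_sampled_taxa(self):
        cfg = sd.SimulationConfig(
            seed=5, shape=sd.TaxonomyShape(4, 3, 2, 2), n_gains=2,
            n_reversals=0, n_studies=3, tips_per_study=16, overlap=0.4,
            n_perturbations=0, unknown_fraction=0.0,
        )
        truth = sd.generate_dataset(cfg)
        tips = set()
        for s in truth.studies:
            tips |= s.tree.tip_set()
        tax_study = taxonomy_study(truth.taxonomy, tips, rank=99)
        assert tax_study.tree.tip_set() == tips
        # every taxonomy grouping is a true clade restriction
        for grouping in extract_groupings(tax_study):
            assert displays(truth.tree, grouping)
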