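"""Ranked grafting of source phylogenies into one synthesis tree.

Published phylogenies rarely share enough taxa (or characters) for
supertree or supermatrix analysis, so the pipeline instead *grafts*
them.  Each rooted source tree is decomposed into ingroup/exclude
groupings (one per internal non-root node: "these taxa group together to
the exclusion of those"), studies are ordered by rank, and groupings are
accepted greedily, highest rank first — a grouping that conflicts with
an already-accepted, higher-ranked grouping is skipped and logged.  The
synthesis tree is then constructed jointly from the accepted groupings
by a BUILD-style subproblem decomposition: at each level, ingroups of
the groupings still constrained at that level are merged into connected
components, which become the child subtrees.  This yields the *minimal*
(most polytomous) tree displaying every accepted grouping; resolution
never exceeds what some source asserted.  When a subproblem cannot be
split (pairwise-compatible groupings can still be jointly unsatisfiable)
the lowest-ranked grouping responsible is dropped, logged as
unresolvable, and construction restarts.

Taxa that end up in no accepted grouping fall out as children of the
root — which is how sparsely overlapping studies accumulate material
toward the base of a synthesis tree.  Optionally the reference taxonomy
joins as one extra, lowest-ranked source of groupings (taxon monophyly
as a null hypothesis that any ranked phylogeny overrides), mirroring
pipelines that graft phylogenies together with the underlying taxonomic
information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .treeio import Node, RootedTree, parse_newick

__all__ = [
    "SourceStudy",
    "Grouping",
    "SkipRecord",
    "SynthesisTree",
    "rank_studies",
    "extract_groupings",
    "conflicts",
    "synthesize",
    "taxonomy_study",
    "summarize_skips",
    "read_manifest",
]

#: Method-class preference used by the ranking comparator: Bayesian /
#: maximum-likelihood beat parsimony, which beats distance methods.
METHOD_PRIORITY = {"BI_ML": 0, "MP": 1, "NJ_ME": 2}


@dataclass
class SourceStudy:
    """One published phylogeny with its study rank and metadata."""

    study_id: str
    tree: RootedTree
    rank: Optional[int] = None
    focal_clade: str = ""
    n_markers: int = 0
    method_class: str = "BI_ML"
    n_ingroup_taxa: int = 0

    def __post_init__(self):
        if self.method_class not in METHOD_PRIORITY:
            raise ValueError(
                f"method_class must be one of {sorted(METHOD_PRIORITY)}, "
                f"got {self.method_class!r}"
            )
        if self.n_ingroup_taxa == 0 and self.tree is not None:
            self.n_ingroup_taxa = self.tree.n_tips()


@dataclass(frozen=True)
class Grouping:
    """Ingroup/exclude constraint from one internal source-tree node."""

    ingroup: frozenset
    exclude: frozenset
    rank: Optional[int] = None
    study_id: str = ""
    node_label: Optional[str] = None

    def __post_init__(self):
        if self.ingroup & self.exclude:
            raise ValueError("ingroup and exclude overlap")
        if len(self.ingroup) < 2:
            raise ValueError("grouping ingroup must have >= 2 taxa")
        if not self.exclude:
            raise ValueError("root groupings (empty exclude) are not emitted")


@dataclass(frozen=True)
class SkipRecord:
    study_id: str
    rank: Optional[int]
    reason: str  # "conflict-with-rank-<k>" or "unresolvable"
    winning_rank: Optional[int]
    grouping: Grouping


@dataclass
class SynthesisTree:
    tree: RootedTree
    accepted: list = field(default_factory=list)  # list[Grouping]
    skips: list = field(default_factory=list)  # list[SkipRecord]


def rank_studies(
    studies: Sequence[SourceStudy],
    explicit_ranks: Optional[dict] = None,
) -> list[SourceStudy]:
    """Order studies, rank 1 first.

    Explicit ranks are authoritative when given (published rankings are
    not always reproducible from their printed metadata).  Otherwise a
    lexicographic comparator applies: denser focal-clade sampling (more
    ingroup taxa) first, then more markers, then better method class
    (BI/ML > MP > NJ/ME), remaining ties broken by study id.
    """
    studies = list(studies)
    if explicit_ranks is not None:
        if len(set(explicit_ranks.values())) != len(explicit_ranks):
            raise ValueError("duplicate explicit rank")
        missing = {s.study_id for s in studies} - set(explicit_ranks)
        if missing:
            raise ValueError(f"explicit_ranks missing studies: {sorted(missing)}")
        ordered = sorted(studies, key=lambda s: explicit_ranks[s.study_id])
    else:
        ordered = sorted(
            studies,
            key=lambda s: (
                -s.n_ingroup_taxa,
                -s.n_markers,
                METHOD_PRIORITY[s.method_class],
                s.study_id,
            ),
        )
    for i, s in enumerate(ordered, start=1):
        s.rank = i
    return ordered


def extract_groupings(study: SourceStudy) -> list[Grouping]:
    """One grouping per internal non-root node, in preorder."""
    tree = study.tree
    all_tips = frozenset(tree.tip_set())
    out = []
    for node in tree.preorder():
        if node is tree.root or node.is_leaf:
            continue
        ingroup = frozenset(tree.tipset_of(node))
        out.append(
            Grouping(
                ingroup=ingroup,
                exclude=all_tips - ingroup,
                rank=study.rank,
                study_id=study.study_id,
                node_label=node.label,
            )
        )
    return out


def conflicts(g: Grouping, h: Grouping) -> bool:
    """Whether two rooted groupings are pairwise incompatible.

    True iff ingroup(g)∩ingroup(h), ingroup(g)∩exclude(h) and
    exclude(g)∩ingroup(h) are all nonempty — the condition under which
    no rooted tree displays both constraints.  Nesting and disjoint
    taxon sets are compatible.  (Pairwise compatibility of a whole set
    does not imply joint satisfiability; that is settled during tree
    construction.)
    """
    return bool(
        g.ingroup & h.ingroup and g.ingroup & h.exclude and g.exclude & h.ingroup
    )


def taxonomy_study(taxonomy, tip_keys: Iterable, rank: int) -> SourceStudy:
    """The reference taxonomy as a nested-polytomy source tree.

    Restricted to the given (sampled) tip keys; each taxon with two or
    more sampled species contributes one grouping.
    """
    from .treeio import resolve_species_keys

    mapping = resolve_species_keys(set(tip_keys), taxonomy)
    inverse = {sp: key for key, sp in mapping.items()}

    def build(tid) -> Optional[Node]:
        rec = taxonomy[tid]
        if rec.rank == "species":
            key = inverse.get(tid)
            if key is None:
                return None
            if isinstance(key, int):
                return Node(label=rec.name, taxon_id=key)
            return Node(label=key)
        node = Node(label=rec.name)
        for child in taxonomy.children[tid]:
            sub = build(child)
            if sub is not None:
                node.add_child(sub)
        return node if node.children else None

    root = build(taxonomy.root_id)
    if root is None:
        raise ValueError("no sampled tips resolve against the taxonomy")
    tree = RootedTree(root).normalize()
    return SourceStudy(study_id="taxonomy", tree=tree, rank=rank)


def synthesize(studies: Sequence[SourceStudy], taxonomy=None) -> SynthesisTree:
    """Graft ranked source trees into a single synthesis tree.

    ``studies`` must already be ordered rank 1 first (see
    :func:`rank_studies`).  Greedy acceptance: groupings are visited in
    rank order (preorder within a study) and skipped when they conflict
    with any higher-priority accepted grouping.  The tree is then built
    jointly from the accepted set (see module docstring); groupings that
    turn out jointly unsatisfiable are dropped lowest-rank-first and
    logged as unresolvable.  Every grouping of the rank-1 study is
    always displayed by the output.
    """
    studies = list(studies)
    if not studies:
        raise ValueError("empty study list")
    for s in studies:
        if s.rank is None:
            raise ValueError(f"study {s.study_id!r} has no rank; call rank_studies first")
    if taxonomy is not None:
        placed_keys = set()
        for s in studies:
            placed_keys |= s.tree.tip_set()
        max_rank = max(s.rank or 0 for s in studies)
        studies.append(taxonomy_study(taxonomy, placed_keys, rank=max_rank + 1))

    # leaf prototypes (label, taxon id) for every taxon across studies
    tip_nodes: dict = {}
    for s in studies:
        for key, leaf in s.tree.tip_map().items():
            tip_nodes.setdefault(key, (leaf.label, leaf.taxon_id))

    accepted: list[Grouping] = []
    skips: list[SkipRecord] = []
    for study in studies:
        for g in extract_groupings(study):
            conflicting = [a for a in accepted if conflicts(g, a)]
            if conflicting:
                win = min(a.rank for a in conflicting)
                skips.append(
                    SkipRecord(g.study_id, g.rank, f"conflict-with-rank-{win}", win, g)
                )
            else:
                accepted.append(g)

    tree, dropped = _build_tree(tip_nodes, accepted)
    for g in dropped:
        accepted.remove(g)
        skips.append(SkipRecord(g.study_id, g.rank, "unresolvable", None, g))
    return SynthesisTree(tree=tree, accepted=accepted, skips=skips)


class _Unsatisfiable(Exception):
    def __init__(self, grouping):
        self.grouping = grouping


def _build_tree(tip_nodes: dict, groupings: Sequence[Grouping]):
    """Minimal rooted tree displaying the groupings; drops on conflict.

    Returns ``(tree, dropped)`` where ``dropped`` lists groupings that
    had to be discarded (lowest rank and latest input position first)
    because a subproblem could not be partitioned.  Construction
    restarts after each drop so earlier levels stay consistent.
    """
    order = {id(g): i for i, g in enumerate(groupings)}
    remaining = list(groupings)
    dropped = []
    while True:
        try:
            root = _build_level(frozenset(tip_nodes), remaining, tip_nodes, order)
            return RootedTree(root).normalize(), dropped
        except _Unsatisfiable as stuck:
            remaining.remove(stuck.grouping)
            dropped.append(stuck.grouping)


def _build_level(taxa: frozenset, groupings, tip_nodes, order) -> Node:
    if len(taxa) == 1:
        (key,) = taxa
        label, tid = tip_nodes[key]
        return Node(label=label, taxon_id=tid)

    # groupings still biting at this level: ingroup straddles >=2 taxa
    # here and something here is excluded; a grouping whose exclude has
    # left the subproblem is vacuously satisfied below this node
    active = [
        g
        for g in groupings
        if len(g.ingroup & taxa) >= 2 and g.exclude & taxa
    ]
    comps = _components(taxa, active)
    if len(comps) == 1:
        raise _Unsatisfiable(_drop_candidate(taxa, active, order))

    node = Node()
    for comp in sorted(comps, key=lambda c: min(map(str, c))):
        sub = [g for g in active if len(g.ingroup & comp) >= 2]
        node.add_child(_build_level(frozenset(comp), sub, tip_nodes, order))
    return node


def _components(taxa: frozenset, active) -> list:
    parent = {t: t for t in taxa}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for g in active:
        members = iter(sorted(g.ingroup & taxa, key=str))
        first = find(next(members))
        for m in members:
            parent[find(m)] = first
    comps: dict = {}
    for t in taxa:
        comps.setdefault(find(t), set()).add(t)
    return list(comps.values())


def _drop_candidate(taxa, active, order):
    """Pick the grouping to discard at an unsplittable level.

    Lowest priority first (largest rank, then latest input position);
    prefer a single drop that already unsticks the level, else fall back
    to the lowest-priority grouping and let the caller iterate.  Rank-1
    groupings are never dropped: they come from a single tree and are
    jointly satisfiable on their own, so removing lower-ranked groupings
    always unsticks a level eventually.
    """
    min_rank = min((g.rank or 0) for g in active)
    ordered = sorted(
        (g for g in active if (g.rank or 0) > min_rank),
        key=lambda g: (-(g.rank or 0), -order[id(g)]),
    )
    if not ordered:
        raise ValueError(
            "groupings of the highest-ranked study are jointly unsatisfiable"
        )
    for g in ordered:
        rest = [h for h in active if h is not g]
        if len(_components(taxa, rest)) > 1:
            return g
    return ordered[0]


def summarize_skips(synth: SynthesisTree) -> pd.DataFrame:
    """One row per skipped grouping: study, rank, reason, winning rank."""
    rows = [
        {
            "study_id": s.study_id,
            "rank": s.rank,
            "reason": s.reason,
            "winning_rank": s.winning_rank,
            "n_ingroup": len(s.grouping.ingroup),
        }
        for s in synth.skips
    ]
    return pd.DataFrame(rows, columns=["study_id", "rank", "reason", "winning_rank", "n_ingroup"])


def skips_to_json(synth: SynthesisTree) -> str:
    return json.dumps(summarize_skips(synth).to_dict(orient="records"), indent=2)


def read_manifest(manifest_path, tree_dir=None) -> list[SourceStudy]:
    """Load studies from a manifest CSV.

    Columns: ``file, study_id, rank, focal_clade, n_markers, method_class,
    n_ingroup_taxa``.  Tree files are newick, resolved relative to
    ``tree_dir`` (defaults to the manifest's directory).
    """
    from pathlib import Path

    manifest_path = Path(manifest_path)
    base = Path(tree_dir) if tree_dir is not None else manifest_path.parent
    df = pd.read_csv(manifest_path)
    studies = []
    for row in df.itertuples(index=False):
        tree = parse_newick((base / row.file).read_text())
        studies.append(
            SourceStudy(
                study_id=str(row.study_id),
                tree=tree,
                rank=int(row.rank),
                focal_clade=str(row.focal_clade),
                n_markers=0 if pd.isna(row.n_markers) else int(row.n_markers),
                method_class=str(row.method_class),
                n_ingroup_taxa=int(row.n_ingroup_taxa),
            )
        )
    studies.sort(key=lambda s: s.rank)
    return studies
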