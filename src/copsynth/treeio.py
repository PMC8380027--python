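"""Rooted trees, reference taxonomies, and lifestyle codings.

This module holds the data model shared by the whole pipeline:

* :class:`RootedTree` — a rooted, possibly multifurcating tree whose tips
  carry either an opaque taxon id (parsed from a trailing ``_ott<digits>``
  label suffix, following Open Tree of Life conventions) or a raw label.
  Polytomies are treated as *soft* (lack of resolution, never a positive
  claim of simultaneous divergence).
* :class:`Taxonomy` — a rank-structured forest of taxon records
  (species < genus < family < suborder < order < superorder < class) with
  species at the leaves, read from OTT-dialect or plain TSV tables.
* :class:`StateCoding` — a species-level mapping to
  {free-living, parasitic, unknown} plus a sampled flag recording whether
  the species appeared in at least one source phylogeny.

Newick handling is intentionally minimal: branch lengths are accepted and
discarded (synthesis trees are topology-only), internal labels are kept,
and single-quote quoting is supported.  NEXUS and branch-length-aware
formats are out of scope.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

import dendropy

__all__ = [
    "FREE_LIVING",
    "PARASITIC",
    "UNKNOWN",
    "Node",
    "RootedTree",
    "TaxonRecord",
    "Taxonomy",
    "StateCoding",
    "TreeError",
    "NewickParseError",
    "DuplicateTipError",
    "TaxonomyError",
    "parse_newick",
    "write_newick",
    "read_taxonomy",
    "write_taxonomy",
    "read_coding",
    "write_coding",
    "mrca",
    "displays",
    "resolve_species_keys",
]

# Character states for the binary lifestyle character.
FREE_LIVING = 0
PARASITIC = 1
UNKNOWN = None

STATE_NAMES = {FREE_LIVING: "free-living", PARASITIC: "parasitic", UNKNOWN: "unknown"}
STATE_VALUES = {v: k for k, v in STATE_NAMES.items()}

# Conventional rank order, smallest first.  "no rank" containers are
# transparent and excluded from the ordering.
RANK_ORDER = ("species", "genus", "family", "suborder", "order", "superorder", "class")
RANK_INDEX = {r: i for i, r in enumerate(RANK_ORDER)}
NO_RANK = "no rank"

TipKey = Union[int, str]

_OTT_SUFFIX = re.compile(r"^(?P<name>.*)_ott(?P<id>\d+)$")


class TreeError(ValueError):
    pass


class NewickParseError(TreeError):
    pass


class DuplicateTipError(TreeError):
    def __init__(self, duplicates):
        self.duplicates = sorted(duplicates, key=str)
        super().__init__(f"duplicate tip labels/ids: {self.duplicates}")


class TaxonomyError(ValueError):
    pass


class Node:
    """One node of a rooted tree; children are kept in insertion order."""

    __slots__ = ("label", "taxon_id", "children", "parent")

    def __init__(self, label: Optional[str] = None, taxon_id: Optional[int] = None):
        self.label = label
        self.taxon_id = taxon_id
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def tip_key(self) -> TipKey:
        """Identity of a tip: taxon id when known, else the raw label."""
        if self.taxon_id is not None:
            return self.taxon_id
        return self.label

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, id={self.taxon_id!r}, n_children={len(self.children)})"


def _leaf_from_label(raw: str) -> Node:
    m = _OTT_SUFFIX.match(raw)
    if m:
        return Node(label=raw, taxon_id=int(m.group("id")))
    return Node(label=raw)


class RootedTree:
    """A rooted tree over tips identified by taxon id or label.

    Invariants (enforced by :meth:`normalize` / :meth:`validate`): exactly
    one root, no unary internal nodes, every tip carries an id or label,
    and tip keys are unique within the tree.  All traversals follow stored
    child order, so identical inputs always produce identical outputs.
    """

    def __init__(self, root: Node):
        self.root = root

    # ---- construction & normalization -------------------------------

    def normalize(self) -> "RootedTree":
        """Collapse unary nodes in place (including a unary root).

        Walks top-down, replacing every child by its first non-unary
        descendant and re-setting parent pointers, so no stale links
        survive the collapse.
        """

        def skip_unary(node: Node) -> Node:
            while len(node.children) == 1:
                child = node.children[0]
                # keep an informative label if the collapsed node had one
                if child.label is None:
                    child.label = node.label
                node = child
            return node

        self.root = skip_unary(self.root)
        self.root.parent = None
        stack = [self.root]
        while stack:
            node = stack.pop()
            fresh = []
            for child in node.children:
                kept = skip_unary(child)
                kept.parent = node
                fresh.append(kept)
            node.children = fresh
            stack.extend(fresh)
        return self

    def validate(self) -> "RootedTree":
        seen: dict = {}
        dups = set()
        for leaf in self.leaves():
            if leaf.taxon_id is None and leaf.label is None:
                raise TreeError("tip with neither taxon id nor label")
            key = leaf.tip_key
            if key in seen:
                dups.add(key)
            seen[key] = leaf
        if dups:
            raise DuplicateTipError(dups)
        return self

    def copy(self) -> "RootedTree":
        def clone(node: Node) -> Node:
            c = Node(node.label, node.taxon_id)
            for child in node.children:
                c.add_child(clone(child))
            return c

        return RootedTree(clone(self.root))

    # ---- traversal ---------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> Iterator[Node]:
        for node in self.preorder():
            if node.is_leaf:
                yield node

    def internal_nodes(self) -> Iterator[Node]:
        for node in self.preorder():
            if not node.is_leaf:
                yield node

    # ---- queries -----------------------------------------------------

    def tip_set(self) -> set:
        return {leaf.tip_key for leaf in self.leaves()}

    def tip_map(self) -> dict:
        return {leaf.tip_key: leaf for leaf in self.leaves()}

    def tipset_of(self, node: Node) -> set:
        out = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.add(n.tip_key)
            else:
                stack.extend(n.children)
        return out

    def n_tips(self) -> int:
        return sum(1 for _ in self.leaves())

    def mrca(self, tips: Iterable[TipKey]) -> Node:
        return mrca(self, tips)

    def restrict(self, keep: Iterable[TipKey]) -> "RootedTree":
        """Restriction of the tree to a tip subset, unary nodes collapsed."""
        keep = set(keep)
        missing = keep - self.tip_set()
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing, key=str)}")

        def prune(node: Node) -> Optional[Node]:
            if node.is_leaf:
                if node.tip_key in keep:
                    return Node(node.label, node.taxon_id)
                return None
            copied = Node(node.label, node.taxon_id)
            for child in node.children:
                sub = prune(child)
                if sub is not None:
                    copied.add_child(sub)
            if not copied.children:
                return None
            return copied

        new_root = prune(self.root)
        if new_root is None:
            raise TreeError("restriction to empty tip set")
        return RootedTree(new_root).normalize()

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"RootedTree(n_tips={self.n_tips()})"


# ---- newick ----------------------------------------------------------


def parse_newick(text: str) -> RootedTree:
    """Parse a rooted newick string into a :class:`RootedTree`.

    Branch lengths are parsed and discarded; internal node labels are
    kept; quoted labels are supported; unary nodes are collapsed.  Raises
    :class:`NewickParseError` on malformed input (the underlying message
    names the offending position) and :class:`DuplicateTipError` when two
    tips resolve to the same identity.
    """
    if not text or not text.strip():
        raise NewickParseError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            case_sensitive_taxon_labels=True,
        )
    except Exception as exc:  # dendropy's message carries line/column info
        if "Duplicate" in type(exc).__name__:
            raise DuplicateTipError(_duplicate_tip_labels(text)) from exc
        raise NewickParseError(f"malformed newick: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            raw = dnode.taxon.label if dnode.taxon is not None else dnode.label
            if raw is None:
                raise NewickParseError("leaf without a label")
            return _leaf_from_label(raw)
        node = Node(label=dnode.label)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    tree = RootedTree(convert(dtree.seed_node)).normalize()
    tree.validate()
    return tree


_TIP_LABEL = re.compile(r"(?:^|[(,])\s*('(?:[^']|'')*'|[^(),:;]+)")


def _duplicate_tip_labels(text: str) -> list:
    """Tip labels occurring more than once (lexical scan, for errors)."""
    seen, dups = set(), set()
    for raw in _TIP_LABEL.findall(text):
        label = raw.strip().split(":")[0].strip("'")
        if label:
            if label in seen:
                dups.add(label)
            seen.add(label)
    return sorted(dups)


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.+-]+$")


def _format_label(label: Optional[str]) -> str:
    if label is None:
        return ""
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: RootedTree) -> str:
    """Serialize a tree to newick, children in stored order, no lengths.

    Tips carrying a taxon id are written with the ``_ott<id>`` suffix
    (unless the label already has it), so identity survives a round trip
    through the reader.
    """

    def tip_label(node: Node) -> str:
        label = node.label or ""
        if node.taxon_id is not None and not _OTT_SUFFIX.match(label):
            label = f"{label}_ott{node.taxon_id}"
        return label

    def fmt(node: Node) -> str:
        if node.is_leaf:
            return _format_label(tip_label(node))
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}){_format_label(node.label)}"

    return fmt(tree.root) + ";"


# ---- mrca / displays -------------------------------------------------


def mrca(tree: RootedTree, tips: Iterable[TipKey]) -> Node:
    """Shallowest node whose tip set contains ``tips``.

    Found by walking down from the root: descend while exactly one child
    subtree contains all query tips.
    """
    tips = set(tips)
    if not tips:
        raise TreeError("mrca of empty tip set")
    tip_map = tree.tip_map()
    for t in tips:
        if t not in tip_map:
            raise TreeError(f"unknown tip: {t!r}")
    if len(tips) == 1:
        return tip_map[next(iter(tips))]
    node = tree.root
    while True:
        carrier = None
        for child in node.children:
            sub = tree.tipset_of(child)
            if tips <= sub:
                carrier = child
                break
            if tips & sub:
                # tips split across children: this node is the mrca
                carrier = None
                break
        if carrier is None:
            return node
        node = carrier


def displays(tree: RootedTree, grouping) -> bool:
    """Whether ``tree`` displays an ingroup/exclude grouping.

    With I' and E' the grouping's ingroup and exclude restricted to the
    tree's tips: vacuously true when I' is empty, otherwise true iff the
    tip set of mrca(I') contains no member of E'.
    """
    tips = tree.tip_set()
    placed_in = set(grouping.ingroup) & tips
    if not placed_in:
        return True
    placed_ex = set(grouping.exclude) & tips
    node = mrca(tree, placed_in)
    return not (tree.tipset_of(node) & placed_ex)


# ---- taxonomy --------------------------------------------------------


@dataclass(frozen=True)
class TaxonRecord:
    id: int
    parent_id: Optional[int]
    name: str
    rank: str

    def __post_init__(self):
        if self.rank != NO_RANK and self.rank not in RANK_INDEX:
            raise TaxonomyError(f"unknown rank {self.rank!r} for taxon {self.id}")


class Taxonomy:
    """Rank-structured forest of taxon records with species at the leaves."""

    def __init__(self, records: Iterable[TaxonRecord]):
        self.records: dict[int, TaxonRecord] = {}
        for rec in records:
            if rec.id in self.records:
                raise TaxonomyError(f"duplicate taxon id {rec.id}")
            self.records[rec.id] = rec
        self.children: dict[int, list[int]] = {i: [] for i in self.records}
        roots = []
        for rec in self.records.values():
            if rec.parent_id is None:
                roots.append(rec.id)
            else:
                if rec.parent_id not in self.records:
                    raise TaxonomyError(
                        f"orphan record {rec.id} ({rec.name}): parent {rec.parent_id} absent"
                    )
                self.children[rec.parent_id].append(rec.id)
        if len(roots) != 1:
            raise TaxonomyError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root_id = roots[0]
        self._check_cycles()
        self._check_rank_order()
        self._species_cache: dict[int, frozenset] = {}

    def _check_cycles(self):
        state: dict[int, int] = {}
        for start in self.records:
            tid, chain = start, []
            while tid is not None:
                if state.get(tid) == 2:
                    break
                if tid in chain:
                    raise TaxonomyError(f"cycle in parent chain at taxon {tid}")
                chain.append(tid)
                tid = self.records[tid].parent_id
            for t in chain:
                state[t] = 2

    def _effective_rank(self, tid: int) -> Optional[int]:
        """Rank index, looking through "no rank" containers toward the root."""
        while tid is not None:
            rank = self.records[tid].rank
            if rank != NO_RANK:
                return RANK_INDEX[rank]
            tid = self.records[tid].parent_id
        return None

    def _check_rank_order(self):
        for rec in self.records.values():
            if rec.parent_id is None or rec.rank == NO_RANK:
                continue
            parent_rank = self._effective_rank(rec.parent_id)
            if parent_rank is not None and RANK_INDEX[rec.rank] >= parent_rank:
                raise TaxonomyError(
                    f"rank order violation: {rec.rank!r} taxon {rec.id} under "
                    f"{RANK_ORDER[parent_rank]!r} parent {rec.parent_id}"
                )

    # ---- accessors ---------------------------------------------------

    def __contains__(self, tid: int) -> bool:
        return tid in self.records

    def __getitem__(self, tid: int) -> TaxonRecord:
        return self.records[tid]

    def parent(self, tid: int) -> Optional[int]:
        return self.records[tid].parent_id

    def ancestors(self, tid: int) -> Iterator[int]:
        t = self.records[tid].parent_id
        while t is not None:
            yield t
            t = self.records[t].parent_id

    def species_of(self, tid: int) -> frozenset:
        """All species-rank descendants of ``tid`` (itself included if species)."""
        cached = self._species_cache.get(tid)
        if cached is not None:
            return cached
        if self.records[tid].rank == "species":
            out = frozenset([tid])
        else:
            acc = set()
            for child in self.children[tid]:
                acc |= self.species_of(child)
            out = frozenset(acc)
        self._species_cache[tid] = out
        return out

    def all_species(self) -> frozenset:
        return self.species_of(self.root_id)

    def taxa_of_rank(self, rank: str) -> list[int]:
        return [t for t, r in self.records.items() if r.rank == rank]

    def id_by_name(self, name: str) -> Optional[int]:
        hits = [t for t, r in self.records.items() if r.name == name]
        if len(hits) == 1:
            return hits[0]
        return None

    def preorder(self) -> Iterator[int]:
        stack = [self.root_id]
        while stack:
            tid = stack.pop()
            yield tid
            stack.extend(reversed(self.children[tid]))


def resolve_species_keys(keys: Iterable[TipKey], taxonomy: Taxonomy) -> dict:
    """Map tree tip keys to taxonomy species ids.

    Integer keys are taken as taxon ids directly; string keys are matched
    against species names (exact, case-sensitive — fuzzy matching and
    synonym resolution are out of scope).  Keys that resolve to nothing
    (or to a non-species record) are absent from the returned mapping.
    """
    by_name: dict[str, Optional[int]] = {}
    for sp in taxonomy.all_species():
        name = taxonomy[sp].name
        by_name[name] = None if name in by_name else sp  # ambiguous names drop out
    out = {}
    for key in keys:
        if isinstance(key, int):
            if key in taxonomy and taxonomy[key].rank == "species":
                out[key] = key
        else:
            hit = by_name.get(key)
            if hit is not None:
                out[key] = hit
    return out


def read_taxonomy(text: str, dialect: str = "ott") -> Taxonomy:
    """Read a taxonomy table.

    ``ott`` dialect: header row, columns ``uid | parent_uid | name | rank``
    separated by tab-pipe-tab.  ``simple`` dialect: 4-column TSV, no header.
    """
    records = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if dialect == "ott":
        if not lines:
            raise TaxonomyError("empty taxonomy table")
        body = lines[1:]
        for ln in body:
            parts = [p.strip() for p in ln.rstrip("\t|").split("\t|\t")]
            if len(parts) < 4:
                raise TaxonomyError(f"bad ott taxonomy row: {ln!r}")
            records.append(_record_from_fields(parts[:4]))
    elif dialect == "simple":
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) != 4:
                raise TaxonomyError(f"bad taxonomy row (expected 4 columns): {ln!r}")
            records.append(_record_from_fields(parts))
    else:
        raise ValueError(f"unknown taxonomy dialect {dialect!r}")
    return Taxonomy(records)


def _record_from_fields(fields) -> TaxonRecord:
    uid, parent, name, rank = fields
    parent_id = None if parent in ("", "-", "none", "None") else int(parent)
    return TaxonRecord(id=int(uid), parent_id=parent_id, name=name, rank=rank)


def write_taxonomy(taxonomy: Taxonomy, dialect: str = "ott") -> str:
    rows = []
    for tid in taxonomy.preorder():
        rec = taxonomy[tid]
        parent = "" if rec.parent_id is None else str(rec.parent_id)
        rows.append((str(rec.id), parent, rec.name, rec.rank))
    if dialect == "ott":
        out = ["uid\t|\tparent_uid\t|\tname\t|\trank\t|"]
        out += ["\t|\t".join(r) + "\t|" for r in rows]
        return "\n".join(out) + "\n"
    if dialect == "simple":
        return "\n".join("\t".join(r) for r in rows) + "\n"
    raise ValueError(f"unknown taxonomy dialect {dialect!r}")


# ---- lifestyle coding ------------------------------------------------


@dataclass
class StateCoding:
    """Species-level lifestyle states plus sampled flags.

    ``states`` maps a species key (taxon id or label) to 0 (free-living),
    1 (parasitic), or None (unknown); ``sampled`` records whether the
    species occurred in at least one source phylogeny.  ``names`` keeps
    display names for serialization.
    """

    states: dict = field(default_factory=dict)
    sampled: dict = field(default_factory=dict)
    names: dict = field(default_factory=dict)

    def set(self, key: TipKey, state, sampled: bool = False, name: str = ""):
        if state not in (FREE_LIVING, PARASITIC, UNKNOWN):
            raise ValueError(f"invalid state {state!r} for {key!r}")
        self.states[key] = state
        self.sampled[key] = bool(sampled)
        self.names[key] = name or str(key)

    def state_of(self, key: TipKey):
        if key not in self.states:
            raise KeyError(f"no lifestyle coding for tip {key!r}")
        return self.states[key]

    def is_sampled(self, key: TipKey) -> bool:
        return bool(self.sampled.get(key, False))

    def parasitic_keys(self) -> set:
        return {k for k, s in self.states.items() if s == PARASITIC}


def _parse_key(raw: str) -> TipKey:
    raw = raw.strip()
    return int(raw) if raw.isdigit() else raw


def read_coding(text: str) -> StateCoding:
    """Read a coding CSV with header ``species_id,name,state,sampled``."""
    coding = StateCoding()
    reader = csv.DictReader(io.StringIO(text))
    required = {"species_id", "name", "state", "sampled"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ValueError(f"coding table must have columns {sorted(required)}")
    for row in reader:
        state_name = row["state"].strip()
        if state_name not in STATE_VALUES:
            raise ValueError(f"invalid state {state_name!r} for {row['species_id']}")
        coding.set(
            _parse_key(row["species_id"]),
            STATE_VALUES[state_name],
            sampled=row["sampled"].strip().lower() in ("1", "true", "yes"),
            name=row["name"],
        )
    return coding


def write_coding(coding: StateCoding) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["species_id", "name", "state", "sampled"])
    for key in sorted(coding.states, key=str):
        writer.writerow(
            [
                key,
                coding.names.get(key, str(key)),
                STATE_NAMES[coding.states[key]],
                "true" if coding.sampled.get(key) else "false",
            ]
        )
    return buf.getvalue()
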