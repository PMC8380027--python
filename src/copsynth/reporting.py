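"""Summary artifacts: sampling coverage, support tiers, clade diversity.

Three products are computed from a grafted tree, a lifestyle coding and a
reference taxonomy:

* a *coverage report* — per-order counts of species (or families) with
  molecular phylogenetic representation, with percentages rounded
  half-up the way such tables are conventionally printed;
* a *support classification* for each parasitic clade — ``direct`` when
  a sampled tip is itself coded parasitic, ``indirect`` when the clade
  was sampled but only through free-living (or unknown) members while
  its parasitic species entered by taxonomy grafting, and ``taxonomic``
  when no member of the clade was ever sampled;
* a *diversity report* — the independent parasitic clades with their
  parasitic species richness, combining gain clades found by ancestral
  state reconstruction with declared indirect/taxonomic clades.

Indirect and taxonomic clades cannot be recovered by parsimony alone:
their parasitic members are polytomy tips grafted under an ancestor
whose sampled descendants are free-living, so the reconstruction places
the gain on a terminal edge at best.  They are therefore declared
explicitly (a clade-definition table naming the containing taxon and the
expected tier) and verified against the tree and coding, mirroring how
such clades are enumerated by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .asr import TransitionClade
from .taxonomy_graft import GraftedTree
from .treeio import PARASITIC, StateCoding, Taxonomy

__all__ = [
    "CoverageRow",
    "CladeDefinition",
    "CladeRecord",
    "TransitionReport",
    "percent",
    "coverage_report",
    "classify_support",
    "diversity_report",
]

SUPPORT_CLASSES = ("direct", "indirect", "taxonomic")


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up.

    Tables conventionally print one decimal (6.2%), prose none (39%);
    banker's rounding would disagree with either on exact halves.
    """
    if denominator == 0:
        raise ZeroDivisionError("percent() with zero denominator")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CoverageRow:
    order: str
    total: int
    sampled: int
    percent: float

    def __post_init__(self):
        if not 0 <= self.sampled <= self.total:
            raise ValueError(f"sampled outside [0, total] for {self.order}")


def coverage_report(
    taxonomy: Taxonomy,
    sampled_tips: Iterable,
    level: str = "species",
) -> pd.DataFrame:
    """Per-order sampling coverage plus a total row.

    ``level='species'`` counts sampled species over described species;
    ``level='family'`` counts families with at least one sampled species
    over described families.  Sampled tips without a taxonomy record are
    excluded from the order rows; their count is carried in
    ``df.attrs['extra_taxonomic']``.
    """
    if level not in ("species", "family"):
        raise ValueError("level must be 'species' or 'family'")
    from .treeio import resolve_species_keys

    raw = set(sampled_tips)
    mapping = resolve_species_keys(raw, taxonomy)
    sampled = set(mapping.values())
    all_species = taxonomy.all_species()
    extra = len(raw - set(mapping))
    orders = sorted(taxonomy.taxa_of_rank("order"), key=lambda t: taxonomy[t].name)
    rows = []
    grand_total = grand_sampled = 0
    for oid in orders:
        species = taxonomy.species_of(oid)
        if level == "species":
            total, got = len(species), len(species & sampled)
        else:
            fams = [f for f in _descendants(taxonomy, oid) if taxonomy[f].rank == "family"]
            total = len(fams)
            got = sum(1 for f in fams if taxonomy.species_of(f) & sampled)
        grand_total += total
        grand_sampled += got
        rows.append(CoverageRow(taxonomy[oid].name, total, got, percent(got, total, 1) if total else 0.0))
    if level == "species":
        # total row spans all species, including those of uncertain
        # ordinal status that hang directly below the root
        grand_total = len(all_species)
        grand_sampled = len(all_species & sampled)
    rows.append(
        CoverageRow(
            "Total", grand_total, grand_sampled,
            percent(grand_sampled, grand_total, 1) if grand_total else 0.0,
        )
    )
    df = pd.DataFrame([r.__dict__ for r in rows], columns=["order", "total", "sampled", "percent"])
    df.attrs["extra_taxonomic"] = extra
    return df


def _descendants(taxonomy: Taxonomy, tid: int):
    stack = list(taxonomy.children[tid])
    while stack:
        t = stack.pop()
        yield t
        stack.extend(taxonomy.children[t])


def classify_support(clade_tips: Iterable, coding: StateCoding) -> str:
    """Evidence tier for one parasitic clade (see module docstring)."""
    tips = set(clade_tips)
    parasitic = {t for t in tips if coding.states.get(t) == PARASITIC}
    if not parasitic:
        raise ValueError("clade has no parasitic member; not a parasitic clade")
    sampled = {t for t in tips if coding.is_sampled(t)}
    if any(coding.states.get(t) == PARASITIC for t in sampled):
        return "direct"
    if sampled:
        return "indirect"
    return "taxonomic"


@dataclass(frozen=True)
class CladeDefinition:
    """A declared parasitic clade: display name, order, expected tier,
    and the species keys of its members."""

    name: str
    order: str
    support: str
    members: frozenset

    def __post_init__(self):
        if self.support not in SUPPORT_CLASSES:
            raise ValueError(f"support must be one of {SUPPORT_CLASSES}")


@dataclass
class CladeRecord:
    name: str
    support: str
    tips: frozenset
    n_parasitic: int
    losses_within: int = 0


@dataclass
class TransitionReport:
    records: list = field(default_factory=list)
    totals: dict = field(default_factory=dict)
    grand_total: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "clade": r.name,
                    "support": r.support,
                    "n_parasitic": r.n_parasitic,
                    "n_tips": len(r.tips),
                    "losses_within": r.losses_within,
                }
                for r in self.records
            ],
            columns=["clade", "support", "n_parasitic", "n_tips", "losses_within"],
        )


def diversity_report(
    grafted: GraftedTree,
    coding: StateCoding,
    gain_clades: Sequence[TransitionClade],
    declared: Sequence[CladeDefinition] = (),
) -> TransitionReport:
    """Independent parasitic clades and their parasitic species richness.

    ``gain_clades`` come from ancestral state reconstruction on the
    synthesis tree of sampled taxa; each is re-expanded on the grafted
    tree (MRCA of its sampled tips) so grafted congeners are counted.
    ``declared`` carries the indirect and taxonomic clades; each
    declaration is verified against the tree and coding, and a
    declaration that classifies differently than expected is an error.
    Overlapping clade records are an error: origins must be independent.
    """
    tree = grafted.tree
    grafted_tips = tree.tip_set()
    report = TransitionReport()

    direct_defs = [d for d in declared if d.support == "direct"]
    for i, clade in enumerate(gain_clades, start=1):
        anchor = set(clade.tips) & grafted_tips
        if not anchor:
            raise ValueError("gain clade has no tips on the grafted tree")
        expanded = frozenset(tree.tipset_of(tree.mrca(anchor)))
        support = classify_support(expanded, coding)
        if support != "direct":
            raise ValueError(
                f"gain clade {i} classifies as {support!r}; reconstruction and "
                "coding disagree"
            )
        name = next(
            (d.name for d in direct_defs if d.members & expanded),
            clade.node.label or f"gain-{i}",
        )
        n_par = sum(1 for t in expanded if coding.states.get(t) == PARASITIC)
        report.records.append(
            CladeRecord(name, "direct", expanded, n_par, losses_within=len(clade.losses_within))
        )

    for d in declared:
        if d.support == "direct":
            continue  # named above; found by reconstruction, not declaration
        tips = frozenset(set(d.members) & grafted_tips)
        if not tips:
            raise ValueError(f"declared clade {d.name!r} has no tips on the grafted tree")
        support = classify_support(tips, coding)
        if support != d.support:
            raise ValueError(
                f"declared clade {d.name!r} expected {d.support!r} but classifies "
                f"as {support!r}"
            )
        n_par = sum(1 for t in tips if coding.states.get(t) == PARASITIC)
        report.records.append(CladeRecord(d.name, support, tips, n_par))

    for i, a in enumerate(report.records):
        for b in report.records[i + 1 :]:
            if a.tips & b.tips:
                raise ValueError(
                    f"overlapping clade records: {a.name!r} and {b.name!r}"
                )

    report.totals = {
        cls: sum(1 for r in report.records if r.support == cls)
        for cls in SUPPORT_CLASSES
    }
    report.grand_total = len(report.records)
    return report
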