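"""Seedable simulator of complete toy datasets for the pipeline.

A run produces a *ground truth*: a rooted binary "true" tree over a few
hundred species, a rank-structured taxonomy whose genera, families and
orders are clades of that tree, a planted history of parasitism gains
(and optional reversals nested inside gain clades), and a set of
overlapping study trees obtained by restricting the true tree to random
tip subsets — optionally perturbed by random sibling regrafts to inject
rank conflicts.  Every pipeline stage (synthesis, grafting, ancestral
state reconstruction, reporting) can then be tested against known truth
without any downloaded data.

Default dimensions are desk-scale stand-ins for the real system: a
taxonomy of 300 species in 3 orders, 14 planted gains with 2 reversals
(the transition counts characteristic of the copepod analysis), and 6
ranked studies of 60 tips each with 50% overlap between consecutive
studies.  Trees are topology-only; the downstream methods never use
branch lengths.

Event placement is validated by construction: a candidate set of gain
and reversal clades is accepted only if unordered parsimony on the true
tree, under both ACCTRAN and DELTRAN, recovers exactly the planted
(gains, losses) — i.e. the planted history is the unique most
parsimonious explanation of the tip states.  Candidates are redrawn
until this holds, so parameter-recovery tests measure the pipeline, not
placement luck.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import asr
from .synthesis import SourceStudy
from .treeio import (
    FREE_LIVING,
    PARASITIC,
    UNKNOWN,
    Node,
    RootedTree,
    StateCoding,
    TaxonRecord,
    Taxonomy,
    parse_newick,
    read_coding,
    read_taxonomy,
    write_coding,
    write_newick,
    write_taxonomy,
)

__all__ = [
    "TaxonomyShape",
    "SimulationConfig",
    "GroundTruth",
    "simulate_true_tree",
    "build_taxonomy",
    "plant_history",
    "sample_studies",
    "generate_dataset",
    "emit_fixtures",
    "load_fixtures",
]


@dataclass(frozen=True)
class TaxonomyShape:
    species_per_genus: int = 5
    genera_per_family: int = 5
    families_per_order: int = 4
    n_orders: int = 3

    @property
    def n_species(self) -> int:
        return (
            self.species_per_genus
            * self.genera_per_family
            * self.families_per_order
            * self.n_orders
        )


@dataclass
class SimulationConfig:
    seed: int = 0
    shape: Optional[TaxonomyShape] = field(default_factory=TaxonomyShape)
    #: used only when ``shape`` is None: a flat random-join tree whose
    #: taxonomy is a single order/family/genus chain over all species
    n_species: int = 50
    n_gains: int = 14
    n_reversals: int = 2
    n_studies: int = 6
    tips_per_study: int = 60
    overlap: float = 0.5
    n_perturbations: int = 0
    unknown_fraction: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap fraction must be in [0, 1]")
        if min(self.n_gains, self.n_reversals, self.n_studies, self.n_perturbations) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_reversals > self.n_gains:
            raise ValueError("reversals are only placed inside gain clades")
        if not 0.0 <= self.unknown_fraction < 1.0:
            raise ValueError("unknown_fraction must be in [0, 1)")

    @property
    def total_species(self) -> int:
        return self.shape.n_species if self.shape is not None else self.n_species


@dataclass
class GroundTruth:
    config: SimulationConfig
    tree: RootedTree
    taxonomy: Taxonomy
    gain_taxa: list = field(default_factory=list)  # taxon ids (clades) carrying a gain
    reversal_taxa: list = field(default_factory=list)  # taxon ids nested in gain clades
    states: dict = field(default_factory=dict)  # species id -> 0 | 1
    coding: StateCoding = field(default_factory=StateCoding)
    studies: list = field(default_factory=list)  # list[SourceStudy]

    def replay_states(self) -> dict:
        """Recompute tip states from the event lists (for replay checks)."""
        gains = [self.taxonomy.species_of(t) for t in self.gain_taxa]
        reversals = [self.taxonomy.species_of(t) for t in self.reversal_taxa]
        out = {}
        for sp in self.taxonomy.all_species():
            state = FREE_LIVING
            if any(sp in g for g in gains):
                state = PARASITIC
                if any(sp in r for r in reversals):
                    state = FREE_LIVING
            out[sp] = state
        return out


# ---- tree simulation -------------------------------------------------


def _random_join(rng: random.Random, nodes: list) -> Node:
    """Uniform random sequential pair-joins (Yule-like, topology only)."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        joint = Node()
        joint.add_child(a)
        joint.add_child(b)
        nodes.append(joint)
    return nodes[0]


def simulate_true_tree(config: SimulationConfig) -> RootedTree:
    """Deterministic per-seed rooted binary tree.

    With a taxonomy shape the joins are nested (species within genus,
    genus within family, ...) so that every taxon is a clade of the true
    tree; without one the tree is a flat random join over ``n_species``
    leaves labelled ``s1..sN``.
    """
    rng = random.Random(config.seed)
    if config.shape is None:
        leaves = [Node(label=f"s{i + 1}") for i in range(config.n_species)]
        if not leaves:
            raise ValueError("n_species must be >= 1")
        return RootedTree(_random_join(rng, leaves))
    tree, _ = _shaped_tree_and_taxonomy(config, rng)
    return tree


def _shaped_tree_and_taxonomy(config: SimulationConfig, rng: random.Random):
    shape = config.shape
    next_id = [1]

    def take_id() -> int:
        next_id[0] += 1
        return next_id[0] - 1

    root_id = take_id()
    records = [TaxonRecord(root_id, None, "SimCopepoda", "class")]
    order_subtrees = []
    for o in range(1, shape.n_orders + 1):
        oid = take_id()
        oname = f"Order{o}"
        records.append(TaxonRecord(oid, root_id, oname, "order"))
        family_subtrees = []
        for f in range(1, shape.families_per_order + 1):
            fid = take_id()
            fname = f"{oname}_fam{f}"
            records.append(TaxonRecord(fid, oid, fname, "family"))
            genus_subtrees = []
            for g in range(1, shape.genera_per_family + 1):
                gid = take_id()
                gname = f"{fname}_gen{g}"
                records.append(TaxonRecord(gid, fid, gname, "genus"))
                leaves = []
                for s in range(1, shape.species_per_genus + 1):
                    sid = take_id()
                    sname = f"{gname}_sp{s}"
                    records.append(TaxonRecord(sid, gid, sname, "species"))
                    leaves.append(Node(label=f"{sname}_ott{sid}", taxon_id=sid))
                genus_subtrees.append(_random_join(rng, leaves))
            family_subtrees.append(_random_join(rng, genus_subtrees))
        order_subtrees.append(_random_join(rng, family_subtrees))
    tree = RootedTree(_random_join(rng, order_subtrees))
    return tree, Taxonomy(records)


def build_taxonomy(config: SimulationConfig) -> Taxonomy:
    """Taxonomy consistent with :func:`simulate_true_tree` for the same config."""
    rng = random.Random(config.seed)
    if config.shape is None:
        records = [
            TaxonRecord(1, None, "SimCopepoda", "class"),
            TaxonRecord(2, 1, "Order1", "order"),
            TaxonRecord(3, 2, "Order1_fam1", "family"),
            TaxonRecord(4, 3, "Order1_fam1_gen1", "genus"),
        ]
        # flat-mode tip keys are labels, not ids; species records mirror them
        for i in range(config.n_species):
            records.append(TaxonRecord(5 + i, 4, f"s{i + 1}", "species"))
        return Taxonomy(records)
    _, taxonomy = _shaped_tree_and_taxonomy(config, rng)
    return taxonomy


# ---- event planting --------------------------------------------------


def plant_history(
    tree: RootedTree,
    taxonomy: Taxonomy,
    config: SimulationConfig,
    rng: Optional[random.Random] = None,
    max_tries: int = 500,
) -> GroundTruth:
    """Plant ``n_gains`` gains and ``n_reversals`` reversals on the true tree.

    Gains fall on stems of randomly chosen genus- or family-level clades
    (pairwise disjoint and non-adjacent, so no two gains merge into a
    cheaper single gain); each reversal reverts one genus nested deep
    enough inside a gained family that reverting it is strictly cheaper
    than parallel gains.  Candidate placements failing the uniqueness
    validation (see module docstring) are redrawn.
    """
    rng = rng or random.Random(config.seed + 1)
    genera = sorted(taxonomy.taxa_of_rank("genus"))
    families = sorted(taxonomy.taxa_of_rank("family"))
    candidates = families + genera

    last_error = "no attempt made"
    for _ in range(max_tries):
        truth = _try_placement(tree, taxonomy, config, rng, candidates, families)
        if truth is not None:
            return truth
        last_error = "placement failed uniqueness validation"
    raise ValueError(
        f"could not place {config.n_gains} gains / {config.n_reversals} reversals "
        f"after {max_tries} tries: {last_error}"
    )


def _try_placement(tree, taxonomy, config, rng, candidates, families):
    if config.n_gains > len(candidates):
        raise ValueError("n_gains exceeds available clades")
    # reversals need a family-level gain with a deep-enough genus inside
    shuffled = list(candidates)
    rng.shuffle(shuffled)
    chosen: list[int] = []
    chosen_species: set = set()
    need_families = config.n_reversals
    for tid in shuffled:
        if len(chosen) == config.n_gains:
            break
        species = taxonomy.species_of(tid)
        if species & chosen_species:
            continue
        remaining = config.n_gains - len(chosen) - 1
        fams_so_far = sum(1 for c in chosen if taxonomy[c].rank == "family")
        if taxonomy[tid].rank != "family" and remaining < need_families - fams_so_far:
            continue  # keep room for the families that must host reversals
        chosen.append(tid)
        chosen_species |= species
    if len(chosen) < config.n_gains:
        return None

    # no two gain clades may together form a clade (their merge would be
    # a strictly cheaper single gain)
    for i, a in enumerate(chosen):
        sa = taxonomy.species_of(a)
        for b in chosen[i + 1 :]:
            union = sa | taxonomy.species_of(b)
            if tree.tipset_of(tree.mrca(union)) == union:
                return None

    gain_fams = [t for t in chosen if taxonomy[t].rank == "family"]
    rng.shuffle(gain_fams)
    reversal_taxa = []
    for fam in gain_fams[: config.n_reversals]:
        genus = _deep_genus(tree, taxonomy, fam, rng)
        if genus is None:
            return None
        reversal_taxa.append(genus)
    if len(reversal_taxa) < config.n_reversals:
        return None

    truth = GroundTruth(
        config=config,
        tree=tree,
        taxonomy=taxonomy,
        gain_taxa=sorted(chosen),
        reversal_taxa=sorted(reversal_taxa),
    )
    truth.states = truth.replay_states()

    coding = StateCoding()
    species = sorted(taxonomy.all_species())
    n_unknown = int(round(config.unknown_fraction * len(species)))
    unknown = set(rng.sample(species, n_unknown)) if n_unknown else set()
    tip_keys = {leaf.taxon_id: leaf for leaf in tree.leaves() if leaf.taxon_id is not None}
    for sp in species:
        key = sp if sp in tip_keys else taxonomy[sp].name
        state = UNKNOWN if sp in unknown else truth.states[sp]
        coding.set(key, state, sampled=False, name=taxonomy[sp].name)
    truth.coding = coding

    # uniqueness validation: both resolutions must recover the history
    expected = (config.n_gains, config.n_reversals)
    for resolution in ("ACCTRAN", "DELTRAN"):
        rec = asr.reconstruct(tree, coding, asr.UNORDERED, resolution=resolution)
        if asr.count_changes(rec) != expected:
            return None
    return truth


def _deep_genus(tree, taxonomy, family, rng):
    """A genus of ``family`` separated from the family stem by >= 3 edges.

    Reverting such a genus leaves at least three maximal parasitic
    subtrees hanging off the path, so one gain plus one loss (cost 2)
    beats parallel gains (cost >= 3) strictly — the reversal is then the
    unique most parsimonious explanation locally.
    """
    fam_species = taxonomy.species_of(family)
    fam_node = tree.mrca(fam_species)
    genera = list(taxonomy.children[family])
    rng.shuffle(genera)
    for gid in genera:
        gsp = taxonomy.species_of(gid)
        gnode = tree.mrca(gsp)
        depth = 0
        cur = gnode
        while cur is not fam_node and cur is not None:
            depth += 1
            cur = cur.parent
        if cur is fam_node and depth >= 3:
            return gid
    return None


# ---- study sampling --------------------------------------------------


def sample_studies(
    truth: GroundTruth,
    config: Optional[SimulationConfig] = None,
    rng: Optional[random.Random] = None,
) -> list[SourceStudy]:
    """Overlapping restrictions of the true tree as ranked studies.

    The first (rank 1) study is always an exact restriction; later
    studies receive ``n_perturbations`` random sibling regrafts each,
    which injects topological conflict with the truth.  Consecutive
    studies share ``overlap`` of their tips.  Sampled flags on the
    truth's coding are updated in place.
    """
    config = config or truth.config
    rng = rng or random.Random(config.seed + 2)
    all_tips = sorted(truth.tree.tip_set(), key=str)
    k = min(config.tips_per_study, len(all_tips))
    methods = ["BI_ML", "MP", "NJ_ME"]

    studies = []
    prev: list = []
    for i in range(config.n_studies):
        n_shared = min(int(round(config.overlap * k)), len(prev))
        shared = rng.sample(prev, n_shared) if n_shared else []
        pool = [t for t in all_tips if t not in set(shared)]
        subset = set(shared) | set(rng.sample(pool, k - len(shared)))
        tree = truth.tree.restrict(subset)
        if i > 0:
            for _ in range(config.n_perturbations):
                _sibling_regraft(tree, rng)
        study = SourceStudy(
            study_id=f"sim{i + 1:02d}",
            tree=tree,
            rank=i + 1,
            focal_clade="SimCopepoda",
            n_markers=rng.randint(1, 5),
            method_class=methods[rng.randrange(3)],
            n_ingroup_taxa=tree.n_tips(),
        )
        studies.append(study)
        prev = sorted(subset, key=str)

    for study in studies:
        for key in study.tree.tip_set():
            if key in truth.coding.states:
                truth.coding.sampled[key] = True
    truth.studies = studies
    return studies


def _sibling_regraft(tree: RootedTree, rng: random.Random) -> None:
    """Detach a random subtree and reattach it as sibling of another node."""
    nodes = [n for n in tree.preorder() if n.parent is not None]
    if len(nodes) < 4:
        return
    mover = nodes[rng.randrange(len(nodes))]
    inside = set()
    stack = [mover]
    while stack:
        n = stack.pop()
        inside.add(id(n))
        stack.extend(n.children)
    targets = [
        n
        for n in nodes
        if id(n) not in inside and n.parent is not mover.parent and n is not mover.parent
    ]
    if not targets:
        return
    target = targets[rng.randrange(len(targets))]
    mover.parent.remove_child(mover)
    parent = target.parent
    idx = parent.children.index(target)
    joint = Node()
    parent.children[idx] = joint
    joint.parent = parent
    joint.add_child(target)
    joint.add_child(mover)
    tree.normalize()


# ---- convenience / fixtures -----------------------------------------


def generate_dataset(config: SimulationConfig) -> GroundTruth:
    """Simulate tree + taxonomy, plant events, sample studies."""
    rng = random.Random(config.seed)
    if config.shape is None:
        tree = simulate_true_tree(config)
        taxonomy = build_taxonomy(config)
    else:
        tree, taxonomy = _shaped_tree_and_taxonomy(config, rng)
    truth = plant_history(tree, taxonomy, config, random.Random(config.seed + 1))
    sample_studies(truth, config, random.Random(config.seed + 2))
    return truth


def emit_fixtures(truth: GroundTruth, directory) -> list:
    """Write newicks, manifest CSV, taxonomy TSV, coding CSV, truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    manifest_rows = ["file,study_id,rank,focal_clade,n_markers,method_class,n_ingroup_taxa"]
    for study in truth.studies:
        fname = f"{study.study_id}.tre"
        (directory / fname).write_text(write_newick(study.tree) + "\n")
        written.append(directory / fname)
        manifest_rows.append(
            f"{fname},{study.study_id},{study.rank},{study.focal_clade},"
            f"{study.n_markers},{study.method_class},{study.n_ingroup_taxa}"
        )
    (directory / "studies.csv").write_text("\n".join(manifest_rows) + "\n")
    (directory / "true_tree.tre").write_text(write_newick(truth.tree) + "\n")
    (directory / "taxonomy.tsv").write_text(write_taxonomy(truth.taxonomy, dialect="ott"))
    (directory / "coding.csv").write_text(write_coding(truth.coding))
    truth_blob = {
        "seed": truth.config.seed,
        "gain_taxa": truth.gain_taxa,
        "reversal_taxa": truth.reversal_taxa,
        "states": {str(k): v for k, v in sorted(truth.states.items())},
        "n_gains": truth.config.n_gains,
        "n_reversals": truth.config.n_reversals,
    }
    (directory / "truth.json").write_text(json.dumps(truth_blob, indent=2) + "\n")
    written += [
        directory / "studies.csv",
        directory / "true_tree.tre",
        directory / "taxonomy.tsv",
        directory / "coding.csv",
        directory / "truth.json",
    ]
    return written


def load_fixtures(directory):
    """Read back what :func:`emit_fixtures` wrote.

    Returns (studies, true_tree, taxonomy, coding, truth_blob).
    """
    from .synthesis import read_manifest

    directory = Path(directory)
    studies = read_manifest(directory / "studies.csv")
    tree = parse_newick((directory / "true_tree.tre").read_text())
    taxonomy = read_taxonomy((directory / "taxonomy.tsv").read_text(), dialect="ott")
    coding = read_coding((directory / "coding.csv").read_text())
    truth_blob = json.loads((directory / "truth.json").read_text())
    return studies, tree, taxonomy, coding, truth_blob
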