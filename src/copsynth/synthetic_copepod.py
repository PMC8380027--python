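"""A synthetic, desk-scale stand-in for the copepod synthesis dataset.

The real analysis ran on a deposited grafted tree of 365 sampled copepod
taxa plus a reference taxonomy of ~14,500 species.  Neither is shipped
here; instead this module constructs a small synthetic dataset that
reproduces the *structure* the analysis depends on, with real copepod
taxon names for readability:

* a sampled synthesis tree whose parasitic clades mirror the seven
  directly supported origins of parasitism — including a large
  "poecilostome" clade with two free-living lineages (Oncaeidae;
  Sapphirinidae + Corycaeidae + *Pachos*) nested inside it, arranged so
  that unconstrained parsimony explains the clade with one gain and two
  reversals while irreversible parsimony needs eight separate gains;
* a taxonomy holding the unsampled species behind the four indirectly
  supported clades (parasitic members of sampled, otherwise free-living
  taxa) and the three clades supported by morphology-based taxonomy only
  (never-sampled taxa), plus assorted free-living species, a broken
  family, and a never-sampled order;
* a complete lifestyle coding with sampled flags.

Everything is generated in code; no species list here claims to be the
deposited data.  Tip identity is by taxonomy id throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .reporting import CladeDefinition
from .tables import load_clade_table
from .treeio import (
    FREE_LIVING,
    PARASITIC,
    UNKNOWN,
    Node,
    RootedTree,
    StateCoding,
    TaxonRecord,
    Taxonomy,
)

__all__ = ["CopepodDataset", "build_dataset"]

_STATE = {"F": FREE_LIVING, "P": PARASITIC, "U": UNKNOWN}

# (name, rank, children); species are (name, state, sampled)
_SPEC = (
    "Copepoda",
    "class",
    [
        ("Calanoida", "order", [
            ("Calanidae", "family", [
                ("Calanus", "genus", [("Calanus_finmarchicus", "F", True),
                                      ("Calanus_glacialis", "F", False)]),
                ("Neocalanus", "genus", [("Neocalanus_cristatus", "F", True)]),
            ]),
            ("Eucalanidae", "family", [
                ("Eucalanus", "genus", [("Eucalanus_bungii", "F", True)]),
            ]),
            ("Acartiidae", "family", [
                ("Acartia", "genus", [("Acartia_tonsa", "F", True),
                                      ("Acartia_clausi", "F", False)]),
            ]),
        ]),
        ("Gelyelloida", "order", [
            ("Gelyellidae", "family", [
                ("Gelyella", "genus", [("Gelyella_droguei", "F", False),
                                       ("Gelyella_monardi", "F", False)]),
            ]),
        ]),
        ("Harpacticoida", "order", [
            ("Canuellidae", "family", [
                ("Canuella", "genus", [("Canuella_perplexa", "F", True)]),
                ("Echinosunaristes", "genus", [("Echinosunaristes_bathycola", "P", False)]),
            ]),
            ("Harpacticidae", "family", [
                ("Harpacticus", "genus", [("Harpacticus_uniremis", "F", True)]),
            ]),
            ("Tisbidae", "family", [
                ("Tisbe", "genus", [("Tisbe_furcata", "F", True)]),
                ("Cholidyinae", "no rank", [
                    ("Cholidya", "genus", [
                        ("Cholidya_polypi", "P", False),
                        ("Cholidya_abyssalis", "P", False),
                        ("Cholidya_profunda", "P", False),
                        ("Cholidya_teuthida", "P", False),
                        ("Cholidya_pacifica", "P", False),
                        ("Cholidya_atlantica", "P", False),
                        ("Cholidya_borealis", "P", False),
                    ]),
                    ("Tisbicola", "genus", [
                        ("Tisbicola_sepiae", "P", False),
                        ("Tisbicola_octopodis", "P", False),
                        ("Tisbicola_loliginis", "P", False),
                        ("Tisbicola_benthica", "P", False),
                        ("Tisbicola_australis", "P", False),
                        ("Tisbicola_arctica", "P", False),
                    ]),
                    ("Neoscutellidium", "genus", [("Neoscutellidium_yeatmani", "P", False)]),
                ]),
            ]),
            ("Thalestridae", "family", [
                ("Phyllothalestris", "genus", [("Phyllothalestris_mysis", "F", True)]),
                ("Diarthrodes", "genus", [
                    ("Diarthrodes_cystoecus", "P", False),
                    ("Diarthrodes_feldmanni", "P", False),
                    ("Diarthrodes_halophilus", "P", False),
                    ("Diarthrodes_gravelicola", "P", False),
                ]),
            ]),
            ("Tegastidae", "family", [
                ("Tegastes", "genus", [("Tegastes_falcatus", "F", True)]),
                ("Aglaogastes", "genus", [("Aglaogastes_cnidicus", "P", False)]),
            ]),
            ("Peltidiidae", "family", [
                ("Peltidium", "genus", [("Peltidium_purpureum", "F", True)]),
                ("Alteuthellopsis", "genus", [("Alteuthellopsis_corallina", "P", True),
                                              ("Alteuthellopsis_lucida", "P", False)]),
            ]),
            ("Ameiridae", "family", [
                ("Ameira", "genus", [("Ameira_parvula", "F", True)]),
                ("Nitokra", "genus", [("Nitokra_bdellurae", "P", True),
                                      ("Nitokra_spinipes", "P", True)]),
            ]),
            ("Laophontidae", "family", [
                ("Mictyricola", "genus", [("Mictyricola_setifera", "P", False),
                                          ("Mictyricola_typica", "P", False)]),
                ("Robustunguis", "genus", [("Robustunguis_minor", "P", False),
                                           ("Robustunguis_fiersi", "P", False)]),
                ("Laophonte", "genus", [("Laophonte_cornuta", "F", False)]),
                ("Paralaophonte", "genus", [("Paralaophonte_brevirostris", "F", False)]),
            ]),
            ("Miraciidae", "family", [
                ("Balaenophilus", "genus", [("Balaenophilus_unisetus", "P", False),
                                            ("Balaenophilus_manatorum", "P", False),
                                            ("Balaenophilus_umigamecolus", "U", False)]),
            ]),
        ]),
        ("Cyclopoida", "order", [
            ("Cyclopidae", "family", [
                ("Cyclops", "genus", [("Cyclops_strenuus", "F", True)]),
                ("Mesocyclops", "genus", [("Mesocyclops_leuckarti", "F", True)]),
                ("Macrocyclops", "genus", [("Macrocyclops_albidus", "F", True)]),
                ("Paracyclops", "genus", [("Paracyclops_fimbriatus", "F", True)]),
                ("Halicyclops", "genus", [("Halicyclops_magniceps", "F", True)]),
                ("Eucyclops", "genus", [("Eucyclops_serrulatus", "F", True),
                                        ("Eucyclops_agilis", "F", True),
                                        ("Eucyclops_bathanalicola", "P", False)]),
            ]),
            ("Oithonidae", "family", [
                ("Oithona", "genus", [("Oithona_similis", "F", True)]),
                ("Limnoithona", "genus", [("Limnoithona_tetraspina", "F", True)]),
                ("Dioithona", "genus", [("Dioithona_rubra", "F", False)]),
            ]),
            ("Cyclopinidae", "family", [
                ("Cyclopina", "genus", [("Cyclopina_gracilis", "F", True)]),
            ]),
            ("Euryteidae", "family", [
                ("Euryte", "genus", [("Euryte_longicauda", "F", True)]),
            ]),
            ("Thaumatopsyllidae", "family", [
                ("Thaumatopsyllus", "genus", [("Thaumatopsyllus_paradoxus", "P", True),
                                              ("Thaumatopsyllus_spinosus", "P", False),
                                              ("Thaumatopsyllus_minor", "P", False)]),
                ("Caribeopsyllus", "genus", [("Caribeopsyllus_amphiodiae", "P", True),
                                             ("Caribeopsyllus_chawayi", "P", False)]),
            ]),
            ("Lernaeidae", "family", [
                ("Lernaea", "genus", [("Lernaea_cyprinacea", "P", True),
                                      ("Lernaea_cruciata", "P", False)]),
                ("Lamproglena", "genus", [("Lamproglena_pulchella", "P", True)]),
            ]),
            ("Notodelphyidae", "family", [
                ("Notodelphys", "genus", [("Notodelphys_agilis", "P", True),
                                          ("Notodelphys_allmani", "P", False)]),
                ("Doropygus", "genus", [("Doropygus_pulex", "P", True)]),
            ]),
            ("Ergasilidae", "family", [
                ("Ergasilus", "genus", [("Ergasilus_sieboldi", "P", True),
                                        ("Ergasilus_briani", "P", False)]),
            ]),
            ("Chondracanthidae", "family", [
                ("Chondracanthus", "genus", [("Chondracanthus_lophii", "P", True)]),
            ]),
            ("Mytilicolidae", "family", [
                ("Mytilicola", "genus", [("Mytilicola_intestinalis", "P", True)]),
            ]),
            ("Bomolochidae", "family", [
                ("Bomolochus", "genus", [("Bomolochus_bellones", "P", True)]),
            ]),
            ("Taeniacanthidae", "family", [
                ("Taeniacanthus", "genus", [("Taeniacanthus_lagocephali", "P", True)]),
            ]),
            ("Pseudanthessiidae", "family", [
                ("Pseudanthessius", "genus", [("Pseudanthessius_liber", "P", True)]),
            ]),
            ("Lichomolgidae", "family", [
                ("Lichomolgus", "genus", [("Lichomolgus_canui", "P", True)]),
            ]),
            ("Clausidiidae", "family", [
                ("Clausidium", "genus", [("Clausidium_vancouverense", "P", True)]),
            ]),
            ("Oncaeidae", "family", [
                ("Oncaea", "genus", [("Oncaea_venusta", "F", True)]),
                ("Triconia", "genus", [("Triconia_conifera", "F", True)]),
            ]),
            ("Sapphirinidae", "family", [
                ("Sapphirina", "genus", [("Sapphirina_angusta", "F", True)]),
                ("Pachos", "genus", [("Pachos_punctatum", "F", True)]),
            ]),
            ("Corycaeidae", "family", [
                ("Corycaeus", "genus", [("Corycaeus_affinis", "F", True)]),
            ]),
        ]),
        ("Siphonostomatoida", "order", [
            ("Caligidae", "family", [
                ("Caligus", "genus", [("Caligus_rogercresseyi", "P", True),
                                      ("Caligus_elongatus", "P", False)]),
                ("Lepeophtheirus", "genus", [("Lepeophtheirus_salmonis", "P", True)]),
            ]),
            ("Pennellidae", "family", [
                ("Pennella", "genus", [("Pennella_balaenopterae", "P", True)]),
            ]),
        ]),
        ("Monstrilloida", "order", [
            ("Monstrillidae", "family", [
                ("Monstrilla", "genus", [("Monstrilla_grandis", "P", True),
                                         ("Monstrilla_helgolandica", "P", False)]),
            ]),
        ]),
    ],
)

# Sampled synthesis tree as a nested-tuple shape (leaves are species
# names): the seven directly supported parasitic clades separated by
# free-living lineages; the poecilostome ladder carries the two nested
# free-living clades (Oncaeidae; Sapphirinidae + Corycaeidae + Pachos).
# Monstrilloida is nested inside Siphonostomatoida, as the source
# phylogenies recover it.
_ONC = ("Oncaea_venusta", "Triconia_conifera")
_SAP = ("Sapphirina_angusta", ("Corycaeus_affinis", "Pachos_punctatum"))
_POEC = (
    "Ergasilus_sieboldi",
    ("Chondracanthus_lophii",
     ("Mytilicola_intestinalis",
      ("Bomolochus_bellones",
       (_ONC,
        ("Taeniacanthus_lagocephali",
         ("Pseudanthessius_liber",
          ("Lichomolgus_canui",
           (_SAP, "Clausidium_vancouverense")))))))),
)
_CYC = (
    "Cyclops_strenuus",
    ("Mesocyclops_leuckarti",
     (("Eucyclops_serrulatus", "Eucyclops_agilis"),
      ("Macrocyclops_albidus",
       (("Thaumatopsyllus_paradoxus", "Caribeopsyllus_amphiodiae"),
        ("Halicyclops_magniceps",
         ("Oithona_similis",
          (("Lernaea_cyprinacea", "Lamproglena_pulchella"),
           ("Paracyclops_fimbriatus",
            ("Cyclopina_gracilis",
             (("Notodelphys_agilis", "Doropygus_pulex"),
              ("Euryte_longicauda",
               ("Limnoithona_tetraspina", _POEC)))))))))))),
)
_HARP = (
    "Canuella_perplexa",
    ("Harpacticus_uniremis",
     (("Tisbe_furcata", "Phyllothalestris_mysis"),
      (("Ameira_parvula", ("Nitokra_bdellurae", "Nitokra_spinipes")),
       ("Tegastes_falcatus",
        ("Peltidium_purpureum", "Alteuthellopsis_corallina"))))),
)
_SIPH = (
    "Caligus_rogercresseyi",
    ("Lepeophtheirus_salmonis",
     ("Monstrilla_grandis", "Pennella_balaenopterae")),
)
_CALAN = (
    ("Calanus_finmarchicus", "Neocalanus_cristatus"),
    ("Eucalanus_bungii", "Acartia_tonsa"),
)
_TREE_SHAPE = (_CALAN, (_HARP, (_CYC, _SIPH)))


@dataclass
class CopepodDataset:
    taxonomy: Taxonomy
    tree: RootedTree  # synthesis tree of sampled taxa
    coding: StateCoding
    clades: list = field(default_factory=list)  # list[CladeDefinition]

    def poecilostome_tips(self) -> frozenset:
        """Tip set of the poecilostome clade on the sampled tree."""
        names = {"Ergasilus_sieboldi", "Clausidium_vancouverense"}
        anchors = {l.tip_key for l in self.tree.leaves() if l.label in names}
        return frozenset(self.tree.tipset_of(self.tree.mrca(anchors)))


def build_dataset() -> CopepodDataset:
    records: list[TaxonRecord] = []
    coding = StateCoding()
    name_to_id: dict[str, int] = {}
    counter = [1000]

    def add(name, rank, parent_id) -> int:
        counter[0] += 1
        records.append(TaxonRecord(counter[0], parent_id, name, rank))
        name_to_id[name] = counter[0]
        return counter[0]

    def walk(spec, parent_id):
        name, rank, children = spec
        tid = add(name, rank, parent_id)
        for child in children:
            if len(child) == 3 and isinstance(child[2], list):
                walk(child, tid)
            else:
                sp_name, state, sampled = child
                sid = add(sp_name, "species", tid)
                coding.set(sid, _STATE[state], sampled=sampled, name=sp_name)

    root_name, root_rank, root_children = _SPEC
    root_id = add(root_name, root_rank, None)
    for child in root_children:
        walk(child, root_id)
    taxonomy = Taxonomy(records)

    def build_node(shape):
        if isinstance(shape, str):
            return Node(label=shape)
        node = Node()
        for child in shape:
            node.add_child(build_node(child))
        return node

    tree = RootedTree(build_node(_TREE_SHAPE)).normalize()
    for leaf in tree.leaves():
        sid = name_to_id.get(leaf.label)
        if sid is None:
            raise ValueError(f"tree tip {leaf.label!r} missing from taxonomy spec")
        if not coding.is_sampled(sid):
            raise ValueError(f"tree tip {leaf.label!r} not flagged sampled")
        leaf.taxon_id = sid
    tree.validate()

    clades = []
    for row in load_clade_table().itertuples(index=False):
        members: set[int] = set()
        for taxon_name in row.defining_taxa.split(";"):
            tid = name_to_id.get(taxon_name.strip())
            if tid is None:
                raise ValueError(f"clade taxon {taxon_name!r} missing from taxonomy spec")
            members |= taxonomy.species_of(tid)
        clades.append(
            CladeDefinition(
                name=row.clade,
                order=row.order,
                support=row.support,
                members=frozenset(members),
            )
        )
    return CopepodDataset(taxonomy=taxonomy, tree=tree, coding=coding, clades=clades)
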