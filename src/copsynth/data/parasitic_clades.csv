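# The 14 independent parasitic copepod clades and their evidence tier:
# direct  - parasitic members themselves molecularly sampled; the clade is
#           recovered as a gain by ancestral state reconstruction
# indirect - the containing taxon was sampled, but only through free-living
#            members; its parasitic species enter by taxonomy grafting
# taxonomic - no member of the taxon sampled at all; independence rests on
#             morphology-based classification
# defining_taxa are taxonomy names (semicolon-separated) whose species
# anchor the clade on a grafted tree.
clade,order,support,defining_taxa
Siphonostomatoida + Monstrilloida,Siphonostomatoida,direct,Siphonostomatoida;Monstrilloida
poecilostomes,Cyclopoida,direct,Ergasilidae
Notodelphyidae + allies,Cyclopoida,direct,Notodelphyidae
Lernaeidae,Cyclopoida,direct,Lernaeidae
Thaumatopsyllidae,Cyclopoida,direct,Thaumatopsyllidae
Ameiridae,Harpacticoida,direct,Nitokra
Peltidiidae,Harpacticoida,direct,Alteuthellopsis
Eucyclops bathanalicola,Cyclopoida,indirect,Eucyclops
Canuellidae,Harpacticoida,indirect,Canuellidae
Thalestridae,Harpacticoida,indirect,Thalestridae
Tegastidae,Harpacticoida,indirect,Tegastidae
Balaenophilus,Harpacticoida,taxonomic,Balaenophilus
Cholidyinae,Harpacticoida,taxonomic,Cholidyinae
Laophontidae,Harpacticoida,taxonomic,Laophontidae
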