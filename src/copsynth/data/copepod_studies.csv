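# Manifest of the 31 published molecular phylogenies grafted into the
# copepod synthesis tree, in rank order (rank 1 = highest priority).
# n_markers counts individually named loci; phylogenomic data sets carry
# the printed locus count (244 orthologs) or no count (transcriptomes,
# whole mitochondrial genomes).  method_class is the best method in the
# study: BI_ML > MP > NJ_ME.
study_id,rank,focal_clade,markers,n_markers,n_ingroup_taxa,method_class
s01,1,Cyclopoida,"18S,28S,CO1",3,121,BI_ML
s02,2,Megacalanidae,"18S,28S,5.8S,CO1,H3,ITS1,ITS2",7,11,BI_ML
s03,3,Paracalanidae,"18S,CO1,H3",3,22,BI_ML
s04,4,Calanoida,"18S,28S,CO1,CytB",4,38,BI_ML
s05,5,Calanoida,"18S,28S,CO1,CytB",4,32,BI_ML
s06,6,Mesocyclops,"18S,ITS2",2,10,BI_ML
s07,7,Cyclopoida,"18S",1,41,BI_ML
s08,8,Copepoda,"18S",1,49,BI_ML
s09,9,Harpacticoida,"18S",1,31,BI_ML
s10,10,Pancrustacea,"244 orthologs",244,9,BI_ML
s11,11,Pancrustacea,"transcriptomes",,7,BI_ML
s12,12,Copepoda,"24 nuclear genes",24,9,BI_ML
s13,13,Copepoda,"18S",1,47,BI_ML
s14,14,Cyclops,"12S,16S,18S,CO1,CytB,ITS1",6,15,BI_ML
s15,15,Copepoda,"mt genome",,6,BI_ML
s16,16,"Aetideidae, Euchaetidae","18S,28S,CO1,ITS2",4,14,BI_ML
s17,17,Cyclopoida,"28S",1,16,BI_ML
s18,18,Neocalanus,"18S,28S,CO1,ND4,ND6",5,7,BI_ML
s19,19,Calanoida,"28S",1,58,BI_ML
s20,20,Copepoda,"18S",1,35,BI_ML
s21,21,Centropagidae,"16S",1,25,BI_ML
s22,22,Centropagidae,"CO1",1,14,BI_ML
s23,23,Pseudocalanus,"18S,CO1",2,7,NJ_ME
s24,24,Neocalanus,"18S,CO1",2,7,NJ_ME
s25,25,Clausocalanus,"18S,CO1",2,14,NJ_ME
s26,26,"Calanidae, Clausocalanidae","18S,CO1",2,12,NJ_ME
s27,27,Neocalanus,"16S,18S",2,11,NJ_ME
s28,28,Calanoida,"16S,18S",2,19,NJ_ME
s29,29,Calanoida,"28S",1,11,MP
s30,30,Euchitidae,"16S",1,8,MP
s31,31,Cyclopoida,"CO1",1,19,NJ_ME
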