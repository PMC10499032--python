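species,division,category,gene_symbol,ncbi_gene_ids,uniprot_ids,ensembl_ids,zfin_ids,flybase_ids,wormbase_ids,common_names
human,Core matrisome,Collagens,COL1A1,1277,P02452,ENSG00000108821,,,,
human,Core matrisome,Collagens,COL3A1,1281,P02461,ENSG00000168542,,,,
human,Core matrisome,ECM Glycoproteins,FN1,2335,P02751,ENSG00000115414,,,,
human,Core matrisome,ECM Glycoproteins,LAMA1,284217,P25391,ENSG00000101680,,,,
human,Core matrisome,Proteoglycans,ACAN,176,P16112,ENSG00000157766,,,,
human,Core matrisome,Proteoglycans,BGN,633,P21810,ENSG00000182492,,,,
human,Matrisome-associated,ECM-affiliated Proteins,ANXA2,302,P07355,ENSG00000182718,,,,
human,Matrisome-associated,ECM-affiliated Proteins,LGALS3,3958,P17931,ENSG00000131981,,,,
human,Matrisome-associated,ECM Regulators,MMP2,4313,P08253,ENSG00000087245,,,,
human,Matrisome-associated,ECM Regulators,TIMP1,7076,P01033,ENSG00000102265,,,,
human,Matrisome-associated,Secreted Factors,VEGFA,7422,P15692,ENSG00000112715,,,,
human,Matrisome-associated,Secreted Factors,TGFB1,7040,P01137,ENSG00000105329,,,,
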