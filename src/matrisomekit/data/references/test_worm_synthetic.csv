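species,division,category,gene_symbol,ncbi_gene_ids,uniprot_ids,ensembl_ids,zfin_ids,flybase_ids,wormbase_ids,common_names
nematode,Core matrisome,Collagens,emb-9,175295,P17139,,,,WBGene00001328,CELE_K04H4.1
nematode,Core matrisome,Collagens,let-2,180806,P17140,,,,WBGene00002283,CELE_F01G12.5
nematode,Core matrisome,ECM Glycoproteins,fbl-1,172679,Q93791,,,,WBGene00001413,CELE_F56H11.1
nematode,Core matrisome,ECM Glycoproteins,mig-6,174228,Q8MQB1,,,,WBGene00003241,CELE_C37C3.6
nematode,Core matrisome,Proteoglycans,unc-52,181775,Q06561,,,,WBGene00006787,CELE_ZC101.2
nematode,Core matrisome,Proteoglycans,sdn-1,177692,Q18953,,,,WBGene00004749,CELE_F57C7.3
nematode,Matrisome-associated,ECM-affiliated Proteins,lec-1,180443,P36573,,,,WBGene00002264,CELE_W09H1.6
nematode,Matrisome-associated,ECM-affiliated Proteins,clec-1,185833,Q9XVS2,,,,WBGene00000526,CELE_C07A4.3
nematode,Matrisome-associated,ECM Regulators,nas-4,177566,Q21116,,,,WBGene00003521,CELE_K04E7.3
nematode,Matrisome-associated,ECM Regulators,mig-17,176911,G5EDW4,,,,WBGene00003247,CELE_F57B7.4
nematode,Matrisome-associated,Secreted Factors,dbl-1,179600,Q94164,,,,WBGene00000936,CELE_T25F10.2
nematode,Matrisome-associated,Secreted Factors,unc-129,177916,Q21225,,,,WBGene00006851,CELE_F56D1.6
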