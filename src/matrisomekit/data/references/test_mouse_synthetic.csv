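species,division,category,gene_symbol,ncbi_gene_ids,uniprot_ids,ensembl_ids,zfin_ids,flybase_ids,wormbase_ids,common_names
mouse,Core matrisome,Collagens,Col1a1,12842,P11087,ENSMUSG00000001506,,,,
mouse,Core matrisome,Collagens,Col3a1,12825,P08121,ENSMUSG00000026043,,,,
mouse,Core matrisome,ECM Glycoproteins,Fn1,14268,P11276,ENSMUSG00000026193,,,,
mouse,Core matrisome,ECM Glycoproteins,Lama1,16772,P19137,ENSMUSG00000032796,,,,
mouse,Core matrisome,Proteoglycans,Acan,11595,Q61282,ENSMUSG00000030607,,,,
mouse,Core matrisome,Proteoglycans,Bgn,12111,P28653,ENSMUSG00000031375,,,,
mouse,Matrisome-associated,ECM-affiliated Proteins,Anxa2,12306,P07356,ENSMUSG00000032231,,,,
mouse,Matrisome-associated,ECM-affiliated Proteins,Lgals3,16854,P16110,ENSMUSG00000050335,,,,
mouse,Matrisome-associated,ECM Regulators,Mmp2,17390,P33434,ENSMUSG00000031740,,,,
mouse,Matrisome-associated,ECM Regulators,Timp1,21857,P12032,ENSMUSG00000001131,,,,
mouse,Matrisome-associated,Secreted Factors,Vegfa,22339,Q00731,ENSMUSG00000023951,,,,
mouse,Matrisome-associated,Secreted Factors,Tgfb1,21803,P04202,ENSMUSG00000002603,,,,
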