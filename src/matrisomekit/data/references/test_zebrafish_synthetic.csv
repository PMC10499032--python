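species,division,category,gene_symbol,ncbi_gene_ids,uniprot_ids,ensembl_ids,zfin_ids,flybase_ids,wormbase_ids,common_names
zebrafish,Core matrisome,Collagens,col1a1a,114632,Q9W7E0,,ZDB-GENE-990415-190,,,
zebrafish,Core matrisome,Collagens,col2a1a,30430,Q91717,,ZDB-GENE-980526-192,,,
zebrafish,Core matrisome,ECM Glycoproteins,fn1a,30332,B8JIW1,,ZDB-GENE-010122-1,,,
zebrafish,Core matrisome,ECM Glycoproteins,lama1,563512,A4QNX5,,ZDB-GENE-030131-9301,,,
zebrafish,Core matrisome,Proteoglycans,acana,560202,E7F2D9,,ZDB-GENE-081104-344,,,
zebrafish,Core matrisome,Proteoglycans,bgnb,447925,Q5U3B3,,ZDB-GENE-041001-153,,,
zebrafish,Matrisome-associated,ECM-affiliated Proteins,anxa2a,30757,Q6TH49,,ZDB-GENE-000412-3,,,
zebrafish,Matrisome-associated,ECM-affiliated Proteins,lgals1l1,30060,Q6NYH1,,ZDB-GENE-980526-342,,,
zebrafish,Matrisome-associated,ECM Regulators,mmp2,406397,Q9I8N9,,ZDB-GENE-030131-1239,,,
zebrafish,Matrisome-associated,ECM Regulators,timp2a,565745,F1QHM1,,ZDB-GENE-040426-2617,,,
zebrafish,Matrisome-associated,Secreted Factors,vegfaa,30682,O73682,,ZDB-GENE-980526-324,,,
zebrafish,Matrisome-associated,Secreted Factors,tgfb1a,100002825,B3DJX2,,ZDB-GENE-080403-2,,,
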