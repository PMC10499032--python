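species,division,category,gene_symbol,ncbi_gene_ids,uniprot_ids,ensembl_ids,zfin_ids,flybase_ids,wormbase_ids,common_names
fruit_fly,Core matrisome,Collagens,vkg,36023,Q9VXG6,,,FBgn0016075,,
fruit_fly,Core matrisome,Collagens,Col4a1,36021,P08120,,,FBgn0000299,,
fruit_fly,Core matrisome,ECM Glycoproteins,LanA,40482,P10011,,,FBgn0002526,,
fruit_fly,Core matrisome,ECM Glycoproteins,Tig,38491,A1Z8P0,,,FBgn0011722,,
fruit_fly,Core matrisome,Proteoglycans,Sdc,37288,P49415,,,FBgn0010415,,
fruit_fly,Core matrisome,Proteoglycans,trol,45559,Q9VZZ4,,,FBgn0284408,,
fruit_fly,Matrisome-associated,ECM-affiliated Proteins,Idgf1,33241,Q9V769,,,FBgn0020416,,
fruit_fly,Matrisome-associated,ECM-affiliated Proteins,Hml,39081,Q9VCU8,,,FBgn0029167,,
fruit_fly,Matrisome-associated,ECM Regulators,Mmp1,35151,Q9VYX1,,,FBgn0035049,,
fruit_fly,Matrisome-associated,ECM Regulators,Timp,41603,Q9XZH1,,,FBgn0025879,,
fruit_fly,Matrisome-associated,Secreted Factors,dpp,33432,P07713,,,FBgn0000490,,
fruit_fly,Matrisome-associated,Secreted Factors,spz,43117,P48607,,,FBgn0003495,,
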