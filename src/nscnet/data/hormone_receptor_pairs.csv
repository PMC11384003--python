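ligand,ligand_genes,receptor1,receptor2
Crz,Crz,CrzR,
Dh44,Dh44,Dh44-R1,Dh44-R2
Dh31,Dh31,Dh31-R,
ITP,ITP,Gyc76C,
sNPF,sNPF,sNPF-R,
Ms,Ms,MsR1,MsR2
Hug,Hug,PK2-R1,PK2-R2
Capa,Capa,CapaR,
DILP,Ilp2;Ilp3;Ilp5,InR,
Tk,Tk,TkR86C,TkR99D
Lk,Lk,Lkr,
Akh,Akh,AkhR,
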