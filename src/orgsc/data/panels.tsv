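panel	gene
E	Cdh1
E	Tjp1
E	Cldn3
E	Cldn4
E	Cldn6
E	Cldn7
E	Ocln
E	Krt8
E	Krt18
E	Krt19
E	Col4a1
E	Col4a2
M	Vim
M	S100a4
M	Acta2
M	Fn1
M	Cdh2
M	Col1a1
M	Col1a2
M	Col3a1
S	Pou5f1
S	Sox2
S	Nanog
S	Lin28a
S	Klf4
S	Sall4
S	Tbx3
S	Esrrb
S	Zfp42
S	Utf1
S	Lif
S	Stat3
S	Fgf4
S	Tfcp2l1
S	Dppa3
G1S	Mcm5
G1S	Pcna
G1S	Tyms
G1S	Fen1
G1S	Mcm2
G1S	Mcm4
G1S	Rrm1
G1S	Ung
G1S	Gins2
G1S	Mcm6
G1S	Cdca7
G1S	Dtl
G1S	Prim1
G1S	Uhrf1
G1S	Cenpu
G1S	Hells
G1S	Rfc2
G1S	Rpa2
G1S	Nasp
G1S	Rad51ap1
G1S	Gmnn
G1S	Wdr76
G1S	Slbp
G1S	Ccne2
G1S	Ubr7
G1S	Pold3
G1S	Msh2
G1S	Atad2
G1S	Rad51
G1S	Rrm2
G1S	Cdc45
G1S	Cdc6
G1S	Exo1
G1S	Tipin
G1S	Dscc1
G1S	Blm
G1S	Casp8ap2
G1S	Usp1
G1S	Clspn
G1S	Pola1
G1S	Chaf1b
G1S	Brip1
G1S	E2f8
G2M	Hmgb2
G2M	Cdk1
G2M	Nusap1
G2M	Ube2c
G2M	Birc5
G2M	Tpx2
G2M	Top2a
G2M	Ndc80
G2M	Cks2
G2M	Nuf2
G2M	Cks1b
G2M	Mki67
G2M	Tmpo
G2M	Cenpf
G2M	Tacc3
G2M	Pimreg
G2M	Smc4
G2M	Ccnb2
G2M	Ckap2l
G2M	Ckap2
G2M	Aurkb
G2M	Bub1
G2M	Kif11
G2M	Anp32e
G2M	Tubb4b
G2M	Gtse1
G2M	Kif20b
G2M	Hjurp
G2M	Cdca3
G2M	Jpt1
G2M	Cdc20
G2M	Ttk
G2M	Cdc25c
G2M	Kif2c
G2M	Rangap1
G2M	Ncapd2
G2M	Dlgap5
G2M	Cdca2
G2M	Cdca8
G2M	Ect2
G2M	Kif23
G2M	Hmmr
G2M	Aurka
G2M	Psrc1
G2M	Anln
G2M	Lbr
G2M	Ckap5
G2M	Cenpe
G2M	Ctcf
G2M	Nek2
G2M	G2e3
G2M	Gas2l3
G2M	Cbx5
G2M	Cenpa
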