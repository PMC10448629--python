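source_symbol	target_symbol
CD4	Cd4
CD8A	Cd8a
FOXP3	Foxp3
CD44	Cd44
SELL	Sell
CCR7	Ccr7
KLRB1C	Klrb1c
TRGC1	Tcrg-C1
TRDC	Trdc
LY6C1	Ly6c1
GZMK	Gzmk
S1PR1	S1pr1
CXCR6	Cxcr6
CCR5	Ccr5
SLAMF7	Slamf7
ADGRE5	Adgre5
S100A4	S100a4
S100A6	S100a6
CTSW	Ctsw
LGALS1	Lgals1
REEP5	Reep5
HLA-A	H2-D1
CD8B1	Cd8b1
CST7	Cst7
GZMB	Gzmb
GZMM	Gzmm
IFNG	Ifng
NKG7	Nkg7
PRF1	Prf1
EFHD2	Efhd2
CCL5	Ccl5
CCL4	Ccl4
PDCD1	Pdcd1
TIGIT	Tigit
LAG3	Lag3
HAVCR2	Havcr2
CTLA4	Ctla4
PTPN6	Ptpn6
PTPN11	Ptpn11
PTPN2	Ptpn2
IRF4	Irf4
NR4A1	Nr4a1
GATA3	Gata3
TOX	Tox
BATF	Batf
PRDM1	Prdm1
EOMES	Eomes
IL2RA	Il2ra
STAT5A	Stat5a
IL10	Il10
NRP1	Nrp1
CD83	Cd83
RORC	Rorc
RORA	Rora
IL17A	Il17a
ITGA1	Itga1
ITGAE	Itgae
CD101	Cd101
CD69	Cd69
KLF2	Klf2
KLF3	Klf3
S1PR5	S1pr5
CD80	Cd80
CD86	Cd86
CD40	Cd40
CD274	Cd274
PDCD1LG2	Pdcd1lg2
FAS	Fas
ICOSL	Icosl
LGALS3	Lgals3
CD200	Cd200
MT-CO1	mt-Co1
MT-CO3	mt-Co3
MT-ATP8	mt-Atp8
MT-ND1	mt-Nd1
MT-CYTB	mt-Cytb
ACTB	Actb
B2M	B2m
GAPDH	Gapdh
PGK1	Pgk1
TBP	Tbp
RPL3	Rpl3
RPL4	Rpl4
RPL5	Rpl5
RPL6	Rpl6
RPL7	Rpl7
RPL8	Rpl8
RPL9	Rpl9
RPL10	Rpl10
RPL11	Rpl11
RPL12	Rpl12
RPL13	Rpl13
RPL14	Rpl14
RPL15	Rpl15
RPL16	Rpl16
RPL17	Rpl17
RPL18	Rpl18
RPL19	Rpl19
RPL20	Rpl20
RPL21	Rpl21
RPL22	Rpl22
RPS2	Rps2
RPS3	Rps3
RPS4	Rps4
RPS5	Rps5
RPS6	Rps6
RPS7	Rps7
RPS8	Rps8
RPS9	Rps9
RPS10	Rps10
RPS11	Rps11
RPS12	Rps12
RPS13	Rps13
RPS14	Rps14
RPS15	Rps15
RPS16	Rps16
RPS17	Rps17
RPS18	Rps18
RPS19	Rps19
RPS20	Rps20
RPS21	Rps21
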