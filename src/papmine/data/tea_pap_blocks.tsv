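gene_id	name	block1	block2	block3	block4	block5	domains
CSA004804	CsPAP2		GDISY	GNHE	VQGH	GHVH	MPP_PAPs
CSA005153	CsPAP15b	GDLG	GDVTY	GNHD	ATWH	GHVH	MPP_PAPs;Pur_ac_phosph_N
CSA006013	CsPAP1	GDLG	GDICY	GNHE	FLAH	GHVH	MPP_PAPs;Pur_ac_phosph_N
CSA006536	CsPAP29a	ADMH	GDNIF	GNHD	VYFH	GHDH	MPP_Dcr2
CSA006537	CsPAP29b		GDNIF	GNHD	VYFH	GHDH	MPP_Dcr2
CSA006539	CsPAP29c	ADMH	GDNIF	GNHD	VYFH	GHDH	MPP_Dcr2
CSA008696	CsPAP12	GDLG	GDLSY	GNHE	VLMH	GHVH	MPP_PAPs;Pur_ac_phosph_N
CSA011989	CsPAP15a	GDLG	GDATY	GNHD	ASWH	GHVH	MPP_PAPs;Pur_ac_phosph_N
CSA018804	CsPAP27a	GDMG	GDLSY	GNHE	FAAH	GHVH	MPP_PAPs;Pur_ac_phosph_N;Metallophos_C
CSA019400	CsPAP3b		GDNFY	GNHD	VVGH	GHDH	MPP_ACP5
CSA021776	CsPAP3c	GDMG	GDISY	GNHE	FAGH	GHVH	MPP_PAPs;Pur_ac_phosph_N
CSA026817	CsPAP27c	GDMG	GDIVY	GNHE	FIAH	GHVH	MPP_PAPs;Pur_ac_phosph_N
CSA027593	CsPAP27b	GDMG	GDLPY	GNHE	FAAH	GHVH	MPP_PAPs;Pur_ac_phosph_N
CSA028799	CsPAP10b	GDLG	GDLSY	GNHE	VLMH	GHVH	MPP_PAPs;Pur_ac_phosph_N
CSA030189	CsPAP6a	GDLG	GDLSY	GNHE	VILH	GHVH	MPP_PAPs;Pur_ac_phosph_N
CSA030190	CsPAP6b	GDLG	GDLSY	GNHE	VILH	GHVH	MPP_PAPs;Pur_ac_phosph_N
CSA031017	CsPAP10a	GDLG	GDLSY	GNHE	VLLH	GHVH	MPP_PAPs;Pur_ac_phosph_N
CSA034553	CsPAP3a	GDWG	GDNFY	GNHD	VVGH	GHDH	MPP_ACP5
CSA036115	CsPAP23	GDLG	GDLTY	GNHE	AAWH	GHVH	MPP_PAPs;Pur_ac_phosph_N;Metallophos_C
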