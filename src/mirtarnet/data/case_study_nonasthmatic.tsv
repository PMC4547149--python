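mirna_id	mrna_id	correlation	genmir	mine	targetscan	microrna_org
hp_hsa-mir-3118-5_x_st	ACVR2B	TRUE	TRUE	FALSE	TRUE	FALSE
hsa-let-7b-star_st	ACVR2B	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-9-3_x_st	ADAMTS18	TRUE	TRUE	FALSE	TRUE	TRUE
hsa-let-7b-star_st	ADRB1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-9-3_x_st	AGAP1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-103a-1_st	CACNA2D1	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-92a-2_x_st	CAMK2A	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-181a-2_st	CD4	TRUE	TRUE	TRUE	TRUE	TRUE
hp_hsa-mir-9-3_x_st	CDX2	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-181a-2_st	CECR2	TRUE	TRUE	TRUE	TRUE	TRUE
hp_hsa-mir-320b-2_st	CEP68	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-320b-1_st	CEP68	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-320b-2_st	CLASP2	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-320b-1_st	CLASP2	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-92a-2_x_st	CUL3	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-181a-2_st	CUL3	TRUE	TRUE	TRUE	TRUE	TRUE
hp_hsa-mir-92a-2_x_st	DOCK9	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-4295_st	ESCO2	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-320b-2_st	FAM120C	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-320b-1_st	FAM120C	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-196a-1_st	FAM169A	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-181a-2_st	GABRA4	TRUE	TRUE	TRUE	TRUE	FALSE
hp_hsa-mir-196a-1_st	GCNT4	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-320b-2_st	ID4	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-320b-1_st	ID4	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-103a-1_st	KIAA2018	TRUE	TRUE	FALSE	TRUE	FALSE
hsa-let-7b-star_st	KIF21B	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-3118-5_x_st	MLL2	TRUE	TRUE	FALSE	TRUE	FALSE
hsa-let-7b-star_st	MLL2	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-let-7d_x_st	MOBKL2B	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-320b-2_st	MOBKL2B	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-320b-1_st	MOBKL2B	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-let-7g_st	MOBKL2B	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-181a-2_st	MOBKL2B	TRUE	TRUE	TRUE	TRUE	FALSE
hp_hsa-mir-190_st	NEUROD1	TRUE	TRUE	TRUE	TRUE	TRUE
hp_hsa-mir-92a-2_x_st	PIKFYVE	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-92a-2_x_st	PTF1A	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-181a-2_st	SAMHD1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-92a-2_x_st	SERINC5	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-4295_st	SLC25A32	TRUE	TRUE	FALSE	TRUE	FALSE
hsa-let-7b-star_st	SOCS7	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-222_st	STX1B	TRUE	TRUE	TRUE	TRUE	FALSE
hp_hsa-mir-218-2_st	STX1B	TRUE	TRUE	FALSE	TRUE	FALSE
hsa-let-7b-star_st	TET2	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-let-7g_st	TMPO	TRUE	TRUE	FALSE	TRUE	FALSE
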