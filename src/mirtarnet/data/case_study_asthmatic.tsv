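mirna_id	mrna_id	correlation	genmir	mine	targetscan	microrna_org
hp_hsa-mir-3118-1_x_st	ACVR2B	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-320b-1_st	ACVR2B	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-103a-1_st	ACVR2B	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-3118-6_x_st	ACVR2B	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-320b-2_st	ACVR2B	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-320c-1_x_st	ACVR2B	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-23a_x_st	ACVR2B	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-103a-1_x_st	ACVR2B	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-23a_x_st	DENND1B	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-23a_x_st	ELOVL3	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-4295_st	ERBB4	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-3167_x_st	ERBB4	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-7-2_st	ERBB4	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-7-3_st	ERBB4	TRUE	TRUE	FALSE	TRUE	TRUE
hsa-let-7b-star_st	FAM123C	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-196a-1_st	FAM169A	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-128-1_st	FAM84B	TRUE	TRUE	FALSE	TRUE	TRUE
hsa-let-7b-star_st	FIGN	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-320c-1_st	GNAI1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-320b-1_x_st	GNAI1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-3118-5_x_st	HDX	TRUE	TRUE	FALSE	TRUE	FALSE
hsa-let-7b-star_st	HDX	TRUE	TRUE	FALSE	TRUE	FALSE
hsa-let-7b-star_st	IGF1	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-32_st	LRCH1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-93_st	LRCH1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-3118-5_x_st	MAGI2	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-190_st	MAGI2	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-190_x_st	MAGI2	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-320d-1_st	NRN1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-320b-1_st	NRN1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-320b-2_st	NRN1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-320c-1_x_st	NRN1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-4295_st	NRSN1	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-93_st	NRSN1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-7-2_st	NRSN1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-7-3_st	NRSN1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-3118-5_x_st	ODZ2	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-23a_x_st	PAK6	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-320c-2_x_st	PLXNC1	TRUE	TRUE	TRUE	TRUE	TRUE
hp_hsa-mir-320c-1_st	PLXNC1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-320b-1_x_st	PLXNC1	TRUE	TRUE	FALSE	TRUE	TRUE
hsa-let-7b-star_st	PLXNC1	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-320c-1_st	PPARGC1B	TRUE	TRUE	FALSE	TRUE	FALSE
hsa-let-7b-star_st	PPARGC1B	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-30c-2_x_st	PRUNE2	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-708_st	PRUNE2	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-329-1_s_st	PRUNE2	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-454_st	PRUNE2	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-196a-1_st	PRUNE2	TRUE	TRUE	FALSE	TRUE	TRUE
hsa-let-7b-star_st	SLC25A18	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-320c-1_st	TFCP2L1	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-9-3_st	TINAGL1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-9-3_x_st	TINAGL1	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-133a-2_s_st	TPD52	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-320c-1_x_st	TPD52	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-133a-2_s_st	TRIM55	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-218-1_st	ZC3H6	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-31_st	ZC3H6	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-23a_x_st	ZC3H6	TRUE	TRUE	FALSE	TRUE	FALSE
hp_hsa-mir-320c-1_st	ZDHHC21	TRUE	TRUE	FALSE	TRUE	TRUE
hp_hsa-mir-320b-1_x_st	ZDHHC21	TRUE	TRUE	FALSE	TRUE	TRUE
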