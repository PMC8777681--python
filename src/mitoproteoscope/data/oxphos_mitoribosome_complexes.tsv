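# mitoproteoscope v0.1.0
accession	complex
MT-ND1	CI
MT-ND2	CI
MT-ND3	CI
MT-ND4	CI
MT-ND4L	CI
MT-ND5	CI
MT-ND6	CI
NDUFV1	CI
NDUFV2	CI
NDUFV3	CI
NDUFS1	CI
NDUFS2	CI
NDUFS3	CI
NDUFS4	CI
NDUFS5	CI
NDUFS6	CI
NDUFS7	CI
NDUFS8	CI
NDUFA1	CI
NDUFA2	CI
NDUFA3	CI
NDUFA5	CI
NDUFA6	CI
NDUFA7	CI
NDUFA8	CI
NDUFA9	CI
NDUFA10	CI
NDUFA11	CI
NDUFA12	CI
NDUFA13	CI
NDUFAB1	CI
NDUFB1	CI
NDUFB2	CI
NDUFB3	CI
NDUFB4	CI
NDUFB5	CI
NDUFB6	CI
NDUFB7	CI
NDUFB8	CI
NDUFB9	CI
NDUFB10	CI
NDUFB11	CI
NDUFC1	CI
NDUFC2	CI
SDHA	CII
SDHB	CII
SDHC	CII
SDHD	CII
MT-CYB	CIII
UQCRC1	CIII
UQCRC2	CIII
CYC1	CIII
UQCRFS1	CIII
UQCRB	CIII
UQCRQ	CIII
UQCRH	CIII
UQCR10	CIII
UQCR11	CIII
MT-CO1	CIV
MT-CO2	CIV
MT-CO3	CIV
COX4I1	CIV
COX5A	CIV
COX5B	CIV
COX6A1	CIV
COX6B1	CIV
COX6C	CIV
COX7A2	CIV
COX7B	CIV
COX7C	CIV
COX8A	CIV
NDUFA4	CIV
MT-ATP6	CV
MT-ATP8	CV
ATP5F1A	CV
ATP5F1B	CV
ATP5F1C	CV
ATP5F1D	CV
ATP5F1E	CV
ATP5PB	CV
ATP5PD	CV
ATP5PF	CV
ATP5PO	CV
ATP5MC1	CV
ATP5MC2	CV
ATP5MC3	CV
ATP5ME	CV
ATP5MF	CV
ATP5MG	CV
ATP5IF1	CV
MRPL1	LSU
MRPL2	LSU
MRPL3	LSU
MRPL4	LSU
MRPL9	LSU
MRPL10	LSU
MRPL11	LSU
MRPL12	LSU
MRPL13	LSU
MRPL14	LSU
MRPL15	LSU
MRPL16	LSU
MRPL17	LSU
MRPL18	LSU
MRPL19	LSU
MRPL20	LSU
MRPL21	LSU
MRPL22	LSU
MRPL23	LSU
MRPL24	LSU
MRPL27	LSU
MRPL28	LSU
MRPL30	LSU
MRPL32	LSU
MRPL33	LSU
MRPL34	LSU
MRPL35	LSU
MRPL36	LSU
MRPL37	LSU
MRPL38	LSU
MRPL39	LSU
MRPL40	LSU
MRPL41	LSU
MRPL42	LSU
MRPL43	LSU
MRPL44	LSU
MRPL45	LSU
MRPL46	LSU
MRPL47	LSU
MRPL48	LSU
MRPL49	LSU
MRPL50	LSU
MRPL51	LSU
MRPL52	LSU
MRPL53	LSU
MRPL54	LSU
MRPL55	LSU
MRPL57	LSU
MRPL58	LSU
MRPS2	SSU
MRPS5	SSU
MRPS6	SSU
MRPS7	SSU
MRPS9	SSU
MRPS10	SSU
MRPS11	SSU
MRPS12	SSU
MRPS14	SSU
MRPS15	SSU
MRPS16	SSU
MRPS17	SSU
MRPS18A	SSU
MRPS18B	SSU
MRPS18C	SSU
MRPS21	SSU
MRPS22	SSU
MRPS23	SSU
MRPS24	SSU
MRPS25	SSU
MRPS26	SSU
MRPS27	SSU
MRPS28	SSU
MRPS30	SSU
MRPS31	SSU
MRPS33	SSU
MRPS34	SSU
MRPS35	SSU
MRPS36	SSU
DAP3	SSU
PTCD3	SSU
AURKAIP1	SSU
CHCHD1	SSU
ERAL1	SSU
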