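# Published per-interaction H-bond rupture free energies (PMF_HB_break, kcal/mol)
# for the CRBN–SALL4 zinc-finger-2 interface, without glue (binary) and with each
# IMiD (pomalidomide POM, lenalidomide LEN, thalidomide THA).  Transcribed from
# the source study's summary table; uncertainties are 50-fold bootstrap sds.
# reference_condition: CRBN-SALL4
interaction_id	condition	value	sd
CRBN_W400-SALL4_C415	CRBN-SALL4	1.3	0.2
CRBN_H357-SALL4_V414	CRBN-SALL4	2.7	0.3
CRBN_N351-SALL4_S413	CRBN-SALL4	3.2	0.3
CRBN_W400-SALL4_C415	CRBN-SALL4-POM	7.0	0.3
CRBN_H357-SALL4_V414	CRBN-SALL4-POM	6.3	0.3
CRBN_N351-SALL4_S413	CRBN-SALL4-POM	9.0	0.1
CRBN_W400-SALL4_C415	CRBN-SALL4-LEN	3.9	0.7
CRBN_H357-SALL4_V414	CRBN-SALL4-LEN	5.0	0.5
CRBN_N351-SALL4_S413	CRBN-SALL4-LEN	9.0	0.2
CRBN_W400-SALL4_C415	CRBN-SALL4-THA	6.2	0.7
CRBN_H357-SALL4_V414	CRBN-SALL4-THA	7.8	0.1
CRBN_N351-SALL4_S413	CRBN-SALL4-THA	8.5	0.3
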