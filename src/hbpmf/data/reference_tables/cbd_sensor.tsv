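# Published per-interaction H-bond rupture free energies (PMF_HB_break, kcal/mol)
# for the CA14–DB21 dual-nanobody cannabidiol sensor, without (binary) and with
# cannabidiol (CBD).  Only the six interactions that passed the significance and
# correlation screens are listed, as published.  Uncertainties are 50-fold
# bootstrap sds.
# reference_condition: CA14-DB21
interaction_id	condition	value	sd
CA14_P59-DB21_Y61	CA14-DB21	2.6	0.4
CA14_Q58com-DB21_F48com	CA14-DB21	4.2	0.2
CA14_D34com-DB21_R46	CA14-DB21	4.7	0.2
CA14_K101-DB21_E108com	CA14-DB21	8.1	0.2
CA14_N106-DB21_E108_1	CA14-DB21	4.8	0.1
CA14_N106-DB21_E108_2	CA14-DB21	10.8	0.4
CA14_P59-DB21_Y61	CA14-DB21-CBD	6.8	0.3
CA14_Q58com-DB21_F48com	CA14-DB21-CBD	6.8	0.3
CA14_D34com-DB21_R46	CA14-DB21-CBD	6.1	0.5
CA14_K101-DB21_E108com	CA14-DB21-CBD	10.2	0.8
CA14_N106-DB21_E108_1	CA14-DB21-CBD	5.6	0.1
CA14_N106-DB21_E108_2	CA14-DB21-CBD	14.1	0.3
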