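# Published per-interaction H-bond rupture free energies (PMF_HB_break, kcal/mol)
# for the 14-3-3σ–SSBP4 interface, in the glue-free conformation (non-FC-A) and
# with Fusicoccin A (FC-A).  The phospho-S384 row aggregates the three contacts
# of phosphorylated S384 with R56/R129/Y130 measured through a coordination-count
# collective variable.  Two interactions correlated with retained ones are
# omitted, as published.  Uncertainties are 50-fold bootstrap sds.
# reference_condition: 14-3-3s-SSBP4
interaction_id	condition	value	sd
14-3-3s_R56.R129.Y130-SSBP4_pS384	14-3-3s-SSBP4	19.5	0.9
14-3-3s_K49-SSBP4_V385com	14-3-3s-SSBP4	2.1	0.2
14-3-3s_N175com-SSBP4_V385com	14-3-3s-SSBP4	6.2	0.2
14-3-3s_N226com-SSBP4_M383com	14-3-3s-SSBP4	5.2	0.2
14-3-3s_R56.R129.Y130-SSBP4_pS384	14-3-3s-SSBP4-FCA	26.1	0.6
14-3-3s_K49-SSBP4_V385com	14-3-3s-SSBP4-FCA	3.3	0.2
14-3-3s_N175com-SSBP4_V385com	14-3-3s-SSBP4-FCA	7.7	0.5
14-3-3s_N226com-SSBP4_M383com	14-3-3s-SSBP4-FCA	7.6	0.3
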