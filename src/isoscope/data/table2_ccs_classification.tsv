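# Published CCS read classification counts per library (same study)
library	n_ccs	n_5p	n_3p	n_polya	n_fl	n_flnc	mean_flnc_len
F 0-2k	427494	386518	387826	367398	347788	327713	1675
F 2k+	337154	286996	288005	269671	244810	239600	3124
M 0-2k	400518	352792	356931	333916	312660	296777	1572
M 2k+	371683	304514	310103	288588	259044	257442	2856
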