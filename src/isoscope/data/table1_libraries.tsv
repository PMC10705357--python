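# Published per-library sequencing statistics (P. sinensis full-length transcriptome; F/M = sex, 0-2k/2k+ = size fraction)
library	total_bases_bp	rois	mean_length_bp	read_n50
F 0-2k	12461189105	661271	18844	42250
F 2k+	10011411220	686536	14582	33750
M 0-2k	10292266219	680809	15118	36750
M 2k+	10677216778	752012	14198	32750
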