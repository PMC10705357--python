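# Published gene-locus length-bin counts (same study). The 2000-3000 bin was
# printed as 8682, which is inconsistent with the stated 30,670 locus total and
# with all four printed percentages; 8628 (digit transposition) reconciles both
# (8628/30670 = 28.13%, column sum = 30670) and is used here.
bin	count
<1000	2096
1000-2000	8975
2000-3000	8628
>3000	10971
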