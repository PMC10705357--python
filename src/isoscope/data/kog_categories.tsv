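# Published KOG functional classification counts; the four largest named
# categories are listed individually, the remaining 22 are aggregated.
category	count
General function prediction only	202
Signal transduction mechanisms	180
Post-translational modification, protein turnover, chaperones	139
Cytoskeleton	85
Other categories (22, aggregated)	463
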