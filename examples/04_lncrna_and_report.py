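"""lncRNA filtering/classification and replay of published summary tables.

The lncRNA cascade keeps transcripts >= 200 bp with no protein-database
hit and low coding potential, then classifies them as intergenic,
intronic, sense, antisense or other. The report module also replays the
bundled published tables of a P. sinensis full-length transcriptome
study.
"""

from pathlib import Path

from isoscope import io as iio
from isoscope.isoforms import (
    annotate_junction_support, apply_retention_filter, collapse,
    filter_degraded, partition_split_reads,
)
from isoscope.lncrna import classify_candidates, filter_lncrna, length_summary
from isoscope.report import aggregate_library_stats, category_shares, load_table
from isoscope.sim import SimConfig, simulate, translate_evidence

outdir = Path("scratch/example04") if Path("scratch").exists() else Path("example04_out")
res = simulate(SimConfig(seed=4), outdir)

simple, _ = partition_split_reads(iio.read_alignments(res.alignments_sam))
kept, _ = filter_degraded(collapse(simple))
annotate_junction_support(kept, res.annotation.junction_set())
kept, _ = apply_retention_filter(kept)
ev = translate_evidence(iio.read_tsv(res.evidence_tsv), res.truth, kept)
cands = classify_candidates(
    filter_lncrna(kept, ev), {i.id: i for i in kept}, res.annotation
)
print(f"{len(cands)} lncRNA candidates:")
for c in cands:
    print(f"  {c.isoform_id}: {c.length} bp, {c.positional_class}")
means, bins = length_summary(cands)
print("\nlength bins:\n" + bins.to_string(index=False))

print("\nreplayed published library totals:")
t1 = load_table("table1_libraries")
print(aggregate_library_stats(t1, ["total_bases_bp", "rois"]).to_string())
print("\nKOG category shares (largest named category drives annotation):")
print(category_shares(load_table("kog_categories")).to_string(index=False))
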