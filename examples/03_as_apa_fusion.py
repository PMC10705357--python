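"""Alternative splicing, polyadenylation sites and fusion transcripts.

AS events are classified between isoform pairs of one locus into ten
categories (SKIP/MSKIP/IR/MIR/AE and their approximate X variants);
APA sites are clustered from read 3' ends (5 bp grouping, >= 2 reads,
15 bp exclusion); fusion candidates must hit two genes >= 10 kb apart
with > 10% coverage each, > 99% combined, and paired-end support.
"""

from pathlib import Path

from isoscope import io as iio
from isoscope.apa import apa_gene_stats, detect_apa_all, ends_from_alignments
from isoscope.events import classify_locus, summarize_events
from isoscope.fusion import call_fusions, fusion_gene_summary
from isoscope.isoforms import assign_loci, collapse, filter_degraded, partition_split_reads
from isoscope.sim import SimConfig, simulate

outdir = Path("scratch/example03") if Path("scratch").exists() else Path("example03_out")
res = simulate(
    SimConfig(seed=3, frac_noncoding_genes=0.0, reads_per_isoform=(6, 8),
              frac_fusion_reads=0.05),
    outdir,
)

simple, split = partition_split_reads(iio.read_alignments(res.alignments_sam))
kept, _ = filter_degraded(collapse(simple))
loci = assign_loci(kept)

by_locus = {}
for iso in kept:
    by_locus.setdefault(iso.locus_id, []).append(iso)
events = [e for isos in by_locus.values() for e in classify_locus(isos)[0]]
print("AS events by category (deduplicated per locus):")
print(summarize_events(events).to_string(index=False))

spans = {l.id: (l.chrom, l.strand, l.span) for l in loci}
sites = detect_apa_all(ends_from_alignments(simple, spans))
stats = apa_gene_stats([s for ss in sites.values() for s in ss])
print(f"\nAPA: {stats.attrs['n_sites_total']} sites in {stats.attrs['n_genes']} loci; "
      f"{stats.attrs['n_multi_apa_genes']} loci use more than one site")

pe = {
    tuple(sorted((r.gene_a, r.gene_b))): int(r.pe_count)
    for r in iio.read_tsv(res.pe_support_tsv).itertuples()
}
cands = call_fusions(split, res.annotation, pe)
s = fusion_gene_summary(cands)
print(f"\nfusions: {s['n_fusion_events']} reads pass all four criteria, "
      f"{s['n_distinct_genes']} genes involved, "
      f"{s['inter_chromosomal_fraction']:.0%} inter-chromosomal")
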