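"""Discover intergenic sRNAs, antisense RNAs and small-ORF mRNAs.

Expressed runs on the TEX-untreated coverage are intersected with
intergenic space, filtered for abundance (more than 50 raw reads) and for
independence from flanking mRNAs, then classified: antisense to a CDS,
antisense to a UTR, small-ORF mRNA (30-99 aa with a Shine-Dalgarno lead),
or trans-encoded sRNA candidate.
"""

import primarytx as px
from primarytx.pipeline import call_tss
from primarytx.srna_discovery import classify_segments, segment_igrs, segment_table
from primarytx.transcript_annotation import assign_utrs

params = px.SimulationParams(seed=42)
genome, truth = px.generate_genome(params)
libs = px.simulate_libraries(genome, truth, params)

tss, _ = call_tss(genome, libs)
utrs = assign_utrs(tss, genome.genes)
tex_minus = [l for l in libs if not l.tex]
segments = classify_segments(segment_igrs(tex_minus, genome),
                             genome.genes, utrs, genome)

print(segment_table(segments).to_string(index=False))
n = {c: sum(1 for s in segments if s.seg_class == c)
     for c in ("srna_candidate", "asRNA_cds", "asRNA_utr", "small_orf_mrna")}
print(f"\n{len(segments)} segments: {n}")
print("flags: excludon-like =", [f"{s.start}-{s.end}" for s in segments
                                 if "excludon_like" in s.flags],
      "| 3'UTR-derived =", [f"{s.start}-{s.end}" for s in segments
                            if "three_prime_utr_derived" in s.flags])
# an excludon-like segment is a long antisense RNA spanning two genes on the
# opposite strand; a 3'UTR-derived sRNA starts inside the 3' region of the
# upstream gene.
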