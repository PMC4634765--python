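"""Map the 5'UTR landscape: leaderless mRNAs, long UTRs, +1 composition.

The 5'UTR of each gene is the distance from its primary TSS to the
annotated start codon.  UTRs shorter than 10 nt mark leaderless mRNAs
(translated without a ribosome-binding leader); UTRs longer than 100 nt
may harbour cis-regulatory elements, and those longer than 70 nt are
exported as riboswitch-search candidates.
"""

import primarytx as px
from primarytx.pipeline import call_tss
from primarytx.transcript_annotation import (
    assign_utrs, flag_riboswitch_candidates, plus_one_composition, utr_histogram,
)

params = px.SimulationParams(seed=42)
genome, truth = px.generate_genome(params)
libs = px.simulate_libraries(genome, truth, params)
tss, _ = call_tss(genome, libs)

utrs = assign_utrs(tss, genome.genes)
print(f"5'UTRs assigned for {len(utrs)} genes")
print(utr_histogram(utrs).to_string(index=False))

leaderless = sorted(r.gene_id for r in utrs if r.utr_class == "leaderless")
print(f"leaderless mRNAs (<10 nt): {leaderless}")
long_utr = sorted(r.gene_id for r in utrs if r.utr_class == "long")
print(f"long 5'UTRs (>100 nt): {long_utr}")

flagged = flag_riboswitch_candidates(utrs, genome.genes, genome)
print(f"riboswitch-search candidates (UTR > 70 nt): {[g for g, _ in flagged]}")

comp = plus_one_composition(tss, genome)
print(f"+1 composition: purine fraction {comp['purine']:.2f} "
      "(transcription initiates preferentially on A/G)")
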