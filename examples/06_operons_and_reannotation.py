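"""Validate predicted operons and correct mis-annotated start codons.

An operon prediction is validated when every junction between adjacent
genes keeps at least half the coverage of the weaker flanking gene in some
TEX-untreated library.  A gene inside a predicted operon that fires its own
primary TSS while its upstream junction is silent is transcribed
monocistronically in that sample.  Separately, internal TSSs found within
50 bp downstream of an annotated start codon trigger a scan for the true
start (40-100 bp downstream of the TSS, led by a Shine-Dalgarno match).
"""

import primarytx as px
from primarytx.pipeline import analyze
from primarytx.transcript_annotation import reannotation_table

params = px.SimulationParams(seed=42)
genome, truth = px.generate_genome(params)
libs = px.simulate_libraries(genome, truth, params)

res = analyze(genome, libs, operons=truth.predicted_operons)

for r in res.operons:
    support = ", ".join(f"{s:.2f}" for s in r.junction_support)
    mono = {g: v for g, v in r.monocistronic_members.items()}
    print(f"{r.operon_id}: genes={r.gene_ids} junction support=[{support}] "
          f"validated={r.validated} monocistronic={mono or '-'}")
# opC2's own TSS fires only at middle stationary phase (the #9h samples):
# the operon is polycistronic early and switches to monocistronic later.

print("\nproposed start-codon corrections:")
print(reannotation_table(res.reannotations).to_string(index=False))
print("each proposal moves the start 40-100 bp downstream of the internal "
      "TSS, onto an ATG/GTG/TTG with a ribosome-binding site ~7 bp upstream")
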