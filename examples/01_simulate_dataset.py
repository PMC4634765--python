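"""Generate a synthetic dRNA-seq dataset with planted ground truth.

Builds the default 50-kb scene (60 genes, 82 transcripts) and simulates the
twelve libraries: six samples (four media x two stationary-phase time
points), each split into a TEX-treated and an untreated half.  Everything is
written as plain FASTA/GFF3/BED plus a JSON truth file.
"""

from collections import Counter

import primarytx as px

params = px.SimulationParams(seed=42)
genome, truth, libs = px.simulate_dataset(params, "example_output/dataset")

print(f"genome: {len(genome):,} nt, {len(genome.genes)} genes")
print(f"transcripts planted: {len(truth.transcripts)}")
print("planted TSS categories:", dict(Counter(
    "+".join(sorted(e.categories)) for e in truth.tss)))
print(f"libraries: {len(libs)}, {libs[0].total_mapped:,} reads each")
print("library ids:", ", ".join(l.library_id for l in libs[:4]), "...")

# Each planted TSS records the TEX+ 5'-end height the detector should see.
weakest = min(e.expected_height_rpm for e in truth.tss)
print(f"weakest planted TSS: {weakest:.0f} RPM "
      "(reads-per-million 5'-end height in its best TEX+ library)")
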