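"""Call transcription start sites by TEX enrichment and classify them.

A position is a TSS candidate when its TEX+ 5'-end height, the coverage
step relative to the upstream neighbour, and the TEX+/TEX- enrichment ratio
all clear their thresholds.  Candidates are clustered across the six
samples and classified against the annotation into primary / secondary /
internal / antisense / orphan.
"""

from collections import Counter

import primarytx as px
from primarytx.pipeline import call_tss
from primarytx.synthetic_data import evaluate_calls

params = px.SimulationParams(seed=42)
genome, truth = px.generate_genome(params)
libs = px.simulate_libraries(genome, truth, params)

tss, _cov = call_tss(genome, libs)

print(f"called {len(tss)} TSSs "
      f"({sum(1 for t in tss if len(t.detected_samples) == 6)} seen in all six samples)")
print("category counts:", dict(Counter(c for t in tss for c in t.categories)))

ev = evaluate_calls([(t.pos, t.strand) for t in tss],
                    [(e.pos, e.strand) for e in truth.tss], tolerance_nt=1)
print(f"vs planted truth (+-1 nt): recall {ev['recall']:.3f}, "
      f"precision {ev['precision']:.3f}")
# recall = fraction of planted TSSs recovered; precision = fraction of calls
# that correspond to a planted site.
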