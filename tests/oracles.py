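"""Independent brute-force reference implementations used as test oracles.

These deliberately re-derive results with naive per-element loops, written
against the rules directly rather than sharing code with the package.
"""

from __future__ import annotations

import math


def brute_classify(tss_list, genes, primary_window=500, antisense_window=100):
    """Exhaustive all-pairs TSS classification.

    ``tss_list``: (pos, strand, height) tuples; ``genes``: objects with
    id/start/end/strand.  Returns a list of (category set, link set) in input
    order, where links are (gene_id, category) pairs.
    """
    cats = [set() for _ in tss_list]
    links = [set() for _ in tss_list]
    for gi, g in enumerate(genes):
        gene_start = g.start if g.strand == "+" else g.end
        candidates = []
        for i, (pos, strand, height) in enumerate(tss_list):
            if strand == g.strand:
                d_up = gene_start - pos if g.strand == "+" else pos - gene_start
                if 0 <= d_up <= primary_window:
                    candidates.append(i)
                if g.start < pos < g.end:
                    cats[i].add("internal")
                    links[i].add((g.id, "internal"))
            else:
                if g.start - antisense_window <= pos <= g.end + antisense_window:
                    cats[i].add("antisense")
                    links[i].add((g.id, "antisense"))
        if candidates:
            def rank(i):
                pos = tss_list[i][0]
                upstream = -pos if g.strand == "+" else pos
                return (tss_list[i][2], upstream)
            best = max(candidates, key=rank)
            for i in candidates:
                cat = "primary" if i == best else "secondary"
                cats[i].add(cat)
                links[i].add((g.id, cat))
    for c in cats:
        if not c:
            c.add("orphan")
    return list(zip(cats, links))


def brute_de_passes(rpkm_a, rpkm_b, raw_a, min_fold=2.0, min_rpkm=2.0, min_raw=50):
    """The three-filter differential-expression rule, spelled out."""
    if rpkm_b > 0:
        fold = rpkm_a / rpkm_b
    elif rpkm_a > 0:
        fold = math.inf
    else:
        fold = 0.0
    return fold > min_fold and rpkm_a > min_rpkm and raw_a > min_raw


def brute_count_overlaps(reads, genes):
    """All-pairs same-strand >=1 nt overlap counting."""
    counts = {g.id: 0 for g in genes}
    for (rs, re_, strand) in reads:
        for g in genes:
            if strand == g.strand and rs <= g.end and re_ >= g.start:
                counts[g.id] += 1
    return counts


def brute_coverage(reads, genome_length):
    """Per-position loop over reads: full and 5'-end counts per strand."""
    full = {"+": [0.0] * genome_length, "-": [0.0] * genome_length}
    end5 = {"+": [0.0] * genome_length, "-": [0.0] * genome_length}
    for (rs, re_, strand) in reads:
        for p in range(rs, re_ + 1):
            full[strand][(p - 1) % genome_length] += 1
        five = rs if strand == "+" else re_
        end5[strand][(five - 1) % genome_length] += 1
    return full, end5


def brute_segment_strand(cov, in_gene, min_cov, max_gap, floor):
    """Reference IGR segmentation for one strand (0-based arrays in, 1-based out).

    Mirrors the published rule chain position by position: threshold runs
    with gap bridging, valley split at the stray-read floor, intersection
    with intergenic space, discard of gene-contiguous extensions, and
    boundary trim at the floor.
    """
    n = len(cov)
    expressed = [c >= min_cov for c in cov]

    def runs(mask, gap):
        out, start, last = [], None, None
        for i, m in enumerate(mask):
            if m:
                if start is None:
                    start = i
                elif i - last > gap + 1:
                    out.append((start, last))
                    start = i
                last = i
        if start is not None:
            out.append((start, last))
        return out

    segments = []
    for a, b in runs(expressed, max_gap):
        submask = [a <= i <= b and cov[i] >= floor for i in range(n)]
        for sa, sb in runs(submask, max_gap):
            igr_mask = [sa <= i <= sb and not in_gene[i] for i in range(n)]
            for pa, pb in runs(igr_mask, 0):
                contiguous = False
                if pa - 1 >= 0 and in_gene[pa - 1] and expressed[pa - 1] and expressed[pa]:
                    contiguous = True
                if pb + 1 < n and in_gene[pb + 1] and expressed[pb + 1] and expressed[pb]:
                    contiguous = True
                if contiguous:
                    continue
                keep = [i for i in range(pa, pb + 1) if cov[i] >= floor]
                if keep:
                    segments.append((keep[0] + 1, keep[-1] + 1))
    return segments
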