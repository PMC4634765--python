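"""Validation of predicted operons against dRNA-seq coverage continuity.

A predicted polycistron is accepted when, for every adjacent gene pair, the
minimum coverage across the junction holds at least ``alpha`` of the mean
coverage of the weaker flanking gene in at least one TEX-untreated library
(TEX+ libraries are unsuitable: the treatment depletes internal processed
coverage).  Genes inside a predicted operon that fire their own primary TSS
in a sample where the upstream junction is unsupported are reported as
monocistronically transcribed in that sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import CoverageTracks, Gene, GenomeModel
from .tss_core import AnnotatedTSS


@dataclass
class OperonRecord:
    operon_id: str
    gene_ids: list[str]
    junction_support: list[float] = field(default_factory=list)  # best library, per pair
    junction_support_by_library: list[dict[str, float]] = field(default_factory=list)
    validated: bool = False
    monocistronic_members: dict[str, list[str]] = field(default_factory=dict)  # gene -> samples
    shared_primary_tss: bool = False  # first gene owns a primary TSS upstream of the operon


def read_operon_table(path: str | Path) -> list[tuple[str, list[str]]]:
    """Predicted operons from TSV (operon_id, comma-joined gene ids)."""
    df = pd.read_csv(path, sep="\t")
    if not {"operon_id", "gene_ids"} <= set(df.columns):
        raise ValueError("operon table must have columns operon_id, gene_ids")
    return [(str(r["operon_id"]), str(r["gene_ids"]).split(",")) for _, r in df.iterrows()]


def write_operon_table(records: list[OperonRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "operon_id": r.operon_id,
            "gene_ids": ",".join(r.gene_ids),
            "junction_support": ",".join(f"{s:.3f}" for s in r.junction_support),
            "validated": r.validated,
            "shared_primary_tss": r.shared_primary_tss,
            "monocistronic_members": ";".join(
                f"{g}:{','.join(samples)}" for g, samples in sorted(r.monocistronic_members.items())
            ),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _ordered_genes(gene_ids: list[str], genome: GenomeModel) -> list[Gene]:
    genes = [genome.gene(gid) for gid in gene_ids]
    strands = {g.strand for g in genes}
    if len(strands) != 1:
        raise ValueError(f"operon genes must share a strand, got {strands}")
    reverse = strands == {"-"}
    return sorted(genes, key=lambda g: g.start, reverse=reverse)


def _junction_span(g_left: Gene, g_right: Gene) -> tuple[int, int]:
    """Chromosomal positions between two adjacent genes (boundary bases if they abut)."""
    lo = min(g_left.end, g_right.end)
    hi = max(g_left.start, g_right.start)
    if hi - lo >= 2:
        return lo + 1, hi - 1
    return lo, hi  # abutting or overlapping: use the boundary positions themselves


def _support(g_a: Gene, g_b: Gene, tracks: CoverageTracks, denominator: str = "weaker") -> float:
    """Ratio of minimum junction coverage to a flanking-gene mean.

    ``denominator`` is the weaker flanking gene for continuity validation,
    or the downstream gene (``g_b``) when testing whether that gene's
    transcription arrives through the junction at all.
    """
    full = tracks.full(g_a.strand)
    j_lo, j_hi = _junction_span(g_a, g_b)
    junction_min = float(full[j_lo - 1 : j_hi].min())
    means = [float(full[g.start - 1 : g.end].mean()) for g in (g_a, g_b)]
    ref = min(means) if denominator == "weaker" else means[1]
    if ref <= 0:
        return 0.0
    return junction_min / ref


def validate_operon(
    operon_id: str,
    gene_ids: list[str],
    genome: GenomeModel,
    coverage_by_library: dict[str, CoverageTracks],
    alpha: float = 0.5,
    tss_set: list[AnnotatedTSS] | None = None,
) -> OperonRecord:
    """Score one predicted operon; ``coverage_by_library`` maps TEX- library
    ids to normalized tracks.  Single-gene predictions are rejected."""
    if len(gene_ids) < 2:
        raise ValueError(f"operon {operon_id}: not polycistronic ({len(gene_ids)} gene)")
    genes = _ordered_genes(gene_ids, genome)
    record = OperonRecord(operon_id=operon_id, gene_ids=[g.id for g in genes])
    for g_a, g_b in zip(genes[:-1], genes[1:]):
        by_lib = {lib: _support(g_a, g_b, tracks) for lib, tracks in coverage_by_library.items()}
        record.junction_support_by_library.append(by_lib)
        record.junction_support.append(max(by_lib.values()) if by_lib else 0.0)
    record.validated = all(s >= alpha for s in record.junction_support)
    if tss_set is not None:
        record.shared_primary_tss = any(
            (g := genes[0]).id in {gid for gid, cat, _ in t.gene_links if cat == "primary"}
            for t in tss_set
        )
    return record


def detect_monocistronic(
    record: OperonRecord,
    tss_set: list[AnnotatedTSS],
    genome: GenomeModel,
    coverage_by_sample: dict[str, CoverageTracks],
    alpha: float = 0.5,
) -> OperonRecord:
    """Internal operon genes transcribed as their own unit in some sample.

    A gene (not the first of the operon) is monocistronic in sample ``s``
    when it owns a primary TSS detected in ``s`` and the junction to its
    upstream neighbour has support below ``alpha`` in that sample's TEX-
    library.  Support here is measured against the gene's own mean coverage
    (not the weaker flank): the question is whether this gene's
    transcription arrives through the junction, and residual expression of
    the upstream gene must not mask an alternative TSS.
    ``coverage_by_sample`` maps sample names to TEX- tracks.
    """
    genes = _ordered_genes(record.gene_ids, genome)
    primary_tss_of: dict[str, AnnotatedTSS] = {}
    for t in tss_set:
        for gid, cat, _d in t.gene_links:
            if cat == "primary":
                primary_tss_of[gid] = t
    record.monocistronic_members = {}
    for i, g in enumerate(genes[1:], start=1):
        t = primary_tss_of.get(g.id)
        if t is None:
            continue
        hit_samples = []
        for sample, tracks in coverage_by_sample.items():
            if sample not in t.detected_samples:
                continue
            if _support(genes[i - 1], g, tracks, denominator="downstream") < alpha:
                hit_samples.append(sample)
        if hit_samples:
            record.monocistronic_members[g.id] = sorted(hit_samples)
    return record


def validate_operons(
    operons: list[tuple[str, list[str]]],
    genome: GenomeModel,
    coverage_by_library: dict[str, CoverageTracks],
    alpha: float = 0.5,
    tss_set: list[AnnotatedTSS] | None = None,
    coverage_by_sample: dict[str, CoverageTracks] | None = None,
) -> list[OperonRecord]:
    records = []
    for operon_id, gene_ids in operons:
        rec = validate_operon(operon_id, gene_ids, genome, coverage_by_library, alpha, tss_set)
        if tss_set is not None and coverage_by_sample is not None:
            rec = detect_monocistronic(rec, tss_set, genome, coverage_by_sample, alpha)
        records.append(rec)
    return records
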