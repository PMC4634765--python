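"""High-level orchestration: from libraries to a fully annotated transcriptome.

This module wires the analysis stages together the way the CLI and the
bundled examples use them; each stage remains callable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_model import CoverageTracks, GenomeModel, LibraryAlignments, count_reads, coverage
from .tss_core import (
    AnnotatedTSS,
    ClassificationParams,
    TSSDetectionParams,
    classify_tss,
    cluster_tss,
    detect_sample_tss,
)
from .transcript_annotation import (
    ReannotationParams,
    ReannotationProposal,
    UTRParams,
    UTRRecord,
    assign_utrs,
    propose_reannotation,
)
from .expression_de import DEParams, DEResult, STANDARD_COMPARISONS, differential_genes
from .srna_discovery import IGRSegment, SrnaParams, classify_segments, segment_igrs
from .operon_validation import OperonRecord, validate_operons


@dataclass
class AnalysisResult:
    tss: list[AnnotatedTSS]
    coverage_by_library: dict[str, CoverageTracks]
    utrs: list[UTRRecord] = field(default_factory=list)
    reannotations: list[ReannotationProposal] = field(default_factory=list)
    segments: list[IGRSegment] = field(default_factory=list)
    operons: list[OperonRecord] = field(default_factory=list)
    de: dict[str, list[DEResult]] = field(default_factory=dict)
    expression: dict[str, pd.DataFrame] = field(default_factory=dict)


def pair_libraries(libs: list[LibraryAlignments]) -> dict[str, tuple[LibraryAlignments, LibraryAlignments]]:
    """Map each sample to its (TEX+, TEX-) library pair."""
    by_sample: dict[str, dict[bool, LibraryAlignments]] = {}
    for lib in libs:
        by_sample.setdefault(lib.sample, {})[lib.tex] = lib
    pairs = {}
    for sample, d in by_sample.items():
        if True not in d or False not in d:
            raise ValueError(f"sample {sample} is missing a TEX treatment; need both +/-")
        pairs[sample] = (d[True], d[False])
    return pairs


def compute_coverage(libs: list[LibraryAlignments], genome: GenomeModel) -> dict[str, CoverageTracks]:
    return {lib.library_id: coverage(lib, len(genome), normalize=True, circular=genome.circular)
            for lib in libs}


def call_tss(
    genome: GenomeModel,
    libs: list[LibraryAlignments],
    detection: TSSDetectionParams | None = None,
    classification: ClassificationParams | None = None,
    coverage_by_library: dict[str, CoverageTracks] | None = None,
) -> tuple[list[AnnotatedTSS], dict[str, CoverageTracks]]:
    """Detect per sample, cluster across samples, classify against the annotation."""
    detection = detection or TSSDetectionParams()
    cov = coverage_by_library or compute_coverage(libs, genome)
    candidates, lib_of_sample = {}, {}
    for sample, (plus, minus) in sorted(pair_libraries(libs).items()):
        candidates[sample] = detect_sample_tss(
            cov[plus.library_id], cov[minus.library_id], detection,
            sample=sample, circular=genome.circular,
        )
        lib_of_sample[sample] = plus.library_id
    tss = cluster_tss(candidates, detection.cluster_window, lib_of_sample)
    classify_tss(tss, genome.genes, classification or ClassificationParams())
    return tss, cov


def expression_by_sample(libs: list[LibraryAlignments], genome: GenomeModel) -> dict[str, pd.DataFrame]:
    """Per-sample expression tables from the TEX-untreated libraries."""
    out = {}
    for lib in libs:
        if lib.tex:
            continue
        out[lib.sample] = pd.DataFrame(
            [{"gene_id": r.gene_id, "raw_reads": r.raw_reads, "rpkm": r.rpkm}
             for r in count_reads(lib, genome)]
        )
    return out


def run_de(
    expr: dict[str, pd.DataFrame],
    comparisons=STANDARD_COMPARISONS,
    params: DEParams | None = None,
) -> dict[str, list[DEResult]]:
    """Both directions of each comparison; keys like 'SE#9h|SE#6h' and reversed."""
    out = {}
    for a, b in comparisons:
        out[f"{a}|{b}"] = differential_genes(expr[a], expr[b], params, cond_a=a, cond_b=b)
        out[f"{b}|{a}"] = differential_genes(expr[b], expr[a], params, cond_a=b, cond_b=a)
    return out


def analyze(
    genome: GenomeModel,
    libs: list[LibraryAlignments],
    detection: TSSDetectionParams | None = None,
    classification: ClassificationParams | None = None,
    utr_params: UTRParams | None = None,
    reann_params: ReannotationParams | None = None,
    de_params: DEParams | None = None,
    srna_params: SrnaParams | None = None,
    operons: list[tuple[str, list[str]]] | None = None,
    operon_alpha: float = 0.5,
) -> AnalysisResult:
    """Run the full primary-transcriptome analysis on one dataset."""
    tss, cov = call_tss(genome, libs, detection, classification)
    res = AnalysisResult(tss=tss, coverage_by_library=cov)
    res.utrs = assign_utrs(tss, genome.genes, utr_params)
    res.reannotations = propose_reannotation(tss, genome.genes, genome, reann_params)
    tex_minus = [l for l in libs if not l.tex]
    res.segments = classify_segments(
        segment_igrs(tex_minus, genome, srna_params), genome.genes, res.utrs, genome, srna_params
    )
    res.expression = expression_by_sample(libs, genome)
    available = set(res.expression)
    comps = [(a, b) for a, b in STANDARD_COMPARISONS if a in available and b in available]
    res.de = run_de(res.expression, comps, de_params)
    if operons:
        cov_minus = {l.library_id: cov[l.library_id] for l in tex_minus}
        cov_by_sample = {l.sample: cov[l.library_id] for l in tex_minus}
        res.operons = validate_operons(operons, genome, cov_minus, operon_alpha, tss, cov_by_sample)
    return res
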