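"""Discovery of expressed intergenic transcripts and their classification.

Expressed runs are detected on the TEX-untreated coverage of each library
(gaps up to ``max_gap`` bridged), split at valleys where coverage falls to
the level of isolated stray reads (below ``min_boundary_reads`` overlapping
reads), intersected with strand-specific intergenic space, and discarded
when their coverage is contiguous with the body of a flanking sense-strand
gene (an mRNA extension rather than an independent transcript).  Segment
boundaries are likewise trimmed to the outermost positions with at least
``min_boundary_reads`` overlapping reads, so that stray reads chained onto
a transcript do not inflate its extent.
Retained segments are classified, in order, as antisense to a CDS, antisense
to a UTR, small-ORF mRNA, or trans-encoded sRNA candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (
    CoverageTracks,
    Gene,
    GenomeModel,
    LibraryAlignments,
    STRANDS,
    coverage,
)
from .transcript_annotation import ReannotationParams, UTRRecord, codon_at, find_sd

STOP_CODONS = ("TAA", "TAG", "TGA")
SEGMENT_CLASSES = ("srna_candidate", "asRNA_cds", "asRNA_utr", "small_orf_mrna")


@dataclass
class SrnaParams:
    min_raw_reads: int = 50  # strict >: segments need more than this many reads
    min_cov: float = 2.0  # RPM floor defining "expressed"
    max_gap: int = 10  # sub-threshold gap tolerated inside a run
    min_boundary_reads: float = 2.5  # overlapping-read depth defining a real boundary/valley
    orf_min_aa: int = 30
    orf_max_aa: int = 99
    excludon_min_genes: int = 2
    three_prime_utr_len: int = 100  # inferred 3'UTR extent downstream of a stop

    def __post_init__(self) -> None:
        if min(self.min_raw_reads, self.min_cov, self.max_gap) <= 0:
            raise ValueError("thresholds must be > 0")
        if self.min_boundary_reads <= 0:
            raise ValueError("min_boundary_reads must be > 0")


@dataclass
class IGRSegment:
    start: int
    end: int
    strand: str
    max_cov: float = 0.0
    raw_reads: int = 0
    best_library: str = ""
    seg_class: str | None = None
    flags: set[str] = field(default_factory=set)
    known_names: list[str] = field(default_factory=list)
    orf: tuple[int, int] | None = None  # (start coordinate, aa length) when small ORF found

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _gene_mask(genes: list[Gene], strand: str, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for g in genes:
        if g.strand == strand:
            mask[g.start - 1 : g.end] = True
    return mask


def _runs(mask: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Maximal True runs (0-based inclusive index pairs), bridging gaps <= max_gap."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def _segment_one_library(
    lib: LibraryAlignments,
    tracks: CoverageTracks,
    genes: list[Gene],
    params: SrnaParams,
) -> list[IGRSegment]:
    L = len(tracks)
    segments: list[IGRSegment] = []
    for strand in STRANDS:
        full = tracks.full(strand)
        expressed = full >= params.min_cov
        in_gene = _gene_mask(genes, strand, L)
        for run_s, run_e in _runs(expressed, params.max_gap):
            # split the bridged run where coverage drops to stray-read level
            floor = _floor(tracks, params)
            for sub_s, sub_e in _runs(full[run_s : run_e + 1] >= floor, params.max_gap):
                sa, sb = run_s + sub_s, run_s + sub_e
                intergenic = ~in_gene[sa : sb + 1]
                if not intergenic.any():
                    continue
                for piece_s, piece_e in _runs(intergenic, 0):
                    a, b = sa + piece_s, sa + piece_e
                    if _contiguous_with_gene(expressed, in_gene, a, b, L):
                        continue
                    a, b = _trim(full, a, b, tracks, params)
                    if a is None:
                        continue
                    seg = IGRSegment(start=a + 1, end=b + 1, strand=strand,
                                     max_cov=float(full[a : b + 1].max()),
                                     best_library=lib.library_id)
                    seg.raw_reads = _count_overlapping(lib, seg)
                    segments.append(seg)
    return segments


def _contiguous_with_gene(expressed: np.ndarray, in_gene: np.ndarray,
                          a: int, b: int, L: int) -> bool:
    """True when coverage runs across an IGR/gene boundary with no sub-threshold hole."""
    left, right = a - 1, b + 1
    if left >= 0 and in_gene[left] and expressed[left] and expressed[a]:
        return True
    if right < L and in_gene[right] and expressed[right] and expressed[b]:
        return True
    return False


def _floor(tracks: CoverageTracks, params: SrnaParams) -> float:
    """Valley/boundary floor in track units: ``min_boundary_reads``
    overlapping reads, converted through the library's normalization scale.

    Chains of isolated stray reads never stack this deep, while any segment
    abundant enough to pass the raw-read filter holds a body coverage an
    order of magnitude above it."""
    return max(params.min_boundary_reads * tracks.scale, params.min_cov)


def _trim(full: np.ndarray, a: int, b: int, tracks: CoverageTracks, params: SrnaParams):
    floor = _floor(tracks, params)
    keep = np.flatnonzero(full[a : b + 1] >= floor)
    if len(keep) == 0:
        return None, None
    return a + int(keep[0]), a + int(keep[-1])


def _count_overlapping(lib: LibraryAlignments, seg: IGRSegment) -> int:
    mask = (lib.strands == seg.strand) & (lib.starts <= seg.end) & (lib.ends >= seg.start)
    return int(mask.sum())


def segment_igrs(
    tex_minus_libs: list[LibraryAlignments],
    genome: GenomeModel,
    params: SrnaParams | None = None,
) -> list[IGRSegment]:
    """Expressed intergenic segments consolidated over the TEX- libraries.

    Each library is segmented on its own normalized full-coverage track;
    overlapping per-library candidates are merged and represented by the
    library with the most supporting reads.  Segments are retained only when
    that best library holds strictly more than ``min_raw_reads`` reads.
    """
    params = params or SrnaParams()
    candidates: list[IGRSegment] = []
    for lib in tex_minus_libs:
        if lib.tex:
            raise ValueError("segment_igrs expects TEX-untreated libraries")
        tracks = coverage(lib, len(genome), normalize=True, circular=genome.circular)
        candidates.extend(_segment_one_library(lib, tracks, genome.genes, params))
    merged: list[IGRSegment] = []
    for strand in STRANDS:
        group = sorted([s for s in candidates if s.strand == strand], key=lambda s: s.start)
        cluster: list[IGRSegment] = []
        cluster_end = -1
        for s in group:
            if cluster and s.start > cluster_end:
                merged.append(max(cluster, key=lambda x: x.raw_reads))
                cluster = []
                cluster_end = -1
            cluster.append(s)
            cluster_end = max(cluster_end, s.end)
        if cluster:
            merged.append(max(cluster, key=lambda x: x.raw_reads))
    retained = [s for s in merged if s.raw_reads > params.min_raw_reads]
    retained.sort(key=lambda s: (s.strand, s.start))
    return retained


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def three_prime_utr_regions(genes: list[Gene], genome_length: int,
                            utr_len: int = 100) -> list[tuple[int, int, str]]:
    """Inferred 3'UTR intervals: up to ``utr_len`` nt downstream of each stop,
    truncated where any neighbouring gene intervenes."""
    occupied = np.zeros(genome_length, dtype=bool)
    for g in genes:
        occupied[g.start - 1 : g.end] = True
    regions = []
    for g in genes:
        if g.strand == "+":
            lo, hi = g.end + 1, min(g.end + utr_len, genome_length)
        else:
            lo, hi = max(g.start - utr_len, 1), g.start - 1
        if lo > hi:
            continue
        span = np.arange(lo - 1, hi)
        free = ~occupied[span]
        if g.strand == "+":
            n = int(np.argmin(free)) if not free.all() else len(free)
            if n == 0:
                continue
            regions.append((lo, lo + n - 1, g.strand))
        else:
            rev = free[::-1]
            n = int(np.argmin(rev)) if not rev.all() else len(rev)
            if n == 0:
                continue
            regions.append((hi - n + 1, hi, g.strand))
    return regions


def _overlaps(a1: int, a2: int, b1: int, b2: int) -> bool:
    return a1 <= b2 and a2 >= b1


def small_orf_scan(
    segment: IGRSegment,
    genome: GenomeModel,
    params: SrnaParams | None = None,
    sd_params: ReannotationParams | None = None,
) -> tuple[int, int] | None:
    """Longest SD-led ORF of 30-99 aa on the segment strand, or None.

    Returns (coordinate of the start codon's first base, protein length in
    aa).  The ORF must begin with ATG/GTG/TTG carrying a Shine-Dalgarno
    match at ribosome-binding spacing and terminate at an in-frame stop
    codon inside the segment.
    """
    params = params or SrnaParams()
    sd_params = sd_params or ReannotationParams()
    if segment.length < 3 * (params.orf_min_aa + 1):
        return None
    sign = 1 if segment.strand == "+" else -1
    best: tuple[int, int] | None = None
    for offset in range(segment.length - 2):
        pos = segment.five_prime + sign * offset
        if codon_at(genome, pos, segment.strand) not in sd_params.start_codons:
            continue
        if find_sd(genome, pos, segment.strand, sd_params) is None:
            continue
        aa = _orf_length(pos, segment, genome, sign)
        if aa is not None and params.orf_min_aa <= aa <= params.orf_max_aa:
            if best is None or aa > best[1]:
                best = (pos, aa)
    return best


def _orf_length(start_pos: int, segment: IGRSegment, genome: GenomeModel, sign: int) -> int | None:
    aa = 0
    pos = start_pos
    while True:
        last_base = pos + sign * 2
        if not (segment.start <= min(pos, last_base) and max(pos, last_base) <= segment.end):
            return None  # ran off the segment without a stop
        if codon_at(genome, pos, segment.strand) in STOP_CODONS:
            return aa
        aa += 1
        pos += sign * 3


def classify_segment(
    segment: IGRSegment,
    genes: list[Gene],
    utrs: list[UTRRecord],
    genome: GenomeModel,
    params: SrnaParams | None = None,
) -> IGRSegment:
    """Assign a single class and additive flags to a retained segment."""
    params = params or SrnaParams()
    gene_by_id = {g.id: g for g in genes}
    opposite = [g for g in genes if g.strand != segment.strand]
    anti_genes = [g for g in opposite if _overlaps(segment.start, segment.end, g.start, g.end)]
    utr3 = three_prime_utr_regions(genes, len(genome), params.three_prime_utr_len)
    if anti_genes:
        segment.seg_class = "asRNA_cds"
    elif _overlaps_opposite_utr(segment, utrs, gene_by_id, utr3):
        segment.seg_class = "asRNA_utr"
    else:
        orf = small_orf_scan(segment, genome, params)
        if orf is not None:
            segment.seg_class = "small_orf_mrna"
            segment.orf = orf
        else:
            segment.seg_class = "srna_candidate"
    for lo, hi, strand in utr3:
        if strand == segment.strand and lo <= segment.five_prime <= hi:
            segment.flags.add("three_prime_utr_derived")
            break
    if segment.seg_class in ("asRNA_cds", "asRNA_utr") and len(anti_genes) >= params.excludon_min_genes:
        segment.flags.add("excludon_like")
    return segment


def _overlaps_opposite_utr(segment: IGRSegment, utrs: list[UTRRecord],
                           gene_by_id: dict[str, Gene],
                           utr3: list[tuple[int, int, str]]) -> bool:
    for r in utrs:
        g = gene_by_id.get(r.gene_id)
        if g is None or g.strand == segment.strand or r.length == 0:
            continue
        lo, hi = (r.tss_pos, g.start - 1) if g.strand == "+" else (g.end + 1, r.tss_pos)
        if _overlaps(segment.start, segment.end, lo, hi):
            return True
    for lo, hi, strand in utr3:
        if strand != segment.strand and _overlaps(segment.start, segment.end, lo, hi):
            return True
    return False


def classify_segments(segments: list[IGRSegment], genes: list[Gene], utrs: list[UTRRecord],
                      genome: GenomeModel, params: SrnaParams | None = None) -> list[IGRSegment]:
    return [classify_segment(s, genes, utrs, genome, params) for s in segments]


def match_known_srnas(segments: list[IGRSegment], homolog_table: pd.DataFrame | str | Path) -> list[IGRSegment]:
    """Flag segments overlapping user-supplied known sRNA loci.

    The table needs columns name, start, end and optionally strand; all
    overlapping entry names are recorded on the segment.
    """
    if not isinstance(homolog_table, pd.DataFrame):
        homolog_table = pd.read_csv(homolog_table, sep="\t")
    required = {"name", "start", "end"}
    if not required <= set(homolog_table.columns):
        raise ValueError(f"homolog table must have columns {sorted(required)}")
    for seg in segments:
        for _, row in homolog_table.iterrows():
            if "strand" in homolog_table.columns and str(row["strand"]) not in ("nan", ""):
                if str(row["strand"]) != seg.strand:
                    continue
            if _overlaps(seg.start, seg.end, int(row["start"]), int(row["end"])):
                seg.flags.add("known_homolog")
                seg.known_names.append(str(row["name"]))
    return segments


def segment_table(segments: list[IGRSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"start": s.start, "end": s.end, "strand": s.strand, "length": s.length,
          "max_cov": s.max_cov, "raw_reads": s.raw_reads, "best_library": s.best_library,
          "class": s.seg_class, "flags": ";".join(sorted(s.flags)),
          "known_names": ";".join(s.known_names)} for s in segments],
        columns=["start", "end", "strand", "length", "max_cov", "raw_reads",
                 "best_library", "class", "flags", "known_names"],
    )


def write_segments_gff3(segments: list[IGRSegment], path: str | Path,
                        chrom: str = "chromosome") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, s in enumerate(sorted(segments, key=lambda s: s.start), start=1):
            attrs = f"ID=seg{i};class={s.seg_class or 'unclassified'}"
            if s.flags:
                attrs += f";flags={','.join(sorted(s.flags))}"
            fh.write(f"{chrom}\tprimarytx\tncRNA\t{s.start}\t{s.end}\t.\t{s.strand}\t.\t{attrs}\n")


def write_segment_fasta(segments: list[IGRSegment], genome: GenomeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sorted(segments, key=lambda s: s.start), start=1):
            fh.write(f">seg{i}_{s.start}_{s.end}_{s.strand}\n{genome.fetch(s.start, s.end, s.strand)}\n")
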