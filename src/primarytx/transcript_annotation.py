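"""5'UTR assignment, upstream-sequence analysis and start-codon re-annotation.

The 5'UTR of a gene is the distance from its primary TSS to the annotated
translation start.  UTRs shorter than 10 nt mark leaderless mRNAs, longer
than 100 nt mark long-UTR mRNAs, and UTRs longer than 70 nt are exported as
riboswitch-search candidates.  Internal TSSs found shortly downstream of an
annotated start codon trigger a scan for a corrected start further
downstream, supported by a Shine-Dalgarno match at ribosome-binding spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np
import pandas as pd

from .genome_model import Gene, GenomeModel
from .tss_core import AnnotatedTSS

START_CODONS = ("ATG", "GTG", "TTG")
SD_MOTIF = "AGGAGG"


@dataclass
class UTRParams:
    leaderless_max: int = 10  # exclusive: UTR < 10 nt is leaderless
    long_min: int = 100  # exclusive: UTR > 100 nt is long
    riboswitch_min: int = 70  # strict: UTR > 70 nt flagged for Rfam search
    histogram_bins: tuple[int, ...] = (0, 10, 25, 50, 75, 100, 150, 200, 300, 500)

    def __post_init__(self) -> None:
        if self.leaderless_max >= self.long_min:
            raise ValueError("leaderless_max must be below long_min")


@dataclass(frozen=True)
class UTRRecord:
    gene_id: str
    tss_pos: int
    length: int
    utr_class: str  # leaderless | standard | long


@dataclass
class ReannotationParams:
    internal_tss_max_downstream: int = 50
    new_start_min: int = 40
    new_start_max: int = 100
    sd_motif: str = SD_MOTIF
    sd_min_match: int = 4
    sd_spacer_min: int = 5
    sd_spacer_max: int = 9
    start_codons: tuple[str, ...] = START_CODONS

    def __post_init__(self) -> None:
        if self.new_start_min >= self.new_start_max:
            raise ValueError("new-start window bounds out of order")
        if self.sd_spacer_min > self.sd_spacer_max:
            raise ValueError("SD spacer bounds out of order")


@dataclass(frozen=True)
class ReannotationProposal:
    gene_id: str
    strand: str
    old_start: int  # annotated translation-start coordinate
    tss_pos: int
    new_start: int  # proposed translation-start coordinate
    sd_pos: int  # coordinate of the SD hexamer base closest to the start codon
    sd_matches: int


def assign_utrs(
    tss_set: list[AnnotatedTSS],
    genes: list[Gene],
    params: UTRParams | None = None,
) -> list[UTRRecord]:
    """One UTR record per gene with a primary TSS; negative lengths excluded."""
    params = params or UTRParams()
    gene_by_id = {g.id: g for g in genes}
    records: list[UTRRecord] = []
    for t in tss_set:
        for gid, cat, _d in t.gene_links:
            if cat != "primary":
                continue
            g = gene_by_id[gid]
            length = (g.start - t.pos) if g.strand == "+" else (t.pos - g.end)
            if length < 0:
                warnings.warn(f"gene {gid}: primary TSS downstream of start, UTR record excluded")
                continue
            records.append(UTRRecord(gid, t.pos, length, classify_utr_length(length, params)))
    records.sort(key=lambda r: r.gene_id)
    return records


def classify_utr_length(length: int, params: UTRParams | None = None) -> str:
    params = params or UTRParams()
    if length < params.leaderless_max:
        return "leaderless"
    if length > params.long_min:
        return "long"
    return "standard"


def utr_histogram(records: list[UTRRecord], bins: tuple[int, ...] | None = None) -> pd.DataFrame:
    """Counts of UTR lengths per bin edge interval [b_i, b_{i+1}), plus overflow."""
    if not records:
        raise ValueError("cannot histogram an empty UTR record set")
    edges = list(bins if bins is not None else UTRParams().histogram_bins)
    lengths = np.array([r.length for r in records])
    counts, _ = np.histogram(lengths, bins=edges + [np.inf])
    labels = [f"[{a},{b})" for a, b in zip(edges[:-1], edges[1:])] + [f">={edges[-1]}"]
    return pd.DataFrame({"bin": labels, "count": counts})


def extract_upstream(tss: AnnotatedTSS | tuple[int, str], genome: GenomeModel, span: int = 50) -> str:
    """Sequence at positions -span..-1 relative to the TSS on the TSS strand.

    Reverse-complemented on the minus strand; wraps through the origin on a
    circular genome.
    """
    if span < 1:
        raise ValueError("span must be >= 1")
    pos, strand = (tss.pos, tss.strand) if isinstance(tss, AnnotatedTSS) else tss
    if strand == "+":
        return genome.fetch(pos - span, pos - 1, "+")
    return genome.fetch(pos + 1, pos + span, "-")


def plus_one_composition(tss_set: list[AnnotatedTSS], genome: GenomeModel) -> dict[str, float]:
    """Base frequencies at the +1 (first transcribed) position, plus purine share."""
    if not tss_set:
        raise ValueError("empty TSS set")
    counts = {b: 0 for b in "ACGT"}
    for t in tss_set:
        base = genome.base(t.pos)
        if t.strand == "-":
            base = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(base, base)
        if base in counts:
            counts[base] += 1
    n = sum(counts.values())
    freqs = {b: c / n for b, c in counts.items()}
    freqs["purine"] = freqs["A"] + freqs["G"]
    return freqs


def flag_riboswitch_candidates(
    records: list[UTRRecord],
    genes: list[Gene],
    genome: GenomeModel,
    params: UTRParams | None = None,
    fasta_path: str | Path | None = None,
) -> list[tuple[str, str]]:
    """Genes whose 5'UTR is strictly longer than the riboswitch floor.

    Returns (gene_id, UTR sequence) pairs, UTR given 5'->3' on the gene
    strand, and optionally writes them as FASTA for an external Rfam search
    (no covariance-model scoring is performed here).
    """
    params = params or UTRParams()
    gene_by_id = {g.id: g for g in genes}
    out: list[tuple[str, str]] = []
    for r in records:
        if r.length > params.riboswitch_min:
            g = gene_by_id[r.gene_id]
            if g.strand == "+":
                seq = genome.fetch(r.tss_pos, g.start - 1, "+")
            else:
                seq = genome.fetch(g.end + 1, r.tss_pos, "-")
            out.append((r.gene_id, seq))
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for gid, seq in out:
                fh.write(f">{gid}_5UTR\n{seq}\n")
    return out


def _sd_match_count(hexamer: str, motif: str) -> int:
    return sum(1 for a, b in zip(hexamer, motif) if a == b)


def find_sd(genome: GenomeModel, start_pos: int, strand: str,
            params: ReannotationParams) -> tuple[int, int] | None:
    """Best SD hexamer whose 3' end lies sd_spacer nt upstream of a start codon.

    ``start_pos`` is the coordinate of the first base of the candidate start
    codon on ``strand``.  Returns (coordinate of SD base nearest the start,
    match count) for the best qualifying placement, or None.
    """
    best: tuple[int, int] | None = None
    for spacer in range(params.sd_spacer_min, params.sd_spacer_max + 1):
        if strand == "+":
            hex_start = start_pos - spacer - len(params.sd_motif)
            hexamer = genome.fetch(hex_start, hex_start + len(params.sd_motif) - 1, "+")
            sd_pos = hex_start + len(params.sd_motif) - 1
        else:
            hex_end = start_pos + spacer + len(params.sd_motif)
            hexamer = genome.fetch(hex_end - len(params.sd_motif) + 1, hex_end, "-")
            sd_pos = hex_end - len(params.sd_motif) + 1
        m = _sd_match_count(hexamer, params.sd_motif)
        if m >= params.sd_min_match and (best is None or m > best[1]):
            best = (sd_pos, m)
    return best


def codon_at(genome: GenomeModel, pos: int, strand: str) -> str:
    """Codon whose first base sits at ``pos`` reading 5'->3' on ``strand``."""
    if strand == "+":
        return genome.fetch(pos, pos + 2, "+")
    return genome.fetch(pos - 2, pos, "-")


def propose_reannotation(
    tss_set: list[AnnotatedTSS],
    genes: list[Gene],
    genome: GenomeModel,
    params: ReannotationParams | None = None,
) -> list[ReannotationProposal]:
    """Start-codon corrections for genes whose TSS lies inside the annotated CDS.

    Eligible cases: an internal TSS 1..50 nt downstream of the annotated
    start codon.  The scan looks 40-100 nt downstream of the TSS for the
    nearest start codon in the annotated reading frame that carries an SD
    match (>= sd_min_match of AGGAGG) ending 5-9 nt upstream.
    """
    params = params or ReannotationParams()
    gene_by_id = {g.id: g for g in genes}
    proposals: list[ReannotationProposal] = []
    for t in tss_set:
        for gid, cat, _d in t.gene_links:
            if cat != "internal":
                continue
            g = gene_by_id[gid]
            d_down = (t.pos - g.start) if g.strand == "+" else (g.end - t.pos)
            if not (0 < d_down <= params.internal_tss_max_downstream):
                continue
            if g.strand == "+" and g.end + 2 > len(genome) and not genome.circular:
                raise ValueError(f"gene {gid} truncated at genome edge")
            proposal = _scan_new_start(t, g, genome, params)
            if proposal is not None:
                proposals.append(proposal)
    proposals.sort(key=lambda p: p.gene_id)
    return proposals


def _scan_new_start(t: AnnotatedTSS, g: Gene, genome: GenomeModel,
                    params: ReannotationParams) -> ReannotationProposal | None:
    sign = 1 if g.strand == "+" else -1
    anchor = g.start if g.strand == "+" else g.end  # annotated translation start
    for d in range(params.new_start_min, params.new_start_max + 1):
        pos = t.pos + sign * d
        # stay in the annotated reading frame (same frame as the stop codon)
        if (sign * (pos - anchor)) % 3 != 0:
            continue
        if codon_at(genome, pos, g.strand) not in params.start_codons:
            continue
        sd = find_sd(genome, pos, g.strand, params)
        if sd is None:
            continue
        return ReannotationProposal(
            gene_id=g.id,
            strand=g.strand,
            old_start=anchor,
            tss_pos=t.pos,
            new_start=pos,
            sd_pos=sd[0],
            sd_matches=sd[1],
        )
    return None


def utr_table(records: list[UTRRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": r.gene_id, "tss_pos": r.tss_pos, "length": r.length, "class": r.utr_class}
         for r in records],
        columns=["gene_id", "tss_pos", "length", "class"],
    )


def reannotation_table(proposals: list[ReannotationProposal]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": p.gene_id, "strand": p.strand, "old_start": p.old_start,
          "tss": p.tss_pos, "new_start": p.new_start, "sd_pos": p.sd_pos,
          "sd_matches": p.sd_matches} for p in proposals],
        columns=["gene_id", "strand", "old_start", "tss", "new_start", "sd_pos", "sd_matches"],
    )


def write_reannotation_gff3(proposals: list[ReannotationProposal], genes: list[Gene],
                            path: str | Path, chrom: str = "chromosome") -> None:
    """GFF3 patch of the proposed corrected CDS extents."""
    gene_by_id = {g.id: g for g in genes}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in proposals:
            g = gene_by_id[p.gene_id]
            start = p.new_start if g.strand == "+" else g.start
            end = g.end if g.strand == "+" else p.new_start
            fh.write(f"{chrom}\tprimarytx\tCDS\t{start}\t{end}\t.\t{g.strand}\t0\t"
                     f"ID={p.gene_id};note=corrected_start\n")
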