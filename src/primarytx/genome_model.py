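"""Genome, annotation and mapped-read data model for dRNA-seq analysis.

All coordinates are 1-based inclusive (GFF3 convention); BED input is
converted at the boundary.  Strands are ``"+"`` / ``"-"``.  Coverage is kept
as dense per-nucleotide numpy arrays, one pair of tracks per strand: full
read coverage and biological 5'-end counts.  Normalisation is
reads-per-million mapped reads (RPM), computed per library.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

STRANDS = ("+", "-")

#: GFF3 feature types mapped onto Gene.kind; anything else becomes "other".
_KIND_MAP = {"CDS": "CDS", "gene": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}


class GFF3ParseError(ValueError):
    """Raised for a malformed GFF3 feature line; message names the line number."""


class BoundsError(ValueError):
    """Raised when an annotated feature or read lies outside the genome."""


class BEDFormatError(ValueError):
    """Raised for malformed BED6 records."""


@dataclass(frozen=True)
class Gene:
    """An annotated feature on the chromosome.

    ``start <= end`` always; orientation is carried by ``strand``.  For a
    gene on the minus strand the translation start is the ``end`` coordinate.
    """

    id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    product: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise BoundsError(f"gene {self.id}: invalid extent {self.start}..{self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.id}: strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tss_side(self) -> int:
        """Coordinate of the annotated translation start (strand-aware 5' end)."""
        return self.start if self.strand == "+" else self.end

    @property
    def stop_side(self) -> int:
        """Coordinate of the last nucleotide of the CDS (strand-aware 3' end)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class GenomeModel:
    """A (possibly circular) chromosome with its annotated genes."""

    sequence: str
    genes: list[Gene]
    circular: bool = True
    name: str = "chromosome"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        seen: set[str] = set()
        for g in self.genes:
            if g.end > len(self.sequence):
                raise BoundsError(
                    f"gene {g.id} extends to {g.end} beyond genome length {len(self.sequence)}"
                )
            if g.id in seen:
                raise ValueError(f"duplicate gene id {g.id}")
            seen.add(g.id)
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.strand))

    def __len__(self) -> int:
        return len(self.sequence)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def base(self, pos: int) -> str:
        """Base at a 1-based position, wrapping on a circular chromosome."""
        L = len(self.sequence)
        if self.circular:
            return self.sequence[(pos - 1) % L]
        if not 1 <= pos <= L:
            raise BoundsError(f"position {pos} outside linear genome of length {L}")
        return self.sequence[pos - 1]

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Sequence of 1-based inclusive ``start..end`` on ``strand``.

        On the minus strand the reverse complement is returned.  The interval
        may wrap through the origin on a circular genome (give start > end
        only via wrapping semantics handled by the caller's offsets; here a
        negative or past-end coordinate wraps).
        """
        seq = "".join(self.base(p) for p in range(start, end + 1))
        if strand == "-":
            seq = _revcomp(seq)
        return seq


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class LibraryAlignments:
    """Mapped reads of one cDNA library as 1-based inclusive intervals."""

    library_id: str
    medium: str  # 1CM | RE | SE | RS
    timepoint: str  # 6h | 9h
    tex: bool  # True for the TEX-treated (+) library
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ends: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    strands: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U1"))

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype="U1")
        if not (len(self.starts) == len(self.ends) == len(self.strands)):
            raise ValueError("starts/ends/strands must have equal length")

    @property
    def total_mapped(self) -> int:
        return len(self.starts)

    @property
    def sample(self) -> str:
        """The (medium, timepoint) sample this library belongs to, e.g. ``SE#9h``."""
        return f"{self.medium}#{self.timepoint}"

    @property
    def reads(self) -> list[tuple[int, int, str]]:
        return list(zip(self.starts.tolist(), self.ends.tolist(), self.strands.tolist()))

    @classmethod
    def from_reads(
        cls,
        library_id: str,
        medium: str,
        timepoint: str,
        tex: bool,
        reads: Iterable[tuple[int, int, str]],
    ) -> "LibraryAlignments":
        rows = list(reads)
        return cls(
            library_id=library_id,
            medium=medium,
            timepoint=timepoint,
            tex=tex,
            starts=np.array([r[0] for r in rows], dtype=np.int64),
            ends=np.array([r[1] for r in rows], dtype=np.int64),
            strands=np.array([r[2] for r in rows], dtype="U1"),
        )


@dataclass
class CoverageTracks:
    """Per-nucleotide stranded coverage of one library.

    ``full_*`` counts reads overlapping each position; ``end5_*`` counts
    biological read 5' ends (interval start on +, interval end on -).  When
    ``normalized`` all four tracks are in RPM: raw x 1e6 / total_mapped.
    """

    full_fwd: np.ndarray
    full_rev: np.ndarray
    end5_fwd: np.ndarray
    end5_rev: np.ndarray
    normalized: bool
    scale: float = 1.0  # multiplier applied to raw counts (1e6/total_mapped when normalized)

    def __post_init__(self) -> None:
        n = {len(self.full_fwd), len(self.full_rev), len(self.end5_fwd), len(self.end5_rev)}
        if len(n) != 1:
            raise ValueError("all four tracks must have equal length")

    def full(self, strand: str) -> np.ndarray:
        return self.full_fwd if strand == "+" else self.full_rev

    def end5(self, strand: str) -> np.ndarray:
        return self.end5_fwd if strand == "+" else self.end5_rev

    def __len__(self) -> int:
        return len(self.full_fwd)


@dataclass(frozen=True)
class ExpressionRecord:
    """Raw read count and RPKM of one gene in one library."""

    gene_id: str
    library_id: str
    raw_reads: int
    rpkm: float


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genome(fasta_path: str | Path, gff3_path: str | Path, circular: bool = True) -> GenomeModel:
    """Load a genome FASTA plus a GFF3 annotation into a :class:`GenomeModel`.

    Every GFF3 feature row becomes one :class:`Gene`; feature types outside
    CDS/rRNA/tRNA map to kind ``other``.  Genes come back sorted by start.
    """
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    sequence = str(record.seq).upper()
    genes: list[Gene] = []
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3ParseError(
                    f"{gff3_path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if seqid != record.id:
                raise GFF3ParseError(
                    f"{gff3_path}: line {lineno}: seqid {seqid!r} does not match FASTA record {record.id!r}"
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GFF3ParseError(f"{gff3_path}: line {lineno}: non-integer coordinate") from exc
            if strand not in STRANDS:
                raise GFF3ParseError(f"{gff3_path}: line {lineno}: strand must be + or -")
            if end > len(sequence):
                raise BoundsError(
                    f"{gff3_path}: line {lineno}: feature ends at {end} beyond genome length {len(sequence)}"
                )
            attr_map = _parse_attributes(attrs)
            gid = attr_map.get("ID") or attr_map.get("locus_tag") or f"feature{lineno}"
            genes.append(
                Gene(
                    id=gid,
                    start=start,
                    end=end,
                    strand=strand,
                    kind=_KIND_MAP.get(ftype, "other"),
                    product=attr_map.get("product", ""),
                )
            )
    return GenomeModel(sequence=sequence, genes=genes, circular=circular, name=record.id)


def _parse_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        key, value = item.split("=", 1)
        out[key] = value
    return out


def write_genome(genome: GenomeModel, fasta_path: str | Path, gff3_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.name}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {len(genome)}\n")
        ftype_of = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "other": "misc_feature"}
        for g in genome.genes:
            attrs = f"ID={g.id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                "\t".join(
                    [
                        genome.name,
                        "primarytx",
                        ftype_of.get(g.kind, "misc_feature"),
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_alignments(bed_path: str | Path, metadata: dict) -> LibraryAlignments:
    """Read a BED6 file of mapped reads into :class:`LibraryAlignments`.

    BED is 0-based half-open; intervals are converted to 1-based inclusive.
    ``metadata`` must provide library_id, medium, timepoint and tex.
    """
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BEDFormatError(f"{bed_path}: line {lineno}: BED6 requires 6 columns (strand missing)")
            start0, end0, strand = int(fields[1]), int(fields[2]), fields[5]
            if strand not in STRANDS:
                raise BEDFormatError(f"{bed_path}: line {lineno}: strand must be + or -, got {strand!r}")
            if start0 >= end0:
                raise BEDFormatError(f"{bed_path}: line {lineno}: start >= end ({start0} >= {end0})")
            starts.append(start0 + 1)
            ends.append(end0)
            strands.append(strand)
    return LibraryAlignments(
        library_id=metadata["library_id"],
        medium=metadata["medium"],
        timepoint=metadata["timepoint"],
        tex=bool(metadata["tex"]),
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
        strands=np.array(strands, dtype="U1"),
    )


def write_alignments(lib: LibraryAlignments, bed_path: str | Path, chrom: str = "chromosome") -> None:
    """Write reads back to BED6 (0-based half-open)."""
    with open(bed_path, "w") as fh:
        for i in range(lib.total_mapped):
            fh.write(
                f"{chrom}\t{lib.starts[i] - 1}\t{lib.ends[i]}\tr{i + 1}\t0\t{lib.strands[i]}\n"
            )


# ---------------------------------------------------------------------------
# coverage and expression
# ---------------------------------------------------------------------------

def coverage(lib: LibraryAlignments, genome_length: int, normalize: bool = True,
             circular: bool = True) -> CoverageTracks:
    """Per-nucleotide full and 5'-end coverage for one library.

    Full tracks count overlapping reads per position and strand; 5'-end
    tracks count biological 5' ends (interval start on +, interval end on -).
    Intervals extending past the end of a circular chromosome wrap; on a
    linear chromosome they raise :class:`BoundsError`.
    """
    if normalize and lib.total_mapped == 0:
        raise ValueError("cannot normalize a library with zero mapped reads")
    L = genome_length
    full = {s: np.zeros(L, dtype=np.float64) for s in STRANDS}
    end5 = {s: np.zeros(L, dtype=np.float64) for s in STRANDS}
    for s in STRANDS:
        mask = lib.strands == s
        starts = lib.starts[mask]
        ends = lib.ends[mask]
        if len(starts) == 0:
            continue
        if starts.min() < 1 or (not circular and ends.max() > L):
            raise BoundsError("read interval outside genome bounds")
        # difference-array trick for full coverage; wrapping intervals split
        diff = np.zeros(L + 1, dtype=np.float64)
        wrap = ends > L
        ok_s, ok_e = starts[~wrap], ends[~wrap]
        np.add.at(diff, ok_s - 1, 1.0)
        np.add.at(diff, ok_e, -1.0)
        if wrap.any():
            ws, we = starts[wrap], ends[wrap] - L
            if we.max() > L:
                raise BoundsError("read wraps more than once around the chromosome")
            np.add.at(diff, ws - 1, 1.0)
            diff[L] += 0.0
            np.add.at(diff, np.zeros(len(we), dtype=np.int64), 1.0)
            np.add.at(diff, we, -1.0)
        full[s] = np.cumsum(diff[:L])
        five = starts if s == "+" else ends
        five = (five - 1) % L
        np.add.at(end5[s], five, 1.0)
    scale = 1.0
    if normalize:
        scale = 1e6 / lib.total_mapped
        for s in STRANDS:
            full[s] *= scale
            end5[s] *= scale
    return CoverageTracks(
        full_fwd=full["+"], full_rev=full["-"],
        end5_fwd=end5["+"], end5_rev=end5["-"],
        normalized=normalize, scale=scale,
    )


def count_reads(lib: LibraryAlignments, genome: GenomeModel) -> list[ExpressionRecord]:
    """Raw same-strand overlap counts per gene (>= 1 nt overlap; multi-counting).

    A read is counted for every gene it overlaps on the same strand, so
    overlapping genes may share reads.  RPKM is filled in as well.
    """
    records: list[ExpressionRecord] = []
    by_strand = {}
    for s in STRANDS:
        mask = lib.strands == s
        st = np.sort(lib.starts[mask])
        en = np.sort(lib.ends[mask])
        by_strand[s] = (st, en, int(mask.sum()))
    for g in genome.genes:
        st, en, n = by_strand[g.strand]
        # overlap iff read.start <= gene.end and read.end >= gene.start
        n_start_after = n - np.searchsorted(st, g.end, side="right")
        n_end_before = np.searchsorted(en, g.start, side="left")
        raw = int(n - n_start_after - n_end_before)
        value = rpkm(raw, g.length, lib.total_mapped) if lib.total_mapped else 0.0
        records.append(ExpressionRecord(g.id, lib.library_id, raw, value))
    return records


def rpkm(raw_reads: int, gene_length_nt: int, total_mapped: int) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_length_nt <= 0 or total_mapped <= 0:
        raise ValueError("gene length and total mapped reads must be positive")
    return raw_reads * 1e9 / (gene_length_nt * total_mapped)


def expression_table(libs: Sequence[LibraryAlignments], genome: GenomeModel) -> pd.DataFrame:
    """Tidy expression table (gene_id, library_id, raw_reads, rpkm) over libraries."""
    rows = []
    for lib in libs:
        for rec in count_reads(lib, genome):
            rows.append(dataclasses.asdict(rec))
    return pd.DataFrame(rows, columns=["gene_id", "library_id", "raw_reads", "rpkm"])


def write_bedgraph(tracks: CoverageTracks, prefix: str | Path, chrom: str = "chromosome") -> list[Path]:
    """Export all four tracks as bedGraph (suffixes .fwd/.rev, .5p.fwd/.5p.rev)."""
    prefix = Path(prefix)
    outputs = []
    for suffix, arr in [
        (".fwd.bedgraph", tracks.full_fwd),
        (".rev.bedgraph", tracks.full_rev),
        (".5p.fwd.bedgraph", tracks.end5_fwd),
        (".5p.rev.bedgraph", tracks.end5_rev),
    ]:
        path = prefix.with_name(prefix.name + suffix)
        with open(path, "w") as fh:
            _write_bedgraph_track(fh, arr, chrom)
        outputs.append(path)
    return outputs


def _write_bedgraph_track(fh, arr: np.ndarray, chrom: str) -> None:
    # run-length encode identical consecutive values, omitting zero runs
    change = np.flatnonzero(np.diff(arr) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(arr)]))
    for s, e in zip(starts, ends):
        v = arr[s]
        if v != 0:
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
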