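"""Seeded dRNA-seq data generator with planted ground truth.

The generator lays out a toy bacterial chromosome (default 50 kb, 60 genes)
whose scene contains every structure the analysis is designed to find:
operons (continuous, broken, and with a condition-dependent internal TSS),
leaderless and long-5'UTR genes, secondary and internal TSSs, mis-annotated
start codons, antisense RNAs over CDSs and UTRs, an excludon-like antisense
transcript spanning two divergently oriented genes, intergenic sRNAs
(including a 3'UTR-derived one and two small-ORF mRNAs), and genes
differentially expressed between growth phases or in response to root
exudate.  Twelve libraries (six samples x TEX+/-) are then simulated by
drawing read 5' ends from a per-transcript mixture of

* TSS-anchored ends (``tss_decay`` of the mass on the TSS itself, the
  remainder spread over the next five nucleotides),
* processing-site-anchored ends at discrete planted sites, and
* body-wide processed ends uniform along the transcript (random decay
  intermediates), plus a uniform genomic background.

Processed (5'-monophosphorylated) ends survive TEX treatment with
probability ``tex_depletion``; TSS-anchored (5'-triphosphorylated) ends
always survive.  Each library holds exactly ``depth_per_library`` reads, so
the TEX contrast manifests as a composition shift, exactly as it does in
real per-library-normalized dRNA-seq data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .genome_model import (
    Gene,
    GenomeModel,
    LibraryAlignments,
    write_alignments,
    write_genome,
)
from .tss_core import (
    AnnotatedTSS,
    ClassificationParams,
    SAMPLES,
    classify_tss,
)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = np.array(list("ACGT"))
SD = "AGGAGG"
STOPS = ("TAA", "TAG", "TGA")
START_CODONS = ("ATG", "GTG", "TTG")

#: samples grown in media containing maize root exudate / middle stationary phase
RE_SAMPLES = ("RE#6h", "RS#6h", "RS#9h")
LATE_SAMPLES = ("SE#9h", "RS#9h")

#: minimum clearance between a planted TSS/segment and foreign gene boundaries,
#: chosen above the 100-nt antisense window so planted categories are unambiguous
CLEAR = 110


@dataclass
class SimulationParams:
    seed: int = 42
    genome_length: int = 50_000
    n_genes: int = 60
    mean_gene_len: int = 450
    depth_per_library: int = 50_000
    tss_decay: float = 0.7
    tex_depletion: float = 0.1
    processed_site_rate: float = 0.5  # sites per kb of transcript (min. one per transcript)
    background_rate: float = 0.02
    read_length: int = 50
    primary_fraction: float = 0.30  # share of a transcript's 5' ends that are primary
    site_fraction: float = 0.10
    body_fraction: float = 0.60
    purine_bias: float = 0.8  # probability of A/G at the +1 position
    utr3_overhang: int = 25  # transcript extension past the stop codon

    def __post_init__(self) -> None:
        for name in ("tss_decay", "tex_depletion", "background_rate",
                     "primary_fraction", "site_fraction", "body_fraction", "purine_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = self.primary_fraction + self.site_fraction + self.body_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("primary/site/body fractions must sum to 1")
        if self.n_genes < 60:
            raise ValueError("the planted scene requires at least 60 genes")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class Transcript:
    id: str
    strand: str
    tss: int
    end3: int  # last transcribed position (end3 < tss on the minus strand)
    role: str
    weight_by_sample: dict[str, float]
    sites: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return abs(self.end3 - self.tss) + 1

    @property
    def sign(self) -> int:
        return 1 if self.strand == "+" else -1


@dataclass
class TruthTSS:
    pos: int
    strand: str
    categories: set[str]
    gene_links: dict[str, str]  # gene_id -> expected category
    active_samples: set[str]
    expected_height_rpm: float  # expected TEX+ 5'-end height, best sample


@dataclass
class TruthSegment:
    id: str
    start: int
    end: int
    strand: str
    seg_class: str
    flags: set[str] = field(default_factory=set)
    orf_aa: int | None = None


@dataclass
class SimulationTruth:
    params: SimulationParams
    transcripts: list[Transcript] = field(default_factory=list)
    tss: list[TruthTSS] = field(default_factory=list)
    segments: list[TruthSegment] = field(default_factory=list)
    utr_length: dict[str, int] = field(default_factory=dict)
    leaderless_genes: set[str] = field(default_factory=set)
    long_utr_genes: set[str] = field(default_factory=set)
    reannotations: dict[str, tuple[int, int]] = field(default_factory=dict)
    correct_start_genes: set[str] = field(default_factory=set)
    predicted_operons: list[tuple[str, list[str]]] = field(default_factory=list)
    operon_validated: dict[str, bool] = field(default_factory=dict)
    operon_monocistronic: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    de_fold: dict[str, dict[str, float]] = field(default_factory=dict)
    de_excluded: set[str] = field(default_factory=set)


class _SceneBuilder:
    """Linear left-to-right layout of genes, transcripts and planted features."""

    def __init__(self, params: SimulationParams, rng: np.random.Generator):
        self.p = params
        self.rng = rng
        self.truth = SimulationTruth(params=params)
        self.genes: list[Gene] = []
        self.cursor = 300  # furthest occupied coordinate (incl. transcript overhangs)

    # -- primitives ---------------------------------------------------------

    def gene(self, gid: str, strand: str, length: int, utr: int | None, role: str,
             weight, *, gap: int | None = None) -> Gene:
        """Place one gene; when ``utr`` is given, also its own primary transcript."""
        if gap is None:
            gap = CLEAR + (utr or 0) if strand == "+" else CLEAR
        start = self.cursor + gap + 1
        g = Gene(id=gid, start=start, end=start + length - 1, strand=strand,
                 kind="CDS", product=role)
        self.genes.append(g)
        self.cursor = max(self.cursor, g.end)
        if utr is not None:
            if strand == "+":
                tss, end3 = g.start - utr, g.end + self.p.utr3_overhang
            else:
                tss, end3 = g.end + utr, g.start - self.p.utr3_overhang
            self.transcript(f"tx_{gid}", strand, tss, end3, role, weight,
                            categories={"primary"}, links={gid: "primary"})
            self.truth.utr_length[gid] = utr
        return g

    def transcript(self, tid: str, strand: str, tss: int, end3: int, role: str,
                   weight, *, categories: set[str], links: dict[str, str] | None = None) -> Transcript:
        w = dict(weight) if isinstance(weight, dict) else dict.fromkeys(SAMPLES, float(weight))
        tx = Transcript(id=tid, strand=strand, tss=tss, end3=end3, role=role, weight_by_sample=w)
        self.truth.transcripts.append(tx)
        self.truth.tss.append(TruthTSS(
            pos=tss, strand=strand, categories=set(categories),
            gene_links=dict(links or {}),
            active_samples={s for s, v in w.items() if v > 0},
            expected_height_rpm=0.0,
        ))
        self.cursor = max(self.cursor, tss, end3)
        return tx

    # -- composite slots ----------------------------------------------------

    def leaderless(self, n: int, utr: int) -> None:
        gid = f"lead{n}"
        self.gene(gid, "-", 420, utr, "leaderless", 1.5)
        self.truth.leaderless_genes.add(gid)

    def secondary_host(self, n: int) -> None:
        gid = f"sec{n}"
        g = self.gene(gid, "-", 420, 40, "secondary_host", 2.0)
        tss2 = g.end + 80
        self.transcript(f"tx_{gid}_sec", "-", tss2, g.start - self.p.utr3_overhang,
                        "secondary", 0.7, categories={"secondary"}, links={gid: "secondary"})

    def internal_host(self, n: int) -> None:
        gid = f"int{n}"
        g = self.gene(gid, "+", 450, 30, "internal_host", 1.5)
        self.transcript(f"tx_{gid}_int", "+", g.start + 200, g.end + self.p.utr3_overhang,
                        "internal", 1.0, categories={"internal"}, links={gid: "internal"})

    def misannotated(self, n: int) -> None:
        gid = f"mis{n}"
        g = self.gene(gid, "+", 450, None, "misannotated", None, gap=140)
        t_off = int(self.rng.integers(15, 41))
        d = int(self.rng.integers(48, 88))
        d += (-(t_off + d)) % 3  # keep the new start in the annotated reading frame
        tss = g.start + t_off
        self.transcript(f"tx_{gid}", "+", tss, g.end + self.p.utr3_overhang,
                        "misannotated", 2.0, categories={"internal"}, links={gid: "internal"})
        self.truth.reannotations[gid] = (tss, tss + d)

    def de_gene(self, gid: str, strand: str, role: str) -> None:
        w = dict.fromkeys(SAMPLES, 1.5)
        if role == "growth_up":
            for s in LATE_SAMPLES:
                w[s] = 7.5
        elif role == "growth_down":
            w = {s: (7.5 if s not in LATE_SAMPLES else 1.5) for s in SAMPLES}
        elif role == "re_up":
            for s in RE_SAMPLES:
                w[s] = 6.0
        self.gene(gid, strand, 420, 30, role, w)

    def asrna_host(self, n: int) -> None:
        g = self.gene(f"host{n}", "+", 480, 30, "asrna_host", 1.5)
        tss, end3 = g.end - 30, g.end - 179
        self.transcript(f"as_cds{n}", "-", tss, end3, "asRNA_cds", 1.2,
                        categories={"antisense"}, links={g.id: "antisense"})
        self.truth.segments.append(TruthSegment(
            id=f"as_cds{n}", start=end3, end=tss, strand="-", seg_class="asRNA_cds"))

    def long_utr(self, n: int, utr: int, asrna: bool = False) -> None:
        gid = f"long{n}"
        g = self.gene(gid, "+", 420, utr, "long_utr", 1.5)
        self.truth.long_utr_genes.add(gid)
        if asrna:
            tss = g.start - 60  # within the antisense window of the gene start
            end3 = tss - 119
            self.transcript(f"as_utr{n}", "-", tss, end3, "asRNA_utr", 1.2,
                            categories={"antisense"}, links={gid: "antisense"})
            self.truth.segments.append(TruthSegment(
                id=f"as_utr{n}", start=end3, end=tss, strand="-", seg_class="asRNA_utr"))

    def srna(self, sid: str, length: int, *, gap: int = CLEAR, seg_class: str = "srna_candidate",
             flags: tuple[str, ...] = (), orf_aa: int | None = None) -> Transcript:
        tss = self.cursor + gap + 1
        tx = self.transcript(sid, "+", tss, tss + length - 1, seg_class, 2.0,
                             categories={"orphan"})
        self.truth.segments.append(TruthSegment(
            id=sid, start=tss, end=tss + length - 1, strand="+",
            seg_class=seg_class, flags=set(flags), orf_aa=orf_aa))
        return tx

    # -- multi-gene structures ----------------------------------------------

    def operon_plus(self, oid: str, lengths: list[int], gaps: list[int], weight,
                    utr: int = 30) -> list[Gene]:
        members = []
        for i, length in enumerate(lengths):
            gap = None if i == 0 else gaps[i - 1]
            g = self.gene(f"{oid}{i + 1}", "+", length, None,
                          "operon", None, gap=(CLEAR + utr) if i == 0 else gap)
            members.append(g)
        self.transcript(f"tx_{oid}", "+", members[0].start - utr,
                        members[-1].end + self.p.utr3_overhang, "operon", weight,
                        categories={"primary"}, links={members[0].id: "primary"})
        self.truth.utr_length[members[0].id] = utr
        return members

    def operon_minus(self, oid: str, lengths: list[int], gap: int, weight,
                     utr: int = 30) -> list[Gene]:
        # chromosome order is 3' gene first; gene ids number 5'->3'
        n = len(lengths)
        members = []
        for i, length in enumerate(lengths):
            g = self.gene(f"{oid}{n - i}", "-", length, None, "operon", None,
                          gap=CLEAR if i == 0 else gap)
            members.append(g)
        first = members[-1]  # rightmost = 5' first gene
        self.transcript(f"tx_{oid}", "-", first.end + utr,
                        members[0].start - self.p.utr3_overhang, "operon", weight,
                        categories={"primary"}, links={first.id: "primary"})
        self.truth.utr_length[first.id] = utr
        return members


def _decay_probs(decay: float) -> np.ndarray:
    rest = (1.0 - decay) / 5.0
    return np.array([decay] + [rest] * 5)


def generate_genome(params: SimulationParams | None = None) -> tuple[GenomeModel, SimulationTruth]:
    """Build the planted chromosome; byte-identical output for a fixed seed."""
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    b = _SceneBuilder(params, rng)
    t = b.truth

    # -- scene --------------------------------------------------------------
    b.operon_plus("opA", [600, 600, 600], [18, 18], 3.0)
    b.srna("srnaA", 150)
    b.leaderless(1, 2)
    lead_utrs = iter((4, 5, 6, 7))
    for i in (1, 2, 3, 4):
        b.misannotated(i)
        b.leaderless(i + 1, next(lead_utrs))
    b.de_gene("growth_up1", "+", "growth_up")
    b.asrna_host(1)
    b.long_utr(1, 115, asrna=True)
    b.srna("srnaB", 160)
    b.srna("smorf1", 220, seg_class="small_orf_mrna", orf_aa=41)
    b.secondary_host(1)
    for i in (5, 6, 7, 8):
        b.misannotated(i)
        b.secondary_host(i - 3)
    b.de_gene("growth_up2", "+", "growth_up")
    b.asrna_host(2)
    b.long_utr(2, 140, asrna=True)
    b.srna("srnaC", 140)
    b.srna("smorf2", 220, seg_class="small_orf_mrna", orf_aa=60)
    b.de_gene("growth_down1", "-", "growth_down")
    followers = ["growth_down2", "re_up1", "re_up2", "re_up3"]
    for i, fol in zip((1, 2, 3, 4), followers):
        b.internal_host(i)
        role = "growth_down" if fol.startswith("growth_down") else "re_up"
        b.de_gene(fol, "-", role)
    b.internal_host(5)
    b.de_gene("re_up4", "-", "re_up")
    b.de_gene("growth_up3", "+", "growth_up")
    b.asrna_host(3)
    b.long_utr(3, 160)
    b.srna("srnaD", 170)
    b.operon_minus("opB", [600, 600], 18, 3.0)
    b.de_gene("growth_up4", "+", "growth_up")
    b.asrna_host(4)
    b.long_utr(4, 190)
    b.srna("srnaE", 130)
    # excludon: two '-' genes spanned by one long '+' antisense transcript
    e1 = b.gene("excl1", "-", 420, 30, "excludon", 1.2)
    e2 = b.gene("excl2", "-", 420, 30, "excludon", 1.2, gap=30)
    b.transcript("as_excl", "+", e1.start + 200, e2.start + 150, "asRNA_cds", 1.5,
                 categories={"antisense"}, links={e1.id: "antisense", e2.id: "antisense"})
    t.segments.append(TruthSegment(id="as_excl", start=e1.start + 200, end=e2.start + 150,
                                   strand="+", seg_class="asRNA_cds", flags={"excludon_like"}))
    b.de_gene("growth_up5", "+", "growth_up")
    # broken operon predictions: adjacent same-strand genes transcribed separately
    bp1a = b.gene("bp1a", "+", 450, 30, "broken_pair", 1.5)
    bp1b = b.gene("bp1b", "+", 450, 30, "broken_pair", 1.5, gap=125)
    b.long_utr(5, 230)
    b.srna("srna3utr", 150, gap=40 - params.utr3_overhang,
           flags=("three_prime_utr_derived",))
    bp2a = b.gene("bp2a", "-", 450, 30, "broken_pair", 1.5)
    bp2b = b.gene("bp2b", "-", 450, 30, "broken_pair", 1.5, gap=120)
    b.de_gene("growth_up6", "+", "growth_up")
    # operon C: polycistronic at ESP, internal gene fires its own TSS at MSP
    w_poly = {s: (0.05 if s in LATE_SAMPLES else 3.0) for s in SAMPLES}
    w_switch = {s: (3.0 if s in LATE_SAMPLES else 0.0) for s in SAMPLES}
    c1 = b.gene("opC1", "+", 600, None, "operon", None, gap=CLEAR + 30)
    c2 = b.gene("opC2", "+", 550, None, "operon", None, gap=60)
    c3 = b.gene("opC3", "+", 400, None, "operon", None, gap=18)
    b.transcript("tx_opC", "+", c1.start - 30, c3.end + params.utr3_overhang,
                 "operon", w_poly, categories={"primary"}, links={c1.id: "primary"})
    t.utr_length["opC1"] = 30
    b.transcript("tx_opC_switch", "+", c2.start - 25, c3.end + params.utr3_overhang,
                 "switch", w_switch, categories={"primary"}, links={c2.id: "primary"})
    t.utr_length["opC2"] = 25
    b.srna("srnaF", 150)
    b.de_gene("ctrl1", "-", "plain")
    b.de_gene("ctrl2", "+", "plain")
    for i in range(params.n_genes - 60):
        b.de_gene(f"extra{i + 1}", "+" if i % 2 == 0 else "-", "plain")

    if b.cursor + 300 > params.genome_length:
        raise ValueError(
            f"infeasible packing: scene needs {b.cursor + 300} nt, genome is {params.genome_length}"
        )

    # -- DE / operon truth ---------------------------------------------------
    up = [g.id for g in b.genes if g.product == "growth_up"]
    down = [g.id for g in b.genes if g.product == "growth_down"]
    re_up = [g.id for g in b.genes if g.product == "re_up"]
    for comp in ("SE#9h|SE#6h", "RS#9h|RS#6h"):
        t.de_fold[comp] = {**{g: 5.0 for g in up}, **{g: 0.2 for g in down}}
    t.de_fold["RS#9h|SE#9h"] = {g: 4.0 for g in re_up}
    t.de_excluded = {"opC1", "opC2", "opC3"}
    t.predicted_operons = [
        ("opA", ["opA1", "opA2", "opA3"]),
        ("opB", ["opB1", "opB2"]),
        ("opC", ["opC1", "opC2", "opC3"]),
        ("bp1", ["bp1a", "bp1b"]),
        ("bp2", ["bp2b", "bp2a"]),
    ]
    t.operon_validated = {"opA": True, "opB": True, "opC": True, "bp1": False, "bp2": False}
    # the broken pairs are genuine monocistronic-within-predicted-operon cases:
    # the downstream gene fires its own TSS whenever it is expressed (all samples)
    t.operon_monocistronic = {"opA": {}, "opB": {},
                              "bp1": {"bp1b": sorted(SAMPLES)},
                              "bp2": {"bp2a": sorted(SAMPLES)},
                              "opC": {"opC2": sorted(LATE_SAMPLES)}}
    t.correct_start_genes = {g.id for g in b.genes if g.id not in t.reannotations}

    # -- sequence planting ---------------------------------------------------
    seq = rng.integers(0, 4, size=params.genome_length)
    for g in b.genes:
        _plant_gene_signals(seq, g)
    for gid, (tss, new_start) in t.reannotations.items():
        g = next(x for x in b.genes if x.id == gid)
        _plant(seq, new_start, "ATG")
        _plant(seq, new_start - 13, SD)
        for p in range(g.start, new_start, 3):  # scrub competing in-frame starts
            if p >= tss + 40 and _codon(seq, p) in START_CODONS:
                _plant(seq, p, "CTG")
    for seg in t.segments:
        if seg.seg_class == "small_orf_mrna":
            _plant_small_orf(seq, seg)
        if seg.seg_class in ("small_orf_mrna", "srna_candidate"):
            _scrub_orfs(seq, seg)
    for entry in t.tss:  # +1 purine bias
        purine = rng.random() < params.purine_bias
        pool = ("A", "G") if purine else ("C", "T")
        base = pool[int(rng.integers(0, 2))]
        if entry.strand == "-":
            base = {"A": "T", "G": "C", "C": "G", "T": "A"}[base]
        seq[entry.pos - 1] = _CODE[base]

    genome = GenomeModel(sequence="".join(_BASE[seq]), genes=b.genes, circular=True)

    _place_processing_sites(t, rng)
    _fill_expected_heights(t, params)
    _verify_scene(genome, t)
    return genome, t


def _plant(seq: np.ndarray, pos: int, motif: str) -> None:
    for i, c in enumerate(motif):
        seq[pos - 1 + i] = _CODE[c]


def _codon(seq: np.ndarray, pos: int) -> str:
    return "".join(_BASE[seq[pos - 1 : pos + 2]])


def _plant_gene_signals(seq: np.ndarray, g: Gene) -> None:
    """Start codon, stop codon and an SD hexamer at 7-nt spacing for one gene."""
    if g.strand == "+":
        _plant(seq, g.start, "ATG")
        _plant(seq, g.end - 2, "TAA")
        _plant(seq, g.start - 13, SD)
    else:
        _plant(seq, g.end - 2, "CAT")  # revcomp(ATG)
        _plant(seq, g.start, "TTA")  # revcomp(TAA)
        _plant(seq, g.end + 8, "CCTCCT")  # revcomp(AGGAGG), spacer 7


def _plant_small_orf(seq: np.ndarray, seg: TruthSegment) -> None:
    """An SD-led ORF of ``seg.orf_aa`` codons 30 nt into a '+' segment."""
    orf = seg.start + 30
    _plant(seq, orf - 13, SD)
    _plant(seq, orf, "ATG")
    rng = np.random.default_rng(seg.start)  # content-local; reproducible per scene
    for k in range(1, seg.orf_aa):
        codon = "".join(_BASE[rng.integers(0, 4, 3)])
        while codon in STOPS or codon in START_CODONS:
            codon = "".join(_BASE[rng.integers(0, 4, 3)])
        _plant(seq, orf + 3 * k, codon)
    _plant(seq, orf + 3 * seg.orf_aa, "TAA")


def _find_orfs(seq: np.ndarray, lo: int, hi: int) -> list[tuple[int, int]]:
    """SD-led 30-99 aa ORFs on the '+' strand inside [lo, hi] (generator-side scan)."""
    hits = []
    for p in range(lo, hi - 1):
        if _codon(seq, p) not in START_CODONS:
            continue
        if not any(
            sum(1 for a, c in zip(_BASE[seq[p - sp - 7 : p - sp - 1]], SD) if a == c) >= 4
            for sp in range(5, 10)
        ):
            continue
        aa, q = 0, p
        while q + 2 <= hi:
            if _codon(seq, q) in STOPS:
                if 30 <= aa <= 99:
                    hits.append((p, aa))
                break
            aa += 1
            q += 3
    return hits


def _scrub_orfs(seq: np.ndarray, seg: TruthSegment) -> None:
    """Mutate accidental SD-led start codons so only the planted ORF (if any) remains."""
    planted = seg.start + 30 if seg.seg_class == "small_orf_mrna" else None
    for _ in range(50):
        extra = [p for p, _aa in _find_orfs(seq, seg.start, seg.end) if p != planted]
        if not extra:
            return
        for p in extra:
            seq[p] = _CODE["C"]  # middle base: ATG/GTG/TTG -> ACG/GCG/TCG
    raise RuntimeError("could not scrub accidental ORFs from a planted segment")


def _place_processing_sites(truth: SimulationTruth, rng: np.random.Generator) -> None:
    p = truth.params
    tss_by_strand = {"+": set(), "-": set()}
    for e in truth.tss:
        tss_by_strand[e.strand].add(e.pos)
    for tx in truth.transcripts:
        n = max(1, int(rng.poisson(p.processed_site_rate * tx.length / 1000.0)))
        sites: list[int] = []
        guard = 0
        while len(sites) < n and guard < 200:
            guard += 1
            off = int(rng.integers(40, tx.length - 29))
            pos = tx.tss + tx.sign * off
            if any(abs(pos - q) < 30 for q in tss_by_strand[tx.strand]):
                continue
            sites.append(pos)
        if not sites:  # degenerate fallback: mid-transcript
            sites = [tx.tss + tx.sign * (tx.length // 2)]
        tx.sites = sorted(sites)


def _tex_plus_denominator(truth: SimulationTruth, sample: str) -> float:
    p = truth.params
    return sum(
        tx.weight_by_sample[sample]
        * (p.primary_fraction + (p.site_fraction + p.body_fraction) * p.tex_depletion)
        for tx in truth.transcripts
    )


def _fill_expected_heights(truth: SimulationTruth, params: SimulationParams) -> None:
    for entry, tx in zip(truth.tss, truth.transcripts):
        best = 0.0
        for s in entry.active_samples:
            denom = _tex_plus_denominator(truth, s)
            share = tx.weight_by_sample[s] * params.primary_fraction / denom
            best = max(best, (1 - params.background_rate) * share * params.tss_decay * 1e6)
        entry.expected_height_rpm = best


def _verify_scene(genome: GenomeModel, truth: SimulationTruth) -> None:
    """Planted TSS geometry must be unambiguous under the classification rules."""
    tss_objs = [
        AnnotatedTSS(pos=e.pos, strand=e.strand,
                     height_by_library={"expected": e.expected_height_rpm},
                     detected_samples=set(e.active_samples))
        for e in truth.tss
    ]
    classify_tss(tss_objs, genome.genes, ClassificationParams())
    for e, obj in zip(truth.tss, tss_objs):
        if obj.categories != e.categories:
            raise RuntimeError(
                f"planted TSS at {e.pos}{e.strand} classifies as {sorted(obj.categories)}, "
                f"planted as {sorted(e.categories)}"
            )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_libraries(
    genome: GenomeModel,
    truth: SimulationTruth,
    params: SimulationParams | None = None,
) -> list[LibraryAlignments]:
    """Simulate the 12 libraries (six samples x TEX+/-), deterministic per seed."""
    params = params or truth.params
    rng = np.random.default_rng(params.seed + 1)
    libs = []
    for sample in SAMPLES:
        medium, timepoint = sample.split("#")
        for tex in (False, True):
            libs.append(_simulate_library(truth.transcripts, sample, medium, timepoint,
                                          tex, params, rng, len(genome)))
    return libs


def _simulate_library(
    transcripts: list[Transcript],
    sample: str,
    medium: str,
    timepoint: str,
    tex: bool,
    params: SimulationParams,
    rng: np.random.Generator,
    genome_length: int,
) -> LibraryAlignments:
    p = params
    dep = p.tex_depletion if tex else 1.0
    comp_w = []
    for tx in transcripts:
        w = tx.weight_by_sample.get(sample, 0.0)
        comp_w.extend([w * p.primary_fraction, w * p.site_fraction * dep, w * p.body_fraction * dep])
    comp_w = np.array(comp_w)
    n_bg = int(rng.binomial(p.depth_per_library, p.background_rate)) if p.background_rate else 0
    n_tx = p.depth_per_library - n_bg
    pos_list, strand_list = [], []
    if comp_w.sum() > 0 and n_tx > 0:
        counts = rng.multinomial(n_tx, comp_w / comp_w.sum())
    else:
        counts = np.zeros(len(comp_w), dtype=int)
        n_bg = p.depth_per_library
    decay = _decay_probs(p.tss_decay)
    for i, tx in enumerate(transcripts):
        n_pri, n_site, n_body = counts[3 * i : 3 * i + 3]
        sign = tx.sign
        if n_pri:
            offs = rng.choice(6, size=n_pri, p=decay)
            pos_list.append(tx.tss + sign * offs)
        if n_site:
            pos_list.append(rng.choice(np.array(tx.sites), size=n_site))
        if n_body:
            offs = rng.integers(10, tx.length - 4, size=n_body)
            pos_list.append(tx.tss + sign * offs)
        total = n_pri + n_site + n_body
        if total:
            strand_list.append(np.full(total, tx.strand, dtype="U1"))
    if n_bg:
        pos_list.append(rng.integers(1, genome_length + 1, size=n_bg))
        strand_list.append(np.where(rng.random(n_bg) < 0.5, "+", "-").astype("U1"))
    pos = np.concatenate(pos_list) if pos_list else np.empty(0, dtype=np.int64)
    strands = np.concatenate(strand_list) if strand_list else np.empty(0, dtype="U1")
    ends3 = np.empty(len(pos), dtype=np.int64)
    k = 0
    for i, tx in enumerate(transcripts):
        n = int(counts[3 * i : 3 * i + 3].sum())
        ends3[k : k + n] = tx.end3
        k += n
    ends3[k:] = -1  # background reads: clip at genome bounds only
    plus = strands == "+"
    starts = np.where(plus, pos, np.maximum(pos - p.read_length + 1, 1))
    ends = np.where(plus, np.minimum(pos + p.read_length - 1, genome_length), pos)
    tx_mask = ends3 >= 0
    starts[tx_mask & ~plus] = np.maximum(starts[tx_mask & ~plus], ends3[tx_mask & ~plus])
    ends[tx_mask & plus] = np.minimum(ends[tx_mask & plus], ends3[tx_mask & plus])
    order = np.lexsort((ends, starts, strands))
    lib_id = f"{medium}#{timepoint}#TEX{'+' if tex else '-'}"
    return LibraryAlignments(
        library_id=lib_id, medium=medium, timepoint=timepoint, tex=tex,
        starts=starts[order], ends=ends[order], strands=strands[order],
    )


# ---------------------------------------------------------------------------
# evaluation and serialisation
# ---------------------------------------------------------------------------

def evaluate_calls(
    calls: list[tuple[int, str]],
    truth_positions: list[tuple[int, str]],
    tolerance_nt: int = 1,
) -> dict:
    """Greedy nearest matching of calls to planted positions on the same strand.

    Each call matches at most one truth entry within +-tolerance.  Precision
    is reported as None (NA) when there are no calls.
    """
    if tolerance_nt < 0:
        raise ValueError("tolerance must be >= 0")
    pairs = []
    for ci, (cp, cs) in enumerate(calls):
        for ti, (tp, ts) in enumerate(truth_positions):
            if cs == ts and abs(cp - tp) <= tolerance_nt:
                pairs.append((abs(cp - tp), ci, ti))
    pairs.sort()
    used_c, used_t, matches = set(), set(), []
    for _d, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        matches.append((ci, ti))
    recall = len(matches) / len(truth_positions) if truth_positions else 0.0
    precision = len(matches) / len(calls) if calls else None
    return {
        "n_calls": len(calls),
        "n_truth": len(truth_positions),
        "n_matched": len(matches),
        "recall": recall,
        "precision": precision,
        "matches": matches,
    }


def library_file_stem(lib: LibraryAlignments) -> str:
    return lib.library_id.replace("#", "_").replace("+", "plus").replace("-", "minus")


def truth_to_dict(truth: SimulationTruth) -> dict:
    return {
        "params": dataclasses.asdict(truth.params),
        "transcripts": [
            {**dataclasses.asdict(tx)} for tx in truth.transcripts
        ],
        "tss": [
            {"pos": e.pos, "strand": e.strand, "categories": sorted(e.categories),
             "gene_links": e.gene_links, "active_samples": sorted(e.active_samples),
             "expected_height_rpm": e.expected_height_rpm}
            for e in truth.tss
        ],
        "segments": [
            {"id": s.id, "start": s.start, "end": s.end, "strand": s.strand,
             "class": s.seg_class, "flags": sorted(s.flags), "orf_aa": s.orf_aa}
            for s in truth.segments
        ],
        "utr_length": truth.utr_length,
        "leaderless_genes": sorted(truth.leaderless_genes),
        "long_utr_genes": sorted(truth.long_utr_genes),
        "reannotations": {k: list(v) for k, v in truth.reannotations.items()},
        "predicted_operons": [[oid, gids] for oid, gids in truth.predicted_operons],
        "operon_validated": truth.operon_validated,
        "operon_monocistronic": truth.operon_monocistronic,
        "de_fold": truth.de_fold,
        "de_excluded": sorted(truth.de_excluded),
    }


def simulate_dataset(params: SimulationParams, outdir: str | Path) -> tuple[GenomeModel, SimulationTruth, list[LibraryAlignments]]:
    """Generate genome + 12 libraries and write everything to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = generate_genome(params)
    libs = simulate_libraries(genome, truth, params)
    write_genome(genome, outdir / "genome.fasta", outdir / "annotation.gff3")
    for lib in libs:
        write_alignments(lib, outdir / f"{library_file_stem(lib)}.bed", chrom=genome.name)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_to_dict(truth), fh, indent=1, sort_keys=True)
    params.to_yaml(outdir / "params.yaml")
    with open(outdir / "predicted_operons.tsv", "w") as fh:
        fh.write("operon_id\tgene_ids\n")
        for oid, gids in truth.predicted_operons:
            fh.write(f"{oid}\t{','.join(gids)}\n")
    return genome, truth, libs
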