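"""TEX-enrichment TSS detection, cross-sample clustering and classification.

Detection works per sample on the paired TEX+/TEX- coverage tracks and calls
a position a TSS candidate when three gates all pass:

* the TEX+ 5'-end height reaches ``min_step_height`` (RPM),
* the TEX+ full coverage steps up by ``min_step_factor`` relative to the
  strand-aware upstream neighbour,
* the TEX+/TEX- 5'-end ratio (with a pseudocount on the denominator)
  reaches ``min_enrichment``.

Candidates from the six samples are clustered within a small window and each
consolidated TSS is classified against the annotation into the five standard
positional categories: primary, secondary, internal, antisense, orphan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .genome_model import CoverageTracks, Gene, STRANDS

SAMPLES = ("1CM#6h", "RE#6h", "SE#6h", "RS#6h", "SE#9h", "RS#9h")
CATEGORIES = ("primary", "secondary", "internal", "antisense", "orphan")

_TINY = 1e-12  # machine-min stand-in for empty upstream coverage


@dataclass
class TSSDetectionParams:
    """Thresholds for per-sample TSS calling.

    ``min_step_height`` is in RPM and its default (100 RPM) corresponds to
    five reads at the bundled generator's default depth of 50,000 reads per
    library — roughly the logarithmic midpoint between the Poisson
    coincidence tail of TEX-surviving processed 5' ends and the weakest
    genuine TSS signal.  For deeply sequenced real libraries (1e7-1e8 reads)
    values in the 0.1-1 RPM range are the conventional operating point.
    """

    min_step_height: float = 100.0
    min_step_factor: float = 2.0
    min_enrichment: float = 2.0
    pseudocount: float = 1.0
    cluster_window: int = 3

    def __post_init__(self) -> None:
        for name in ("min_step_height", "min_step_factor", "min_enrichment", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.cluster_window <= 0:
            raise ValueError("cluster_window must be > 0")


@dataclass
class ClassificationParams:
    primary_window: int = 500
    antisense_window: int = 100

    def __post_init__(self) -> None:
        if self.primary_window <= 0 or self.antisense_window <= 0:
            raise ValueError("windows must be > 0")


@dataclass(frozen=True)
class TSSCandidate:
    """A per-sample detection: position, strand, TEX+ 5'-end height, enrichment."""

    pos: int
    strand: str
    height: float
    enrichment: float
    sample: str


@dataclass
class AnnotatedTSS:
    """A consolidated TSS with per-library heights and category labels."""

    pos: int
    strand: str
    height_by_library: dict[str, float] = field(default_factory=dict)
    enrichment_by_sample: dict[str, float] = field(default_factory=dict)
    categories: set[str] = field(default_factory=set)
    gene_links: list[tuple[str, str, int]] = field(default_factory=list)
    detected_samples: set[str] = field(default_factory=set)

    @property
    def max_height(self) -> float:
        """Strongest expression: maximal normalized 5'-end height over libraries."""
        return max(self.height_by_library.values()) if self.height_by_library else 0.0


def detect_sample_tss(
    tex_plus: CoverageTracks,
    tex_minus: CoverageTracks,
    params: TSSDetectionParams | None = None,
    sample: str = "",
    library_id: str = "",
    circular: bool = True,
) -> list[TSSCandidate]:
    """Call TSS candidates on one sample from its TEX+/TEX- track pair."""
    params = params or TSSDetectionParams()
    if not (tex_plus.normalized and tex_minus.normalized):
        raise ValueError("detection requires normalized (RPM) coverage tracks")
    if len(tex_plus) != len(tex_minus):
        raise ValueError("TEX+ and TEX- tracks must cover the same genome")
    out: list[TSSCandidate] = []
    for strand in STRANDS:
        e5p = tex_plus.end5(strand)
        e5m = tex_minus.end5(strand)
        full = tex_plus.full(strand)
        upstream = _shift_upstream(full, strand, circular)
        step = full / np.maximum(upstream, _TINY)
        enrich = e5p / (e5m + params.pseudocount)
        called = (
            (e5p >= params.min_step_height)
            & (step >= params.min_step_factor)
            & (enrich >= params.min_enrichment)
        )
        for idx in np.flatnonzero(called):
            out.append(
                TSSCandidate(
                    pos=int(idx) + 1,
                    strand=strand,
                    height=float(e5p[idx]),
                    enrichment=float(enrich[idx]),
                    sample=sample or library_id,
                )
            )
    out.sort(key=lambda c: (c.strand, c.pos))
    return out


def _shift_upstream(full: np.ndarray, strand: str, circular: bool) -> np.ndarray:
    """Full coverage at the strand-aware upstream neighbour of each position."""
    if strand == "+":
        up = np.roll(full, 1)
        if not circular:
            up[0] = 0.0
    else:
        up = np.roll(full, -1)
        if not circular:
            up[-1] = 0.0
    return up


def cluster_tss(
    candidates_by_sample: dict[str, list[TSSCandidate]],
    cluster_window: int = 3,
    library_of_sample: dict[str, str] | None = None,
) -> list[AnnotatedTSS]:
    """Consolidate per-sample candidates into one TSS list.

    Candidates on the same strand whose positions chain within
    ``cluster_window`` nt are merged.  The representative position is the
    candidate of maximal height over all samples; ties go to the most
    upstream position (strand-aware).  ``detected_samples`` is the union of
    contributing samples.
    """
    library_of_sample = library_of_sample or {}
    pooled: list[TSSCandidate] = []
    for sample, cands in candidates_by_sample.items():
        for c in cands:
            pooled.append(c if c.sample == sample else TSSCandidate(c.pos, c.strand, c.height, c.enrichment, sample))
    result: list[AnnotatedTSS] = []
    for strand in STRANDS:
        group = sorted((c for c in pooled if c.strand == strand), key=lambda c: c.pos)
        cluster: list[TSSCandidate] = []
        for c in group:
            if cluster and c.pos - cluster[-1].pos > cluster_window:
                result.append(_consolidate(cluster, strand, library_of_sample))
                cluster = []
            cluster.append(c)
        if cluster:
            result.append(_consolidate(cluster, strand, library_of_sample))
    result.sort(key=lambda t: (t.strand, t.pos))
    return result


def _consolidate(cluster: list[TSSCandidate], strand: str,
                 library_of_sample: dict[str, str]) -> AnnotatedTSS:
    upstream_sign = 1 if strand == "+" else -1
    best = max(cluster, key=lambda c: (c.height, upstream_sign * -c.pos))
    tss = AnnotatedTSS(pos=best.pos, strand=strand)
    for c in cluster:
        lib = library_of_sample.get(c.sample, c.sample)
        tss.height_by_library[lib] = max(tss.height_by_library.get(lib, 0.0), c.height)
        tss.enrichment_by_sample[c.sample] = max(
            tss.enrichment_by_sample.get(c.sample, 0.0), c.enrichment
        )
        tss.detected_samples.add(c.sample)
    return tss


def classify_tss(
    tss_list: list[AnnotatedTSS],
    genes: list[Gene],
    params: ClassificationParams | None = None,
) -> list[AnnotatedTSS]:
    """Assign the five positional categories to a consolidated TSS set.

    Per gene, the strongest TSS (maximal height over libraries) within the
    upstream window on the sense strand is primary and all others secondary;
    sense-strand TSSs strictly inside a gene body are internal for that
    gene; opposite-strand TSSs inside a gene or within the antisense window
    of its boundaries are antisense; a TSS with no link at all is orphan.
    Multi-category membership across different genes is allowed; categories
    are filled in place and the same list is returned.
    """
    params = params or ClassificationParams()
    for t in tss_list:
        t.categories = set()
        t.gene_links = []
    primary_candidates: dict[str, list[AnnotatedTSS]] = {}
    for t in tss_list:
        for g in genes:
            if g.strand == t.strand:
                d_up = (g.start - t.pos) if g.strand == "+" else (t.pos - g.end)
                if 0 <= d_up <= params.primary_window:
                    primary_candidates.setdefault(g.id, []).append(t)
                if g.start < t.pos < g.end:
                    t.categories.add("internal")
                    t.gene_links.append((g.id, "internal", _signed_distance(t, g)))
            else:
                if g.start - params.antisense_window <= t.pos <= g.end + params.antisense_window:
                    t.categories.add("antisense")
                    t.gene_links.append((g.id, "antisense", _signed_distance(t, g)))
    for gid, cands in primary_candidates.items():
        g = next(x for x in genes if x.id == gid)
        upstream_sign = 1 if g.strand == "+" else -1
        primary = max(cands, key=lambda t: (t.max_height, upstream_sign * -t.pos))
        for t in cands:
            cat = "primary" if t is primary else "secondary"
            t.categories.add(cat)
            t.gene_links.append((gid, cat, _signed_distance(t, g)))
    for t in tss_list:
        if not t.categories:
            t.categories = {"orphan"}
    return tss_list


def _signed_distance(t: AnnotatedTSS, g: Gene) -> int:
    """Distance from TSS to the annotated translation start; positive = upstream."""
    return (g.start - t.pos) if g.strand == "+" else (t.pos - g.end)


def condition_specific_tss(tss_set: list[AnnotatedTSS]) -> dict[str, list[AnnotatedTSS]]:
    """TSSs detected in exactly one sample, bucketed by that sample."""
    out: dict[str, list[AnnotatedTSS]] = {}
    for t in tss_set:
        if len(t.detected_samples) == 1:
            (sample,) = t.detected_samples
            out.setdefault(sample, []).append(t)
    return out


def category_overlap_counts(tss_set: list[AnnotatedTSS]) -> pd.DataFrame:
    """Counts per category and per category combination (Venn-style table)."""
    rows = []
    for r in range(1, len(CATEGORIES) + 1):
        for combo in combinations(CATEGORIES, r):
            n = sum(1 for t in tss_set if set(combo) <= t.categories)
            rows.append({"categories": "+".join(combo), "count": n})
    return pd.DataFrame(rows)


def tss_table(tss_set: list[AnnotatedTSS]) -> pd.DataFrame:
    """Flat TSV-ready table of a classified TSS set."""
    rows = []
    for t in tss_set:
        rows.append(
            {
                "pos": t.pos,
                "strand": t.strand,
                "categories": ";".join(sorted(t.categories)),
                "gene_links": ";".join(f"{g}:{c}:{d}" for g, c, d in sorted(t.gene_links)),
                "max_height": t.max_height,
                "detected_samples": ";".join(sorted(t.detected_samples)),
            }
        )
    return pd.DataFrame(rows, columns=["pos", "strand", "categories", "gene_links",
                                       "max_height", "detected_samples"])


def write_tss_gff3(tss_set: list[AnnotatedTSS], path, chrom: str = "chromosome") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, t in enumerate(sorted(tss_set, key=lambda t: (t.pos, t.strand)), start=1):
            attrs = f"ID=TSS{i};categories={','.join(sorted(t.categories))}"
            fh.write(f"{chrom}\tprimarytx\tTSS\t{t.pos}\t{t.pos}\t.\t{t.strand}\t.\t{attrs}\n")
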