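import numpy as np
import pandas as pd
import pytest

from primarytx.genome_model import Gene, GenomeModel, LibraryAlignments, coverage
from primarytx.srna_discovery import (
    IGRSegment,
    SrnaParams,
    _floor,
    _gene_mask,
    classify_segment,
    match_known_srnas,
    segment_igrs,
    small_orf_scan,
    three_prime_utr_regions,
)

from oracles import brute_segment_strand


def _genome(genes, length=5000):
    return GenomeModel(sequence="".join("ACGT"[i % 4] for i in range(length)),
                       genes=genes, circular=False)


def _lib(reads, tex=False):
    return LibraryAlignments.from_reads("SE#9h#TEX-", "SE", "9h", tex, reads)


GENES = [Gene("gL", 500, 1900, "+"), Gene("gR", 3100, 4500, "+")]


def _segment_reads(lo, hi, n, strand="+", read_len=50):
    """n reads tiling [lo, hi] evenly on one strand."""
    starts = np.linspace(lo, hi - read_len, n).astype(int)
    return [(int(s), int(s) + read_len - 1, strand) for s in starts]


class TestSegmentation:
    def test_abundant_igr_transcript_yields_one_segment(self):
        genome = _genome(GENES)
        lib = _lib(_segment_reads(2100, 2300, 120))
        (seg,) = segment_igrs([lib], genome)
        assert seg.strand == "+"
        assert abs(seg.start - 2100) <= 5 and abs(seg.end - 2300) <= 5
        assert seg.raw_reads == 120

    def test_weak_transcript_fails_strict_raw_filter(self):
        genome = _genome(GENES)
        assert segment_igrs([_lib(_segment_reads(2100, 2300, 30))], genome) == []
        # exactly at the floor is still rejected (strict >)
        assert segment_igrs([_lib(_segment_reads(2100, 2300, 50))], genome) == []

    def test_run_continuous_with_gene_body_is_discarded_as_extension(self):
        genome = _genome(GENES)
        lib = _lib(_segment_reads(1700, 2300, 300))  # flows out of gL into the IGR
        assert segment_igrs([lib], genome) == []

    def test_gap_between_gene_and_segment_keeps_it(self):
        genome = _genome(GENES)
        lib = _lib(_segment_reads(1700, 1880, 100) + _segment_reads(2100, 2300, 120))
        (seg,) = segment_igrs([lib], genome)
        assert seg.start >= 2090

    def test_tex_treated_library_rejected(self):
        with pytest.raises(ValueError):
            segment_igrs([_lib([], tex=True)], _genome(GENES))

    def test_boundaries_match_positionwise_oracle(self):
        params = SrnaParams()
        for seed in range(20):
            rng = np.random.default_rng(seed)
            genome = _genome(GENES)
            reads = []
            for _ in range(int(rng.integers(1, 4))):
                lo = int(rng.integers(1950, 2700))
                hi = lo + int(rng.integers(120, 350))
                reads += _segment_reads(lo, hi, int(rng.integers(60, 200)))
            n_noise = int(rng.integers(0, 60))
            noise_starts = rng.integers(1, 4900, n_noise)
            reads += [(int(s), int(s) + 49, "+") for s in noise_starts]
            lib = _lib(reads)
            tracks = coverage(lib, len(genome), normalize=True)
            got = {(s.start, s.end) for s in segment_igrs([lib], genome, params)}
            cov = tracks.full("+")
            in_gene = _gene_mask(genome.genes, "+", len(genome))
            floor = _floor(tracks, params)
            want_all = brute_segment_strand(cov.tolist(), in_gene.tolist(),
                                            params.min_cov, params.max_gap, floor)
            want = set()
            for a, b in want_all:
                seg = IGRSegment(start=a, end=b, strand="+")
                n = int(((lib.starts <= b) & (lib.ends >= a) & (lib.strands == "+")).sum())
                if n > params.min_raw_reads:
                    want.add((a, b))
            assert got == want, f"seed {seed}"


class TestClassification:
    def test_segment_over_opposite_cds_is_asrna(self):
        genome = _genome(GENES)
        seg = IGRSegment(start=600, end=750, strand="-")
        assert classify_segment(seg, genome.genes, [], genome).seg_class == "asRNA_cds"

    def test_plain_igr_segment_is_srna_candidate(self):
        genome = _genome([Gene("g", 500, 1900, "+")])
        seg = IGRSegment(start=2500, end=2650, strand="+")
        out = classify_segment(seg, genome.genes, [], genome)
        assert out.seg_class == "srna_candidate" and not out.flags

    def test_antisense_spanning_two_genes_is_excludon_like(self):
        genes = [Gene("a", 500, 900, "-"), Gene("b", 1000, 1400, "-")]
        genome = _genome(genes)
        seg = IGRSegment(start=700, end=1200, strand="+")
        out = classify_segment(seg, genes, [], genome)
        assert out.seg_class == "asRNA_cds" and "excludon_like" in out.flags

    def test_three_prime_region_truncated_by_neighbour(self):
        genes = [Gene("a", 500, 900, "+"), Gene("b", 950, 1400, "+")]
        regions = three_prime_utr_regions(genes, 5000)
        assert (901, 949, "+") in regions

    def test_segment_starting_in_upstream_three_prime_utr_flagged(self):
        genes = [Gene("a", 500, 900, "+")]
        genome = _genome(genes)
        seg = IGRSegment(start=940, end=1100, strand="+")
        out = classify_segment(seg, genes, [], genome)
        assert "three_prime_utr_derived" in out.flags

    def test_classes_partition_retained_segments(self, default_analysis):
        segs = default_analysis.segments
        assert all(s.seg_class in ("srna_candidate", "asRNA_cds", "asRNA_utr",
                                   "small_orf_mrna") for s in segs)
        counts = {}
        for s in segs:
            counts[s.seg_class] = counts.get(s.seg_class, 0) + 1
        assert sum(counts.values()) == len(segs)


def _orf_genome(aa=41, sd=True, spacer=7):
    """A 600-nt '+' segment carrying one SD-led ORF of ``aa`` codons."""
    rng = np.random.default_rng(77)
    seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 2000)))
    orf = 800
    for p in range(700, 700 + 500):  # clear accidental starts near the ORF
        if "".join(seq[p - 1 : p + 2]) in ("ATG", "GTG", "TTG"):
            seq[p - 1 : p + 2] = list("CCC")
    seq[orf - 1 : orf + 2] = list("ATG")
    seq[orf - 16 : orf - 5] = list("C" * 11)  # blank the whole RBS spacer window
    if sd:
        seq[orf - spacer - 7 : orf - spacer - 1] = list("AGGAGG")
    for k in range(1, aa):  # inert filler: cannot form starts or stops in any frame
        seq[orf - 1 + 3 * k : orf + 2 + 3 * k] = list("CCC")
    seq[orf - 1 + 3 * aa : orf + 2 + 3 * aa] = list("TAA")
    genome = GenomeModel(sequence="".join(seq), genes=[], circular=False)
    return genome, IGRSegment(start=700, end=1300, strand="+"), orf


class TestSmallOrfScan:
    def test_planted_41aa_orf_detected(self):
        genome, seg, orf = _orf_genome(aa=41)
        assert small_orf_scan(seg, genome) == (orf, 41)

    def test_orf_below_size_floor_ignored(self):
        genome, seg, _ = _orf_genome(aa=25)
        assert small_orf_scan(seg, genome) is None

    def test_orf_above_size_ceiling_ignored(self):
        genome, seg, _ = _orf_genome(aa=120)
        assert small_orf_scan(seg, genome) is None

    def test_no_sd_means_no_orf(self):
        genome, seg, _ = _orf_genome(aa=41, sd=False)
        assert small_orf_scan(seg, genome) is None

    def test_segment_too_short_for_scan(self):
        genome, _, _ = _orf_genome()
        assert small_orf_scan(IGRSegment(start=700, end=750, strand="+"), genome) is None


class TestKnownSrnas:
    SEGS = [IGRSegment(start=100, end=250, strand="+"),
            IGRSegment(start=400, end=500, strand="+")]

    def _fresh(self):
        return [IGRSegment(start=s.start, end=s.end, strand=s.strand) for s in self.SEGS]

    def test_overlapping_locus_flagged(self):
        table = pd.DataFrame([{"name": "bsrX", "start": 90, "end": 120}])
        segs = match_known_srnas(self._fresh(), table)
        assert segs[0].flags == {"known_homolog"} and segs[0].known_names == ["bsrX"]
        assert segs[1].flags == set()

    def test_empty_table_flags_nothing(self):
        segs = match_known_srnas(self._fresh(), pd.DataFrame(columns=["name", "start", "end"]))
        assert all(not s.flags for s in segs)

    def test_multiple_hits_all_recorded(self):
        table = pd.DataFrame([{"name": "a", "start": 90, "end": 120},
                              {"name": "b", "start": 200, "end": 300}])
        segs = match_known_srnas(self._fresh(), table)
        assert segs[0].known_names == ["a", "b"]

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError):
            match_known_srnas(self._fresh(), pd.DataFrame([{"name": "x", "pos": 1}]))


class TestRunProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.booleans(), min_size=1, max_size=120), st.integers(0, 5))
    @settings(derandomize=True, max_examples=80)
    def test_runs_cover_all_true_positions_and_respect_gaps(self, mask, gap):
        import numpy as np
        from primarytx.srna_discovery import _runs
        arr = np.array(mask)
        runs = _runs(arr, gap)
        covered = set()
        for a, b in runs:
            assert arr[a] and arr[b]  # runs start and end on covered positions
            covered.update(i for i in range(a, b + 1) if arr[i])
        assert covered == set(np.flatnonzero(arr))
        for (a1, b1), (a2, b2) in zip(runs[:-1], runs[1:]):
            assert a2 - b1 > gap + 1  # separated by more than the bridged gap
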