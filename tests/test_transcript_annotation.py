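import numpy as np
import pytest

from primarytx.genome_model import Gene, GenomeModel
from primarytx.tss_core import AnnotatedTSS, classify_tss
from primarytx.transcript_annotation import (
    ReannotationParams,
    UTRParams,
    assign_utrs,
    extract_upstream,
    flag_riboswitch_candidates,
    plus_one_composition,
    propose_reannotation,
    utr_histogram,
)


def _primary_tss(pos, gene, strand="+"):
    t = AnnotatedTSS(pos=pos, strand=strand, height_by_library={"l": 10.0})
    t.categories = {"primary"}
    d = (gene.start - pos) if strand == "+" else (pos - gene.end)
    t.gene_links = [(gene.id, "primary", d)]
    return t


class TestUTRs:
    def test_short_utr_is_leaderless(self):
        g = Gene("g", 1000, 2000, "+")
        (rec,) = assign_utrs([_primary_tss(995, g)], [g])
        assert (rec.length, rec.utr_class) == (5, "leaderless")

    def test_long_utr(self):
        g = Gene("g", 1000, 2000, "+")
        (rec,) = assign_utrs([_primary_tss(850, g)], [g])
        assert (rec.length, rec.utr_class) == (150, "long")

    def test_minus_strand_utr(self):
        g = Gene("g", 100, 500, "-")
        (rec,) = assign_utrs([_primary_tss(520, g, "-")], [g])
        assert (rec.length, rec.utr_class) == (20, "standard")

    @pytest.mark.parametrize("length,cls", [(0, "leaderless"), (9, "leaderless"),
                                            (10, "standard"), (100, "standard"),
                                            (101, "long")])
    def test_strict_boundaries(self, length, cls):
        g = Gene("g", 1000, 2000, "+")
        (rec,) = assign_utrs([_primary_tss(1000 - length, g)], [g])
        assert rec.utr_class == cls

    def test_negative_length_excluded_with_warning(self):
        g = Gene("g", 1000, 2000, "+")
        t = AnnotatedTSS(pos=1010, strand="+", height_by_library={"l": 1.0})
        t.gene_links = [("g", "primary", -10)]
        with pytest.warns(UserWarning):
            assert assign_utrs([t], [g]) == []

    def test_classes_partition_records(self, default_analysis):
        utrs = default_analysis.utrs
        by_class = {c: sum(1 for r in utrs if r.utr_class == c)
                    for c in ("leaderless", "standard", "long")}
        assert sum(by_class.values()) == len(utrs)


class TestHistogram:
    def test_default_bins_place_examples(self):
        g = Gene("g", 10_000, 11_000, "+")
        recs = assign_utrs([_primary_tss(10_000 - d, g) for d in (5,)], [g])
        recs += assign_utrs([_primary_tss(10_000 - 20, g)], [g])
        recs += assign_utrs([_primary_tss(10_000 - 120, g)], [g])
        table = utr_histogram(recs).set_index("bin")["count"]
        assert table["[0,10)"] == 1 and table["[10,25)"] == 1 and table["[100,150)"] == 1
        assert table.sum() == 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            utr_histogram([])

    def test_counts_match_brute_tally(self):
        rng = np.random.default_rng(9)
        g = Gene("g", 10_000, 11_000, "+")
        lengths = rng.integers(0, 600, 200)
        recs = assign_utrs([_primary_tss(10_000 - int(d), g) for d in lengths], [g])
        edges = list(UTRParams().histogram_bins)
        table = utr_histogram(recs)
        for (lo, hi), row in zip(zip(edges[:-1], edges[1:]), table.itertuples()):
            assert row.count == int(((lengths >= lo) & (lengths < hi)).sum())
        assert table["count"].sum() == 200


class TestUpstreamSequence:
    GENOME = GenomeModel(sequence="".join("ACGT"[i % 4] for i in range(200)),
                         genes=[], circular=True)

    def test_plus_strand_window(self):
        seq = extract_upstream((100, "+"), self.GENOME, span=5)
        assert seq == self.GENOME.sequence[94:99]

    def test_wraps_through_origin(self):
        seq = extract_upstream((3, "+"), self.GENOME, span=5)
        assert seq == self.GENOME.sequence[-3:] + self.GENOME.sequence[:2]
        assert len(seq) == 5

    def test_minus_strand_is_reverse_complement(self):
        seq = extract_upstream((100, "-"), self.GENOME, span=5)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        assert seq == "".join(comp[b] for b in self.GENOME.sequence[100:105][::-1])

    def test_composition_all_same_base(self):
        genome = GenomeModel(sequence="A" * 50, genes=[], circular=True)
        tss = [AnnotatedTSS(pos=p, strand="+") for p in (5, 10, 20)]
        comp = plus_one_composition(tss, genome)
        assert comp["A"] == 1.0 and comp["purine"] == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            plus_one_composition([], self.GENOME)

    def test_planted_purine_bias_recovered(self, default_sim, default_tss):
        genome, truth, _libs = default_sim
        comp = plus_one_composition(default_tss, genome)
        n = len(default_tss)
        sd = (0.8 * 0.2 / n) ** 0.5
        assert abs(comp["purine"] - 0.8) < 4 * sd + 1 / n


class TestRiboswitchFlagging:
    def _case(self, utr_len, tmp_path=None):
        g = Gene("g", 1000, 2000, "+")
        genome = GenomeModel(sequence="".join("ACGT"[i % 4] for i in range(3000)),
                             genes=[g], circular=True)
        recs = assign_utrs([_primary_tss(1000 - utr_len, g)], [g])
        return g, genome, recs

    def test_strictly_above_floor_flagged(self):
        g, genome, recs = self._case(71)
        assert [gid for gid, _ in flag_riboswitch_candidates(recs, [g], genome)] == ["g"]

    def test_at_floor_not_flagged(self):
        g, genome, recs = self._case(70)
        assert flag_riboswitch_candidates(recs, [g], genome) == []

    def test_fasta_export_roundtrips(self, tmp_path):
        g, genome, recs = self._case(120)
        out = flag_riboswitch_candidates(recs, [g], genome, fasta_path=tmp_path / "rs.fasta")
        from Bio import SeqIO
        parsed = {r.id: str(r.seq) for r in SeqIO.parse(str(tmp_path / "rs.fasta"), "fasta")}
        assert parsed == {f"{gid}_5UTR": seq for gid, seq in out}
        assert len(out[0][1]) == 120


def _reannotation_fixture(tss_offset=21, new_start_offset=60, sd=True):
    """A '+' gene whose true start sits ``new_start_offset`` nt downstream of an
    internal TSS, in the annotated reading frame, with an SD hexamer at 7-nt
    spacing (tss_offset + new_start_offset must be divisible by 3)."""
    L = 3000
    rng = np.random.default_rng(1234)
    seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, L)))
    g = Gene("g", 1000, 1900, "+")
    tss_pos = g.start + tss_offset
    new_start = tss_pos + new_start_offset
    # scrub competing in-frame starts between the TSS and the planted start
    for p in range(g.start, new_start, 3):
        if "".join(seq[p - 1 : p + 2]) in ("ATG", "GTG", "TTG"):
            seq[p - 1 : p + 2] = list("CTG")
    seq[new_start - 1 : new_start + 2] = list("ATG")
    if sd:
        seq[new_start - 14 : new_start - 8] = list("AGGAGG")
    else:
        seq[new_start - 20 : new_start - 2] = list("C" * 18)
    genome = GenomeModel(sequence="".join(seq), genes=[g], circular=True)
    t = AnnotatedTSS(pos=tss_pos, strand="+", height_by_library={"l": 50.0})
    classify_tss([t], [g])
    return genome, g, t, new_start


class TestReannotation:
    def test_planted_start_recovered(self):
        genome, g, t, new_start = _reannotation_fixture()
        (prop,) = propose_reannotation([t], [g], genome)
        assert prop.new_start == new_start
        assert prop.sd_matches == 6
        assert prop.old_start == g.start

    def test_tss_too_deep_inside_gene_not_eligible(self):
        genome, g, t, _ = _reannotation_fixture(tss_offset=80)
        assert propose_reannotation([t], [g], genome) == []

    def test_no_sd_means_no_proposal(self):
        genome, g, t, _ = _reannotation_fixture(sd=False)
        assert propose_reannotation([t], [g], genome) == []

    def test_spacer_window_is_enforced(self):
        params = ReannotationParams(sd_spacer_min=5, sd_spacer_max=9)
        genome, g, t, new_start = _reannotation_fixture()
        # moving the window away from the planted 7-nt spacer loses the hit
        far = ReannotationParams(sd_spacer_min=15, sd_spacer_max=19)
        assert propose_reannotation([t], [g], genome, far) == []
        assert propose_reannotation([t], [g], genome, params) != []
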