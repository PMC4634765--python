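import numpy as np
import pytest

from primarytx.genome_model import CoverageTracks, Gene
from primarytx.tss_core import (
    AnnotatedTSS,
    ClassificationParams,
    TSSCandidate,
    TSSDetectionParams,
    category_overlap_counts,
    classify_tss,
    cluster_tss,
    condition_specific_tss,
    detect_sample_tss,
)

from oracles import brute_classify

#: the conventional ratio-based thresholds used in the worked examples below
EXAMPLE_PARAMS = TSSDetectionParams(min_step_height=0.3, min_step_factor=2.0,
                                    min_enrichment=2.0, pseudocount=1.0)


def _tracks(length=20, **kw):
    arrays = {k: np.zeros(length) for k in ("full_fwd", "full_rev", "end5_fwd", "end5_rev")}
    arrays.update({k: np.asarray(v, dtype=float) for k, v in kw.items()})
    return CoverageTracks(**arrays, normalized=True, scale=1.0)


def _tss(pos, strand="+", height=1.0, samples=("SE#9h",)):
    return AnnotatedTSS(pos=pos, strand=strand, height_by_library={"lib": height},
                        detected_samples=set(samples))


class TestDetection:
    def _pair(self, e5p, e5m, full):
        plus = _tracks(end5_fwd=e5p, full_fwd=full)
        minus = _tracks(end5_fwd=e5m)
        return plus, minus

    def test_enriched_step_is_called(self):
        e5p = np.zeros(20); e5p[9] = 30
        e5m = np.zeros(20); e5m[9] = 5
        full = np.ones(20); full[9:] = 10  # ten-fold step at position 10
        plus, minus = self._pair(e5p, e5m, full)
        cands = detect_sample_tss(plus, minus, EXAMPLE_PARAMS, sample="s")
        assert [(c.pos, c.strand) for c in cands] == [(10, "+")]
        assert cands[0].enrichment == pytest.approx(30 / 6)

    def test_unenriched_site_not_called(self):
        e5 = np.zeros(20); e5[9] = 30
        full = np.ones(20); full[9:] = 10
        plus, minus = self._pair(e5, e5.copy(), full)  # 30/(30+1) < 2
        assert detect_sample_tss(plus, minus, EXAMPLE_PARAMS) == []

    def test_pseudocount_handles_zero_untreated_height(self):
        e5p = np.zeros(20); e5p[9] = 30
        full = np.ones(20); full[9:] = 10
        plus, minus = self._pair(e5p, np.zeros(20), full)
        cands = detect_sample_tss(plus, minus, EXAMPLE_PARAMS)
        assert cands and cands[0].enrichment == pytest.approx(30.0)

    def test_no_coverage_step_not_called(self):
        e5p = np.zeros(20); e5p[9] = 30
        full = np.full(20, 50.0)  # flat coverage: no step
        plus, minus = self._pair(e5p, np.zeros(20), full)
        assert detect_sample_tss(plus, minus, EXAMPLE_PARAMS) == []

    def test_minus_strand_uses_downstream_neighbour(self):
        e5 = np.zeros(20); e5[9] = 30
        full = np.zeros(20); full[:10] = 10; full[10:] = 1  # step when read right-to-left
        plus = _tracks(end5_rev=e5, full_rev=full)
        minus = _tracks()
        cands = detect_sample_tss(plus, minus, EXAMPLE_PARAMS)
        assert [(c.pos, c.strand) for c in cands] == [(10, "-")]

    def test_unnormalized_input_rejected(self):
        raw = CoverageTracks(*(np.zeros(5) for _ in range(4)), normalized=False)
        with pytest.raises(ValueError):
            detect_sample_tss(raw, raw, EXAMPLE_PARAMS)

    def test_raising_enrichment_threshold_shrinks_called_set(self):
        rng = np.random.default_rng(5)
        L = 400
        plus = _tracks(L, end5_fwd=rng.integers(0, 40, L), full_fwd=rng.integers(0, 60, L),
                       end5_rev=rng.integers(0, 40, L), full_rev=rng.integers(0, 60, L))
        minus = _tracks(L, end5_fwd=rng.integers(0, 20, L), end5_rev=rng.integers(0, 20, L))
        called = {}
        for enr in (1.2, 2.0, 3.5, 8.0):
            p = TSSDetectionParams(min_step_height=0.3, min_enrichment=enr)
            called[enr] = {(c.pos, c.strand) for c in detect_sample_tss(plus, minus, p)}
        assert called[8.0] <= called[3.5] <= called[2.0] <= called[1.2]


class TestClustering:
    def test_same_position_across_samples_merges(self):
        cands = {f"s{i}": [TSSCandidate(100, "+", 10 + i, 5.0, f"s{i}")] for i in range(6)}
        merged = cluster_tss(cands, 3)
        assert len(merged) == 1
        assert len(merged[0].detected_samples) == 6
        assert merged[0].pos == 100

    def test_nearby_positions_merge_to_highest(self):
        cands = {"a": [TSSCandidate(100, "+", 5.0, 3.0, "a")],
                 "b": [TSSCandidate(102, "+", 9.0, 3.0, "b")]}
        merged = cluster_tss(cands, 3)
        assert [(m.pos, sorted(m.detected_samples)) for m in merged] == [(102, ["a", "b"])]

    def test_separated_positions_stay_apart(self):
        cands = {"a": [TSSCandidate(100, "+", 5.0, 3.0, "a"), TSSCandidate(110, "+", 5.0, 3.0, "a")]}
        assert [m.pos for m in cluster_tss(cands, 3)] == [100, 110]

    def test_equal_height_tie_goes_upstream(self):
        plus = cluster_tss({"a": [TSSCandidate(100, "+", 5.0, 3.0, "a"),
                                  TSSCandidate(101, "+", 5.0, 3.0, "a")]}, 3)
        minus = cluster_tss({"a": [TSSCandidate(200, "-", 5.0, 3.0, "a"),
                                   TSSCandidate(201, "-", 5.0, 3.0, "a")]}, 3)
        assert plus[0].pos == 100  # upstream on + is the smaller coordinate
        assert minus[0].pos == 201  # upstream on - is the larger coordinate


class TestClassification:
    GENES = [Gene("gA", 1000, 2000, "+")]

    def test_upstream_tss_is_primary(self):
        t = _tss(900)
        classify_tss([t], self.GENES)
        assert t.categories == {"primary"}
        assert ("gA", "primary", 100) in t.gene_links

    def test_weaker_upstream_tss_is_secondary(self):
        strong, weak = _tss(950, height=9.0), _tss(880, height=2.0)
        classify_tss([strong, weak], self.GENES)
        assert strong.categories == {"primary"} and weak.categories == {"secondary"}

    def test_opposite_strand_inside_gene_is_antisense(self):
        t = _tss(1500, strand="-")
        classify_tss([t], self.GENES)
        assert t.categories == {"antisense"}

    def test_sense_inside_gene_is_internal(self):
        t = _tss(1500)
        classify_tss([t], self.GENES)
        assert t.categories == {"internal"}

    def test_remote_tss_is_orphan(self):
        t = _tss(5000)
        classify_tss([t], self.GENES)
        assert t.categories == {"orphan"}

    def test_distance_zero_tss_is_primary_not_internal(self):
        t = _tss(1000)  # leaderless: TSS on the start codon
        classify_tss([t], self.GENES)
        assert t.categories == {"primary"}

    def test_random_scenes_match_brute_force_oracle(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            genes = [Gene(f"g{i}", int(s), int(s) + int(l), "+-"[int(x)])
                     for i, (s, l, x) in enumerate(zip(
                         rng.integers(1, 9000, 20), rng.integers(50, 900, 20),
                         rng.integers(0, 2, 20)))]
            tss = [_tss(int(p), "+-"[int(x)], float(h)) for p, x, h in zip(
                rng.integers(1, 10000, 30), rng.integers(0, 2, 30),
                rng.integers(1, 1000, 30))]
            classify_tss(tss, genes)
            expected = brute_classify([(t.pos, t.strand, t.max_height) for t in tss], genes)
            for t, (cats, links) in zip(tss, expected):
                assert t.categories == cats, f"seed {seed} pos {t.pos}{t.strand}"
                assert {(g, c) for g, c, _d in t.gene_links} == links

    def test_each_gene_has_at_most_one_primary(self, default_tss):
        per_gene = {}
        for t in default_tss:
            for gid, cat, _d in t.gene_links:
                if cat == "primary":
                    per_gene.setdefault(gid, []).append(t)
        assert all(len(v) == 1 for v in per_gene.values())

    def test_orphan_is_exclusive_and_categories_nonempty(self, default_tss):
        for t in default_tss:
            assert t.categories
            if "orphan" in t.categories:
                assert t.categories == {"orphan"}


class TestSetOperations:
    def test_condition_specific_selects_single_sample_tss(self):
        t1 = _tss(10, samples=("SE#9h",))
        t2 = _tss(20, samples=("SE#9h", "RS#9h"))
        t3 = _tss(30, samples=("1CM#6h", "RE#6h", "SE#6h", "RS#6h", "SE#9h", "RS#9h"))
        buckets = condition_specific_tss([t1, t2, t3])
        assert buckets == {"SE#9h": [t1]}

    def test_overlap_counts_match_subset_enumeration(self):
        rng = np.random.default_rng(3)
        cats = ("primary", "secondary", "internal", "antisense", "orphan")
        tss = []
        for i in range(60):
            k = int(rng.integers(1, 4))
            t = _tss(i + 1)
            t.categories = set(rng.choice(cats, size=k, replace=False))
            tss.append(t)
        table = category_overlap_counts(tss).set_index("categories")["count"]
        # multi-label TSSs count once per category and once per covered combination
        assert table["primary"] == sum(1 for t in tss if "primary" in t.categories)
        for combo in ("primary+internal", "secondary+antisense", "internal+antisense+orphan"):
            want = sum(1 for t in tss if set(combo.split("+")) <= t.categories)
            assert table[combo] == want
        singles = sum(table[c] for c in cats)
        assert singles >= len(tss)


class TestClusterProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.tuples(st.integers(1, 300), st.integers(1, 50)), min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=60)
    def test_clusters_partition_candidates_within_window(self, items):
        window = 3
        cands = {"s": [TSSCandidate(pos, "+", float(h), 3.0, "s") for pos, h in items]}
        merged = cluster_tss(cands, window)
        positions = sorted({p for p, _h in items})
        # every candidate is within the chained extent of exactly one cluster
        reps = [m.pos for m in merged]
        assert reps == sorted(reps)
        # consecutive cluster representatives are separated by more than the window
        for a, b in zip(merged[:-1], merged[1:]):
            assert b.pos - a.pos > 0
        # total height mass is preserved: each cluster's height is one of its inputs
        heights = {float(h) for _p, h in items}
        assert all(m.max_height in heights for m in merged)
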