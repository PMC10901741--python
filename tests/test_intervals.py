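"""Interval algebra against per-base occupancy oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from te_exonize.intervals import (
    Gene,
    GenomicInterval,
    RepeatElement,
    flatten_gene,
    fragment_by_priority,
    intersect_length,
    reduce_intervals,
    subtract_intervals,
)

from conftest import coverage_oracle, random_intervals, runs_from_coverage


class TestGenomicInterval:
    def test_rejects_empty_and_inverted(self):
        with pytest.raises(ValueError, match="invalid interval"):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError, match="invalid interval"):
            GenomicInterval("chr1", 20, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)

    def test_length_and_containment(self):
        iv = GenomicInterval("chr1", 10, 30, "+")
        assert iv.length == 20
        assert iv.contains(GenomicInterval("chr1", 10, 30))
        assert not iv.contains(GenomicInterval("chr1", 9, 30))
        assert iv.contains_pos(29) and not iv.contains_pos(30)


class TestReduce:
    def test_empty(self):
        assert reduce_intervals([]) == []

    def test_overlap_union(self):
        got = reduce_intervals(
            [GenomicInterval("chr1", 10, 20, "+"), GenomicInterval("chr1", 15, 30, "+")]
        )
        assert got == [GenomicInterval("chr1", 10, 30, "+")]

    def test_touching_merge(self):
        got = reduce_intervals(
            [GenomicInterval("chr1", 10, 20, "+"), GenomicInterval("chr1", 20, 30, "+")]
        )
        assert got == [GenomicInterval("chr1", 10, 30, "+")]

    def test_strand_separation(self):
        ivs = [GenomicInterval("chr1", 10, 20, "+"), GenomicInterval("chr1", 15, 30, "-")]
        assert len(reduce_intervals(ivs, strand_aware=True)) == 2
        assert len(reduce_intervals(ivs, strand_aware=False)) == 1

    def test_matches_per_base_oracle(self, rng):
        """1,000 random intervals on a toy chromosome reduce to exactly the
        maximal covered runs of a per-base occupancy oracle."""
        ivs = random_intervals(rng, 1000, 10_000, strands=("+",))
        got = reduce_intervals(ivs)
        cov = coverage_oracle(ivs, 10_000, strand="+")
        expected = runs_from_coverage(cov)
        assert [(iv.start, iv.end) for iv in got] == expected

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 60)),
            min_size=0,
            max_size=30,
        )
    )
    def test_idempotent(self, raw):
        ivs = [GenomicInterval("chr1", s, s + l, "+") for s, l in raw]
        once = reduce_intervals(ivs)
        assert reduce_intervals(once) == once


class TestSubtract:
    def test_split_by_mask(self):
        got = subtract_intervals(
            [GenomicInterval("chr1", 100, 300, "+")],
            [GenomicInterval("chr1", 150, 200, "+")],
        )
        assert [(iv.start, iv.end) for iv in got] == [(100, 150), (200, 300)]

    def test_matches_per_base_oracle(self, rng):
        a = random_intervals(rng, 300, 5000, strands=("+",))
        b = random_intervals(rng, 300, 5000, strands=("+",))
        got = subtract_intervals(reduce_intervals(a), b)
        cov = coverage_oracle(a, 5000) & ~coverage_oracle(b, 5000)
        assert [(iv.start, iv.end) for iv in got] == runs_from_coverage(cov)


class TestFlattenGene:
    def test_span_and_identity(self):
        g = Gene(
            "g1",
            GenomicInterval("chr1", 100, 600, "+"),
            [GenomicInterval("chr1", 100, 200, "+"), GenomicInterval("chr1", 500, 600, "+")],
        )
        assert flatten_gene(g) == GenomicInterval("chr1", 100, 600, "+")
        single = Gene(
            "g2",
            GenomicInterval("chr1", 100, 200, "+"),
            [GenomicInterval("chr1", 100, 200, "+")],
        )
        assert flatten_gene(single) == GenomicInterval("chr1", 100, 200, "+")

    def test_exonless_rejected(self):
        with pytest.raises(ValueError, match="no exons"):
            Gene("g", GenomicInterval("chr1", 0, 10, "+"), [])

    def test_matches_brute_force(self, rng):
        for i in range(50):
            starts = sorted(rng.integers(0, 5000, size=4))
            exons = [GenomicInterval("chr1", int(s), int(s) + 50, "+") for s in starts]
            g = Gene("g", GenomicInterval("chr1", 0, 10_000, "+"), exons)
            fp = flatten_gene(g)
            assert fp.start == min(e.start for e in g.exons)
            assert fp.end == max(e.end for e in g.exons)


def _fragment_label_oracle(gene, repeats, peaks, priority):
    """Per-base label assignment by scanning every feature at every base."""
    fp = flatten_gene(gene)
    rank = {lab: i for i, lab in enumerate(list(priority) + ["intron"])}
    labels = []
    for pos in range(fp.start, fp.end):
        best = "intron"
        for exon in gene.exons:
            if exon.contains_pos(pos) and rank.get("exon", 99) < rank[best]:
                best = "exon"
        for rep in repeats:
            if rep.interval.contains_pos(pos) and rank.get("repeat", 99) < rank[best]:
                best = "repeat"
        for pk in peaks:
            if pk.contains_pos(pos) and rank.get("peak", 99) < rank[best]:
                best = "peak"
        labels.append(best)
    return labels


class TestFragmentByPriority:
    def _gene(self, exons, strand="+", chrom_len=1000):
        return Gene(
            "g1",
            GenomicInterval("chr1", 0, chrom_len, strand),
            [GenomicInterval("chr1", s, e, strand) for s, e in exons],
        )

    def test_exon_shadows_repeat(self):
        gene = Gene(
            "g1",
            GenomicInterval("chr1", 0, 1000, "+"),
            [GenomicInterval("chr1", 0, 10, "+"),
             GenomicInterval("chr1", 100, 200, "+"),
             GenomicInterval("chr1", 990, 1000, "+")],
        )
        rep = RepeatElement(GenomicInterval("chr1", 150, 400, "+"), "L1", "LINE")
        frags = fragment_by_priority(gene, [rep], priority=("exon", "repeat", "intron"))
        spans = [(f.interval.start, f.interval.end, f.label) for f in frags]
        assert (100, 200, "exon") in spans
        assert (200, 400, "repeat") in spans
        assert (10, 100, "intron") in spans

    def test_no_features_alternating(self):
        gene = self._gene([(100, 200), (500, 600)])
        frags = fragment_by_priority(gene)
        assert [(f.interval.start, f.interval.end, f.label) for f in frags] == [
            (100, 200, "exon"),
            (200, 500, "intron"),
            (500, 600, "exon"),
        ]

    def test_unknown_priority_label_rejected(self):
        gene = self._gene([(100, 200), (500, 600)])
        with pytest.raises(ValueError, match="unknown label"):
            fragment_by_priority(gene, priority=("exon", "enhancer"))

    def test_matches_per_base_oracle(self, rng):
        """100 random genes: every base's fragment label equals the naive
        highest-priority-feature-covering-it rule."""
        for _ in range(100):
            n_ex = int(rng.integers(1, 4))
            bounds = np.sort(rng.choice(np.arange(0, 900), size=2 * n_ex, replace=False))
            exons = [
                GenomicInterval("chr1", int(bounds[2 * i]), int(bounds[2 * i + 1]) + 1, "+")
                for i in range(n_ex)
            ]
            gene = Gene("g", GenomicInterval("chr1", 0, 1000, "+"), exons)
            reps = [
                RepeatElement(iv, "L1", "LINE")
                for iv in random_intervals(rng, int(rng.integers(0, 4)), 950, strands=("+", "-"))
            ]
            pks = random_intervals(rng, int(rng.integers(0, 3)), 950, strands=("+",))
            priority = ("exon", "repeat", "peak")
            frags = fragment_by_priority(gene, reps, pks, priority)
            expected = _fragment_label_oracle(gene, reps, pks, priority)
            got = []
            for f in frags:
                got.extend([f.label] * f.interval.length)
            assert got == expected

    def test_length_conservation(self, rng):
        for _ in range(30):
            gene = self._gene([(50, 150), (300, 420), (700, 900)])
            reps = [
                RepeatElement(iv, "Alu", "SINE")
                for iv in random_intervals(rng, 3, 900, strands=("+", "-"))
            ]
            frags = fragment_by_priority(gene, reps)
            fp = flatten_gene(gene)
            assert sum(f.interval.length for f in frags) == fp.length
            # pairwise disjoint and sorted
            for a, b in zip(frags, frags[1:]):
                assert a.interval.end <= b.interval.start

    def test_priority_monotonicity(self, rng):
        """Promoting the repeat label never shrinks repeat-labeled bases."""
        gene = self._gene([(50, 150), (300, 420), (700, 900)])
        for _ in range(20):
            reps = [
                RepeatElement(iv, "L1", "LINE")
                for iv in random_intervals(rng, 4, 900, strands=("+",))
            ]
            pks = random_intervals(rng, 2, 900, strands=("+",))
            low = fragment_by_priority(gene, reps, pks, ("exon", "peak", "repeat"))
            high = fragment_by_priority(gene, reps, pks, ("repeat", "exon", "peak"))
            n_low = sum(f.interval.length for f in low if f.label == "repeat")
            n_high = sum(f.interval.length for f in high if f.label == "repeat")
            assert n_high >= n_low


def test_intersect_length_matches_oracle(rng):
    a = random_intervals(rng, 100, 3000)
    b = random_intervals(rng, 100, 3000)
    got = intersect_length(a, b)
    assert got == int((coverage_oracle(a, 3000) & coverage_oracle(b, 3000)).sum())
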