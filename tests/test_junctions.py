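"""Junction filtering, splicing index, the stringent panel chain,
TE distances and the splice-site survey."""

import numpy as np
import pytest

from te_exonize.intervals import Gene, GenomicInterval, RepeatElement
from te_exonize.junctions import (
    HexamerScorer,
    Junction,
    SpliceSiteScore,
    differential_junction_usage,
    filter_junctions,
    nearest_te_distance,
    read_sj_tab,
    splicing_index,
    stringent_panel_filter,
    window_site_survey,
)
from te_exonize.simulate import stringent_panel_fixture


def _gene(gene_id, start, end, strand="+", chrom="chr1"):
    return Gene(
        gene_id,
        GenomicInterval(chrom, start, end, strand),
        [
            GenomicInterval(chrom, start, start + 50, strand),
            GenomicInterval(chrom, end - 50, end, strand),
        ],
    )


class TestSjTab:
    def test_coordinate_conversion(self, tmp_path):
        """SJ dialect is 1-based first/last intronic base; a + intron at
        [101, 200] has donor at 0-based 100 and acceptor at 199."""
        path = tmp_path / "SJ.out.tab"
        path.write_text(
            "chr1\t101\t200\t1\t1\t0\t42\t3\t20\n"
            "chr1\t301\t400\t2\t2\t0\t7\t0\t20\n"
            "chr1\t501\t600\t0\t0\t0\t9\t0\t20\n"  # unstranded: skipped
        )
        juncs = read_sj_tab(path, "s1")
        assert len(juncs) == 2
        plus, minus = juncs
        assert (plus.donor_pos, plus.acceptor_pos) == (100, 199)
        assert plus.counts == {"s1": 42}
        # minus strand: donor is the right edge
        assert (minus.donor_pos, minus.acceptor_pos) == (399, 300)


class TestFilter:
    GENES = {
        "gA": _gene("gA", 100, 2000),
        "gB": _gene("gB", 5000, 8000),
        # gC overlaps gB -> junctions inside both are ambiguous
        "gC": _gene("gC", 5500, 9000),
    }

    def test_ambiguous_host_dropped(self):
        j = Junction("chr1", 5600, 5900, "+", {"s1": 50})
        assert filter_junctions([j], self.GENES) == []

    def test_low_support_dropped(self):
        j = Junction("chr1", 200, 800, "+", {"s1": 4, "s2": 5})  # 9 < 10
        assert filter_junctions([j], self.GENES) == []

    def test_survivor(self):
        j = Junction("chr1", 200, 800, "+", {"s1": 4, "s2": 6})
        out = filter_junctions([j], self.GENES)
        assert len(out) == 1 and out[0].host_gene == "gA"

    def test_matches_brute_force(self, rng):
        juncs = []
        for _ in range(200):
            start = int(rng.integers(0, 9000))
            end = start + int(rng.integers(50, 800))
            juncs.append(
                Junction("chr1", start, end, "+", {"s1": int(rng.integers(0, 30))})
            )
        got = {j.junction_id for j in filter_junctions(juncs, self.GENES)}
        for j in juncs:
            hosts = [
                g.gene_id
                for g in self.GENES.values()
                if g.exons[0].start <= j.donor_pos
                and j.acceptor_pos < g.exons[-1].end
                and g.strand == j.strand
            ]
            expect = len(hosts) == 1 and j.total() >= 10
            assert (j.junction_id in got) == expect


class TestSplicingIndex:
    def test_single_junction_is_one(self):
        j = Junction("chr1", 100, 300, "+", {"s1": 9})
        si = splicing_index([j], "donor")
        assert si[j.donor_id][j.junction_id] == 1.0

    def test_shares(self):
        a = Junction("chr1", 100, 300, "+", {"s1": 80})
        b = Junction("chr1", 100, 500, "+", {"s1": 20})
        si = splicing_index([a, b], "donor")
        assert si[a.donor_id][a.junction_id] == pytest.approx(0.8)
        assert si[a.donor_id][b.junction_id] == pytest.approx(0.2)

    def test_normalization_exact(self, rng):
        """Shares at every site sum to exactly 1 on random panels."""
        juncs = []
        seen = set()
        for _ in range(300):
            donor = int(rng.integers(0, 20)) * 1000
            acceptor = donor + int(rng.integers(1, 50)) * 37
            if (donor, acceptor) in seen:
                continue
            seen.add((donor, acceptor))
            counts = {f"t{k}": int(rng.integers(0, 200)) for k in range(4)}
            juncs.append(Junction("chr1", donor, acceptor, "+", counts))
        si = splicing_index(juncs, "donor")
        for site, shares in si.items():
            total = sum(v for v in shares.values() if np.isfinite(v))
            if any(np.isfinite(v) for v in shares.values()):
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_zero_site_undefined(self):
        j = Junction("chr1", 100, 300, "+", {"s1": 0})
        si = splicing_index([j], "donor")
        assert np.isnan(si[j.donor_id][j.junction_id])


class TestStringentPanel:
    def test_constructed_panel(self):
        """Exactly the 3 compliant junctions survive; every decoy is
        attributed to the one rule it was built to violate."""
        fx = stringent_panel_fixture()
        survivors, attrition = stringent_panel_filter(
            fx["junctions"],
            fx["tissue_totals"],
            fx["genes"],
            fx["annotated_donors"],
            fx["intronic_peaks"],
        )
        got = {j.junction_id for j in survivors}
        expect_pass = {jid for jid, v in fx["expected"].items() if v == "pass"}
        assert got == expect_pass and len(got) == fx["n_pass"]
        attributed = dict(zip(attrition["junction_id"], attrition["failed_filter"]))
        for jid, rule in fx["expected"].items():
            if rule != "pass":
                assert attributed[jid] == rule, jid

    def test_order_stability(self, rng):
        fx = stringent_panel_fixture()
        juncs = list(fx["junctions"])
        rng.shuffle(juncs)
        survivors, _ = stringent_panel_filter(
            juncs, fx["tissue_totals"], fx["genes"], fx["annotated_donors"],
            fx["intronic_peaks"],
        )
        assert {j.junction_id for j in survivors} == {
            jid for jid, v in fx["expected"].items() if v == "pass"
        }

    def test_monotone_in_thresholds(self):
        fx = stringent_panel_fixture()
        base, _ = stringent_panel_filter(
            fx["junctions"], fx["tissue_totals"], fx["genes"],
            fx["annotated_donors"], fx["intronic_peaks"],
        )
        stricter, _ = stringent_panel_filter(
            fx["junctions"], fx["tissue_totals"], fx["genes"],
            fx["annotated_donors"], fx["intronic_peaks"],
            si_min=0.5, read_min=900,
        )
        assert {j.junction_id for j in stricter} <= {j.junction_id for j in base}

    def test_empty_panel_rejected(self):
        fx = stringent_panel_fixture()
        with pytest.raises(ValueError, match="empty"):
            stringent_panel_filter(
                [], fx["tissue_totals"], fx["genes"], fx["annotated_donors"],
                fx["intronic_peaks"],
            )


class TestNearestTeDistance:
    GENES = {"gA": _gene("gA", 0, 10_000)}

    def _rep(self, s, e, strand="+", family="L1"):
        return RepeatElement(GenomicInterval("chr1", s, e, strand), family, family)

    def test_direct_gap(self):
        out = nearest_te_distance(
            [("chr1", 990, "+")], [self._rep(1000, 1200)], self.GENES, ["L1"]
        )
        row = out[(out.family == "L1") & (out.orientation == "sense")].iloc[0]
        assert row.distance == 10

    def test_inside_te_is_zero(self):
        out = nearest_te_distance(
            [("chr1", 1100, "+")], [self._rep(1000, 1200)], self.GENES, ["L1"]
        )
        row = out[(out.family == "L1") & (out.orientation == "sense")].iloc[0]
        assert row.distance == 0

    def test_absent_family_undefined(self):
        out = nearest_te_distance(
            [("chr1", 1100, "+")], [self._rep(1000, 1200)], self.GENES, ["L1", "Alu"]
        )
        alu = out[(out.family == "Alu") & (out.orientation == "sense")].iloc[0]
        assert np.isnan(alu.distance)

    def test_site_outside_gene_skipped(self):
        out = nearest_te_distance(
            [("chr1", 50_000, "+")], [self._rep(1000, 1200)], self.GENES, ["L1"]
        )
        assert out.empty

    def test_matches_exhaustive_scan(self, rng):
        reps = [
            self._rep(int(s), int(s) + int(l), str(st), str(fam))
            for s, l, st, fam in zip(
                rng.integers(0, 9000, 40),
                rng.integers(100, 600, 40),
                rng.choice(["+", "-"], 40),
                rng.choice(["L1", "Alu"], 40),
            )
        ]
        sites = [("chr1", int(p), "+") for p in rng.integers(0, 10_000, 30)]
        out = nearest_te_distance(sites, reps, self.GENES, ["L1", "Alu"])
        for row in out.itertuples():
            cands = []
            for rep in reps:
                if rep.family != row.family:
                    continue
                ori = "sense" if rep.interval.strand == "+" else "antisense"
                if ori != row.orientation:
                    continue
                iv = rep.interval
                if iv.start <= row.position < iv.end:
                    cands.append(0)
                elif row.position < iv.start:
                    cands.append(iv.start - row.position)
                else:
                    cands.append(row.position - iv.end + 1)
            if cands:
                assert row.distance == min(cands)
            else:
                assert np.isnan(row.distance)


class TestWindowSurvey:
    def test_indicator_scorer(self):
        seq = "A" * 240 + "AG" + "A" * 60 + "AG" + "A" * 200
        planted = 240

        def scorer(pos):
            return SpliceSiteScore(pos, "acceptor", 1.0 if pos == planted else 0.0)

        res = window_site_survey(scorer, planted, "acceptor", "+", seq)
        assert res["novel_is_best"]
        res2 = window_site_survey(scorer, 302, "acceptor", "+", seq)
        assert not res2["novel_is_best"]

    def test_constant_scorer(self):
        seq = "AGAG" * 200

        def scorer(pos):
            return SpliceSiteScore(pos, "acceptor", 0.5)

        res = window_site_survey(scorer, 400, "acceptor", "+", seq)
        assert res["best_dinucleotide_score"] == 0.5
        assert set(res["random_dinucleotide_scores"]) == {0.5}

    def test_no_candidates_undefined(self):
        res = window_site_survey(
            lambda p: SpliceSiteScore(p, "donor", 0.0), 500, "donor", "+", "A" * 1000
        )
        assert res == {"defined": False}

    def test_hexamer_scorer_ranks_planted_site(self, rng):
        """A consensus donor planted in random sequence outranks all other
        GT dinucleotides in the window."""
        bases = list("ACT")  # no G: GT occurs only where we plant it
        seq = "".join(rng.choice(bases, size=1000))
        planted = 500
        seq = seq[:planted] + "GTAAGT" + seq[planted + 6 :]
        scorer = HexamerScorer(seq, "donor", "+")
        assert scorer(planted).score == 1.0
        res = window_site_survey(scorer, planted, "donor", "+", seq)
        assert res["defined"] and res["novel_is_best"]


def test_differential_junction_usage_planted(default_sim):
    """Planted novel junctions (absent in control, sizeable share in
    knockdown) come out with positive usage effects and small padj."""
    truth = default_sim["truth"]
    design = default_sim["design"]
    res = differential_junction_usage(default_sim["junctions"], design)
    novel = [
        t.novel_junction_id for t in truth.genes.values() if t.novel_junction_id
    ]
    sub = res.loc[[j for j in novel if j in res.index]]
    assert (sub["log2fc"] > 1).mean() >= 0.9
    assert (sub["padj"] < 0.05).mean() >= 0.9
    null = res.drop(index=sub.index)
    assert abs(null["log2fc"].median()) < 0.2
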