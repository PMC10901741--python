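"""The differential-count engine: normalization, moderated tests,
multiple-testing correction and the 2x2 association statistic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from te_exonize.diffstats import (
    Design,
    bh_adjust,
    chi2_odds_ratio,
    moderated_count_test,
    relative_usage_test,
    size_factors,
)


def _design(n=3):
    samples = [f"c{i}" for i in range(n)] + [f"t{i}" for i in range(n)]
    cond = {s: ("control" if s.startswith("c") else "treatment") for s in samples}
    return Design(samples, cond)


def _nb_table(rng, n_features, mu, alpha, samples):
    r = 1 / alpha
    p = r / (r + mu)
    return pd.DataFrame(
        rng.negative_binomial(r, p, size=(n_features, len(samples))),
        index=[f"f{i}" for i in range(n_features)],
        columns=samples,
    )


class TestDesign:
    def test_requires_both_conditions(self):
        with pytest.raises(ValueError, match="control"):
            Design(["a", "b"], {"a": "control", "b": "control"})

    def test_missing_sample_condition(self):
        with pytest.raises(ValueError, match="without condition"):
            Design(["a", "b"], {"a": "control"})


class TestSizeFactors:
    def test_identical_samples_equal_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        f = size_factors(counts)
        assert f["a"] == pytest.approx(f["b"])

    def test_doubled_library(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_matches_formula_oracle(self, rng):
        design = _design()
        counts = _nb_table(rng, 200, 100, 0.1, design.samples) + 1
        f = size_factors(counts)
        # direct median-of-ratios recomputation
        mat = counts.to_numpy(float)
        gm = np.exp(np.mean(np.log(mat), axis=1))
        for j, s in enumerate(counts.columns):
            assert f[s] == pytest.approx(np.median(mat[:, j] / gm))

    def test_no_universal_feature_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="size_factors"):
            size_factors(counts)


class TestModeratedCountTest:
    def test_null_feature_flat(self, rng):
        design = _design()
        counts = _nb_table(rng, 500, 100, 0.05, design.samples)
        res = moderated_count_test(counts, design, lfc_threshold=1.0)
        # with a fold-change threshold, null features sit at p ~ 1
        assert res["p"].median() > 0.9
        assert abs(res["log2fc"].mean()) < 0.05

    def test_low_count_filter(self, rng):
        design = _design()
        counts = _nb_table(rng, 50, 100, 0.05, design.samples)
        counts.iloc[0] = [2, 2, 2, 1, 1, 1]  # total 9 < 10
        res = moderated_count_test(counts, design, min_total=10)
        assert "f0" not in res.index

    def test_single_replicate_rejected(self):
        design = Design(
            ["c0", "t0", "t1"],
            {"c0": "control", "t0": "treatment", "t1": "treatment"},
        )
        counts = pd.DataFrame(
            np.ones((5, 3)) * 50, columns=design.samples,
            index=[f"f{i}" for i in range(5)],
        )
        with pytest.raises(ValueError, match="replicates"):
            moderated_count_test(counts, design)

    def test_planted_fold_change_recovered(self, rng):
        design = _design()
        counts = _nb_table(rng, 300, 100, 0.05, design.samples)
        trt = [s for s in design.samples if s.startswith("t")]
        r = 1 / 0.05
        counts.loc["f0":"f9", trt] = rng.negative_binomial(
            r, r / (r + 400), size=(10, 3)
        )
        res = moderated_count_test(counts, design)
        planted = res.loc[[f"f{i}" for i in range(10)]]
        assert planted["log2fc"].mean() == pytest.approx(2.0, abs=0.3)
        assert (planted["padj"] < 0.05).all()

    def test_library_size_invariance(self, rng):
        """Doubling one sample's depth barely moves the effect estimates
        (median-of-ratios normalization absorbs it)."""
        design = _design()
        counts = _nb_table(rng, 400, 100, 0.05, design.samples)
        scaled = counts.copy()
        scaled["c0"] = scaled["c0"] * 2
        a = moderated_count_test(counts, design)
        b = moderated_count_test(scaled, design)
        assert np.abs(a["log2fc"] - b["log2fc"]).mean() < 0.05


class TestRelativeUsage:
    def test_constant_share_is_null(self, rng):
        design = _design()
        f = _nb_table(rng, 200, 50, 0.05, design.samples)
        g = f + _nb_table(rng, 200, 450, 0.05, design.samples)
        res = relative_usage_test(f, g, design)
        assert abs(res["log2fc"].mean()) < 0.1
        assert (res["p"] > 0.05).mean() > 0.8

    def test_planted_share_gain(self, rng):
        design = _design()
        f = _nb_table(rng, 100, 30, 0.05, design.samples)
        other = _nb_table(rng, 100, 570, 0.05, design.samples)
        trt = [s for s in design.samples if s.startswith("t")]
        f.loc["f0", trt] = [260, 250, 240]  # share 0.05 -> ~0.30
        g = f + other
        res = relative_usage_test(f, g, design)
        assert res.at["f0", "log2fc"] > 1.5
        assert res.at["f0", "padj"] < 0.05

    def test_common_scale_invariance(self, rng):
        """Multiplying one sample's counts by a constant leaves the usage
        statistic essentially unchanged (shares are ratios)."""
        design = _design()
        f = _nb_table(rng, 150, 80, 0.05, design.samples)
        g = f + _nb_table(rng, 150, 300, 0.05, design.samples)
        f2, g2 = f.copy(), g.copy()
        f2["t0"] = f2["t0"] * 10
        g2["t0"] = g2["t0"] * 10
        a = relative_usage_test(f, g, design)
        b = relative_usage_test(f2, g2, design)
        assert np.abs(a["log2fc"] - b["log2fc"]).max() < 0.05

    def test_dead_group_filtered(self, rng):
        design = _design()
        f = pd.DataFrame(0, index=["f0"], columns=design.samples)
        g = pd.DataFrame(0, index=["f0"], columns=design.samples)
        g[[s for s in design.samples if s.startswith("t")]] = 10
        res = relative_usage_test(f, g, design)
        assert np.isnan(res.at["f0", "p"])
        assert np.isnan(res.at["f0", "padj"])

    def test_feature_exceeding_group_rejected(self, rng):
        design = _design()
        f = pd.DataFrame(5, index=["f0"], columns=design.samples)
        g = pd.DataFrame(4, index=["f0"], columns=design.samples)
        with pytest.raises(ValueError, match="exceeds"):
            relative_usage_test(f, g, design)


class TestBhAdjust:
    def test_single_p(self):
        assert bh_adjust([0.05]).tolist() == [0.05]

    def test_hand_computed(self):
        # p*(m/rank) = .04, .04, .04, .04 after monotonicity
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_dominates_p(self, rng):
        p = rng.random(200)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_nan_passthrough(self):
        got = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(got[1]) and np.isfinite(got[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestChi2OddsRatio:
    def test_independence(self):
        chi2, p, orat = chi2_odds_ratio([[10, 10], [10, 10]])
        assert chi2 == 0.0 and orat == 1.0 and p == pytest.approx(1.0)

    def test_closed_form_example(self):
        chi2, _, orat = chi2_odds_ratio([[30, 70], [20, 80]])
        assert orat == pytest.approx(12 / 7)
        n = 200.0
        expect = n * (30 * 80 - 70 * 20) ** 2 / (100 * 100 * 50 * 150)
        assert chi2 == pytest.approx(expect, abs=1e-12)

    def test_matches_scipy_on_random_tables(self, rng):
        """Cross-check against an independent implementation to 1e-12."""
        for _ in range(100):
            t = rng.integers(1, 500, size=(2, 2))
            chi2, p, orat = chi2_odds_ratio(t)
            ref = stats.chi2_contingency(t, correction=False)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-12, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12, rel=1e-9)
            a, b = t[0]
            c, d = t[1]
            assert orat == pytest.approx((a * d) / (b * c))

    def test_zero_cell_haldane(self):
        chi2, _, orat = chi2_odds_ratio([[0, 10], [10, 10]])
        assert orat == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_odds_ratio([[0, 0], [10, 10]])
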