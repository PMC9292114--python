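"""TPM, multiple testing, Fisher enrichment and the expression tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from homeoscan import expr


class TestTpm:
    def test_equal_rates_split_evenly(self):
        counts = pd.DataFrame({"s1": [100, 200]}, index=["a", "b"])
        lengths = pd.Series([1000, 2000], index=["a", "b"])
        t = expr.tpm(counts, lengths)
        assert t.loc["a", "s1"] == pytest.approx(500000)
        assert t.loc["b", "s1"] == pytest.approx(500000)

    def test_columns_sum_to_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, size=(30, 4)))
        lengths = pd.Series(rng.integers(200, 3000, size=30))
        t = expr.tpm(counts, lengths)
        assert np.allclose(t.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_count_transcript_zero_tpm(self):
        counts = pd.DataFrame({"s1": [0, 10]}, index=["a", "b"])
        t = expr.tpm(counts, pd.Series([100, 100], index=["a", "b"]))
        assert t.loc["a", "s1"] == 0.0

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            expr.tpm(counts, pd.Series([100, 100], index=["a", "b"]))


class TestBhAdjust:
    def test_stepup_arithmetic(self):
        out = expr.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert expr.bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_all_ones(self):
        assert np.allclose(expr.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_permutation_invariant(self, rng):
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        out = expr.bh_adjust(p)
        out_perm = expr.bh_adjust(p[perm])
        assert np.allclose(out[perm], out_perm)


def _fisher_enumeration(table):
    """Two-sided Fisher p by summing hypergeometric pmf over all tables."""
    (a, b), (c, d) = table
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    rv = stats.hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-10):
            total += pk
    return min(total, 1.0)


class TestFisherEnrichment:
    def test_printed_count_table(self):
        """The 2x2 table built from the printed counts (4/10 sex-biased on the
        sex chromosome vs 262/1500 expressed) — exact enumeration value."""
        p = expr.fisher_enrichment([[4, 6], [258, 1232]])
        assert p == pytest.approx(_fisher_enumeration([[4, 6], [258, 1232]]), abs=1e-9)
        assert p == pytest.approx(0.0799, abs=5e-5)

    def test_identical_proportions(self):
        assert expr.fisher_enrichment([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table(self):
        assert expr.fisher_enrichment([[3, 0], [0, 3]]) == pytest.approx(0.1)

    def test_zero_margin_convention(self):
        assert expr.fisher_enrichment([[0, 0], [3, 7]]) == 1.0

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(50):
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert expr.fisher_enrichment(t) == pytest.approx(_fisher_enumeration(t), abs=1e-9)


class TestNbDeTest:
    def test_constant_counts_null(self):
        counts = pd.DataFrame(np.full((20, 12), 50))
        res = expr.nb_de_test(counts, ["M"] * 6 + ["F"] * 6)
        assert np.allclose(res["log2FC"], 0.0, atol=1e-6)
        assert (res["p"] > 0.9).all()

    def test_strong_effect_detected(self, rng):
        mu = np.full((100, 12), 200.0)
        mu[:10, :6] *= 4.0
        counts = pd.DataFrame(rng.poisson(mu))
        res = expr.nb_de_test(counts, ["M"] * 6 + ["F"] * 6)
        assert res["significant"].to_numpy()[:10].all()
        assert res["log2FC"].to_numpy()[:10].mean() == pytest.approx(-2.0, abs=0.2)

    def test_all_zero_gene_excluded(self):
        counts = pd.DataFrame(np.vstack([np.zeros(12), np.full(12, 30)]))
        res = expr.nb_de_test(counts, ["M"] * 6 + ["F"] * 6)
        assert len(res) == 1

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            expr.nb_de_test(pd.DataFrame(np.ones((3, 4))), ["M"] * 4)


class TestSubfunctionalization:
    def _pairs(self, n):
        return pd.DataFrame(
            {"pair": [f"p{i}" for i in range(n)], "sub1": [f"a{i}" for i in range(n)], "sub2": [f"b{i}" for i in range(n)]}
        )

    def _tpm(self, ratios_m, ratios_f, n_pairs, rng, base=100.0):
        """TPM frame with log2(sub1/sub2) targets per sex."""
        cols = [f"M{i}" for i in range(6)] + [f"F{i}" for i in range(6)]
        rows = {}
        for i in range(n_pairs):
            r = np.array([ratios_m[i]] * 6 + [ratios_f[i]] * 6) + rng.normal(0, 0.15, 12)
            rows[f"a{i}"] = base * 2.0 ** (r / 2)
            rows[f"b{i}"] = base * 2.0 ** (-r / 2)
        return pd.DataFrame(rows).T.set_axis(cols, axis=1)

    def test_opposite_bias_detected(self, rng):
        n = 40
        rm = np.zeros(n)
        rf = np.zeros(n)
        rm[0], rf[0] = 2.0, -2.0
        t = self._tpm(rm, rf, n, rng)
        res = expr.subfunctionalization_test(self._pairs(n), t, ["M"] * 6 + ["F"] * 6)
        row = res.set_index("pair").loc["p0"]
        assert row["padj"] < 0.05
        assert row["pattern"] == "opposite_bias"
        assert (res.set_index("pair").drop("p0")["pattern"] == "none").all()

    def test_identical_ratios_not_significant(self, rng):
        n = 30
        t = self._tpm(np.ones(n), np.ones(n), n, rng)
        res = expr.subfunctionalization_test(self._pairs(n), t, ["M"] * 6 + ["F"] * 6)
        assert (res["pattern"] == "none").all()

    def test_low_expression_pairs_skipped(self, rng):
        t = self._tpm([2.0], [-2.0], 1, rng, base=0.01)
        res = expr.subfunctionalization_test(self._pairs(1), t, ["M"] * 6 + ["F"] * 6)
        assert res.empty

    def test_classify_pattern_rules(self):
        assert expr.classify_pattern(2.0, -2.0) == "opposite_bias"
        assert expr.classify_pattern(2.0, 0.0) == "single_homeolog_bias"
        assert expr.classify_pattern(2.0, 1.0) == "same_direction_magnitude"


class TestHomeologBias:
    def test_balanced_pairs_mostly_null(self, rng):
        n = 50
        cols = [f"s{i}" for i in range(12)]
        rows = {}
        for i in range(n):
            rows[f"a{i}"] = 100 * 2.0 ** rng.normal(0, 0.2, 12)
            rows[f"b{i}"] = 100 * 2.0 ** rng.normal(0, 0.2, 12)
        t = pd.DataFrame(rows).T.set_axis(cols, axis=1)
        pairs = pd.DataFrame(
            {"pair": [f"p{i}" for i in range(n)], "sub1": [f"a{i}" for i in range(n)], "sub2": [f"b{i}" for i in range(n)]}
        )
        res = expr.homeolog_bias_test(pairs, t)
        assert (res["direction"] == "none").mean() > 0.9

    def test_shifted_pair_detected(self, rng):
        cols = [f"s{i}" for i in range(12)]
        rows = {"a0": np.full(12, 800.0) * 2 ** rng.normal(0, 0.1, 12), "b0": np.full(12, 100.0)}
        for i in range(1, 30):
            rows[f"a{i}"] = 100 * 2.0 ** rng.normal(0, 0.2, 12)
            rows[f"b{i}"] = 100 * 2.0 ** rng.normal(0, 0.2, 12)
        t = pd.DataFrame(rows).T.set_axis(cols, axis=1)
        pairs = pd.DataFrame(
            {"pair": [f"p{i}" for i in range(30)], "sub1": [f"a{i}" for i in range(30)], "sub2": [f"b{i}" for i in range(30)]}
        )
        res = expr.homeolog_bias_test(pairs, t).set_index("pair")
        assert res.loc["p0", "direction"] == "sub1_higher"
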