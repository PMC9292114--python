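"""Weir-Cockerham FST, sex-biased heterozygosity and the rolling scan."""

import itertools

import numpy as np
import pandas as pd
import pytest

from homeoscan import sdrscan as sc
from homeoscan.genotypes import GT_HET, GT_HOM_ALT, GT_HOM_REF

from conftest import make_variant_table


def _anova_components(gt_row, pop):
    """Independent WC84 oracle via the nested ANOVA mean-square route."""
    ys = []
    for mask in (pop, ~pop):
        g = gt_row[mask]
        g = g[g != -1]
        arr = np.zeros((g.size, 2))
        arr[g == 1, 1] = 1.0
        arr[g == 2] = 1.0
        ys.append(arr)
    n1, n2 = len(ys[0]), len(ys[1])
    if min(n1, n2) == 0 or n1 + n2 < 3:
        return None
    gm = np.vstack(ys).mean()
    ssg = ssi = ssp = 0.0
    for arr in ys:
        im = arr.mean(axis=1)
        pm = arr.mean()
        ssg += ((arr - im[:, None]) ** 2).sum()
        ssi += 2 * ((im - pm) ** 2).sum()
        ssp += 2 * len(arr) * (pm - gm) ** 2
    dfi = n1 + n2 - 2
    if dfi == 0:
        return None
    msg = ssg / (n1 + n2)
    msi = ssi / dfi
    msp = ssp
    nbar = (n1 + n2) / 2
    nc = (2 * nbar - (n1 * n1 + n2 * n2) / (2 * nbar)) / 1.0
    return ((msp - msi) / (2 * nc), (msi - msg) / 2, msg)


class TestWcFst:
    def test_all_males_het_females_homref(self):
        gt = np.array([GT_HET] * 6 + [GT_HOM_REF] * 6, dtype=np.int8)
        pop = np.array([True] * 6 + [False] * 6)
        a, b, c = sc.wc_fst_components(gt, pop)
        assert a == pytest.approx(0.125)
        assert b == pytest.approx(-0.125)
        assert c == pytest.approx(0.25)
        assert a / (a + b + c) == pytest.approx(0.5)

    def test_fixed_difference(self):
        gt = np.array([GT_HOM_ALT] * 6 + [GT_HOM_REF] * 6, dtype=np.int8)
        pop = np.array([True] * 6 + [False] * 6)
        a, b, c = sc.wc_fst_components(gt, pop)
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_identical_configurations_nonpositive(self):
        gt = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0, 1, 2], dtype=np.int8)
        pop = np.array([True] * 6 + [False] * 6)
        a, b, c = sc.wc_fst_components(gt, pop)
        assert a / (a + b + c) <= 0.0

    def test_matches_anova_oracle_on_all_configurations(self):
        """Component-by-component equivalence with the nested-ANOVA oracle on
        every genotype-count configuration with <= 6 diploids per sex."""
        def configs(n_max):
            for n in range(1, n_max + 1):
                for n0 in range(n + 1):
                    for n1 in range(n + 1 - n0):
                        yield (n0, n1, n - n0 - n1)

        checked = 0
        for cm in configs(6):
            for cf in configs(6):
                gm = np.repeat([0, 1, 2], cm).astype(np.int8)
                gf = np.repeat([0, 1, 2], cf).astype(np.int8)
                gt = np.concatenate([gm, gf])
                pop = np.array([True] * gm.size + [False] * gf.size)
                got = sc.wc_fst_components(gt, pop)
                want = _anova_components(gt, pop)
                if want is None or not np.isfinite(got[0]):
                    continue
                for g, w in zip(got, want):
                    assert g == pytest.approx(w, abs=1e-9), (cm, cf)
                checked += 1
        assert checked > 3000

    def test_single_site_transcript_equals_component_ratio(self):
        gt = np.array([[GT_HET] * 6 + [GT_HOM_REF] * 6], dtype=np.int8)
        vt = make_variant_table(gt, ["M"] * 6 + ["F"] * 6)
        a, b, c = sc.wc_fst_components(gt[0], vt.male_mask)
        assert sc.transcript_fst(vt, "t1") == pytest.approx(a / (a + b + c))


class TestSexBiasedHeterozygosity:
    def test_equal_means_zero(self):
        gt = np.tile([GT_HET] * 12, (4, 1)).astype(np.int8)
        vt = make_variant_table(gt, ["M"] * 6 + ["F"] * 6)
        assert sc.sex_biased_heterozygosity(vt, "t1") == pytest.approx(0.0)

    def test_tenfold_ratio(self):
        # males: 20 het sites of 1000 assayable -> 0.02; females: 2 -> 0.002
        gt = np.zeros((20, 12), dtype=np.int8)
        gt[:, :6] = GT_HET
        gt[:2, 6:] = GT_HET
        vt = make_variant_table(gt, ["M"] * 6 + ["F"] * 6)
        assert sc.sex_biased_heterozygosity(vt, "t1") == pytest.approx(1.0, abs=0.05)

    def test_zero_female_het_finite(self):
        gt = np.zeros((5, 12), dtype=np.int8)
        gt[:, :6] = GT_HET
        vt = make_variant_table(gt, ["M"] * 6 + ["F"] * 6)
        v = sc.sex_biased_heterozygosity(vt, "t1")
        assert np.isfinite(v) and v > 0


class TestRollingScan:
    def _series(self, values, lg=1):
        return pd.DataFrame(
            {
                "lg": lg,
                "cM": np.arange(len(values), dtype=float),
                "value": values,
                "transcript": [f"t{lg}_{i}" for i in range(len(values))],
            }
        )

    def test_constant_input_degenerate(self):
        s = self._series([0.3] * 30)
        scan = sc.rolling_scan_with_ci(s, s, seed=0)
        assert np.allclose(scan.windows["rolling_mean"], 0.3)
        assert scan.ci == (pytest.approx(0.3), pytest.approx(0.3))
        assert not scan.windows["elevated"].any()

    def test_too_few_transcripts_no_windows(self):
        short = self._series(np.random.default_rng(0).normal(size=19), lg=1)
        auto = self._series(np.random.default_rng(1).normal(size=40), lg=2)
        scan = sc.rolling_scan_with_ci(short, auto, seed=0)
        assert scan.windows.empty

    def test_no_autosomal_run_raises(self):
        s = self._series([0.1] * 25)
        with pytest.raises(ValueError):
            sc.rolling_scan_with_ci(s, self._series([0.1] * 10, lg=2), seed=0)

    def test_null_exceedance_near_five_percent(self):
        """Exchangeable values give ~5% of windows outside the bootstrap CI."""
        rng = np.random.default_rng(3)
        rates = []
        for _ in range(30):
            frames = [self._series(rng.normal(size=40), lg=k) for k in range(1, 9)]
            df = pd.concat(frames)
            auto = df[df["lg"] > 1]
            scan = sc.rolling_scan_with_ci(df, auto, seed=int(rng.integers(2**31)))
            w = scan.windows
            rates.append(((w["rolling_mean"] > w["hi"]) | (w["rolling_mean"] < w["lo"])).mean())
        assert 0.02 < np.mean(rates) < 0.08

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        s = self._series(rng.normal(size=60))
        a = sc.rolling_scan_with_ci(s, s, seed=7)
        b = sc.rolling_scan_with_ci(s, s, seed=7)
        assert a.ci == b.ci
        pd.testing.assert_frame_equal(a.windows, b.windows)


def _mw_enumeration_p(x, y):
    """Brute-force two-sided rank-sum p by enumerating group labelings."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()

    def stat(idx):
        r1 = ranks[list(idx)].sum()
        u1 = r1 - n1 * (n1 + 1) / 2
        return min(u1, len(x) * len(y) - u1)

    obs = stat(range(n1))
    total = hits = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        hits += stat(idx) <= obs + 1e-12
    return hits / total


class TestRegionCompare:
    def _frame(self, groups):
        rows = []
        for name, vals in groups.items():
            rows += [{"region_class": name, "value": v} for v in vals]
        return pd.DataFrame(rows)

    def test_identical_samples_p_one(self):
        df = self._frame({"a": [1, 2, 3, 4.5], "b": [1, 2, 3, 4.5]})
        res = sc.region_compare(df)
        assert res.iloc[0]["p"] == pytest.approx(1.0, abs=0.05)

    def test_fully_separated_exact_p(self):
        df = self._frame({"a": list(range(10)), "b": list(range(100, 110))})
        res = sc.region_compare(df)
        assert res.iloc[0]["p"] == pytest.approx(2 / 184756, rel=1e-6)

    def test_matches_enumeration_oracle_small_samples(self, rng):
        for _ in range(5):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            df = self._frame({"a": x, "b": y})
            got = sc.region_compare(df).iloc[0]["p"]
            want = _mw_enumeration_p(x, y)
            assert got == pytest.approx(want, rel=1e-9)

    def test_three_groups_three_comparisons(self, rng):
        df = self._frame({"a": rng.normal(size=8), "b": rng.normal(size=8), "c": rng.normal(size=8)})
        assert len(sc.region_compare(df)) == 3
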