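"""Synthetic allopolyploid generator: sequence evolution, planting, counts."""

import numpy as np
import pytest

from homeoscan import codonevol as ce
from homeoscan import sdrscan as sc
from homeoscan import simdata as sd


class TestSimConfig:
    def test_divergence_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sd.SimConfig(target_ds_homeolog=0.8)

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sd.SimConfig(sexbias_fraction=1.5)

    def test_progenitor_divergence_must_be_smaller(self):
        with pytest.raises(ValueError):
            sd.SimConfig(target_ds_sub1_prog=0.2, target_ds_homeolog=0.14)


class TestEvolveSequence:
    def test_zero_target_identity(self, rng):
        anc = sd.random_orf(100, rng)
        assert sd.evolve_sequence(anc, 0.0, rng) == anc

    def test_realized_ds_near_target(self, rng):
        for target in (0.07, 0.14):
            anc = sd.random_orf(300, rng)
            out = sd.evolve_sequence(anc, target, rng)
            realized = ce.ng86_sequences(anc, out).dS
            assert realized == pytest.approx(target, rel=0.10)

    def test_no_internal_stops(self, rng):
        anc = sd.random_orf(200, rng)
        out = sd.evolve_sequence(anc, 0.3, rng)
        codons = [out[i : i + 3] for i in range(0, len(out), 3)]
        assert not any(c in ce.STOP_CODONS for c in codons)
        assert len(out) == len(anc)

    def test_saturated_target_rejected(self, rng):
        with pytest.raises(ValueError):
            sd.evolve_sequence(sd.random_orf(60, rng), 0.9, rng)


class TestPlantSexLinked:
    def _vt(self, ds):
        return ds.variants

    def test_partial_mode_fst_half(self, small_dataset):
        from homeoscan import genotypes as gt

        called = gt.call_genotypes(small_dataset.variants)
        planted = np.flatnonzero(called.sites["sex_linked"].to_numpy())
        assert planted.size > 0
        for i in planted[:20]:
            a, b, c = sc.wc_fst_components(called.genotypes[i], called.male_mask)
            assert a / (a + b + c) == pytest.approx(0.5, abs=0.02)

    def test_fixed_mode_fst_one(self, small_dataset):
        vt = small_dataset.variants
        idx = np.flatnonzero(vt.sites["sex_linked"].to_numpy())[:5]
        out = sd.plant_sex_linked_variants(vt, site_indices=idx, mode="fixed", rng=0)
        for i in idx:
            a, b, c = sc.wc_fst_components(out.genotypes[i], out.male_mask)
            assert a / (a + b + c) == pytest.approx(1.0)

    def test_region_selection_requires_mapped_transcripts(self, small_dataset):
        with pytest.raises(ValueError):
            sd.plant_sex_linked_variants(
                small_dataset.variants,
                linkage=small_dataset.linkage,
                span=(900.0, 950.0),
                rng=0,
            )

    def test_neutral_sites_balanced_between_sexes(self, small_dataset):
        vt = small_dataset.variants
        neutral = ~vt.sites["sex_linked"].to_numpy()
        g = vt.genotypes[neutral].astype(float)
        male_freq = g[:, vt.male_mask].mean()
        female_freq = g[:, ~vt.male_mask].mean()
        assert male_freq == pytest.approx(female_freq, abs=0.05)


class TestSimulateCounts:
    def test_same_seed_identical(self, small_dataset):
        cfg = small_dataset.config
        a = sd.simulate_counts(small_dataset.truth, cfg, rng=5)
        b = sd.simulate_counts(small_dataset.truth, cfg, rng=5)
        assert a.counts.equals(b.counts)

    def test_poisson_limit_variance(self, rng):
        cfg = sd.SimConfig(n_genes=40, seed=1, nb_dispersion=0.0, sexbias_fraction=0.0, subfunc_fraction=0.0)
        ds = sd.simulate_dataset(cfg)
        c = ds.expression.counts.to_numpy(dtype=float)
        ratio = c.var(axis=1, ddof=1) / np.maximum(c.mean(axis=1), 1e-9)
        # index of dispersion concentrates around 1 for Poisson
        assert np.median(ratio) == pytest.approx(1.0, abs=0.3)

    def test_planted_fourfold_effect_recovered(self):
        """Monte-Carlo over planted genes: realized male/female ratio near 4."""
        rng = np.random.default_rng(11)
        ratios = []
        for rep in range(100):
            mu = 400.0
            m = np.full((1, 12), mu)
            m[0, :6] *= 2.0
            m[0, 6:] /= 2.0
            shape = 1 / 0.01
            counts = rng.negative_binomial(shape, shape / (shape + m))
            ratios.append(counts[0, :6].mean() / counts[0, 6:].mean())
        assert np.mean(ratios) == pytest.approx(4.0, rel=0.25)

    def test_planted_effects_in_generator(self, small_dataset):
        cfg = small_dataset.config
        em = small_dataset.expression
        tr = small_dataset.truth.transcripts
        biased = tr[tr["sex_bias_log2"] != 0.0]
        if len(biased):
            t = biased.iloc[0]
            row = em.counts.loc[t["transcript"]].to_numpy(dtype=float)
            obs = np.log2((row[:6].mean() + 0.5) / (row[6:].mean() + 0.5))
            assert np.sign(obs) == np.sign(t["sex_bias_log2"])

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            sd.SimConfig(nb_dispersion=-1.0)


class TestSimulateDataset:
    def test_truth_partitions_transcripts(self, small_dataset):
        tr = small_dataset.truth.transcripts
        assert tr["transcript"].is_unique
        emitted = {t.id for t in small_dataset.poly}
        assert emitted == set(tr["transcript"])

    def test_sdr_only_on_lg1_sub1(self, small_dataset):
        tr = small_dataset.truth.transcripts
        sdr = tr[(tr["region_class"] == "sex_linked") & (tr["subgenome"] == "sub1")]
        lo, hi = small_dataset.config.sdr_span
        assert (sdr["lg"] == 1).all()
        assert sdr["cM"].between(lo, hi).all()
        planted = small_dataset.variants.sites[small_dataset.variants.sites["sex_linked"]]
        assert set(planted["transcript"]) <= set(sdr["transcript"])

    def test_byte_identical_replication(self, tmp_path, small_dataset):
        import hashlib

        cfg = small_dataset.config
        ds2 = sd.simulate_dataset(cfg)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        small_dataset.write(str(d1))
        ds2.write(str(d2))
        for f in sorted(p.name for p in d1.iterdir()):
            h1 = hashlib.sha256((d1 / f).read_bytes()).hexdigest()
            h2 = hashlib.sha256((d2 / f).read_bytes()).hexdigest()
            assert h1 == h2, f

    def test_realized_median_homeolog_ds(self, small_dataset):
        seq = {t.id: t.sequence for t in small_dataset.poly}
        dss = []
        for rec in small_dataset.truth.pairs.itertuples():
            if rec.single_copy:
                continue
            dss.append(ce.ng86_sequences(seq[rec.sub1], seq[rec.sub2]).dS)
        med = float(np.median(dss))
        assert med == pytest.approx(0.14, rel=0.10)

    def test_ds_ordering_coalescent_logic(self, small_dataset):
        """ds(sub1, prog) < ds(sub2, prog) for nearly all genes at defaults."""
        seq = {t.id: t.sequence for t in small_dataset.poly}
        pseq = {t.id: t.sequence for t in small_dataset.prog}
        ok = tot = 0
        for rec in small_dataset.truth.pairs.itertuples():
            if rec.single_copy:
                continue
            d1 = ce.ng86_sequences(seq[rec.sub1], pseq[rec.prog]).dS
            d2 = ce.ng86_sequences(seq[rec.sub2], pseq[rec.prog]).dS
            tot += 1
            ok += d1 < d2
        assert ok / tot >= 0.95
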