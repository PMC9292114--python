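"""Synthetic allopolyploid transcriptome generator with known ground truth.

The generator emulates a recent allotetraploid with an XY sex-determining
system inherited from one progenitor lineage.  Coding sequences evolve
along a fixed four-taxon tree: a root ancestor splits into the lineage of
subgenome 2 and the ancestor of (subgenome 1, extant progenitor), with an
outgroup attached basally.  Branch lengths are chosen so the realized
silent-site divergences hit the configured targets — by default a median
homeolog dS of 0.14 with subgenome 1 at half that distance (0.07) from
the extant progenitor and ~0.5 to the outgroup — mirroring the divergence
scale of a polyploidization a few million generations old.  Sequence
evolution places synonymous substitutions (plus a small nonsynonymous
fraction) until the NG86 dS to the immediate ancestor reaches the branch
target, so tip-to-tip distances are approximately additive in the
corrected scale.

The dataset comprises:

* three transcript FASTA sets: polyploid (both subgenomes, plus truncated
  isoform copies exercising the clustering step), extant progenitor, and
  outgroup orthologs;
* a linkage map (transcript -> linkage group, cM, region class) with a
  non-recombining sex-linked block on linkage group 1 of subgenome 1 —
  transcripts of the block stack within the configured cM span, as SDR
  markers do on a genetic map;
* biallelic genotype data (allele depths and qualities) for sexed
  individuals, with Y-specific alleles planted in the sex-linked block
  (males heterozygous, females homozygous reference in ``partial`` mode);
* negative-binomial expression counts with planted sex-biased transcripts
  and sexually subfunctionalized homeolog pairs;
* a truth table recording every planted feature.

Everything is driven by one seed through spawned child generators, so
identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .codonevol import (
    SENSE_CODONS,
    STOP_CODONS,
    codon_differences,
    jukes_cantor,
    synonymous_sites,
    translate_codon,
)
from .expr import ExpressionMatrix
from .genotypes import GT_HET, GT_HOM_ALT, GT_HOM_REF, VariantTable
from .homeology import Transcript, write_fasta

BASES = "ACGT"


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic allopolyploid dataset.

    Divergence targets are NG86 dS (substitutions per synonymous site);
    the defaults place the two subgenomes at median homeolog dS 0.14 with
    subgenome 1 at 0.07 from the extant progenitor.  Six males and six
    females are genotyped and quantified, matching a typical sexed
    RNA-seq design.  ``mutation_rate`` is per site per generation and is
    only used for TMRCA conversion downstream.
    """

    n_genes: int = 300
    target_ds_homeolog: float = 0.14
    target_ds_sub1_prog: float = 0.07
    outgroup_ds: float = 0.5
    n_males: int = 6
    n_females: int = 6
    sdr_span: tuple[float, float] = (40.0, 55.0)
    n_lgs: int = 8
    sdr_gene_fraction: float = 0.12
    isoform_redundancy_rate: float = 0.10
    nb_dispersion: float = 0.05
    sexbias_fraction: float = 0.05
    subfunc_fraction: float = 0.05
    sexbias_log2: float = 2.0
    subfunc_log2: float = 2.0
    mutation_rate: float = 7.5e-9
    min_codons: int = 150
    max_codons: int = 600
    nonsyn_fraction: float = 0.10
    mean_depth: float = 30.0
    sites_per_kb: float = 8.0
    sdr_sites_per_kb: float = 6.0
    diversity_ratio_sub1: float = 1.5
    single_copy_fraction: float = 0.0
    sdr_mode: str = "partial"  # {partial, fixed}
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("target_ds_homeolog", "target_ds_sub1_prog", "outgroup_ds"):
            v = getattr(self, name)
            if not 0.0 < v < 0.74:
                raise ValueError(f"{name} must lie in (0, 0.74), got {v}")
        for name in (
            "sdr_gene_fraction",
            "isoform_redundancy_rate",
            "sexbias_fraction",
            "subfunc_fraction",
            "single_copy_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_males + self.n_females < 2:
            raise ValueError("need at least two sexed individuals")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be positive")
        if self.target_ds_sub1_prog >= self.target_ds_homeolog:
            raise ValueError("progenitor divergence must be below homeolog divergence")
        if self.sdr_mode not in ("partial", "fixed"):
            raise ValueError("sdr_mode must be 'partial' or 'fixed'")

    @property
    def samples(self) -> list[str]:
        return [f"M{i+1}" for i in range(self.n_males)] + [f"F{i+1}" for i in range(self.n_females)]

    @property
    def sexes(self) -> list[str]:
        return ["M"] * self.n_males + ["F"] * self.n_females


@dataclass
class TruthTable:
    """Ground truth for every emitted transcript and homeolog pair."""

    transcripts: pd.DataFrame  # transcript, gene, subgenome, lg, cM, region_class, length, is_isoform, sex_bias_log2
    pairs: pd.DataFrame  # gene, sub1, sub2, prog, outgroup, lg, cM, region_class, subfunc, single_copy


@dataclass
class SyntheticDataset:
    """All artefacts of one simulation run."""

    config: SimConfig
    poly: list[Transcript]
    prog: list[Transcript]
    outgroup: list[Transcript]
    variants: VariantTable
    linkage: pd.DataFrame
    expression: ExpressionMatrix
    truth: TruthTable

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.poly, os.path.join(outdir, "polyploid.fasta"))
        write_fasta(self.prog, os.path.join(outdir, "progenitor.fasta"))
        write_fasta(self.outgroup, os.path.join(outdir, "outgroup.fasta"))
        self.variants.to_vcf(os.path.join(outdir, "genotypes.vcf"))
        self.linkage.to_csv(os.path.join(outdir, "linkage_map.tsv"), sep="\t", index=False)
        counts = self.expression.counts.copy()
        counts.insert(0, "length", self.expression.lengths)
        counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t", index_label="transcript_id")
        pd.DataFrame({"sample": self.expression.counts.columns, "sex": self.expression.sex}).to_csv(
            os.path.join(outdir, "design.tsv"), sep="\t", index=False
        )
        self.truth.transcripts.to_csv(os.path.join(outdir, "truth_transcripts.tsv"), sep="\t", index=False)
        self.truth.pairs.to_csv(os.path.join(outdir, "truth_pairs.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence evolution


def random_orf(n_codons: int, rng: np.random.Generator) -> str:
    """Random in-frame coding sequence with uniform sense codon usage."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


class _Ng86Tracker:
    """Incremental NG86 dS between a fixed ancestor and an evolving copy."""

    def __init__(self, ancestor_codons: list[str]):
        self.anc = ancestor_codons
        self.cur = list(ancestor_codons)
        self.s_anc = sum(synonymous_sites(c) for c in ancestor_codons)
        self.s_cur = self.s_anc
        self.sd = 0.0
        self.nd = 0.0

    def apply(self, i: int, new_codon: str) -> tuple[str, float, float]:
        old = self.cur[i]
        d_old = codon_differences(self.anc[i], old)
        d_new = codon_differences(self.anc[i], new_codon)
        self.sd += d_new[0] - d_old[0]
        self.nd += d_new[1] - d_old[1]
        self.s_cur += synonymous_sites(new_codon) - synonymous_sites(old)
        self.cur[i] = new_codon
        return old, d_old[0], d_old[1]

    def revert(self, i: int, old_codon: str) -> None:
        self.apply(i, old_codon)

    def ds(self) -> Optional[float]:
        s_bar = (self.s_anc + self.s_cur) / 2.0
        if s_bar <= 0:
            return 0.0
        return jukes_cantor(self.sd / s_bar)


def evolve_sequence(
    ancestor: str,
    target_ds: float,
    rng: np.random.Generator | int,
    nonsyn_fraction: float = 0.10,
) -> str:
    """Evolve a coding sequence to a target NG86 dS from its ancestor.

    Substitutions are applied one at a time — synonymous with probability
    1 - ``nonsyn_fraction``, nonsynonymous otherwise, never creating a
    stop codon — until the NG86 dS between ancestor and result reaches
    ``target_ds``; the final substitution is reverted when the previous
    state was closer to the target.  Length and frame are preserved.
    """
    if not 0.0 <= target_ds < 0.74:
        raise ValueError("target_ds must lie in [0, 0.74)")
    if len(ancestor) % 3:
        raise ValueError("ancestor length must be divisible by 3")
    codons = [ancestor[i : i + 3].upper() for i in range(0, len(ancestor), 3)]
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("ancestor contains internal stop codons")
    if target_ds == 0.0:
        return ancestor.upper()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    tracker = _Ng86Tracker(codons)
    n = len(codons)
    max_events = 400 * n
    events = 0
    prev_gap = target_ds  # |ds - target| before any event
    while events < max_events:
        want_nonsyn = rng.random() < nonsyn_fraction
        # rejection-sample a single-step change of the wanted class
        for _ in range(200):
            i = int(rng.integers(n))
            pos = int(rng.integers(3))
            b = BASES[int(rng.integers(4))]
            cur = tracker.cur[i]
            if b == cur[pos]:
                continue
            new = cur[:pos] + b + cur[pos + 1 :]
            if new in STOP_CODONS:
                continue
            syn = translate_codon(new) == translate_codon(cur)
            if syn != (not want_nonsyn):
                continue
            break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not sample a substitution")
        old, *_ = tracker.apply(i, new)
        events += 1
        ds = tracker.ds()
        if ds is None:
            tracker.revert(i, old)
            break
        gap = abs(ds - target_ds)
        if ds >= target_ds:
            if gap > prev_gap:
                tracker.revert(i, old)
            break
        prev_gap = gap
    return "".join(tracker.cur)


def _evolve_gene_family(n_codons: int, cfg: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    """Evolve one gene along the fixed four-taxon tree; returns tip sequences."""
    t_sister = cfg.target_ds_sub1_prog / 2.0
    t_mid = (cfg.target_ds_homeolog - cfg.target_ds_sub1_prog) / 2.0
    t_sub2 = cfg.target_ds_homeolog / 2.0
    t_out = max(cfg.outgroup_ds - t_sub2, 0.01)
    root = random_orf(n_codons, rng)
    anc1 = evolve_sequence(root, t_mid, rng, cfg.nonsyn_fraction)
    return {
        "sub1": evolve_sequence(anc1, t_sister, rng, cfg.nonsyn_fraction),
        "prog": evolve_sequence(anc1, t_sister, rng, cfg.nonsyn_fraction),
        "sub2": evolve_sequence(root, t_sub2, rng, cfg.nonsyn_fraction),
        "outgroup": evolve_sequence(root, t_out, rng, cfg.nonsyn_fraction),
    }


# ---------------------------------------------------------------------------
# map, variants, counts


def _gene_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign genes to linkage groups and cM, with an SDR block on LG1."""
    n_sdr = int(round(cfg.n_genes * cfg.sdr_gene_fraction))
    n_rest = cfg.n_genes - n_sdr
    lgs = np.concatenate([np.ones(n_sdr, dtype=int), 1 + np.arange(n_rest) % cfg.n_lgs])
    lo, hi = cfg.sdr_span
    cms = np.empty(cfg.n_genes)
    cms[:n_sdr] = rng.uniform(lo, hi, size=n_sdr)
    for k in range(n_sdr, cfg.n_genes):
        if lgs[k] == 1:
            # PAR transcripts: outside the sex-linked span
            while True:
                c = rng.uniform(0.0, 100.0)
                if not (lo <= c <= hi):
                    break
            cms[k] = c
        else:
            cms[k] = rng.uniform(0.0, 100.0)
    region = np.where(
        (lgs == 1) & (cms >= lo) & (cms <= hi), "sex_linked", np.where(lgs == 1, "PAR", "autosomal")
    )
    df = pd.DataFrame(
        {
            "gene": [f"g{i:04d}" for i in range(cfg.n_genes)],
            "lg": lgs,
            "cM": cms,
            "region_class": region,
        }
    )
    return df.sort_values(["lg", "cM"], kind="mergesort").reset_index(drop=True)


def _depths_from_genotypes(
    gt: np.ndarray, mean_depth: float, rng: np.random.Generator, err: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Allele depths consistent with true genotypes (Poisson total depth)."""
    total = rng.poisson(mean_depth, size=gt.shape)
    frac = np.where(gt == GT_HET, 0.5, np.where(gt == GT_HOM_ALT, 1.0 - err, err))
    alt = rng.binomial(total, frac)
    return total - alt, alt


def simulate_variants(
    truth_tr: pd.DataFrame,
    sequences: dict[str, str],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> VariantTable:
    """Biallelic genotype data for the sexed individuals.

    Neutral sites get allele frequencies drawn from the same distribution
    in both sexes (Hardy-Weinberg genotypes); transcripts of the
    sex-linked block on subgenome 1 additionally receive planted
    Y-specific sites via :func:`plant_sex_linked_variants`.
    """
    n_samples = cfg.n_males + cfg.n_females
    recs = []
    gts = []
    sdr_site_idx = []
    canonical = truth_tr[~truth_tr["is_isoform"]]
    for row in canonical.itertuples():
        seq = sequences[row.transcript]
        length = len(seq)
        rate = cfg.sites_per_kb / 1000.0
        if row.subgenome == "sub1":
            rate *= cfg.diversity_ratio_sub1
        n_sites = rng.poisson(length * rate)
        n_sdr = 0
        if row.region_class == "sex_linked" and row.subgenome == "sub1":
            n_sdr = max(int(rng.poisson(length * cfg.sdr_sites_per_kb / 1000.0)), 2)
        n_total = n_sites + n_sdr
        if n_total == 0:
            continue
        pos = rng.choice(length, size=min(n_total, length), replace=False) + 1
        pos.sort()
        is_sdr = np.zeros(len(pos), dtype=bool)
        if n_sdr > 0:
            is_sdr[rng.choice(len(pos), size=min(n_sdr, len(pos)), replace=False)] = True
        for p, sdr_flag in zip(pos, is_sdr):
            ref = seq[p - 1]
            alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(3))) % 4] if ref in BASES else "A"
            qual = max(float(rng.normal(40.0, 8.0)), 0.0)
            freq = rng.uniform(0.05, 0.95)
            g = rng.binomial(2, freq, size=n_samples).astype(np.int8)
            recs.append((row.transcript, int(p), ref, alt, qual, bool(sdr_flag)))
            gts.append(g)
            if sdr_flag:
                sdr_site_idx.append(len(recs) - 1)
    sites = pd.DataFrame(recs, columns=["transcript", "pos", "ref", "alt", "qual", "sex_linked"])
    gt = np.array(gts, dtype=np.int8).reshape(len(sites), n_samples)
    ref_d, alt_d = _depths_from_genotypes(gt, cfg.mean_depth, rng)
    vt = VariantTable(
        samples=cfg.samples,
        sex=cfg.sexes,
        sites=sites,
        ref_depth=ref_d,
        alt_depth=alt_d,
        genotypes=gt,
        assayable={r.transcript: len(sequences[r.transcript]) for r in canonical.itertuples()},
    )
    if sdr_site_idx:
        vt = plant_sex_linked_variants(vt, np.array(sdr_site_idx), mode=cfg.sdr_mode, rng=rng, mean_depth=cfg.mean_depth)
    return vt


def plant_sex_linked_variants(
    vt: VariantTable,
    site_indices: Optional[np.ndarray] = None,
    linkage: Optional[pd.DataFrame] = None,
    span: Optional[tuple[float, float]] = None,
    lg: int = 1,
    mode: str = "partial",
    rng: np.random.Generator | int | None = None,
    mean_depth: float = 30.0,
) -> VariantTable:
    """Plant Y-specific alleles at selected sites.

    In ``partial`` mode all males become heterozygous (X carries the
    reference, Y a derived allele) and all females homozygous reference —
    the signature of a young, little-differentiated XY region with no
    heterozygosity deficit in males.  ``fixed`` mode makes males
    homozygous alternate (a fixed X-Y difference, per-site FST of 1).

    Sites may be given directly (``site_indices``) or located through a
    linkage map and a cM ``span`` on linkage group ``lg``; a span that
    matches no mapped transcript is an error.  Depths at planted sites are
    regenerated to stay consistent with the planted genotypes.
    """
    if mode not in ("partial", "fixed"):
        raise ValueError("mode must be 'partial' or 'fixed'")
    if site_indices is None:
        if linkage is None or span is None:
            raise ValueError("provide site_indices or a linkage map with a span")
        lo, hi = span
        sel = linkage[(linkage["lg"] == lg) & (linkage["cM"] >= lo) & (linkage["cM"] <= hi)]
        if sel.empty:
            raise ValueError(f"no transcripts on LG{lg} within {span}")
        wanted = set(sel["transcript_id" if "transcript_id" in sel else "transcript"])
        site_indices = np.flatnonzero(vt.sites["transcript"].isin(wanted).to_numpy())
        if site_indices.size == 0:
            raise ValueError("selected region has no variant sites")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    gt = vt.genotypes.copy() if vt.genotypes is not None else np.zeros((vt.n_sites, len(vt.samples)), dtype=np.int8)
    males = vt.male_mask
    male_code = GT_HET if mode == "partial" else GT_HOM_ALT
    gt[np.ix_(site_indices, np.flatnonzero(males))] = male_code
    gt[np.ix_(site_indices, np.flatnonzero(~males))] = GT_HOM_REF
    ref_d = vt.ref_depth.copy()
    alt_d = vt.alt_depth.copy()
    sub_ref, sub_alt = _depths_from_genotypes(gt[site_indices], mean_depth, rng)
    ref_d[site_indices] = sub_ref
    alt_d[site_indices] = sub_alt
    sites = vt.sites.copy()
    if "sex_linked" not in sites:
        sites["sex_linked"] = False
    sites.iloc[site_indices, sites.columns.get_loc("sex_linked")] = True
    return replace(vt, sites=sites, ref_depth=ref_d, alt_depth=alt_d, genotypes=gt)


def simulate_counts(truth: TruthTable, cfg: SimConfig, rng: np.random.Generator | int | None = None) -> ExpressionMatrix:
    """Negative-binomial expression counts with planted effects.

    Per-transcript baseline means are log-normal; planted sex-biased
    transcripts differ between sexes by ``sexbias_log2`` in expectation,
    and subfunctionalized pairs swap homeolog bias between the sexes
    (ratio difference 2 x ``subfunc_log2``).  Counts are NB with
    dispersion ``nb_dispersion`` (Poisson in the zero-dispersion limit).
    """
    if cfg.nb_dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    tr = truth.transcripts[~truth.transcripts["is_isoform"]].reset_index(drop=True)
    n_t = len(tr)
    n_samples = cfg.n_males + cfg.n_females
    sex = np.array(cfg.sexes)
    base_gene = dict(zip(truth.pairs["gene"], np.exp(rng.normal(5.5, 1.0, size=len(truth.pairs)))))
    base = np.array([base_gene[g] for g in tr["gene"]])
    mu = np.tile(base[:, None], (1, n_samples))

    male_cols = sex == "M"
    sb = tr["sex_bias_log2"].to_numpy(dtype=float)
    mu[:, male_cols] *= 2.0 ** (sb[:, None] / 2.0)
    mu[:, ~male_cols] *= 2.0 ** (-sb[:, None] / 2.0)

    subfunc_pairs = truth.pairs[truth.pairs["subfunc"]]
    tidx = {t: i for i, t in enumerate(tr["transcript"])}
    half = cfg.subfunc_log2 / 2.0
    for rec in subfunc_pairs.itertuples():
        i1, i2 = tidx.get(rec.sub1), tidx.get(rec.sub2)
        if i1 is None or i2 is None:
            continue
        mu[i1, male_cols] *= 2.0**half
        mu[i2, male_cols] *= 2.0**-half
        mu[i1, ~male_cols] *= 2.0**-half
        mu[i2, ~male_cols] *= 2.0**half

    if cfg.nb_dispersion < 1e-6:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(shape, shape / (shape + mu))
    frame = pd.DataFrame(counts, index=tr["transcript"].to_numpy(), columns=cfg.samples)
    lengths = pd.Series(tr["length"].to_numpy(), index=frame.index, name="length")
    return ExpressionMatrix(counts=frame, lengths=lengths, sex=list(cfg.sexes))


# ---------------------------------------------------------------------------
# full dataset


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate the complete synthetic dataset for one configuration."""
    root_ss = np.random.SeedSequence(cfg.seed)
    rng_seq, rng_map, rng_var, rng_cnt, rng_iso = (np.random.default_rng(s) for s in root_ss.spawn(5))

    gene_map = _gene_map(cfg, rng_map)
    n_single = int(round(cfg.n_genes * cfg.single_copy_fraction))
    single_genes = set(gene_map["gene"].iloc[:: max(cfg.n_genes // n_single, 1)][:n_single]) if n_single else set()

    poly: list[Transcript] = []
    prog: list[Transcript] = []
    outg: list[Transcript] = []
    tr_rows = []
    pair_rows = []
    sequences: dict[str, str] = {}
    sexbias_draw = rng_cnt.random(cfg.n_genes * 2)
    sb_signs = rng_cnt.choice([-1.0, 1.0], size=cfg.n_genes * 2)
    subfunc_draw = rng_cnt.random(cfg.n_genes)

    for k, row in enumerate(gene_map.itertuples()):
        n_codons = int(rng_seq.integers(cfg.min_codons, cfg.max_codons + 1))
        fam = _evolve_gene_family(n_codons, cfg, rng_seq)
        g = row.gene
        ids = {"sub1": f"{g}_s1", "sub2": f"{g}_s2", "prog": f"{g}_prog", "out": f"{g}_out"}
        single = g in single_genes
        subfunc = (subfunc_draw[k] < cfg.subfunc_fraction) and not single
        prog.append(Transcript(ids["prog"], fam["prog"]))
        outg.append(Transcript(ids["out"], fam["outgroup"]))
        members = ["sub1"] if single else ["sub1", "sub2"]
        for m_i, sub in enumerate(members):
            tid = ids[sub]
            poly.append(Transcript(tid, fam[sub]))
            sequences[tid] = fam[sub]
            biased = sexbias_draw[2 * k + m_i] < cfg.sexbias_fraction and not subfunc
            tr_rows.append(
                {
                    "transcript": tid,
                    "gene": g,
                    "subgenome": sub,
                    "lg": row.lg,
                    "cM": row.cM,
                    "region_class": row.region_class if sub == "sub1" else ("autosomal" if row.lg != 1 else row.region_class),
                    "length": len(fam[sub]),
                    "is_isoform": False,
                    "sex_bias_log2": sb_signs[2 * k + m_i] * cfg.sexbias_log2 if biased else 0.0,
                }
            )
        sequences[ids["prog"]] = fam["prog"]
        pair_rows.append(
            {
                "gene": g,
                "sub1": ids["sub1"],
                "sub2": ids["sub2"] if not single else "",
                "prog": ids["prog"],
                "outgroup": ids["out"],
                "lg": row.lg,
                "cM": row.cM,
                "region_class": row.region_class,
                "subfunc": subfunc,
                "single_copy": single,
            }
        )

    # isoform redundancy: truncated duplicates of a random subset
    iso_rows = []
    for t in list(poly):
        if rng_iso.random() < cfg.isoform_redundancy_rate:
            frac = rng_iso.uniform(0.6, 0.95)
            cut = max(int(len(t.sequence) * frac) // 3 * 3, 150)
            iso = Transcript(f"{t.id}_iso", t.sequence[:cut])
            poly.append(iso)
            iso_rows.append(
                {
                    "transcript": iso.id,
                    "gene": t.id.rsplit("_", 1)[0],
                    "subgenome": "isoform",
                    "lg": 0,
                    "cM": np.nan,
                    "region_class": "none",
                    "length": cut,
                    "is_isoform": True,
                    "sex_bias_log2": 0.0,
                }
            )

    truth = TruthTable(
        transcripts=pd.DataFrame(tr_rows + iso_rows),
        pairs=pd.DataFrame(pair_rows),
    )
    variants = simulate_variants(truth.transcripts, sequences, cfg, rng_var)
    expression = simulate_counts(truth, cfg, rng_cnt)

    canonical = truth.transcripts[~truth.transcripts["is_isoform"]]
    linkage = pd.DataFrame(
        {
            "transcript_id": canonical["transcript"],
            "lg": canonical["lg"],
            "cM": canonical["cM"],
            "region_class": canonical["region_class"],
        }
    ).reset_index(drop=True)

    return SyntheticDataset(
        config=cfg,
        poly=sorted(poly, key=lambda t: t.id),
        prog=sorted(prog, key=lambda t: t.id),
        outgroup=sorted(outg, key=lambda t: t.id),
        variants=variants,
        linkage=linkage,
        expression=expression,
        truth=truth,
    )


def simulate_progenitor_mapped_variants(
    ds: SyntheticDataset,
    rng: np.random.Generator | int | None = None,
) -> VariantTable:
    """Variant table emulating polyploid reads mapped onto the progenitor.

    Both homeologs of a gene map to the same progenitor ortholog, so
    homeolog-divergent positions appear heterozygous within every
    individual; genes with a lost homeolog show only ordinary allelic
    polymorphism and land in the low-heterozygosity (single-copy) tail of
    the fractionation screen.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    cfg = ds.config
    n_samples = cfg.n_males + cfg.n_females
    seq_of = {t.id: t.sequence for t in ds.poly}
    recs, gts = [], []
    assayable = {}
    for rec in ds.truth.pairs.itertuples():
        prog_id = rec.prog
        s1 = seq_of[rec.sub1]
        assayable[prog_id] = len(s1)
        if not rec.single_copy and rec.sub2:
            s2 = seq_of[rec.sub2]
            div_pos = [i + 1 for i in range(min(len(s1), len(s2))) if s1[i] != s2[i]]
        else:
            div_pos = []
        n_poly = rng.poisson(len(s1) * cfg.sites_per_kb / 1000.0 * 0.5)
        poly_pos = list(rng.choice(len(s1), size=min(n_poly, len(s1)), replace=False) + 1)
        for p in sorted(set(div_pos)):
            qual = max(float(rng.normal(40.0, 8.0)), 0.0)
            recs.append((prog_id, int(p), s1[p - 1], "A" if s1[p - 1] != "A" else "C", qual, False))
            gts.append(np.full(n_samples, GT_HET, dtype=np.int8))
        for p in sorted(set(poly_pos) - set(div_pos)):
            qual = max(float(rng.normal(40.0, 8.0)), 0.0)
            freq = rng.uniform(0.05, 0.95)
            recs.append((prog_id, int(p), s1[p - 1], "A" if s1[p - 1] != "A" else "C", qual, False))
            gts.append(rng.binomial(2, freq, size=n_samples).astype(np.int8))
    sites = pd.DataFrame(recs, columns=["transcript", "pos", "ref", "alt", "qual", "sex_linked"])
    gt = np.array(gts, dtype=np.int8).reshape(len(sites), n_samples)
    ref_d, alt_d = _depths_from_genotypes(gt, cfg.mean_depth, rng)
    return VariantTable(
        samples=cfg.samples,
        sex=cfg.sexes,
        sites=sites,
        ref_depth=ref_d,
        alt_depth=alt_d,
        genotypes=gt,
        assayable=assayable,
    )
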