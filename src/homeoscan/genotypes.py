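"""Genotype calling from allele depths and per-transcript heterozygosity.

RNA-seq genotyping here follows a hard-threshold scheme: a biallelic site
is kept only when every individual is covered by at least ``min_depth``
reads and the site quality exceeds ``min_qual``; per individual, the
variant allele frequency f = alt/(ref+alt) calls the genotype
(f < 0.15 hom_ref, f > 0.85 hom_alt, otherwise het).

Within-individual heterozygosity (SNP density) is the number of
heterozygous genotyped sites over the assayable sites of the transcript;
transcripts whose mean heterozygosity falls below 0.01 are candidate
single-copy genes (one homeolog lost or silenced), the fractionation
screen used when polyploid reads are mapped onto the progenitor
transcriptome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1

#: default genotype-calling thresholds
MIN_DEPTH = 10
MIN_QUAL = 20.0
HET_BAND = (0.15, 0.85)
SINGLE_COPY_HET = 0.01


@dataclass
class VariantTable:
    """Per-site biallelic data for sexed individuals on transcript coordinates.

    ``sites`` has one row per site with columns ``transcript``, ``pos``
    (1-based), ``ref``, ``alt``, ``qual`` and optionally ``sex_linked``
    (generator truth).  Depth matrices are ``(n_sites, n_samples)``.
    ``genotypes`` is filled by :func:`call_genotypes` (codes above).
    ``assayable`` maps transcript -> number of assayable positions used as
    the heterozygosity denominator (defaults to transcript length).
    """

    samples: list[str]
    sex: list[str]
    sites: pd.DataFrame
    ref_depth: np.ndarray
    alt_depth: np.ndarray
    genotypes: Optional[np.ndarray] = None
    assayable: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.sex):
            raise ValueError("samples and sex labels differ in length")
        n = len(self.sites)
        for mat in (self.ref_depth, self.alt_depth):
            if mat.shape != (n, len(self.samples)):
                raise ValueError("depth matrix shape mismatch")
        if not set(self.sex) <= {"M", "F"}:
            raise ValueError("sex labels must be 'M' or 'F'")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def male_mask(self) -> np.ndarray:
        return np.array([s == "M" for s in self.sex])

    def site_indices(self, transcript: str) -> np.ndarray:
        return np.flatnonzero((self.sites["transcript"] == transcript).to_numpy())

    def transcripts(self) -> list[str]:
        return list(dict.fromkeys(self.sites["transcript"]))

    # -- VCF round trip -----------------------------------------------------

    def to_vcf(self, path: str) -> None:
        """Write a minimal VCF v4.2 with GT, AD and DP fields."""
        gt = self.genotypes
        gt_str = {GT_HOM_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1", GT_MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
            for t, n in self.assayable.items():
                fh.write(f"##contig=<ID={t},length={n}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(self.samples) + "\n")
            for i, row in enumerate(self.sites.itertuples()):
                fields = []
                for j in range(len(self.samples)):
                    g = gt_str[int(gt[i, j])] if gt is not None else "./."
                    rd, ad = int(self.ref_depth[i, j]), int(self.alt_depth[i, j])
                    fields.append(f"{g}:{rd},{ad}:{rd + ad}")
                fh.write(
                    f"{row.transcript}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                    f"{row.qual:.1f}\t.\t.\tGT:AD:DP\t" + "\t".join(fields) + "\n"
                )

    @classmethod
    def from_vcf(cls, path: str, sex_of: dict[str, str], assayable: Optional[dict[str, int]] = None) -> "VariantTable":
        """Load a VCF (GT + AD) produced by :meth:`to_vcf` or an upstream caller."""
        from cyvcf2 import VCF

        vcf = VCF(path)
        samples = list(vcf.samples)
        rows = []
        refd, altd, gts = [], [], []
        contig_len = {}
        for line in vcf.raw_header.splitlines():
            if line.startswith("##contig"):
                parts = dict(p.split("=") for p in line[len("##contig=<") : -1].split(","))
                contig_len[parts["ID"]] = int(parts["length"])
        for v in vcf:
            if len(v.ALT) != 1:
                continue
            rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], v.QUAL if v.QUAL is not None else 0.0))
            ad = v.format("AD")
            refd.append(ad[:, 0])
            altd.append(ad[:, 1])
            code = np.full(len(samples), GT_MISSING, dtype=np.int8)
            types = v.gt_types  # 0 hom_ref, 1 het, 2 unknown, 3 hom_alt
            code[types == 0] = GT_HOM_REF
            code[types == 1] = GT_HET
            code[types == 3] = GT_HOM_ALT
            gts.append(code)
        sites = pd.DataFrame(rows, columns=["transcript", "pos", "ref", "alt", "qual"])
        n = len(sites)
        return cls(
            samples=samples,
            sex=[sex_of[s] for s in samples],
            sites=sites,
            ref_depth=np.array(refd, dtype=int).reshape(n, len(samples)),
            alt_depth=np.array(altd, dtype=int).reshape(n, len(samples)),
            genotypes=np.array(gts, dtype=np.int8).reshape(n, len(samples)) if gts else None,
            assayable=assayable or contig_len,
        )


def call_genotypes(
    vt: VariantTable,
    min_depth: int = MIN_DEPTH,
    min_qual: float = MIN_QUAL,
    het_band: tuple[float, float] = HET_BAND,
) -> VariantTable:
    """Call genotypes from allele depths with hard thresholds.

    A site is retained only when its quality exceeds ``min_qual`` and every
    individual has total depth >= ``min_depth``; dropped sites are removed
    from the table.  Calls are a pure function of depths and thresholds, so
    re-calling is idempotent.
    """
    total = vt.ref_depth + vt.alt_depth
    keep = (vt.sites["qual"].to_numpy() > min_qual) & (total >= min_depth).all(axis=1)
    idx = np.flatnonzero(keep)
    ref = vt.ref_depth[idx]
    alt = vt.alt_depth[idx]
    tot = ref + alt
    if np.any(tot == 0):
        raise RuntimeError("retained site with zero depth: filter violated")
    f = alt / tot
    lo, hi = het_band
    gt = np.full(f.shape, GT_HET, dtype=np.int8)
    gt[f < lo] = GT_HOM_REF
    gt[f > hi] = GT_HOM_ALT
    return replace(
        vt,
        sites=vt.sites.iloc[idx].reset_index(drop=True),
        ref_depth=ref,
        alt_depth=alt,
        genotypes=gt,
    )


def heterozygosity_profile(vt: VariantTable, transcripts: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Per-transcript heterozygosity and the single-copy (fractionation) screen.

    Returns one row per transcript with the per-individual mean
    heterozygosity (het sites / assayable sites, missing genotypes excluded
    from both counts), a divergence proxy (mean per-individual density of
    non-reference genotypes — the SNP density relative to the mapping
    reference), and ``single_copy`` = mean heterozygosity < 0.01.
    Transcripts without assayable sites are excluded.
    """
    if vt.genotypes is None:
        raise ValueError("genotypes not called; run call_genotypes first")
    tr_list = list(transcripts) if transcripts is not None else vt.transcripts()
    gt = vt.genotypes
    tcol = vt.sites["transcript"].to_numpy()
    out = []
    for t in tr_list:
        idx = np.flatnonzero(tcol == t)
        n_assay = vt.assayable.get(t, 0)
        if n_assay <= 0:
            continue
        sub = gt[idx]  # (sites, samples); may be empty
        n_missing = (sub == GT_MISSING).sum(axis=0)
        denom = np.maximum(n_assay - n_missing, 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            het = np.where(denom > 0, (sub == GT_HET).sum(axis=0) / denom, np.nan)
            nonref = np.where(
                denom > 0,
                ((sub == GT_HET) | (sub == GT_HOM_ALT)).sum(axis=0) / denom,
                np.nan,
            )
        mean_het = float(np.nanmean(het)) if np.any(denom > 0) else np.nan
        if np.isnan(mean_het):
            continue
        out.append(
            {
                "transcript": t,
                "mean_het": mean_het,
                "divergence_proxy": float(np.nanmean(nonref)),
                "single_copy": mean_het < SINGLE_COPY_HET,
                "n_sites": len(idx),
            }
        )
    return pd.DataFrame(out, columns=["transcript", "mean_het", "divergence_proxy", "single_copy", "n_sites"])


def per_individual_heterozygosity(vt: VariantTable, transcript: str) -> np.ndarray:
    """Heterozygosity of one transcript for each individual (NaN if no denominator)."""
    if vt.genotypes is None:
        raise ValueError("genotypes not called")
    idx = vt.site_indices(transcript)
    n_assay = vt.assayable.get(transcript, 0)
    sub = vt.genotypes[idx]
    denom = np.maximum(n_assay - (sub == GT_MISSING).sum(axis=0), 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (sub == GT_HET).sum(axis=0) / denom, np.nan)
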