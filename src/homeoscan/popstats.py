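"""Per-transcript diversity and selection statistics and the paired
subgenome contrast.

Nucleotide diversity pi is the mean pairwise difference per assayable
site among the 2N sampled chromosomes (unphased genotypes enter through
allele counts, which is sufficient for pi and Tajima's D).  piN and piS
restrict both numerator and denominator to NG86 nonsynonymous and
synonymous sites of the transcript's reading frame, so piN/piS gauges
purifying selection.  Tajima's D contrasts pi with Watterson's estimator
using the Tajima (1989) constants.  The two subgenomes are compared by an
exact paired Wilcoxon signed-rank test on per-linkage-group means, which
removes the effect of linkage: with 8 linkage groups all deviating in the
same direction the two-sided p is 2/2^8 = 0.007813.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .codonevol import STOP_CODONS, synonymous_sites, translate_codon
from .genotypes import GT_MISSING, VariantTable


@dataclass
class DiversityResult:
    """Diversity and selection summaries for one transcript."""

    transcript: str
    pi: float
    pi_n: Optional[float]
    pi_s: Optional[float]
    pin_pis: Optional[float]
    tajimas_d: Optional[float]
    n_segregating: int
    n_chromosomes: int


def _site_pi(alt_count: int, n_chrom: int) -> float:
    """Mean pairwise difference contributed by one biallelic site."""
    if n_chrom < 2:
        return 0.0
    p = alt_count
    q = n_chrom - alt_count
    return 2.0 * p * q / (n_chrom * (n_chrom - 1.0))


def classify_site(seq: str, pos: int, alt: str) -> Optional[str]:
    """'synonymous' or 'nonsynonymous' for a substitution at 1-based CDS position."""
    ci = (pos - 1) // 3
    off = (pos - 1) % 3
    codon = seq[3 * ci : 3 * ci + 3].upper()
    if len(codon) < 3 or codon in STOP_CODONS:
        return None
    alt_codon = codon[:off] + alt.upper() + codon[off + 1 :]
    if alt_codon in STOP_CODONS:
        return "nonsynonymous"
    return "synonymous" if translate_codon(alt_codon) == translate_codon(codon) else "nonsynonymous"


def diversity_stats(
    vt: VariantTable,
    transcript: str,
    cds: Optional[str] = None,
) -> Optional[DiversityResult]:
    """pi family and Tajima's D for one transcript.

    ``cds`` (the in-frame coding sequence) enables piN/piS via NG86 site
    classification; without it only pi and D are reported.  Returns None
    when the transcript has no assayable sites.
    """
    if vt.genotypes is None:
        raise ValueError("genotypes not called")
    n_assay = vt.assayable.get(transcript, 0)
    if n_assay <= 0:
        return None
    idx = vt.site_indices(transcript)
    gt = vt.genotypes[idx]
    sites = vt.sites.iloc[idx]

    pi_total = 0.0
    pi_syn = 0.0
    pi_non = 0.0
    n_seg = 0
    n_chrom_list = []
    for k in range(len(idx)):
        g = gt[k]
        g = g[g != GT_MISSING]
        n_chrom = 2 * g.size
        if n_chrom < 2:
            continue
        alt_count = int(np.sum(g))
        contrib = _site_pi(alt_count, n_chrom)
        pi_total += contrib
        n_chrom_list.append(n_chrom)
        if 0 < alt_count < n_chrom:
            n_seg += 1
        if cds is not None and contrib > 0:
            cls = classify_site(cds, int(sites.iloc[k]["pos"]), sites.iloc[k]["alt"])
            if cls == "synonymous":
                pi_syn += contrib
            elif cls == "nonsynonymous":
                pi_non += contrib

    pi = pi_total / n_assay
    pi_n = pi_s = pin_pis = None
    if cds is not None and len(cds) >= 3:
        n_codons = len(cds) // 3
        codons = [cds[3 * i : 3 * i + 3].upper() for i in range(n_codons)]
        s_sites = sum(synonymous_sites(c) for c in codons if c not in STOP_CODONS and "N" not in c)
        n_sites = 3.0 * sum(1 for c in codons if c not in STOP_CODONS and "N" not in c) - s_sites
        if s_sites > 0:
            pi_s = pi_syn / s_sites
        if n_sites > 0:
            pi_n = pi_non / n_sites
        if pi_s is not None and pi_n is not None and pi_s > 0:
            pin_pis = pi_n / pi_s

    n_chrom = int(np.median(n_chrom_list)) if n_chrom_list else 2 * len(vt.samples)
    d = tajimas_d(n_seg, n_chrom, pi_total) if n_seg >= 1 and n_chrom >= 4 else None
    return DiversityResult(
        transcript=transcript,
        pi=pi,
        pi_n=pi_n,
        pi_s=pi_s,
        pin_pis=pin_pis,
        tajimas_d=d,
        n_segregating=n_seg,
        n_chromosomes=n_chrom,
    )


def tajimas_d(S: int, n: int, pi_total: float) -> Optional[float]:
    """Tajima's D from segregating sites, sample size and total mean pairwise
    differences, using the Tajima (1989) constants.

    Undefined (None) when S = 0 or n < 4.
    """
    if S < 1 or n < 4:
        return None
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return None
    return (pi_total - S / a1) / float(np.sqrt(var))


def exact_paired_signrank(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Exact two-sided Wilcoxon signed-rank p for paired samples (n <= 20).

    The null distribution of the positive-rank sum W+ is built over all
    2^n sign assignments (via the equivalent rank-sum convolution, exact
    with average ranks for tied |differences|);
    p = min(1, 2 min(P(W+ <= w), P(W+ >= w))).  Zero differences are
    dropped with a warning; all-zero input returns None.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    nz = d != 0
    if not np.any(nz):
        return None
    if not np.all(nz):
        warnings.warn(f"dropping {int(np.sum(~nz))} zero differences", stacklevel=2)
        d = d[nz]
    n = d.size
    if n > 20:
        raise ValueError("exact enumeration limited to n <= 20 pairs")
    order = np.argsort(np.abs(d), kind="mergesort")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    # average ranks for ties in |d|
    absd = np.abs(d)
    for v in np.unique(absd):
        m = absd == v
        ranks[m] = ranks[m].mean()
    w_obs = float(np.sum(ranks[d > 0]))
    # distribution of W+ over sign assignments; doubled ranks are integers
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= 2.0**n
    w2 = int(round(w_obs * 2))
    p_le = float(dist[: w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def per_lg_means(values: pd.DataFrame, value_col: str, lg_col: str = "lg") -> pd.Series:
    """Mean of a per-transcript statistic within each linkage group."""
    return values.groupby(lg_col)[value_col].mean()
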