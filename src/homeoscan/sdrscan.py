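"""Sex-determining-region scan: male-female FST, sex-biased heterozygosity,
rolling windows along linkage groups, and a bootstrap autosomal null.

In a young XY system, X-Y differentiation makes males look like a
partially differentiated "population" relative to females at sex-linked
sites: allele-frequency differentiation (Weir-Cockerham FST between the
sexes) and male-excess heterozygosity (positive log10 male:female
heterozygosity, SBH) both rise inside the non-recombining region, while
autosomes and the pseudoautosomal region stay near zero.  The scan
computes both statistics per transcript, smooths them in sliding windows
of 20 transcripts along each linkage group, and flags windows exceeding
the 95% interval of rolling means resampled from contiguous autosomal
windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GT_HET, GT_HOM_ALT, GT_MISSING, VariantTable, per_individual_heterozygosity

WINDOW = 20
BOOT_REPS = 1000
SBH_EPS = 1e-4


def wc_fst_components(genotypes: np.ndarray, pop: np.ndarray) -> tuple[float, float, float]:
    """Weir-Cockerham (1984) variance components (a, b, c) for one site.

    ``genotypes`` holds diploid codes (0 hom_ref / 1 het / 2 hom_alt /
    -1 missing) and ``pop`` a boolean partition into two populations
    (here: males vs females).  Returns the among-population (a),
    among-individual (b) and within-individual (c) components for the
    alternate allele.  Monomorphic or single-population sites yield
    (0, 0, 0) or components that sum to zero and should be skipped by the
    caller.
    """
    comps = []
    for mask in (pop, ~pop):
        g = genotypes[mask]
        g = g[g != GT_MISSING]
        if g.size == 0:
            return (np.nan, np.nan, np.nan)
        n_i = g.size
        p_i = float(np.mean(g)) / 2.0
        h_i = float(np.mean(g == GT_HET))
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    n_bar = (n1 + n2) / r
    if n_bar <= 1:
        return (np.nan, np.nan, np.nan)
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1.0)) * (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
    )
    c = h_bar / 2.0
    return (a, b, c)


def transcript_fst(vt: VariantTable, transcript: str) -> Optional[float]:
    """Male-female FST of one transcript as a ratio of sums over sites.

    Per-site components are summed and FST = sum(a) / sum(a+b+c); sites
    with zero total variance are skipped.  Negative values are retained so
    the autosomal null stays unbiased.  Returns None when no usable site
    remains.
    """
    if vt.genotypes is None:
        raise ValueError("genotypes not called")
    idx = vt.site_indices(transcript)
    if idx.size == 0:
        return None
    males = vt.male_mask
    num = den = 0.0
    used = 0
    for i in idx:
        a, b, c = wc_fst_components(vt.genotypes[i], males)
        if not np.isfinite(a) or a + b + c == 0.0:
            continue
        num += a
        den += a + b + c
        used += 1
    if used == 0 or den == 0.0:
        return None
    return num / den


def sex_biased_heterozygosity(vt: VariantTable, transcript: str, eps: float = SBH_EPS) -> Optional[float]:
    """log10 of (mean male heterozygosity / mean female heterozygosity).

    A pseudocount ``eps`` keeps the ratio finite when one sex has no
    heterozygous sites.  Returns None when neither sex mean is computable.
    """
    het = per_individual_heterozygosity(vt, transcript)
    males = vt.male_mask
    with np.errstate(invalid="ignore"):
        mh = np.nanmean(het[males])
        fh = np.nanmean(het[~males])
    if np.isnan(mh) or np.isnan(fh):
        return None
    return float(np.log10((mh + eps) / (fh + eps)))


@dataclass
class ScanSeries:
    """Rolling-window scan of one statistic along linkage groups.

    ``windows`` holds one row per window (lg, cM of window start/end,
    rolling mean, flag); ``ci`` is the (lo, hi) bootstrap interval from
    contiguous autosomal windows.
    """

    windows: pd.DataFrame
    ci: tuple[float, float]
    null_means: np.ndarray


def _contiguous_window_means(values_by_lg: Sequence[np.ndarray], window: int) -> list[tuple[int, int]]:
    """All (lg index, start) positions admitting a full window."""
    runs = []
    for k, vals in enumerate(values_by_lg):
        for s in range(0, len(vals) - window + 1):
            runs.append((k, s))
    return runs


def rolling_scan_with_ci(
    series: pd.DataFrame,
    autosomal: pd.DataFrame,
    window: int = WINDOW,
    reps: int = BOOT_REPS,
    seed: Optional[int] = None,
    value_col: str = "value",
) -> ScanSeries:
    """Rolling means along linkage groups with a bootstrap autosomal null.

    ``series`` and ``autosomal`` need columns ``lg``, ``cM`` and
    ``value_col``; rows are sorted by (lg, cM) internally.  The null
    distribution is built from ``reps`` means of ``window`` *consecutive*
    autosomal transcripts, with start positions sampled uniformly over all
    admissible runs pooled across autosomal linkage groups; the 95% CI is
    its 2.5th/97.5th percentiles.  Windows whose mean exceeds the upper
    bound are flagged ``elevated``.
    """
    rng = np.random.default_rng(seed)
    auto = autosomal.dropna(subset=[value_col]).sort_values(["lg", "cM"], kind="mergesort")
    values_by_lg = [g[value_col].to_numpy() for _, g in auto.groupby("lg")]
    runs = _contiguous_window_means(values_by_lg, window)
    if not runs:
        raise ValueError(f"need at least {window} consecutive autosomal transcripts")
    picks = rng.integers(0, len(runs), size=reps)
    null_means = np.array(
        [values_by_lg[runs[i][0]][runs[i][1] : runs[i][1] + window].mean() for i in picks]
    )
    lo, hi = np.percentile(null_means, [2.5, 97.5])

    rows = []
    srt = series.dropna(subset=[value_col]).sort_values(["lg", "cM"], kind="mergesort")
    for lg, g in srt.groupby("lg"):
        vals = g[value_col].to_numpy()
        cm = g["cM"].to_numpy()
        tids = g["transcript"].to_numpy() if "transcript" in g else np.array([None] * len(g))
        if len(vals) < window:
            continue
        means = np.convolve(vals, np.ones(window) / window, mode="valid")
        # tolerance so a degenerate (constant) null never flags by rounding
        flag_tol = 1e-12 * max(1.0, abs(hi))
        for s, m in enumerate(means):
            rows.append(
                {
                    "lg": lg,
                    "start_cM": cm[s],
                    "end_cM": cm[s + window - 1],
                    "start_transcript": tids[s],
                    "rolling_mean": m,
                    "lo": lo,
                    "hi": hi,
                    "elevated": m > hi + flag_tol,
                }
            )
    cols = ["lg", "start_cM", "end_cM", "start_transcript", "rolling_mean", "lo", "hi", "elevated"]
    return ScanSeries(windows=pd.DataFrame(rows, columns=cols), ci=(float(lo), float(hi)), null_means=null_means)


def region_compare(values: pd.DataFrame, value_col: str = "value", group_col: str = "region_class") -> pd.DataFrame:
    """Two-sided rank-sum tests between region classes (sex-linked / PAR / autosomal).

    Returns one row per non-empty pair of classes with the Mann-Whitney U
    and its two-sided p (exact when both groups have n <= 25 and no ties,
    normal approximation with tie correction otherwise).
    """
    groups = {
        k: g[value_col].dropna().to_numpy() for k, g in values.groupby(group_col) if len(g[value_col].dropna())
    }
    names = sorted(groups)
    rows = []
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            x, y = groups[gi], groups[gj]
            pooled = np.concatenate([x, y])
            exact = len(x) <= 25 and len(y) <= 25 and len(np.unique(pooled)) == len(pooled)
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact" if exact else "asymptotic")
            rows.append({"group1": gi, "group2": gj, "n1": len(x), "n2": len(y), "U": res.statistic, "p": res.pvalue})
    return pd.DataFrame(rows, columns=["group1", "group2", "n1", "n2", "U", "p"])
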