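# Methods

This note documents the models, estimators and design choices behind
homeoscan, and what the synthetic generator does and does not emulate.

## Silent-site divergence (NG86)

Divergence between coding sequences is estimated with the Nei–Gojobori
(1986) counting method. Synonymous site counts per codon come from
single-step mutation enumeration; mutations that would create a stop
codon are excluded from the per-position denominator, so S + N equals
3 × (compared codons) exactly. Codons differing at 2–3 positions are
scored by averaging synonymous/nonsynonymous difference counts over all
shortest mutational paths, excluding paths through stops (falling back to
all paths in the degenerate case where every path is blocked — this
cannot occur for one- or two-step differences between sense codons but
is defined for completeness). Proportions use sites averaged over the
two sequences, and rates are Jukes–Cantor corrected,
d = −(3/4) ln(1 − 4p/3); p ≥ 3/4 leaves the rate undefined and excludes
the pair from downstream dS summaries. Codon columns come from a
translation-guided global alignment (BLOSUM62 on the translated longest
ORFs, ≥ 50 codons required); gapped columns are excluded. The
implementation is verified against an independently written
path-enumeration oracle on every stop-free codon pair to 1e-9.

The NG86 + JC model was chosen because it is fully specifiable and
deterministic; maximum-likelihood codon models (rate variation, ts/tv
bias) are out of scope, so absolute dS values may differ slightly from
other calculators. All comparisons in the package are internal and
simulation-anchored.

## Homeolog identification

Local alignments use unit match/mismatch scoring with affine gaps
(match +1, mismatch −1, open −2, extend −1); the match score is
(matches − mismatches) and divergence is mismatches per aligned column.
Transcripts with score > 50 and divergence < 1% are joined; clusters are
connected components (single linkage — the natural closure of a pairwise
grouping rule, and the choice that collapses chains of overlapping
truncated isoforms), represented by the longest member with
lexicographic id tie-break. Pairing requires reciprocal best non-self
hits within the polyploid set and a shared best progenitor hit; hit
ranking breaks ties by higher score, then lower divergence, then id.
An exact shared 15-mer is required before aligning a pair; at the
divergences that can pass the thresholds (≪ 10%) the probability that
two related kilobase-scale transcripts share no exact 15-mer is
negligible, so the prefilter only prunes unrelated pairs. Only the
forward strand is compared — the generator is strand-consistent; real
data would need reverse-complement search.

## Quartet topology test

For each pair, the four-taxon tree of (member a, member b, progenitor,
outgroup) is decided by ordinary least squares on the six JC distances:
each of the three unrooted topologies has a 6×5 design over four pendant
branches and one internal branch, fitted with non-negativity (NNLS), and
the minimal-residual topology wins. A relative residual margin below
1e-9 (including exact ties, e.g. all-equal distances) is unresolved. On
exactly additive distances the correct topology has residual zero. This
replaces a likelihood tree search deliberately: with four taxa the
topology call is the only consumed output, and the OLS decision is
deterministic and oracle-checkable. An optional pipeline flag
(`quartet_filter=False`) keeps all pairs assignable by dS alone, the more
inclusive path.

## Genotyping and heterozygosity

Genotypes are a pure function of allele depths and thresholds: sites
need quality > 20 and ≥ 10 reads in every individual; per individual,
alt frequency < 0.15 is hom-ref, > 0.85 hom-alt, otherwise het.
Within-individual heterozygosity is het sites over assayable sites —
the table carries a per-transcript assayable-site count (transcript
length by default) rather than dividing by transcript length blindly, so
the measure is robust to coverage variation; missing genotypes leave
both numerator and denominator. Transcripts with mean heterozygosity
< 0.01 are single-copy candidates in the fractionation screen (reads
mapped onto the progenitor: present homeolog pairs appear het at
homeolog-divergent sites, lost ones do not). As in the screen's original
use, single homeologs are not attributed to a subgenome: the divergence
proxy does not separate into two distributions.

## SDR scan

Per-site Weir–Cockerham (1984) variance components a (among
populations = sexes), b (among individuals) and c (within individuals)
are aggregated per transcript as FST = Σa / Σ(a+b+c) (ratio of sums; a
single site reduces exactly to its component ratio). Negative
transcript values are retained so the autosomal null is unbiased. The
per-transcript aggregation makes any sub-transcript windowing collapse
to the same summary, which keeps the statistic deterministic and
oracle-checkable (verified component-wise against a nested-ANOVA
implementation on all configurations up to 6 diploids per sex).
Sex-biased heterozygosity is log₁₀((male het + ε)/(female het + ε)) with
ε = 1e-4; the pseudocount is a policy choice to keep transcripts with a
zero sex mean finite. In a young XY system the planted SDR shows
FST ≈ 0.5 per fully sex-linked site (males het, females hom-ref) and
positive SBH — males carry excess heterozygosity, with no deficit.

Rolling means use windows of 20 consecutive transcripts in map order per
linkage group. The null distribution resamples 1000 windows of 20
*consecutive* autosomal transcripts, with start positions uniform over
all admissible runs pooled across autosomal linkage groups (contiguity
respected within a group; whether the original analysis pooled across or
within groups is not specifiable, and pooling uses all autosomal
information). Windows above the 97.5th percentile are flagged, with a
1e-12-scale tolerance so a degenerate constant null never flags through
rounding. Calibration: with exchangeable values, ~5% of window means
fall outside the interval (checked over 100 seeds, ±2%).

## Diversity and selection

π is the mean pairwise difference per assayable site over 2N sampled
chromosomes; unphased heterozygotes contribute allele counts, which is
sufficient for π and Tajima's D (no phasing attempted; verified against
brute-force all-pairs Hamming counts on expanded chromosomes). πN and
πS restrict numerator and denominator to NG86 nonsynonymous/synonymous
sites of the reading frame, reusing the codon machinery for
consistency; πN/πS is undefined when πS = 0. Tajima's D uses the 1989
constants and is undefined at S = 0. Subgenomes are compared by an
exact two-sided paired signed-rank test on per-linkage-group means
(eliminating linkage effects); the null distribution of the positive
rank sum is built exactly over all 2ⁿ sign assignments (as a rank
convolution, identical to enumeration and verified against it), with
average ranks for ties, zero differences dropped with a warning, and
p = min(1, 2·min(P≤, P≥)).

## Expression

TPM normalizes counts by length, scaling each sample to 1e6. Sex-biased
expression uses a negative-binomial Wald test implemented from
specified components rather than calling an external inference package:
median-of-ratios size factors; per-gene method-of-moments dispersions
from within-group variances, shrunk halfway (in log space) toward a
fitted a₀ + a₁/μ trend; a vectorized IRLS fit of the two-parameter
log-link GLM; and the Wald statistic referred to a t distribution with
n − 2 degrees of freedom, which keeps the test near nominal size at 6v6
(measured type-I ≈ 0.04 at p < 0.05 over 2000 null genes; power ≈ 1.0
for 4-fold effects at dispersion 0.05).

Sexual subfunctionalization compares r = log₂(TPM₁+0.5)/(TPM₂+0.5))
between sexes per homeolog pair with empirical-Bayes variance
moderation: a scaled inverse-χ² prior fitted by matching moments of
log s² (winsorized at 5%/95% for robustness to outlier pairs), posterior
variances (df·s² + d₀·s₀²)/(df + d₀), and a t reference with df + d₀
degrees of freedom. Pairs with both homeologs below 1 TPM in more than
half the samples are excluded. Significant pairs (BH-FDR < 0.05
throughout) are classified by per-sex mean ratios with a log₂(1.5)
threshold into opposite bias, single-sex homeolog bias, or a
same-direction magnitude change. A one-sample variant of the same
statistic tests overall homeolog (subgenome) expression bias.

## The synthetic generator

Sequences evolve along a fixed four-taxon tree: root → (subgenome 2;
ancestor of subgenome 1 and the progenitor), plus a basal outgroup.
Branch targets derive from the configured pairwise dS — sister branches
of dS₁ₚ/2 (default 0.035), a root-side branch of (dSₕ − dS₁ₚ)/2, the
subgenome-2 branch dSₕ/2, and an outgroup branch reaching ≈ 0.5 —
so realized tip-to-tip NG86 distances are approximately additive in the
corrected scale (realized median homeolog dS lands within a few percent
of the 0.14 target). Substitutions are synonymous except for a 10%
nonsynonymous fraction, never create stops, and stop one event past the
target with the closer state kept. Ancestors are uniform sense codons,
150–600 codons — desk-scale but long enough for stable dS.

Defaults are the study conditions: homeolog dS 0.14 with subgenome 1 at
0.07 from the progenitor; six males and six females; a sex-linked block
at 40–55 cM on linkage group 1 holding ~12% of genes (transcripts of a
non-recombining region stack within a narrow cM span on a genetic map,
which is what makes ≥ 20-transcript windows inside the span possible);
NB dispersion 0.05 with log-normal baselines; 5% sex-biased transcripts
at 4-fold and 5% subfunctionalized pairs with opposite 2-fold homeolog
bias per sex; read depth Poisson(30) so the 10-read filter is exercised
but not dominant; site qualities N(40, 8) so a small fraction fails the
quality filter; subgenome-1 site density 1.5× subgenome 2 (the extant
lineage is the more polymorphic one, giving an all-LGs-concordant π
contrast); mutation rate 7.5e-9 per site per generation for TMRCA
conversion only. Y-linked sites are planted in `partial` mode (males
het, females hom-ref; per-site FST 0.5) — the X–Y divergence depth of a
real young SDR is not specifiable, and `fixed` mode (FST 1) exists for
contrast. Isoform redundancy adds truncated (60–95%) duplicates of a
random 10% of transcripts, identical over the overlap.

What the generator does **not** emulate: read-level errors and mapping
bias, indels and real alternative splicing, linked selection,
recombination within transcripts, codon-usage bias, and expression
covariance between genes. Passing recovery tests therefore demonstrates
the correctness of the estimators and the pipeline plumbing under the
stated generative model, not robustness to real-data artifacts.

## Numerical choices and degenerate inputs

Seeds fan out from a single `SeedSequence`, giving byte-identical
outputs per configuration. Ties: cluster representatives by length then
id; hit ranking by score, divergence, id; equal dS leaves a pair
unassigned; quartet residual ties are unresolved. Undefined statistics
(saturated dS, S = 0, πS = 0, no assayable sites) propagate as missing
and are excluded from summaries, never coerced to zero. Problem sizes
in the shipped tests and acceptance script (300 genes, 150–600 codons,
2000 DE calibration genes, 100 bootstrap-calibration seeds) were chosen
to make every recovery property measurable on a single CPU in minutes.

## Known limitations

- Forward-strand-only similarity search; real transcriptomes need
  reverse-complement handling.
- The quartet step requires equal-length (pre-aligned) sequences, which
  the generator guarantees; real data would need an MSA front-end.
- NG86/JC underestimates divergence under strong rate heterogeneity;
  comparisons should stay internal to one pipeline run.
- The NB Wald test has no Cook's-distance-style outlier handling and the
  moderated test no array weights; both are calibrated only under the
  generator's models.
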