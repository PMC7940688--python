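# Methods

## Data model and coordinates

Genotypes live in a samples × variants matrix of ALT-allele dosages
(0/1/2; −1 for missing) with per-sample population labels, optional
contrast-group labels and optional per-genotype read depths. Only biallelic
SNPs are represented; multiallelic and indel records are dropped on input
with a logged count. VCF positions stay 1-based inside the matrix; every
window, region and gene interval elsewhere is 0-based half-open, and the
conversion happens exactly once, at the matrix boundary. This keeps BED and
VCF interoperability bit-exact.

## Site filters

A site passes when, after masking genotypes with depth ≤ `min_depth`
(default 3), (i) the missing fraction within *every* population is strictly
below `max_missing` (default 20%) and (ii) the minor allele frequency over
all non-missing alleles is strictly above `min_maf` (default 5%). All bounds
are exclusive; a site at exactly MAF = 5% fails. Depth masking is
per-genotype, because that is how depth is recorded in a VCF; a site whose
missingness only crosses the bound *because* of depth masking is reported as
a depth failure, one that fails on the raw calls as a missingness failure,
giving a deterministic depth → missingness → MAF attribution. Filtering is
idempotent and order-stable.

## Diversity statistics

Per-site π is the unbiased pairwise-difference rate 2·n_ref·n_alt/(n(n−1)).
Window θπ and θw are normalised by the *full physical window length*, not by
an accessible-site count — no accessibility mask exists at desk scale; the
choice only rescales both estimators identically and cancels from the θπ
ratio. Because missingness makes the allele count n vary across sites, the n
used for Watterson's a₁ and the Tajima constants is the median non-missing
allele count over the window's sites, rounded down (`n_rule="min"` selects
the minimum instead). Tajima's D follows the 1989 constants exactly and is
undefined (NaN) when S = 0, when n < 2, or when the variance term vanishes
(it does exactly at n = 2 for any S and at n = 3 with S = 1).

## FST

The per-window statistic is always a ratio of sums: per-site numerator and
denominator components are summed over the window's usable sites before
dividing. Two per-site parameterisations are provided:

- **Hudson** (default): num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1),
  den = p₁(1−p₂) + p₂(1−p₁), with allele counts n. Chosen as the scan default
  for its robustness to unequal sample sizes.
- **Weir–Cockerham (1984)**: the two-level components (a, a+b+c) including the
  heterozygote terms, computed from genotype counts.

Both agree within 0.02 on balanced designs (tested on Balding–Nichols
cohorts at F ∈ {0.05, 0.1, 0.2}). Negative window values — expected when true
differentiation is ~0, since both estimators subtract a finite-sample
correction — are kept for the Z-transform; they are clipped to zero only in
human-readable report output. A window needs ≥ `min_snps` (default 10)
usable sites and a nonzero summed denominator, otherwise its FST is NaN.

## Pooled heterozygosity

Hp = 2·ΣN_maj·ΣN_min/(ΣN_maj+ΣN_min)², summing per-site major and minor
allele counts across the window (the pooled-heterozygosity statistic of
Rubin et al. 2010, the convention in domestication-sweep scans). Major and
minor are defined per site from the selected samples, so Hp is invariant to
REF/ALT labelling. By default Hp is computed over the union of the contrast
samples (one Hp track per scan); per-group Hp is available via `hp_scope`.

## Z-transformation and outlier calling

Z-scores use the sample SD (n−1) over the defined windows of the whole scan;
undefined windows propagate NaN and are excluded from the baseline, so the
defined entries have mean 0 and SD 1 to ~1e−9. Outlier thresholds are
empirical quantiles (numpy's default type-7 linear interpolation), with ties
at the threshold all included; with distinct values exactly ⌈tail·m⌉ windows
flag per tail. The consensus rule is: top-5% FST *and* either 5% tail of the
log₂ θπ ratio. The FST tail is one-sided (only extreme differentiation is a
selection signal) while the ratio is two-sided, because the ratio's sign
says which group lost diversity; thresholds are genome-wide, not
per-chromosome. The plot set — windows with ZHp ≤ 0 and ZFST ≥ 0 — mirrors
the conventional chromosome-distribution display. Flagged windows sharing
≥ 1 bp merge into maximal regions (with the default 50% overlap, consecutive
outliers always merge); a region's direction comes from the sign of the
log₂ ratio at its highest-ZFST window.

## LD

Pairs of loci up to 20 kb apart are phased by the Excoffier–Slatkin EM for
unphased diploids: only double heterozygotes are phase-ambiguous, the E-step
splits them between cis and trans resolutions in proportion to the current
haplotype-frequency products, and iteration stops when max|Δf| < 1e−8. The
EM is initialised deterministically at linkage equilibrium; for a two-locus
biallelic system the likelihood is well behaved and a single start suffices
(a 3-restart option exists for flat degenerate likelihoods). The
log-likelihood is non-decreasing across iterations (asserted in tests).
r² = D²/(p(1−p)q(1−q)) with D = f₁₁ − pq. Distances are differences of
1-based positions, bins are half-open, and at most 100,000 pairs per
chromosome are used (uniform, seeded subsample) to bound runtime. The
half-decay distance is the first bin midpoint at which the binned mean r²
falls to half its maximum — an operational definition on the curve itself,
with no model fitting. Before any LD computation, samples are greedily
removed until all pairwise identity-by-state values are < 0.9 (the member of
a violating pair with the higher mean IBS goes first; ties drop the
later-ordered sample).

## Exact Hardy–Weinberg test

The conditional distribution of the heterozygote count given the allele
counts is enumerated with exact integer weights 2ʰ·n!/(n_AA!·h!·n_aa!); the
p-value is the summed probability of configurations no more probable than
the observed one, converted to float only at the final ratio. Exact
arithmetic makes ties at equal-probability configurations unambiguous and
the result identical to full enumeration for any table size used in
practice (tests cover all tables with ≤ 50 genotypes).

## Synthetic cohorts

The generator implements the Balding–Nichols model: ancestral frequency
p ~ Uniform(maf_floor, 1−maf_floor) per SNP, population frequency
~ Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes ~ Binomial(2, p_pop), so each
population is in Hardy–Weinberg proportions and the expected differentiation
equals F. Sweeps are implanted by moving the population frequency toward the
nearer boundary, p′ = p(1−i) for p < 0.5 else p + (1−p)·i, which deflates
within-population diversity by roughly (1−i); intensity 1 fixes the region.
Defaults encode the study design the package targets: 4 populations × 30
diploids, 10,000 SNPs on one 10-Mb chromosome (200 windows at 100 kb/50 kb),
F = 0.10, one sweep of intensity 0.9 at [5.00, 5.15) Mb — spanning two full
windows — implanted in both populations of the first contrast group, 2%
missing genotypes, Poisson(10) depths, MAF floor 0.05.

What the generator does *not* emulate: linkage between cohort SNPs (sites
are independent given the population frequencies), recombination maps,
demography and drift history, allele-frequency correlation between sweeps
and background, or sequencing artefacts beyond uniform missingness. Passing
recovery tests therefore demonstrates that the estimators and the outlier
logic behave correctly under the model's assumptions — not that real cohorts
meet those assumptions. LD tests use a separate Markov-copying haplotype
generator whose adjacent-locus allele correlation is exactly
exp(−ρ·spacing), giving analytic expected r²(d) = exp(−2ρd) and half-decay
ln 2/(2ρ), so the measured half-decay has a known truth.

## Problem sizes in the shipped checks

The repeated-simulation checks use 20 seeds at the defaults above for FST
and sweep recovery, 5 seeds of 250 SNPs × 60 diploids for LD half-decay, and
a 1,000–1,200-SNP cohort for the end-to-end pipeline determinism check —
sizes chosen to exercise every code path at full statistical scale for the
windowed statistics while keeping the per-pair EM work of the LD stage
proportionate.

## Known limitations

- Two-population FST only; the multi-deme Weir–Cockerham extension is out of
  scope.
- θπ ratio is undefined for windows where either group is monomorphic;
  such windows cannot reach the consensus set (they lack a log₂ ratio).
- The half-decay distance is quantised to bin midpoints; with 1-kb bins the
  reported value can sit a bin above the analytic crossing when finite-sample
  bias lifts the r² tail.
- The EM r² is the unphased-diploid composite estimate; with phased data it
  would be computed from haplotypes directly.
- Haplotype-block partitioning, haplotype-based scans (iHS/XP-EHH) and
  association models are not implemented.
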