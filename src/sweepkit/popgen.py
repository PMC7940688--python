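"""Per-site and per-window population-genetic estimators.

Implements the classical diversity and differentiation statistics used in
selective-sweep scans of resequencing cohorts:

* nucleotide diversity theta_pi (mean pairwise difference, per bp),
* Watterson's theta_w = S / (a1 * L),
* Tajima's D with the standard (Tajima 1989) normalising constants,
* per-site FST variance components in both the Weir & Cockerham (1984)
  and Hudson (ratio-of-averages, Bhatia et al. 2013) parameterisations,
* pooled heterozygosity Hp (Rubin et al. 2010) of windowed major/minor
  allele counts,
* single-locus descriptors He, effective allele number Ne, polymorphism
  information content PIC, and the exact Hardy-Weinberg test.

Window statistics are "ratio of sums": variance components are summed
across the window's usable sites before dividing, never averaged as
per-site ratios.  Undefined values are returned as NaN (``UNDEFINED``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .variant_io import MISSING, GenotypeMatrix

#: Sentinel for statistics that are undefined on the given input.
UNDEFINED = float("nan")


def is_defined(x) -> bool:
    return x is not None and not (isinstance(x, float) and math.isnan(x))


# ---------------------------------------------------------------------
# site-level counts
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class SiteCounts:
    """Allele and diploid genotype counts at one site in one population."""

    n_ref: int
    n_alt: int
    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self):
        if min(self.n_ref, self.n_alt, self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_ref + self.n_alt != 2 * (self.n_hom_ref + self.n_het + self.n_hom_alt):
            raise ValueError("allele counts inconsistent with genotype counts")

    @property
    def n(self) -> int:
        """Total number of called alleles."""
        return self.n_ref + self.n_alt

    @classmethod
    def from_calls(cls, calls: np.ndarray) -> "SiteCounts":
        calls = np.asarray(calls)
        ok = calls != MISSING
        hom_ref = int(np.sum(calls == 0))
        het = int(np.sum(calls == 1))
        hom_alt = int(np.sum(calls == 2))
        alt = het + 2 * hom_alt
        return cls(2 * int(ok.sum()) - alt, alt, hom_ref, het, hom_alt)


def site_counts(gm: GenotypeMatrix, site_index: int, pop: Optional[str] = None) -> SiteCounts:
    """Tally alleles and genotypes at one site over one population (None = all)."""
    rows = gm.sample_indices(pop)
    return SiteCounts.from_calls(gm.calls[rows, site_index])


def allele_counts(gm: GenotypeMatrix, rows: np.ndarray):
    """Vectorised per-site counts for the sample subset ``rows``.

    Returns (n_ref, n_alt, n_hom_ref, n_het, n_hom_alt) as int64 arrays of
    length n_variants.
    """
    sub = gm.calls[rows, :]
    hom_ref = np.sum(sub == 0, axis=0, dtype=np.int64)
    het = np.sum(sub == 1, axis=0, dtype=np.int64)
    hom_alt = np.sum(sub == 2, axis=0, dtype=np.int64)
    alt = het + 2 * hom_alt
    ref = 2 * (hom_ref + het + hom_alt) - alt
    return ref, alt, hom_ref, het, hom_alt


# ---------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------

def site_pi(c: SiteCounts) -> float:
    """Unbiased per-site heterozygosity 2*n_ref*n_alt / (n*(n-1)).

    Equals the fraction of differing pairs among all C(n, 2) allele pairs.
    UNDEFINED for fewer than two called alleles.
    """
    n = c.n
    if n < 2:
        return UNDEFINED
    return 2.0 * c.n_ref * c.n_alt / (n * (n - 1))


def _site_pi_array(n_ref: np.ndarray, n_alt: np.ndarray) -> np.ndarray:
    """Vectorised site_pi; sites with n < 2 contribute 0."""
    n = n_ref + n_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(n >= 2, 2.0 * n_ref * n_alt / np.maximum(n * (n - 1), 1), 0.0)
    return pi


def harmonic(n: int, power: int = 1) -> float:
    """a1 = sum 1/i (power=1) or a2 = sum 1/i^2 (power=2) for i in 1..n-1."""
    return float(sum(1.0 / i**power for i in range(1, n)))


def tajima_constants(n: int) -> dict:
    """Tajima (1989) normalising constants for sample size n (alleles)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    a1 = harmonic(n, 1)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(s: int, n: int, pi_sum: float) -> float:
    """Tajima's D from segregating sites ``s``, allele count ``n`` and the
    un-normalised pairwise-difference sum ``pi_sum`` over the window.

    UNDEFINED when s == 0 or n < 2.
    """
    if n < 2 or s == 0:
        return UNDEFINED
    k = tajima_constants(n)
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    if var <= 0:
        return UNDEFINED
    return (pi_sum - s / k["a1"]) / math.sqrt(var)


@dataclass
class DiversityStats:
    """Windowed diversity summary for one population."""

    pi_per_bp: float
    theta_w_per_bp: float
    tajimas_d: float
    s: int
    n_eff_alleles_used: int
    pi_sum: float = 0.0


def window_diversity(gm: GenotypeMatrix, window, pop: Optional[str] = None,
                     n_rule: str = "median") -> DiversityStats:
    """Diversity statistics of one window for one population.

    theta_pi and theta_w are normalised by the window's full physical
    length in bp.  The allele count n used for Watterson's a1 and the
    Tajima constants is the median (or, with ``n_rule='min'``, the
    minimum) non-missing allele count over the window's sites, rounded
    down.
    """
    length = window.end - window.start
    if length <= 0:
        raise ValueError("zero-length window")
    rows = gm.sample_indices(pop)
    idx, pos = gm.chrom_positions(window.chrom)
    # window is 0-based half-open; positions are 1-based
    lo = np.searchsorted(pos, window.start + 1, side="left")
    hi = np.searchsorted(pos, window.end, side="right")
    sites = idx[lo:hi]
    if len(sites) == 0:
        return DiversityStats(0.0, 0.0, UNDEFINED, 0, 0, 0.0)

    sub = gm.calls[np.ix_(rows, sites)]
    hom_ref = np.sum(sub == 0, axis=0, dtype=np.int64)
    het = np.sum(sub == 1, axis=0, dtype=np.int64)
    hom_alt = np.sum(sub == 2, axis=0, dtype=np.int64)
    alt = het + 2 * hom_alt
    ntot = 2 * (hom_ref + het + hom_alt)
    ref = ntot - alt

    pi_sum = float(_site_pi_array(ref, alt).sum())
    seg = (alt > 0) & (alt < ntot) & (ntot >= 2)
    s = int(seg.sum())
    if n_rule == "median":
        n_used = int(np.median(ntot))
    elif n_rule == "min":
        n_used = int(ntot.min())
    else:
        raise ValueError(f"unknown n_rule {n_rule!r}")

    theta_w = s / (harmonic(n_used) * length) if (s > 0 and n_used >= 2) else 0.0
    d = tajimas_d(s, n_used, pi_sum) if n_used >= 2 else UNDEFINED
    return DiversityStats(pi_sum / length, theta_w, d, s, n_used, pi_sum)


def diversity_table(gm: GenotypeMatrix, windows, n_rule: str = "median"):
    """Per-population mean windowed theta_pi / theta_w summary (DataFrame)."""
    import pandas as pd

    rows = []
    for pop in gm.populations:
        pis, tws, ds = [], [], []
        for w in windows:
            st = window_diversity(gm, w, pop, n_rule=n_rule)
            pis.append(st.pi_per_bp)
            tws.append(st.theta_w_per_bp)
            if is_defined(st.tajimas_d):
                ds.append(st.tajimas_d)
        rows.append({
            "population": pop,
            "theta_pi": float(np.mean(pis)) if pis else UNDEFINED,
            "theta_w": float(np.mean(tws)) if tws else UNDEFINED,
            "tajimas_d": float(np.mean(ds)) if ds else UNDEFINED,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------

def hudson_components(p1, n1, p2, n2):
    """Hudson FST per-site numerator/denominator (Bhatia et al. 2013 eq. 10).

    ``p`` are ALT frequencies, ``n`` allele counts; accepts scalars or arrays.
    """
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def wc_components(counts1: Sequence, counts2: Sequence):
    """Weir & Cockerham (1984) two-population components (a, a+b+c).

    Each ``counts`` is (n_hom_ref, n_het, n_hom_alt); accepts arrays.
    Includes the heterozygote (h-bar) terms of the full estimator.
    """
    h1r, h1h, h1a = (np.asarray(x, dtype=float) for x in counts1)
    h2r, h2h, h2a = (np.asarray(x, dtype=float) for x in counts2)
    n1 = h1r + h1h + h1a
    n2 = h2r + h2h + h2a
    r = 2.0
    p1 = (h1h + 2 * h1a) / (2 * n1)
    p2 = (h2h + 2 * h2a) / (2 * n2)
    hb1 = h1h / n1
    hb2 = h2h / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * hb1 + n2 * hb2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, a + b + c


def fst_site(counts_by_pop: Sequence[SiteCounts], method: str = "hudson") -> Tuple[float, float]:
    """Per-site FST variance components for two populations.

    Returns (numerator, denominator); the window statistic is the ratio of
    their sums over sites.  Sites where a population has no data (or, for
    Hudson, fewer than 2 alleles) yield (nan, nan) and are skipped upstream.
    """
    c1, c2 = counts_by_pop
    if method == "hudson":
        if c1.n < 2 or c2.n < 2:
            return UNDEFINED, UNDEFINED
        p1 = c1.n_alt / c1.n
        p2 = c2.n_alt / c2.n
        num, den = hudson_components(p1, c1.n, p2, c2.n)
        return float(num), float(den)
    elif method == "weir_cockerham":
        if c1.n < 2 or c2.n < 2:
            return UNDEFINED, UNDEFINED
        a, abc = wc_components(
            (c1.n_hom_ref, c1.n_het, c1.n_hom_alt),
            (c2.n_hom_ref, c2.n_het, c2.n_hom_alt),
        )
        return float(a), float(abc)
    raise ValueError(f"unknown FST method {method!r}")


def window_fst(gm: GenotypeMatrix, window, groups: Tuple[str, str],
               method: str = "hudson", min_snps: int = 10) -> float:
    """Ratio-of-sums window FST between two groups; UNDEFINED when the
    summed denominator is zero or fewer than ``min_snps`` sites are usable."""
    rows_a = gm.sample_indices(groups[0])
    rows_b = gm.sample_indices(groups[1])
    idx, pos = gm.chrom_positions(window.chrom)
    lo = np.searchsorted(pos, window.start + 1, side="left")
    hi = np.searchsorted(pos, window.end, side="right")
    sites = idx[lo:hi]
    if len(sites) == 0:
        return UNDEFINED
    num, den, usable = _fst_components_for_sites(gm, sites, rows_a, rows_b, method)
    if usable < min_snps:
        return UNDEFINED
    den_sum = float(den.sum())
    if den_sum == 0:
        return UNDEFINED
    return float(num.sum()) / den_sum


def _fst_components_for_sites(gm, sites, rows_a, rows_b, method):
    """Vectorised per-site components over ``sites``; returns arrays with
    unusable sites zeroed, plus the usable-site count."""
    sub_a = gm.calls[np.ix_(rows_a, sites)]
    sub_b = gm.calls[np.ix_(rows_b, sites)]

    def _counts(sub):
        hr = np.sum(sub == 0, axis=0, dtype=np.int64)
        he = np.sum(sub == 1, axis=0, dtype=np.int64)
        ha = np.sum(sub == 2, axis=0, dtype=np.int64)
        return hr, he, ha

    hr1, he1, ha1 = _counts(sub_a)
    hr2, he2, ha2 = _counts(sub_b)
    n1 = 2 * (hr1 + he1 + ha1)
    n2 = 2 * (hr2 + he2 + ha2)
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "hudson":
            p1 = (he1 + 2 * ha1) / np.maximum(n1, 1)
            p2 = (he2 + 2 * ha2) / np.maximum(n2, 1)
            num, den = hudson_components(p1, np.maximum(n1, 2), p2, np.maximum(n2, 2))
        elif method == "weir_cockerham":
            num, den = wc_components(
                (np.maximum(hr1, 0), he1, ha1), (np.maximum(hr2, 0), he2, ha2)
            )
        else:
            raise ValueError(f"unknown FST method {method!r}")
    num = np.where(usable, num, 0.0)
    den = np.where(usable, den, 0.0)
    num = np.nan_to_num(num, nan=0.0)
    den = np.nan_to_num(den, nan=0.0)
    return num, den, int(usable.sum())


# ---------------------------------------------------------------------
# pooled heterozygosity
# ---------------------------------------------------------------------

def pooled_hp(gm: GenotypeMatrix, window, pop_or_group: Optional[str] = None) -> float:
    """Pooled heterozygosity Hp of the window (Rubin et al. 2010 style):

        Hp = 2 * sum(n_major) * sum(n_minor) / (sum(n_major) + sum(n_minor))^2

    where the sums run over the window's SNPs and major/minor are defined
    per site from the selected samples' allele counts.  Bounded in [0, 0.5];
    UNDEFINED when the window has no called alleles.
    """
    rows = gm.sample_indices(pop_or_group)
    idx, pos = gm.chrom_positions(window.chrom)
    lo = np.searchsorted(pos, window.start + 1, side="left")
    hi = np.searchsorted(pos, window.end, side="right")
    sites = idx[lo:hi]
    if len(sites) == 0:
        return UNDEFINED
    sub = gm.calls[np.ix_(rows, sites)]
    ok = sub != MISSING
    alt = np.where(ok, sub, 0).sum(axis=0, dtype=np.int64)
    ntot = 2 * ok.sum(axis=0, dtype=np.int64)
    ref = ntot - alt
    maj = np.maximum(ref, alt)
    mino = np.minimum(ref, alt)
    s_maj = float(maj.sum())
    s_min = float(mino.sum())
    tot = s_maj + s_min
    if tot == 0:
        return UNDEFINED
    return 2.0 * s_maj * s_min / (tot * tot)


# ---------------------------------------------------------------------
# single-locus descriptors
# ---------------------------------------------------------------------

@dataclass
class LocusMetrics:
    """Descriptive genetic-variability measures for one biallelic locus."""

    genotype_freqs: Tuple[float, float, float]
    allele_freqs: Tuple[float, float]
    he: float
    ne: float
    pic: float
    hwe_p: float


def locus_metrics(c: SiteCounts) -> LocusMetrics:
    """He, effective allele number, PIC and exact HWE p for one locus.

    With allele fractions p, q: He = 1 - p^2 - q^2, Ne = 1/(p^2 + q^2),
    PIC = 1 - (p^2 + q^2) - 2 p^2 q^2.
    """
    n = c.n
    if n < 2:
        return LocusMetrics(
            (UNDEFINED,) * 3, (UNDEFINED,) * 2, UNDEFINED, UNDEFINED, UNDEFINED, UNDEFINED
        )
    p = c.n_ref / n
    q = c.n_alt / n
    ng = c.n_hom_ref + c.n_het + c.n_hom_alt
    gfreqs = (c.n_hom_ref / ng, c.n_het / ng, c.n_hom_alt / ng)
    homsum = p * p + q * q
    he = 1.0 - homsum
    ne = 1.0 / homsum
    pic = 1.0 - homsum - 2.0 * p * p * q * q
    return LocusMetrics(gfreqs, (p, q), he, ne, pic, hwe_exact(c.n_hom_ref, c.n_het, c.n_hom_alt))


def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value (Wigginton et al. 2005 convention).

    Conditional on the allele counts, the p-value is the total probability
    of heterozygote configurations no more probable than the observed one.
    Computed in exact integer arithmetic (configuration weight
    2^h * n! / (n_AA! h! n_aa!)), so ties are handled exactly; the float
    conversion happens only on the final ratio.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotype required")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0

    def weight(h: int) -> int:
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            2**h
            * math.factorial(n)
            // (math.factorial(hom_rare) * math.factorial(h) * math.factorial(hom_common))
        )

    hets = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_het]
    tail = sum(w for w in weights.values() if w <= obs)
    return min(1.0, tail / total)
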