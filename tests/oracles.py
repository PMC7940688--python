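"""Independent brute-force / enumeration oracles used by the test suite.

Every function here re-derives a statistic from first principles by a
different route than the package implementation (pair enumeration, exact
rational arithmetic, literal equation transcription, grid search), so
agreement is evidence of correctness rather than repetition.
"""

from fractions import Fraction
from itertools import combinations
import math

import numpy as np


# -- diversity ---------------------------------------------------------

def pi_by_pair_enumeration(n_ref: int, n_alt: int) -> float:
    """Fraction of differing pairs among all C(n,2) allele pairs."""
    alleles = [0] * n_ref + [1] * n_alt
    pairs = list(combinations(alleles, 2))
    if not pairs:
        return float("nan")
    return sum(a != b for a, b in pairs) / len(pairs)


def tajima_d_transcription(s: int, n: int, pi_sum: float) -> float:
    """Tajima's D via an exact-rational transcription of the 1989 constants."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = float(e1) * s + float(e2) * s * (s - 1)
    if var <= 0:  # degenerate sample sizes (e.g. n = 3 with s = 1)
        return float("nan")
    return (pi_sum - s / float(a1)) / math.sqrt(var)


# -- FST ---------------------------------------------------------------

def hudson_transcription(p1, n1, p2, n2):
    num = (p1 - p2) ** 2 - (p1 * (1.0 - p1)) / (n1 - 1.0) - (p2 * (1.0 - p2)) / (n2 - 1.0)
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return num, den


def wc_transcription(gc1, gc2):
    """Weir & Cockerham (1984) a / (a+b+c) components, transcribed literally
    for two demes from genotype counts (hom_ref, het, hom_alt)."""
    n_i = [sum(gc1), sum(gc2)]
    p_i = [
        (gc1[1] + 2 * gc1[2]) / (2.0 * n_i[0]),
        (gc2[1] + 2 * gc2[2]) / (2.0 * n_i[1]),
    ]
    h_i = [gc1[1] / n_i[0], gc2[1] / n_i[1]]
    r = 2
    nbar = sum(n_i) / r
    nc = (r * nbar - sum(n * n for n in n_i) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
    ssq = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
    a = (nbar / nc) * (
        ssq - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * ssq - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * ssq - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, a + b + c


# -- Hardy-Weinberg ----------------------------------------------------

def hwe_enumeration(hom_ref: int, het: int, hom_alt: int) -> float:
    """Exact HWE p via exact-rational full enumeration of the conditional
    heterozygote distribution, P(h) = 2^h n! nr! nc! / (hr! h! hc! (2n)!)."""
    n = hom_ref + het + hom_alt
    n_a = 2 * hom_ref + het
    n_b = 2 * hom_alt + het
    nr, nc = min(n_a, n_b), max(n_a, n_b)
    if nr == 0:
        return 1.0
    probs = {}
    f = math.factorial
    for h in range(nr % 2, nr + 1, 2):
        hr = (nr - h) // 2
        hc = n - h - hr
        if hc < 0:
            continue
        probs[h] = Fraction(2**h * f(n) * f(nr) * f(nc), f(hr) * f(h) * f(hc) * f(2 * n))
    total = sum(probs.values())
    assert total == 1, "enumeration probabilities must sum to 1"
    obs = probs[het]
    return float(sum(p for p in probs.values() if p <= obs))


# -- locus metrics (second-route expressions) --------------------------

def locus_metrics_second_route(p: float):
    """He / Ne / PIC written as explicit sums over the two alleles."""
    freqs = [p, 1 - p]
    he = sum(freqs[i] * freqs[j] for i in range(2) for j in range(2) if i != j)
    ne = 1.0 / sum(f * f for f in freqs)
    pic = (
        1.0
        - sum(f * f for f in freqs)
        - sum(
            2 * freqs[i] ** 2 * freqs[j] ** 2
            for i in range(2)
            for j in range(i + 1, 2)
        )
    )
    return he, ne, pic


# -- enrichment --------------------------------------------------------

def hypergeom_tail_enumeration(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] by exact-rational summation of the hypergeometric pmf."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return float(acc)


# -- intervals ---------------------------------------------------------

def brute_force_overlaps(regions, genes):
    """All-pairs >=1 bp overlap assignment (half-open intervals)."""
    out = {}
    for r in regions:
        hits = [
            g
            for g in genes
            if g.chrom == r.chrom and g.start < r.end and g.end > r.start
        ]
        hits.sort(key=lambda g: (g.start, g.end, g.gene_id))
        out[(r.chrom, r.start, r.end)] = [g.gene_id for g in hits]
    return out


def union_by_components(intervals):
    """Merge intervals sharing >= 1 bp via explicit connected components
    (independent of the sort-and-sweep in the implementation)."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = intervals[i]
            cj, sj, ej = intervals[j]
            if ci == cj and si < ej and sj < ei:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(intervals[i])
    out = []
    for members in comps.values():
        chrom = members[0][0]
        out.append((chrom, min(m[1] for m in members), max(m[2] for m in members)))
    return sorted(out)


# -- EM ----------------------------------------------------------------

def em_grid_search(tab, step: float = 1e-4):
    """Maximise the two-locus multinomial likelihood over f11 on a grid.

    At the MLE the haplotype margins equal the observed allele
    frequencies, leaving f11 as the single free parameter.
    """
    tab = np.asarray(tab)
    n = tab.sum()
    p = 1 - sum(i * tab[i, :].sum() for i in range(3)) / (2.0 * n)  # REF freq locus 1
    q = 1 - sum(j * tab[:, j].sum() for j in range(3)) / (2.0 * n)
    lo = max(0.0, p + q - 1.0)
    hi = min(p, q)
    best, best_ll = None, -math.inf
    hap = [(0, 0), (0, 1), (1, 0), (1, 1)]
    for f11 in np.arange(lo, hi + step / 2, step):
        f = [f11, p - f11, q - f11, 1 - p - q + f11]
        if min(f) < -1e-12:
            continue
        fr = {h: max(v, 0.0) for h, v in zip(hap, f)}
        ll = 0.0
        for i in range(3):
            for j in range(3):
                c = int(tab[i, j])
                if c == 0:
                    continue
                prob = sum(
                    fr[h1] * fr[h2]
                    for h1 in hap
                    for h2 in hap
                    if h1[0] + h2[0] == i and h1[1] + h2[1] == j
                )
                ll += c * math.log(prob) if prob > 0 else -math.inf
        if ll > best_ll:
            best_ll, best = ll, f
    return best, best_ll
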