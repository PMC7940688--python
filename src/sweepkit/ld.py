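"""Identity-by-state pruning, two-locus EM haplotype frequencies and LD decay.

Linkage disequilibrium between unphased diploid loci is measured through
the Excoffier-Slatkin two-locus EM: only double heterozygotes are phase
ambiguous, and the EM redistributes their two haplotype resolutions in
proportion to the current frequency estimates until the frequencies
stabilise.  r^2 = D^2 / (p(1-p) q(1-q)) with D = f11 - p*q.

The decay curve averages r^2 in distance bins up to 20 kb (the windowed
pairing used for whole-genome LD summaries) and reports the half-decay
distance: the first bin midpoint at which the mean r^2 falls to half its
maximum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .variant_io import MISSING, GenotypeMatrix

logger = logging.getLogger("sweepkit")

UNDEFINED = float("nan")


# ---------------------------------------------------------------------
# identity by state
# ---------------------------------------------------------------------

def ibs_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise identity-by-state fractions.

    IBS(i, j) = mean over shared non-missing sites of (2 - |g_i - g_j|)/2;
    the diagonal is 1 and pairs with no shared sites are NaN.
    """
    if gm.n_samples < 2:
        raise ValueError("need >= 2 samples")
    calls = gm.calls.astype(np.int16)
    ok = calls != MISSING
    n = gm.n_samples
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ok[i] & ok[j]
            m = int(shared.sum())
            if m == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            sim = (2 - np.abs(calls[i, shared] - calls[j, shared])).sum() / (2.0 * m)
            out[i, j] = out[j, i] = sim
    return out


def prune_inbred(gm: GenotypeMatrix, threshold: float = 0.9) -> GenotypeMatrix:
    """Greedily drop samples until no pair has IBS >= ``threshold``.

    While a violating pair exists, the member with the higher mean IBS to
    all other retained samples is removed (ties: the later sample).
    """
    ibs = ibs_matrix(gm)
    keep = list(range(gm.n_samples))
    while True:
        sub = ibs[np.ix_(keep, keep)]
        np.fill_diagonal(sub, np.nan)
        with np.errstate(invalid="ignore"):
            viol = np.argwhere(sub >= threshold)
        if len(viol) == 0:
            break
        mean_ibs = np.nanmean(sub, axis=1)
        # all violating samples are candidates; drop the worst one per pass
        cand = set(viol.ravel().tolist())
        worst = max(cand, key=lambda k: (mean_ibs[k], k))
        removed = keep.pop(worst)
        logger.info("prune_inbred: removed sample %s", gm.sample_ids[removed])
    if len(keep) == gm.n_samples:
        return gm
    return gm.subset_samples(keep)


# ---------------------------------------------------------------------
# two-locus EM
# ---------------------------------------------------------------------

@dataclass
class HaplotypeFreqs:
    """Maximum-likelihood two-locus haplotype frequencies (1 = REF allele)."""

    f11: float
    f12: float
    f21: float
    f22: float
    loglik: float
    n_iter: int

    @property
    def freqs(self):
        return (self.f11, self.f12, self.f21, self.f22)


def _pair_table(g1, g2) -> np.ndarray:
    """3x3 joint genotype count table over complete pairs."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    tab = np.zeros((3, 3), dtype=np.int64)
    for a, b in zip(g1[ok], g2[ok]):
        tab[a, b] += 1
    return tab


def em_haplotype_freqs(g1, g2, tol: float = 1e-8, max_iter: int = 1000,
                       restarts: int = 1) -> Optional[HaplotypeFreqs]:
    """EM estimate of the four two-locus haplotype frequencies from
    unphased diploid genotype vectors (ALT dosage, MISSING dropped pairwise).

    Initialised at linkage equilibrium (product of marginal allele
    frequencies); iterates until max |delta f| < ``tol``.  ``restarts > 1``
    additionally tries cis- and trans-biased initialisations and keeps the
    highest-likelihood solution (useful for degenerate flat likelihoods).
    Returns None when either locus is monomorphic among complete pairs.
    """
    tab = _pair_table(g1, g2)
    best = em_from_table(tab, tol=tol, max_iter=max_iter)
    if best is None or restarts <= 1:
        return best
    for bias in (0.45, -0.45)[: restarts - 1]:
        h = em_from_table(tab, tol=tol, max_iter=max_iter, init_d=bias)
        if h is not None and h.loglik > best.loglik:
            best = h
    return best


def em_from_table(tab: np.ndarray, tol: float = 1e-8,
                  max_iter: int = 1000, init_d: float = 0.0) -> Optional[HaplotypeFreqs]:
    n_ind = int(tab.sum())
    if n_ind == 0:
        return None
    # marginal ALT dosages
    alt1 = int(sum(i * tab[i, :].sum() for i in range(3)))
    alt2 = int(sum(j * tab[:, j].sum() for j in range(3)))
    n_hap = 2 * n_ind
    if alt1 in (0, n_hap) or alt2 in (0, n_hap):
        return None
    pA = 1 - alt1 / n_hap  # REF frequency, locus 1
    pB = 1 - alt2 / n_hap

    # unambiguous haplotype contributions; genotype g contributes alleles
    # (REF count at locus1, locus2).  hap index: 1=REF, 2=ALT.
    k = np.zeros(4)  # f11 f12 f21 f22
    ndh = int(tab[1, 1])
    for i in range(3):
        for j in range(3):
            c = int(tab[i, j])
            if c == 0 or (i == 1 and j == 1):
                continue
            # alleles at locus1: (2-i) REF, i ALT; similarly locus2
            if i == 1:  # het at locus1 only: phase known
                k[0 if j == 0 else 1] += c  # REF1 paired with REF2/ALT2
                k[2 if j == 0 else 3] += c
            elif j == 1:  # het at locus2 only
                k[0 if i == 0 else 2] += c
                k[1 if i == 0 else 3] += c
            else:  # double homozygote: two identical haplotypes
                idx = (0 if i == 0 else 2) + (0 if j == 0 else 1)
                k[idx] += 2 * c

    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    if init_d:
        # push D toward +/- its admissible bound for biased restarts
        dmax = min(pA, pB) - pA * pB if init_d > 0 else pA * pB - max(0.0, pA + pB - 1)
        d = init_d * dmax
        f = np.clip(f + np.array([d, -d, -d, d]), 1e-9, 1.0)
        f /= f.sum()
    loglik = -math.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step: split double heterozygotes between cis (11/22) and
        # trans (12/21) resolutions
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        tot = cis + trans
        w = 0.5 if tot == 0 else cis / tot
        e = k.copy()
        e[0] += ndh * w
        e[3] += ndh * w
        e[1] += ndh * (1 - w)
        e[2] += ndh * (1 - w)
        new_f = e / n_hap
        loglik = _tab_loglik(tab, new_f)
        delta = np.max(np.abs(new_f - f))
        f = new_f
        if delta < tol:
            break
    return HaplotypeFreqs(f[0], f[1], f[2], f[3], loglik, n_iter)


def _tab_loglik(tab: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype table under random
    union of haplotypes with frequencies f = (f11, f12, f21, f22)."""
    f11, f12, f21, f22 = f
    # P(genotype at locus pair): sum over unordered haplotype pairs
    hap = [(0, 0), (0, 1), (1, 0), (1, 1)]  # (ALT? at locus1, locus2)
    fr = {h: v for h, v in zip(hap, f)}
    ll = 0.0
    for i in range(3):
        for j in range(3):
            c = int(tab[i, j])
            if c == 0:
                continue
            p = 0.0
            for h1 in hap:
                for h2 in hap:
                    if h1[0] + h2[0] == i and h1[1] + h2[1] == j:
                        p += fr[h1] * fr[h2]
            ll += c * math.log(p) if p > 0 else -math.inf
    return ll


def r2_pair(h: HaplotypeFreqs) -> float:
    """r^2 = D^2 / (p(1-p) q(1-q)); UNDEFINED if a marginal is 0 or 1."""
    p = h.f11 + h.f12
    q = h.f11 + h.f21
    if not (0 < p < 1) or not (0 < q < 1):
        return UNDEFINED
    d = h.f11 - p * q
    return min(1.0, d * d / (p * (1 - p) * q * (1 - q)))


# ---------------------------------------------------------------------
# decay curve
# ---------------------------------------------------------------------

@dataclass
class LDDecayCurve:
    bin_edges: np.ndarray  # len = n_bins + 1, bp
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    half_decay_bp: float

    def to_tsv(self, path, label: str = "") -> None:
        with open(path, "w") as fh:
            fh.write("bin_lo\tbin_hi\tmean_r2\tn_pairs\n")
            for lo, hi, r2, n in zip(
                self.bin_edges[:-1], self.bin_edges[1:], self.mean_r2, self.n_pairs
            ):
                r2s = "NA" if math.isnan(r2) else f"{r2:.6g}"
                fh.write(f"{int(lo)}\t{int(hi)}\t{r2s}\t{int(n)}\n")
            hd = "NA" if math.isnan(self.half_decay_bp) else f"{self.half_decay_bp:.0f}"
            fh.write(f"# half_decay_bp{('_' + label) if label else ''}\t{hd}\n")


def ld_decay(gm: GenotypeMatrix, pop: Optional[str] = None, max_dist: int = 20_000,
             bin_width: int = 1_000, max_pairs_per_chrom: int = 100_000,
             seed: int = 0) -> LDDecayCurve:
    """Distance-binned mean r^2 over all same-chromosome pairs within
    ``max_dist`` bp, with the half-decay distance.

    Pairs per chromosome are capped at ``max_pairs_per_chrom`` by uniform
    seeded subsampling.  Half-decay is the first bin midpoint (scanning
    by increasing distance) whose mean r^2 <= max(mean r^2)/2, or NaN if
    never reached.
    """
    rows = gm.sample_indices(pop)
    if len(rows) < 2:
        raise ValueError("population needs >= 2 samples")
    edges = np.arange(0, max_dist + bin_width, bin_width)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    rng = np.random.default_rng(seed)

    any_pairs = False
    for chrom in gm.chroms:
        idx, pos = gm.chrom_positions(chrom)
        pairs = []
        for a in range(len(idx)):
            b = a + 1
            while b < len(idx) and pos[b] - pos[a] <= max_dist:
                pairs.append((a, b))
                b += 1
        if not pairs:
            continue
        any_pairs = True
        if len(pairs) > max_pairs_per_chrom:
            sel = rng.choice(len(pairs), size=max_pairs_per_chrom, replace=False)
            pairs = [pairs[i] for i in sorted(sel)]
            logger.info("ld_decay: %s capped to %d pairs", chrom, max_pairs_per_chrom)
        sub = gm.calls[np.ix_(rows, idx)]
        for a, b in pairs:
            h = em_haplotype_freqs(sub[:, a], sub[:, b])
            if h is None:
                continue
            r2 = r2_pair(h)
            if math.isnan(r2):
                continue
            d = int(pos[b] - pos[a])
            k = min(d // bin_width, n_bins - 1)
            sums[k] += r2
            counts[k] += 1
    if not any_pairs:
        raise ValueError("ld_decay: no eligible marker pairs")

    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    half = UNDEFINED
    defined = ~np.isnan(mean_r2)
    if defined.any():
        peak = np.nanmax(mean_r2)
        mids = (edges[:-1] + edges[1:]) / 2.0
        for k in range(n_bins):
            if defined[k] and mean_r2[k] <= peak / 2.0:
                half = float(mids[k])
                break
    return LDDecayCurve(edges, mean_r2, counts, half)
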