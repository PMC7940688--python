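"""Genome-wide sliding-window scans, Z-transforms and outlier calling.

The scan contrasts two groups of samples over a grid of (by default)
100-kb windows sliding in 50-kb steps, computing per window: Hudson or
Weir-Cockerham FST (ratio of sums), theta_pi for each group and their
ratio, pooled heterozygosity Hp, and Tajima's D.  FST and Hp are
Z-transformed genome-wide over defined windows; selection signals are the
consensus of the upper 5% FST tail with either 5% tail of the log2
theta_pi ratio, and consecutive flagged windows are merged into regions.

Windows are 0-based half-open intervals.  Statistics that cannot be
computed (too few SNPs, zero denominators) carry NaN and are excluded
from the Z baselines and the empirical quantiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import popgen
from .popgen import UNDEFINED, is_defined
from .variant_io import GenotypeMatrix


class Window(NamedTuple):
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    is_partial: bool = False


@dataclass
class Region:
    """A merged genomic interval called as a selection signal."""

    chrom: str
    start: int
    end: int
    n_windows: int
    peak_stat: float
    direction: Optional[str]  # which group shows reduced diversity, or None


def make_windows(chrom_lengths: dict, window_size: int = 100_000,
                 step: int = 50_000) -> list:
    """Sliding-window grid: starts at 0, ``step`` apart, per chromosome.

    Trailing windows shorter than ``window_size`` are emitted with
    ``is_partial=True``.  With the defaults every interior bp is covered
    exactly twice.
    """
    if step <= 0 or window_size < step:
        raise ValueError("require window_size >= step > 0")
    windows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom!r}")
        start = 0
        while start < length:
            end = min(start + window_size, length)
            windows.append(Window(chrom, start, end, end - start < window_size))
            start += step
    return windows


def z_transform(values, name: str = "statistic") -> np.ndarray:
    """Z-scores (sample SD, n-1) over defined entries; NaN propagated.

    Raises if fewer than two defined values or zero spread, naming the
    statistic in the message.
    """
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise ValueError(f"z_transform({name}): need >= 2 defined values")
    mu = x[ok].mean()
    sd = x[ok].std(ddof=1)
    if sd == 0:
        raise ValueError(f"z_transform({name}): zero spread")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - mu) / sd
    return out


@dataclass
class ScanTable:
    """Per-window scan statistics with outlier flags.

    Wraps a DataFrame with one row per window (stable column order) plus
    the contrast labels.  Flag columns are added by :func:`call_outliers`.
    """

    df: pd.DataFrame
    group_a: str
    group_b: str

    COLUMNS = [
        "chrom", "start", "end", "is_partial", "n_snps",
        "fst", "pi_a", "pi_b", "pi_ratio", "log2_ratio", "hp",
        "tajima_d_a", "tajima_d_b", "z_fst", "z_hp",
    ]

    def windows(self) -> list:
        return [
            Window(r.chrom, int(r.start), int(r.end), bool(r.is_partial))
            for r in self.df.itertuples()
        ]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")

    def flagged_to_bed(self, path, flag: str = "consensus") -> None:
        """Flagged windows as BED6 (score = round(100 * ZFST))."""
        with open(path, "w") as fh:
            for r in self.df[self.df[flag]].itertuples():
                score = 0 if math.isnan(r.z_fst) else int(round(100 * r.z_fst))
                fh.write(f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\t{flag}\t{score}\t.\n")


def scan(gm: GenotypeMatrix, contrast: Tuple[str, str], windows: Sequence[Window],
         method: str = "hudson", min_snps: int = 10, hp_scope: str = "union",
         n_rule: str = "median") -> ScanTable:
    """Fill the per-window statistics table for one contrast.

    pi_ratio = theta_pi(a) / theta_pi(b); log2_ratio defined only when
    both are positive.  Hp is computed on the union of the contrast
    samples (``hp_scope='a'``/``'b'`` restricts it to one group).  Windows
    with fewer than ``min_snps`` SNPs carry NaN statistics and do not
    enter the Z baselines.
    """
    a, b = contrast
    rows_a = gm.sample_indices(a)
    rows_b = gm.sample_indices(b)
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise ValueError("both contrast groups need >= 2 samples")
    if hp_scope == "union":
        rows_hp = np.unique(np.concatenate([rows_a, rows_b]))
    elif hp_scope == "a":
        rows_hp = rows_a
    elif hp_scope == "b":
        rows_hp = rows_b
    else:
        raise ValueError(f"unknown hp_scope {hp_scope!r}")

    recs = []
    for w in windows:
        idx, pos = gm.chrom_positions(w.chrom)
        lo = np.searchsorted(pos, w.start + 1, side="left")
        hi = np.searchsorted(pos, w.end, side="right")
        sites = idx[lo:hi]
        n_snps = len(sites)
        if n_snps < min_snps:
            recs.append((w.chrom, w.start, w.end, w.is_partial, n_snps) + (np.nan,) * 8)
            continue

        num, den, usable = popgen._fst_components_for_sites(gm, sites, rows_a, rows_b, method)
        den_sum = float(den.sum())
        fst = float(num.sum()) / den_sum if (den_sum != 0 and usable >= min_snps) else np.nan

        length = w.end - w.start
        pi_a, da = _window_pi(gm, sites, rows_a, length, n_rule)
        pi_b, db = _window_pi(gm, sites, rows_b, length, n_rule)
        if pi_b > 0:
            ratio = pi_a / pi_b
        else:
            ratio = np.nan
        log2r = math.log2(pi_a / pi_b) if (pi_a > 0 and pi_b > 0) else np.nan

        sub = gm.calls[np.ix_(rows_hp, sites)]
        ok = sub != -1
        alt = np.where(ok, sub, 0).sum(axis=0, dtype=np.int64)
        ntot = 2 * ok.sum(axis=0, dtype=np.int64)
        maj = np.maximum(ntot - alt, alt).sum()
        mino = np.minimum(ntot - alt, alt).sum()
        tot = float(maj + mino)
        hp = 2.0 * maj * mino / (tot * tot) if tot > 0 else np.nan

        recs.append((w.chrom, w.start, w.end, w.is_partial, n_snps,
                     fst, pi_a, pi_b, ratio, log2r, hp, da, db))

    df = pd.DataFrame(recs, columns=ScanTable.COLUMNS[:13])
    df["z_fst"] = z_transform(df["fst"].to_numpy(), "FST")
    df["z_hp"] = z_transform(df["hp"].to_numpy(), "Hp")
    return ScanTable(df, a, b)


def _window_pi(gm, sites, rows, length, n_rule):
    """(pi_per_bp, Tajima's D) for pre-resolved sites and sample rows."""
    sub = gm.calls[np.ix_(rows, sites)]
    hom_ref = np.sum(sub == 0, axis=0, dtype=np.int64)
    het = np.sum(sub == 1, axis=0, dtype=np.int64)
    hom_alt = np.sum(sub == 2, axis=0, dtype=np.int64)
    alt = het + 2 * hom_alt
    ntot = 2 * (hom_ref + het + hom_alt)
    ref = ntot - alt
    pi_sum = float(popgen._site_pi_array(ref, alt).sum())
    seg = (alt > 0) & (alt < ntot) & (ntot >= 2)
    s = int(seg.sum())
    n_used = int(np.median(ntot)) if n_rule == "median" else int(ntot.min())
    d = popgen.tajimas_d(s, n_used, pi_sum) if n_used >= 2 else np.nan
    return pi_sum / length, d


def call_outliers(table: ScanTable, tail: float = 0.05) -> ScanTable:
    """Flag empirical-tail outlier windows (quantiles: type-7 interpolation;
    ties at the threshold all included).

    Adds boolean columns:

    * ``fst_top``    — FST >= (1 - tail) quantile,
    * ``ratio_low``/``ratio_high`` — log2 pi-ratio in the lower/upper tail,
    * ``consensus``  — fst_top AND (ratio_low OR ratio_high),
    * ``plot_set``   — ZHp <= 0 AND ZFST >= 0.

    Windows with undefined statistics never carry a flag.
    """
    if not 0 < tail < 0.5:
        raise ValueError("tail must lie in (0, 0.5)")
    df = table.df
    fst = df["fst"].to_numpy()
    log2r = df["log2_ratio"].to_numpy()
    if np.sum(~np.isnan(fst)) < 20 or np.sum(~np.isnan(log2r)) < 20:
        raise ValueError("call_outliers: need >= 20 defined windows")

    fst_thr = np.quantile(fst[~np.isnan(fst)], 1 - tail)
    r_lo = np.quantile(log2r[~np.isnan(log2r)], tail)
    r_hi = np.quantile(log2r[~np.isnan(log2r)], 1 - tail)

    with np.errstate(invalid="ignore"):
        df = df.copy()
        df["fst_top"] = ~np.isnan(fst) & (fst >= fst_thr)
        df["ratio_low"] = ~np.isnan(log2r) & (log2r <= r_lo)
        df["ratio_high"] = ~np.isnan(log2r) & (log2r >= r_hi)
        df["consensus"] = df["fst_top"] & (df["ratio_low"] | df["ratio_high"])
        z_fst = df["z_fst"].to_numpy()
        z_hp = df["z_hp"].to_numpy()
        df["plot_set"] = (
            ~np.isnan(z_fst) & ~np.isnan(z_hp) & (z_hp <= 0) & (z_fst >= 0)
        )
    return ScanTable(df, table.group_a, table.group_b)


def merge_regions(table: ScanTable, flag: str = "consensus") -> list:
    """Merge flagged windows sharing >= 1 bp into maximal regions.

    With 50%-overlapping windows, consecutive flagged windows always
    share bp, so runs of outliers coalesce.  ``direction`` reports which
    group shows reduced diversity, from the sign of log2_ratio at the
    window with the highest ZFST (positive log2_ratio means group b has
    the lower diversity).
    """
    if flag not in table.df.columns:
        raise KeyError(f"table has no flag column {flag!r}")
    flagged = table.df[table.df[flag]].sort_values(["chrom", "start"])
    regions: list = []
    cur = None  # [chrom, start, end, members]
    for r in flagged.itertuples():
        if cur is not None and r.chrom == cur[0] and r.start < cur[2]:
            cur[2] = max(cur[2], int(r.end))
            cur[3].append(r)
        else:
            if cur is not None:
                regions.append(_finish_region(cur, table))
            cur = [r.chrom, int(r.start), int(r.end), [r]]
    if cur is not None:
        regions.append(_finish_region(cur, table))
    return regions


def _finish_region(cur, table: ScanTable) -> Region:
    chrom, start, end, members = cur
    zs = [(m.z_fst if not math.isnan(m.z_fst) else -math.inf) for m in members]
    peak = members[int(np.argmax(zs))]
    peak_stat = peak.z_fst
    if math.isnan(peak_stat):
        mags = [abs(m.log2_ratio) if not math.isnan(m.log2_ratio) else -math.inf
                for m in members]
        peak = members[int(np.argmax(mags))]
        peak_stat = abs(peak.log2_ratio) if not math.isnan(peak.log2_ratio) else UNDEFINED
    if is_defined(peak.log2_ratio) and peak.log2_ratio != 0:
        direction = table.group_a if peak.log2_ratio < 0 else table.group_b
    else:
        direction = None
    return Region(chrom, start, end, len(members), float(peak_stat), direction)


def regions_to_bed(regions: Sequence[Region], path) -> None:
    """Regions as BED4 (name = direction or '.')."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction or '.'}\n")
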