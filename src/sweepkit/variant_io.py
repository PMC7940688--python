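"""VCF / popmap input-output and site filtering.

The in-memory substrate for every statistic in the package is
:class:`GenotypeMatrix`: a samples x variants matrix of ALT-allele dosages
(0/1/2, with ``MISSING`` = -1) plus per-sample population (and optional
contrast-group) labels and optional per-genotype depths.

Coordinates follow the VCF convention internally (1-based positions);
all interval logic elsewhere in the package is 0-based half-open and
converts at this boundary.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np

logger = logging.getLogger("sweepkit")

#: Sentinel for a missing diploid genotype call.
MISSING: int = -1

_BASES = frozenset("ACGT")


class VariantSite(NamedTuple):
    """A biallelic SNP record (1-based VCF position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: Optional[str] = None


@dataclass
class FilterReport:
    """Per-rule site tallies from :func:`filter_variants`.

    Failures are attributed to the first failing rule in the fixed order
    depth -> missingness -> MAF, so ``n_pass + failures == n_input``.
    """

    n_input: int
    n_fail_depth: int
    n_fail_missing: int
    n_fail_maf: int
    n_pass: int

    def __post_init__(self) -> None:
        total = self.n_fail_depth + self.n_fail_missing + self.n_fail_maf + self.n_pass
        if total != self.n_input:
            raise ValueError(f"FilterReport tallies {total} != n_input {self.n_input}")


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for a cohort of samples at biallelic SNPs.

    Attributes
    ----------
    sample_ids : list of str
    pop_of : dict mapping sample -> population label
    group_of : optional dict mapping sample -> contrast-group label
    variants : list of VariantSite, sorted by (chrom, pos)
    calls : int8 ndarray (n_samples, n_variants), ALT dosage or MISSING
    depth : optional int32 ndarray (n_samples, n_variants)
    """

    sample_ids: list
    pop_of: dict
    variants: list
    calls: np.ndarray
    depth: Optional[np.ndarray] = None
    group_of: Optional[dict] = None
    _pos_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.variants)})"
            )
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.calls.shape:
                raise ValueError("depth shape does not match calls shape")
        missing_pop = [s for s in self.sample_ids if s not in self.pop_of]
        if missing_pop:
            raise ValueError(f"samples without population label: {missing_pop}")
        for v in self.variants:
            if v.pos < 1 or v.ref == v.alt or v.ref not in _BASES or v.alt not in _BASES:
                raise ValueError(f"invalid variant record {v}")
        keys = [(v.chrom, v.pos) for v in self.variants]
        if keys != sorted(keys):
            raise ValueError("variants must be sorted by (chrom, pos)")

    # -- shape helpers -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def populations(self) -> list:
        seen = {}
        for s in self.sample_ids:
            seen.setdefault(self.pop_of[s], None)
        return list(seen)

    @property
    def groups(self) -> list:
        if self.group_of is None:
            return []
        seen = {}
        for s in self.sample_ids:
            if s in self.group_of:
                seen.setdefault(self.group_of[s], None)
        return list(seen)

    def sample_indices(self, label: Optional[str]) -> np.ndarray:
        """Row indices of samples in population or group ``label``.

        ``None`` selects all samples.  Group labels take precedence over
        population labels when both exist under the same name.
        """
        if label is None:
            return np.arange(self.n_samples)
        if self.group_of is not None and label in set(self.group_of.values()):
            idx = [i for i, s in enumerate(self.sample_ids) if self.group_of.get(s) == label]
        else:
            idx = [i for i, s in enumerate(self.sample_ids) if self.pop_of[s] == label]
            if not idx:
                raise KeyError(f"unknown population or group label: {label!r}")
        return np.asarray(idx, dtype=np.intp)

    def chrom_positions(self, chrom: str):
        """(variant indices, 1-based positions) on ``chrom``, position-sorted."""
        if chrom not in self._pos_cache:
            idx = np.asarray(
                [i for i, v in enumerate(self.variants) if v.chrom == chrom], dtype=np.intp
            )
            pos = np.asarray([self.variants[i].pos for i in idx], dtype=np.int64)
            self._pos_cache[chrom] = (idx, pos)
        return self._pos_cache[chrom]

    @property
    def chroms(self) -> list:
        seen = {}
        for v in self.variants:
            seen.setdefault(v.chrom, None)
        return list(seen)

    # -- subsetting ----------------------------------------------------
    def subset_variants(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            pop_of=dict(self.pop_of),
            group_of=None if self.group_of is None else dict(self.group_of),
            variants=[self.variants[i] for i in idx],
            calls=self.calls[:, idx].copy(),
            depth=None if self.depth is None else self.depth[:, idx].copy(),
        )

    def subset_samples(self, keep_idx) -> "GenotypeMatrix":
        keep_idx = np.asarray(keep_idx, dtype=np.intp)
        ids = [self.sample_ids[i] for i in keep_idx]
        return GenotypeMatrix(
            sample_ids=ids,
            pop_of={s: self.pop_of[s] for s in ids},
            group_of=None
            if self.group_of is None
            else {s: self.group_of[s] for s in ids if s in self.group_of},
            variants=list(self.variants),
            calls=self.calls[keep_idx, :].copy(),
            depth=None if self.depth is None else self.depth[keep_idx, :].copy(),
        )


# ---------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------

def read_popmap(path) -> dict:
    """Read a two-column (sample TAB label) TSV without header."""
    mapping: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            mapping[parts[0]] = parts[1]
    return mapping


def read_vcf(path, popmap, groupmap=None) -> GenotypeMatrix:
    """Load a VCF v4.x into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are dropped (counts logged). Missing
    and half-called genotypes become :data:`MISSING`. Every sample in the
    VCF must appear in the popmap.
    """
    from cyvcf2 import VCF

    pop_of = read_popmap(popmap)
    group_of = read_popmap(groupmap) if groupmap is not None else None

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in pop_of:
            raise ValueError(f"sample {s!r} present in VCF but absent from popmap")

    variants: list = []
    call_cols: list = []
    depth_cols: list = []
    have_depth = False
    n_dropped = 0
    for rec in vcf:
        if (
            len(rec.ALT) != 1
            or len(rec.REF) != 1
            or len(rec.ALT[0]) != 1
            or rec.REF not in _BASES
            or rec.ALT[0] not in _BASES
        ):
            n_dropped += 1
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(rec.genotypes):
            a0, a1 = g[0], g[1]
            col[i] = MISSING if (a0 < 0 or a1 < 0) else a0 + a1
        call_cols.append(col)
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            have_depth = True
            dcol = np.asarray(dp).reshape(-1).astype(np.int32)
            dcol[dcol < 0] = 0
            depth_cols.append(dcol)
        else:
            depth_cols.append(np.zeros(len(samples), dtype=np.int32))
        variants.append(
            VariantSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                id=None if rec.ID in (None, ".") else rec.ID,
            )
        )
    if n_dropped:
        logger.warning("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)

    calls = (
        np.stack(call_cols, axis=1) if call_cols else np.zeros((len(samples), 0), dtype=np.int8)
    )
    depth = np.stack(depth_cols, axis=1) if (depth_cols and have_depth) else None

    order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
    if order != list(range(len(variants))):
        variants = [variants[i] for i in order]
        calls = calls[:, order]
        if depth is not None:
            depth = depth[:, order]

    return GenotypeMatrix(
        sample_ids=samples,
        pop_of={s: pop_of[s] for s in samples},
        group_of=None if group_of is None else {s: group_of[s] for s in samples if s in group_of},
        variants=variants,
        calls=calls,
        depth=depth,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Emit ``gm`` as an unphased VCF v4.2 file (GT, plus DP if depths exist)."""
    fmt = "GT:DP" if gm.depth is not None else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in gm.chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, v in enumerate(gm.variants):
            fields = [v.chrom, str(v.pos), v.id or ".", v.ref, v.alt, ".", "PASS", ".", fmt]
            for i in range(gm.n_samples):
                gt = _GT_STR[int(gm.calls[i, j])]
                if gm.depth is not None:
                    gt = f"{gt}:{int(gm.depth[i, j])}"
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


def write_popmap(mapping: dict, path) -> None:
    with open(path, "w") as fh:
        for s, label in mapping.items():
            fh.write(f"{s}\t{label}\n")


# ---------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------

def filter_variants(
    gm: GenotypeMatrix,
    min_depth: int = 3,
    max_missing: float = 0.20,
    min_maf: float = 0.05,
):
    """Apply the standard post-calling site filters.

    A site passes iff, after masking genotypes with depth <= ``min_depth``
    to MISSING, (a) the missing fraction within EVERY population is
    strictly below ``max_missing`` and (b) the minor allele frequency on
    non-missing alleles is strictly above ``min_maf``.  All boundaries are
    exclusive.

    Returns the filtered matrix (with depth-masked calls) and a
    :class:`FilterReport` attributing each failed site to the first
    failing rule in the order depth -> missingness -> MAF.
    """
    if not (0.0 <= max_missing <= 1.0) or not (0.0 <= min_maf <= 1.0):
        raise ValueError("max_missing and min_maf must lie in [0, 1]")

    calls = gm.calls.copy()
    if gm.depth is None:
        if min_depth > 0:
            logger.warning("filter_variants: no depth information; depth filter skipped")
        masked = calls
    else:
        masked = calls.copy()
        masked[gm.depth <= min_depth] = MISSING

    pop_rows = {p: gm.sample_indices(p) for p in gm.populations}

    def _missing_ok(mat) -> np.ndarray:
        ok = np.ones(gm.n_variants, dtype=bool)
        for rows in pop_rows.values():
            frac = (mat[rows, :] == MISSING).mean(axis=0)
            ok &= frac < max_missing
        return ok

    miss_ok_masked = _missing_ok(masked)
    miss_ok_raw = _missing_ok(calls)

    nonmiss = masked != MISSING
    n_alleles = 2 * nonmiss.sum(axis=0)
    alt = np.where(nonmiss, masked, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    maf_ok = (maf > min_maf) & (n_alleles > 0)

    fail_depth = (~miss_ok_masked) & miss_ok_raw
    fail_missing = ~miss_ok_raw
    fail_maf = miss_ok_masked & ~maf_ok
    passed = miss_ok_masked & maf_ok

    report = FilterReport(
        n_input=gm.n_variants,
        n_fail_depth=int(fail_depth.sum()),
        n_fail_missing=int(fail_missing.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_pass=int(passed.sum()),
    )
    logger.info(
        "filter_variants: %d sites in, %d pass (%d depth / %d missing / %d maf failed)",
        report.n_input, report.n_pass,
        report.n_fail_depth, report.n_fail_missing, report.n_fail_maf,
    )

    out = GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        pop_of=dict(gm.pop_of),
        group_of=None if gm.group_of is None else dict(gm.group_of),
        variants=[v for v, keep in zip(gm.variants, passed) if keep],
        calls=masked[:, passed].copy(),
        depth=None if gm.depth is None else gm.depth[:, passed].copy(),
    )
    return out, report
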