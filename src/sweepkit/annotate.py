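"""Gene overlap of selection-signal regions and gene-set enrichment.

Genes arrive as GFF3 (``gene`` features, 1-based inclusive) or BED4+
(0-based half-open); internally everything is 0-based half-open.  A gene
is assigned to a region when they share at least one bp; strand is
ignored.  Enrichment of a candidate gene list against user-supplied gene
sets uses the hypergeometric upper tail with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, NamedTuple, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class GeneInterval(NamedTuple):
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "."


@dataclass
class EnrichmentRow:
    set_id: str
    k: int  # candidates in set
    K: int  # set size in universe
    n: int  # candidate count
    N: int  # universe size
    p: float
    fdr: float


def _parse_gff_attributes(field: str) -> dict:
    out = {}
    for part in field.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, val = part.split("=", 1)
        elif " " in part:
            key, val = part.split(None, 1)
            val = val.strip('"')
        else:
            continue
        out[key.strip()] = val.strip()
    return out


def read_annotation(path) -> List[GeneInterval]:
    """Read gene intervals from a GFF3 (type ``gene``) or BED4+ file.

    GFF coordinates (1-based inclusive) are converted to 0-based
    half-open.  Duplicate gene identifiers are rejected.
    """
    path = str(path)
    is_gff = path.endswith((".gff", ".gff3"))
    genes: List[GeneInterval] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##gff"):
                    is_gff = True
                continue
            fields = line.split("\t")
            try:
                if is_gff or len(fields) == 9:
                    if len(fields) != 9:
                        raise ValueError("expected 9 GFF columns")
                    if fields[2] != "gene":
                        continue
                    attrs = _parse_gff_attributes(fields[8])
                    gid = attrs.get("ID") or attrs.get("gene_id")
                    if not gid:
                        raise ValueError("gene row lacks ID/gene_id attribute")
                    start = int(fields[3]) - 1
                    end = int(fields[4])
                    strand = fields[6] if fields[6] in "+-" else "."
                    iv = GeneInterval(gid, fields[0], start, end, strand)
                else:
                    if len(fields) < 4:
                        raise ValueError("expected BED4+ columns")
                    strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
                    iv = GeneInterval(fields[3], fields[0], int(fields[1]), int(fields[2]), strand)
                if iv.start >= iv.end:
                    raise ValueError(f"empty interval for gene {iv.gene_id}")
                if iv.gene_id in seen:
                    raise ValueError(f"duplicate gene id {iv.gene_id!r}")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            seen.add(iv.gene_id)
            genes.append(iv)
    return genes


def write_bed(genes: Sequence[GeneInterval], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def overlap_genes(regions, genes: Sequence[GeneInterval]) -> Dict:
    """Map each region to the position-ordered gene ids overlapping it
    by >= 1 bp (intervals half-open; strand ignored)."""
    by_chrom: Dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.start, g.end, g.gene_id))
    out = {}
    for r in regions:
        hits = [
            g.gene_id
            for g in by_chrom.get(r.chrom, [])
            if g.start < r.end and g.end > r.start
        ]
        out[(r.chrom, r.start, r.end)] = hits
    return out


def hypergeom_enrich(candidates: Iterable[str], gene_sets: Dict[str, Iterable[str]],
                     universe: Iterable[str]) -> List[EnrichmentRow]:
    """Hypergeometric upper-tail enrichment with BH FDR across sets.

    p = P[X >= k] with X ~ Hypergeom(N, K, n): N genes in the universe,
    K of them in the set, n candidates drawn, k of those in the set.
    Gene sets are intersected with the universe first.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    cand = set(candidates)
    if not cand <= uni:
        raise ValueError(f"candidates outside universe: {sorted(cand - uni)[:5]}")
    N, n = len(uni), len(cand)
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & uni
        K = len(members)
        if K == 0:
            continue
        k = len(cand & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(EnrichmentRow(set_id, k, K, n, N, min(1.0, p), math.nan))
    if rows:
        fdr = multipletests([r.p for r in rows], method="fdr_bh")[1]
        for r, q in zip(rows, fdr):
            r.fdr = float(q)
        rows.sort(key=lambda r: (r.p, r.set_id))
    return rows


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.set_id, r.k, r.K, r.n, r.N, r.p, r.fdr) for r in rows],
        columns=["set_id", "k", "K", "n", "N", "p", "fdr"],
    )


def read_gene_sets(path) -> Dict[str, list]:
    """TSV: set_id TAB gene[,gene...] or one gene per extra column."""
    sets: Dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            genes = []
            for fld in parts[1:]:
                genes.extend(g for g in fld.split(",") if g)
            sets.setdefault(parts[0], []).extend(genes)
    return sets
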