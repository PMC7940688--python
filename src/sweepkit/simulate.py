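"""Synthetic genotype cohorts with known population structure and sweeps.

The cohort generator follows the Balding-Nichols model: each SNP draws an
ancestral frequency p ~ Uniform(maf_floor, 1 - maf_floor), each population
then draws its own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) — whose
expected differentiation from the ancestral pool is the FST-like
parameter F — and diploid genotypes are Binomial(2, p_pop), i.e. in
Hardy-Weinberg proportions within populations.  Selective sweeps are
implanted by pushing the population frequency toward the nearer boundary:
p' = p(1-intensity) if p < 0.5 else p + (1-p) intensity, which deflates
within-population diversity by roughly (1 - intensity).

Defaults mirror a four-breed resequencing design: 4 populations of 30
diploids each, 10,000 SNPs on one 10-Mb chromosome (200 windows at
100 kb / 50 kb), F = 0.10, one sweep region of intensity 0.9 spanning two
full windows implanted in both populations of the first contrast group,
2% missing genotypes.

A separate Markov-copying generator produces chromosomes with a known
analytic LD decay: adjacent-locus haplotype correlation exp(-rho * d)
gives expected r^2(d) ~ exp(-2 rho d) and half-decay distance
ln(2) / (2 rho).
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .variant_io import MISSING, GenotypeMatrix, VariantSite, write_popmap, write_vcf

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Parameters of the Balding-Nichols cohort generator."""

    n_pops: int = 4
    n_per_pop: int = 30
    chrom_lengths: dict = field(default_factory=lambda: {"1": 10_000_000})
    n_snps: int = 10_000
    fst_param: float = 0.10
    #: (chrom, start, end, target_pop, intensity); 0-based half-open bp
    sweep_regions: list = field(
        default_factory=lambda: [
            ("1", 5_000_000, 5_150_000, "pop1", 0.9),
            ("1", 5_000_000, 5_150_000, "pop2", 0.9),
        ]
    )
    missing_rate: float = 0.02
    maf_floor: float = 0.05
    seed: int = 0
    mean_depth: float = 10.0

    def validate(self) -> None:
        if self.n_pops < 1 or self.n_per_pop < 1 or self.n_snps < 1:
            raise ValueError("n_pops, n_per_pop, n_snps must be positive")
        if not 0 < self.fst_param < 1:
            raise ValueError("fst_param must lie in (0, 1)")
        for rate in (self.missing_rate,):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if not 0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in (0, 0.5)")
        pops = {f"pop{i + 1}" for i in range(self.n_pops)}
        for chrom, start, end, target, intensity in self.sweep_regions:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"sweep chromosome {chrom!r} not simulated")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError("sweep region outside chromosome")
            if target not in pops:
                raise ValueError(f"sweep target {target!r} is not a simulated population")
            if not 0 < intensity <= 1:
                raise ValueError("sweep intensity must lie in (0, 1]")

    @property
    def pop_labels(self) -> List[str]:
        return [f"pop{i + 1}" for i in range(self.n_pops)]


def _draw_positions(rng, chrom_lengths, n_snps):
    """SNP positions allocated proportionally to chromosome length,
    distinct and sorted within each chromosome (1-based)."""
    chroms = list(chrom_lengths)
    total = sum(chrom_lengths.values())
    out: List[Tuple[str, int]] = []
    remaining = n_snps
    for i, chrom in enumerate(chroms):
        share = (
            remaining
            if i == len(chroms) - 1
            else int(round(n_snps * chrom_lengths[chrom] / total))
        )
        share = min(share, remaining, chrom_lengths[chrom])
        pos = rng.choice(chrom_lengths[chrom], size=share, replace=False) + 1
        out.extend((chrom, int(p)) for p in np.sort(pos))
        remaining -= share
    return out


def simulate_cohort(cfg: SimConfig):
    """Generate a cohort under ``cfg``; returns (GenotypeMatrix, truth dict).

    The truth record holds the latent ancestral and per-population allele
    frequencies and the sweep coordinates, making downstream property
    checks self-validating.  Fully reproducible from ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    loci = _draw_positions(rng, cfg.chrom_lengths, cfg.n_snps)
    m = len(loci)
    pops = cfg.pop_labels
    F = cfg.fst_param

    p_anc = rng.uniform(cfg.maf_floor, 1 - cfg.maf_floor, size=m)
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    p_pop = np.empty((cfg.n_pops, m))
    for k in range(cfg.n_pops):
        p_pop[k] = np.clip(rng.beta(a, b), 0.0, 1.0)

    # implant sweeps: push the population frequency toward the nearer boundary
    chrom_arr = np.array([c for c, _ in loci])
    pos_arr = np.array([p for _, p in loci])
    for chrom, start, end, target, intensity in cfg.sweep_regions:
        k = pops.index(target)
        in_region = (chrom_arr == chrom) & (pos_arr > start) & (pos_arr <= end)
        p = p_pop[k, in_region]
        p_pop[k, in_region] = np.where(p < 0.5, p * (1 - intensity), p + (1 - p) * intensity)

    n_samples = cfg.n_pops * cfg.n_per_pop
    calls = np.empty((n_samples, m), dtype=np.int8)
    for k in range(cfg.n_pops):
        rows = slice(k * cfg.n_per_pop, (k + 1) * cfg.n_per_pop)
        calls[rows] = rng.binomial(2, p_pop[k], size=(cfg.n_per_pop, m)).astype(np.int8)

    depth = rng.poisson(cfg.mean_depth, size=calls.shape).astype(np.int32)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING

    refalt = rng.integers(0, 4, size=(m, 2))
    refalt[:, 1] = (refalt[:, 0] + 1 + refalt[:, 1] % 3) % 4
    variants = [
        VariantSite(c, p, _BASES[refalt[i, 0]], _BASES[refalt[i, 1]])
        for i, (c, p) in enumerate(loci)
    ]

    sample_ids = [f"{pop}_s{j + 1:02d}" for pop in pops for j in range(cfg.n_per_pop)]
    pop_of = {s: s.rsplit("_", 1)[0] for s in sample_ids}
    half = (cfg.n_pops + 1) // 2
    group_of = {
        s: ("horned" if pops.index(pop_of[s]) < half else "polled") for s in sample_ids
    } if cfg.n_pops >= 2 else None

    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        pop_of=pop_of,
        group_of=group_of,
        variants=variants,
        calls=calls,
        depth=depth,
    )
    truth = {
        "config": {
            "n_pops": cfg.n_pops,
            "n_per_pop": cfg.n_per_pop,
            "chrom_lengths": dict(cfg.chrom_lengths),
            "n_snps": cfg.n_snps,
            "fst_param": cfg.fst_param,
            "sweep_regions": [list(r) for r in cfg.sweep_regions],
            "missing_rate": cfg.missing_rate,
            "maf_floor": cfg.maf_floor,
            "seed": cfg.seed,
        },
        "p_ancestral": p_anc.tolist(),
        "p_population": {pop: p_pop[k].tolist() for k, pop in enumerate(pops)},
        "positions": [[c, int(p)] for c, p in loci],
        "sweep_regions": [list(r) for r in cfg.sweep_regions],
    }
    return gm, truth


def simulate_ld_chromosome(n_samples: int, n_snps: int, spacing_bp: int,
                           rho: float, seed: int) -> Tuple[GenotypeMatrix, dict]:
    """Markov-copying haplotypes with analytic LD decay.

    Adjacent loci keep the previous allele with probability (1 + c)/2,
    c = exp(-rho * spacing), so allele correlation between loci d bp apart
    is exp(-rho d) and expected r^2(d) = exp(-2 rho d); the analytic
    half-decay distance is ln(2)/(2 rho).  Haplotypes are paired into
    diploids.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_samples
    c = math.exp(-rho * spacing_bp)
    hap = np.empty((n_hap, n_snps), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < 0.5
    # keep-or-flip chain: per-step allele correlation is exactly c
    keep = rng.random((n_hap, n_snps - 1)) < (1 + c) / 2
    for j in range(1, n_snps):
        stay = keep[:, j - 1]
        hap[:, j] = np.where(stay, hap[:, j - 1], 1 - hap[:, j - 1])
    calls = (hap[0::2] + hap[1::2]).astype(np.int8)

    variants = [
        VariantSite("1", (j + 1) * spacing_bp, "A", "G") for j in range(n_snps)
    ]
    sample_ids = [f"s{i + 1:03d}" for i in range(n_samples)]
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        pop_of={s: "pop1" for s in sample_ids},
        variants=variants,
        calls=calls,
    )
    truth = {"rho": rho, "half_decay_bp": math.log(2) / (2 * rho), "spacing_bp": spacing_bp}
    return gm, truth


def write_fixture(outdir, cfg: Optional[SimConfig] = None, gene_span: int = 20_000,
                  gene_tile: int = 50_000) -> dict:
    """Write a complete pipeline fixture: VCF, popmap, groupmap, a toy GFF3
    with genes tiled every ``gene_tile`` bp, a gene-set TSV and the truth
    JSON.  Returns the path map.  Deterministic for a fixed config."""
    cfg = cfg or SimConfig()
    os.makedirs(outdir, exist_ok=True)
    gm, truth = simulate_cohort(cfg)

    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "popmap": os.path.join(outdir, "popmap.tsv"),
        "groupmap": os.path.join(outdir, "groupmap.tsv"),
        "gff": os.path.join(outdir, "genes.gff3"),
        "gene_sets": os.path.join(outdir, "gene_sets.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_vcf(gm, paths["vcf"])
    write_popmap(gm.pop_of, paths["popmap"])
    if gm.group_of:
        write_popmap(gm.group_of, paths["groupmap"])
    else:
        paths.pop("groupmap")

    sweep_genes = []
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in cfg.chrom_lengths.items():
            for i, start0 in enumerate(range(10_000, length - gene_span, gene_tile)):
                gid = f"gene_{chrom}_{i + 1:04d}"
                fh.write(
                    f"{chrom}\tsweepkit\tgene\t{start0 + 1}\t{start0 + gene_span}\t.\t+\t.\t"
                    f"ID={gid}\n"
                )
                for c2, s2, e2, _t, _i in cfg.sweep_regions:
                    if c2 == chrom and start0 < e2 and start0 + gene_span > s2:
                        if gid not in sweep_genes:
                            sweep_genes.append(gid)

    with open(paths["gene_sets"], "w") as fh:
        fh.write("sweep_set\t" + ",".join(sweep_genes) + "\n")
        decoys = [f"gene_1_{i:04d}" for i in (1, 3, 5, 7, 9, 11, 13, 15)]
        fh.write("decoy_set\t" + ",".join(decoys) + "\n")

    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def checksum_dir(path) -> dict:
    """SHA-256 of every regular file under ``path`` (determinism checks)."""
    sums = {}
    for root, _dirs, files in os.walk(path):
        for name in sorted(files):
            fp = os.path.join(root, name)
            with open(fp, "rb") as fh:
                sums[os.path.relpath(fp, path)] = hashlib.sha256(fh.read()).hexdigest()
    return sums
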