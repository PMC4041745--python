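"""Synthetic case-control GWAS scans with planted pathway signals.

The generator builds a toy genome (genes laid left to right with geometric
lengths and gaps), a gene-set collection that overlaps by chance the way
GO/KEGG categories do, and an allelic association scan contrasting
``n_cases`` short-survival cases against ``n_controls`` long-survival
controls (369 vs 369 by default).  Alleles are sampled independently per
individual chromosome, so Hardy-Weinberg equilibrium holds by construction;
genotype-level QC (call rate, HWE exact test) is therefore out of scope,
and the default ``maf_low=0.05`` mirrors the usual MAF >= 5% marker filter.

Signal is planted at the pathway level: each gene set named in
``causal_sets`` has a fraction ``causal_gene_frac`` of its member genes
given one causal SNP, placed uniformly within the gene body.  A causal SNP
with minor-allele frequency *f* in controls has case allele frequency

    f' = theta * f / (1 - f + theta * f),

i.e. a per-allele odds ratio of ``theta``; ``theta = 1`` is the exact null.
Every random draw flows from ``SimulationSpec.seed``, so an identical spec
yields byte-identical association files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .io_formats import GeneModel, GeneSet, SnpAssociation

__all__ = [
    "SimulationSpec",
    "AlleleCounts",
    "GroundTruth",
    "simulate_genome",
    "simulate_genesets",
    "allelic_test",
    "allelic_pvalues",
    "simulate_scan",
]

# stage constants mixed into the seed sequence so the genome, the gene sets
# and the scan draw from decoupled streams of one spec-level seed
_STREAM_GENOME = 0
_STREAM_SETS = 1
_STREAM_SCAN = 2


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic study.

    Defaults describe the reference condition used throughout the test
    suite: a 2,000-gene toy genome (mean gene 15 kb, mean gap 30 kb, 100
    genes per chromosome), about three SNPs per gene body plus an equal
    number of intergenic SNPs, MAF ~ U(0.05, 0.5), and a 369 vs 369
    case-control contrast.
    """

    n_cases: int = 369
    n_controls: int = 369
    n_genes: int = 2000
    gene_len: float = 15_000.0
    gap_len: float = 30_000.0
    snps_per_gene: float = 3.0
    intergenic_snp_frac: float = 0.5
    maf_low: float = 0.05
    maf_high: float = 0.5
    theta: float = 1.8
    causal_sets: tuple = ()
    causal_gene_frac: float = 0.5
    seed: int = 0
    genes_per_chrom: int = 100

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValidationError("n_cases and n_controls must be positive")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not 0.0 < self.maf_low < self.maf_high <= 0.5:
            raise ValidationError("require 0 < maf_low < maf_high <= 0.5")
        if self.theta < 1.0:
            raise ValidationError("theta must be >= 1 (code the risk allele as alternate)")
        if not 0.0 < self.causal_gene_frac <= 1.0:
            raise ValidationError("causal_gene_frac must be in (0, 1]")
        if not 0.0 <= self.intergenic_snp_frac < 1.0:
            raise ValidationError("intergenic_snp_frac must be in [0, 1)")
        if self.gene_len < 1 or self.gap_len < 1:
            raise ValidationError("gene_len and gap_len must be >= 1")


@dataclass(frozen=True)
class AlleleCounts:
    """2x2 allele-count table: (reference, alternate) x (cases, controls)."""

    a: int  # case reference alleles
    b: int  # case alternate alleles
    c: int  # control reference alleles
    d: int  # control alternate alleles

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("allele counts must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Evaluation key recording every planted entity."""

    causal_set_ids: frozenset = field(default_factory=frozenset)
    causal_gene_ids: frozenset = field(default_factory=frozenset)
    causal_snp_ids: frozenset = field(default_factory=frozenset)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def simulate_genome(spec: SimulationSpec) -> list:
    """Lay ``n_genes`` non-overlapping genes left to right.

    Lengths and gaps are geometric with means ``gene_len`` and ``gap_len``;
    chromosomes hold ``genes_per_chrom`` genes each and restart at
    coordinate 0.  Deterministic given ``spec.seed``.
    """
    rng = _rng(spec.seed, _STREAM_GENOME)
    lengths = rng.geometric(1.0 / spec.gene_len, size=spec.n_genes)
    gaps = rng.geometric(1.0 / spec.gap_len, size=spec.n_genes)
    strands = rng.choice(["+", "-"], size=spec.n_genes)
    genes: list[GeneModel] = []
    cursor = 0
    for i in range(spec.n_genes):
        chrom_idx, within = divmod(i, spec.genes_per_chrom)
        if within == 0:
            cursor = 0
        start = cursor + int(gaps[i])
        end = start + int(lengths[i])
        cursor = end
        genes.append(
            GeneModel(
                gene_id=f"G{i + 1:05d}",
                symbol=f"G{i + 1:05d}",
                chrom=f"chr{chrom_idx + 1}",
                start=start,
                end=end,
                strand=str(strands[i]),
            )
        )
    return genes


def simulate_genesets(
    genes: Sequence, n_sets: int, size_mean: float = 25.0, seed: int = 0
) -> list:
    """Draw ``n_sets`` categories whose members are sampled uniformly with
    replacement across all genes (then de-duplicated), so distinct sets
    overlap by chance as real GO/KEGG categories do."""
    if n_sets < 1:
        raise ValidationError("n_sets must be >= 1")
    if size_mean < 2:
        raise ValidationError("size_mean must be >= 2 so categories can pass the min-gene filter")
    rng = _rng(seed, _STREAM_SETS)
    gene_ids = [g.gene_id for g in genes]
    sets: list[GeneSet] = []
    for i in range(n_sets):
        size = max(2, int(rng.poisson(size_mean)))
        members = frozenset(rng.choice(gene_ids, size=size, replace=True))
        sets.append(
            GeneSet(
                set_id=f"SET{i + 1:04d}",
                name=f"synthetic category {i + 1}",
                namespace="SYNTH",
                members=members,
            )
        )
    return sets


def allelic_test(counts: AlleleCounts, yates: bool = False) -> float:
    """Allelic association p-value: Pearson chi-square (1 df) on the 2x2
    allele-count table, without continuity correction by default (the usual
    "allelic" model); ``yates=True`` applies the Yates correction.

    A monomorphic marker (either allele absent from the pooled sample)
    carries no information and returns p = 1.
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    row1, row2 = a + b, c + d
    if row1 == 0 or row2 == 0:
        raise ValidationError("both case and control allele totals must be positive")
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        return 1.0
    n = row1 + row2
    delta = abs(a * d - b * c)
    if yates:
        delta = max(0.0, delta - n / 2.0)
    x2 = n * delta * delta / (row1 * row2 * col1 * col2)
    return float(stats.chi2.sf(x2, df=1))


def allelic_pvalues(
    alt_cases: np.ndarray,
    alt_controls: np.ndarray,
    n_cases: int,
    n_controls: int,
    yates: bool = False,
) -> np.ndarray:
    """Vectorized :func:`allelic_test` over arrays of alternate-allele counts."""
    b = np.asarray(alt_cases, dtype=np.float64)
    d = np.asarray(alt_controls, dtype=np.float64)
    a = 2.0 * n_cases - b
    c = 2.0 * n_controls - d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    n = row1 + row2
    delta = np.abs(a * d - b * c)
    if yates:
        delta = np.maximum(0.0, delta - n / 2.0)
    denom = row1 * row2 * col1 * col2
    monomorphic = (col1 == 0) | (col2 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        x2 = np.where(monomorphic, 0.0, n * delta * delta / np.where(denom == 0, 1.0, denom))
    p = stats.chi2.sf(x2, df=1)
    return np.where(monomorphic, 1.0, p)


def case_allele_frequency(f: float | np.ndarray, theta: float) -> float | np.ndarray:
    """Map a control allele frequency to the case frequency implied by a
    per-allele odds ratio ``theta``: f' = theta*f / (1 - f + theta*f)."""
    return theta * f / (1.0 - f + theta * f)


def simulate_scan(
    spec: SimulationSpec, genes: Sequence, sets: Sequence
) -> tuple[list, GroundTruth]:
    """Simulate one allelic association scan over ``genes``.

    Null SNPs draw case and control alternate-allele counts from
    Binomial(2N, f) with a shared f ~ U(maf_low, maf_high); each causal
    gene (a ``causal_gene_frac`` subsample of every set in
    ``spec.causal_sets``) receives one extra causal SNP whose case draw
    uses the odds-ratio-shifted frequency.  Returns the associations sorted
    by genomic position together with the ground-truth key.
    """
    set_by_id = {s.set_id: s for s in sets}
    for sid in spec.causal_sets:
        if sid not in set_by_id:
            raise ValidationError(f"causal set {sid!r} not present in the collection")

    rng = _rng(spec.seed, _STREAM_SCAN)
    gene_by_id = {g.gene_id: g for g in genes}

    # pick causal genes per causal set (sorted ids -> deterministic)
    causal_genes: set[str] = set()
    for sid in spec.causal_sets:
        members = sorted(set_by_id[sid].members & gene_by_id.keys())
        k = max(1, int(round(spec.causal_gene_frac * len(members))))
        causal_genes.update(rng.choice(members, size=k, replace=False))

    # genic null SNPs
    positions: list[tuple[str, int, bool]] = []  # (chrom, pos0, causal)
    n_per_gene = rng.poisson(spec.snps_per_gene, size=len(genes))
    for g, cnt in zip(genes, n_per_gene):
        for pos0 in rng.integers(g.start, g.end, size=int(cnt)):
            positions.append((g.chrom, int(pos0), False))

    # intergenic null SNPs, uniform over the inter-gene gaps
    n_genic = len(positions)
    frac = spec.intergenic_snp_frac
    n_inter = int(round(n_genic * frac / (1.0 - frac))) if frac > 0 else 0
    if n_inter > 0:
        gap_intervals: list[tuple[str, int, int]] = []
        prev_end: dict[str, int] = {}
        for g in genes:  # genes are in coordinate order per chromosome
            lo = prev_end.get(g.chrom, 0)
            if g.start > lo:
                gap_intervals.append((g.chrom, lo, g.start))
            prev_end[g.chrom] = max(prev_end.get(g.chrom, 0), g.end)
        gap_lens = np.array([hi - lo for _, lo, hi in gap_intervals], dtype=np.float64)
        picks = rng.choice(len(gap_intervals), size=n_inter, p=gap_lens / gap_lens.sum())
        offsets = rng.random(n_inter)
        for idx, u in zip(picks, offsets):
            chrom, lo, hi = gap_intervals[int(idx)]
            positions.append((chrom, lo + int(u * (hi - lo)), False))

    # one causal SNP per causal gene, uniform within the gene body
    for gid in sorted(causal_genes):
        g = gene_by_id[gid]
        positions.append((g.chrom, int(rng.integers(g.start, g.end)), True))

    # sort by genomic coordinate, assign ids, then draw allele counts
    chrom_order = {g.chrom: i for i, g in enumerate(genes)}
    positions.sort(key=lambda t: (chrom_order.get(t[0], 1 << 30), t[1], t[2]))
    n_snps = len(positions)
    maf = rng.uniform(spec.maf_low, spec.maf_high, size=n_snps)
    causal_mask = np.array([c for _, _, c in positions])
    f_case = np.where(causal_mask, case_allele_frequency(maf, spec.theta), maf)
    alt_cases = rng.binomial(2 * spec.n_cases, f_case)
    alt_controls = rng.binomial(2 * spec.n_controls, maf)
    pvals = allelic_pvalues(alt_cases, alt_controls, spec.n_cases, spec.n_controls)

    snps: list[SnpAssociation] = []
    causal_snp_ids: set[str] = set()
    for i, ((chrom, pos0, causal), p) in enumerate(zip(positions, pvals)):
        snp_id = f"rs{i + 1:06d}"
        snps.append(SnpAssociation(snp_id=snp_id, chrom=chrom, pos=pos0 + 1, p=float(p)))
        if causal:
            causal_snp_ids.add(snp_id)

    truth = GroundTruth(
        causal_set_ids=frozenset(spec.causal_sets),
        causal_gene_ids=frozenset(causal_genes),
        causal_snp_ids=frozenset(causal_snp_ids),
    )
    return snps, truth
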