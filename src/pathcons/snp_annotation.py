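"""SNP-to-gene assignment, best-SNP-per-gene collapse, gene-list building.

Two window schemes are supported: ``window_kb = 0`` assigns a SNP to every
gene whose annotated span contains it (the union of 5'UTR, exons, introns
and 3'UTR equals the transcript span, so sub-features are not needed), and
``window_kb = w`` extends each gene symmetrically by ``w`` kb of flanking
sequence on both sides to capture regulatory-region SNPs.  A SNP at
1-based position ``pos`` maps to gene ``g`` iff

    start(g) - 1000*w  <=  pos - 1  <  end(g) + 1000*w

on the same chromosome.  A SNP falling in the overlap of two windows counts
for both genes; the per-gene collapse to the single best (minimum-p) SNP
keeps large genes from dominating downstream enrichment.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError
from .io_formats import normalize_chrom

__all__ = [
    "AnnotationConfig",
    "GeneScore",
    "GeneListSpec",
    "GeneList",
    "map_snps_to_genes",
    "best_snp_per_gene",
    "make_gene_list",
    "gene_list_label",
    "summarize_counts",
]


@dataclass(frozen=True)
class AnnotationConfig:
    """Flank width in kb; 0 means gene body only."""

    window_kb: float = 0.0

    def __post_init__(self) -> None:
        if self.window_kb < 0:
            raise ValidationError("window_kb must be >= 0")


@dataclass(frozen=True)
class GeneScore:
    """A gene's best (minimum) SNP p-value under one window scheme."""

    gene_id: str
    best_p: float
    best_snp_id: str
    n_snps: int


@dataclass(frozen=True)
class GeneListSpec:
    """Allelic p-value threshold (strict ``<``) plus the window it pairs with."""

    cutoff: float
    window_kb: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff <= 1.0:
            raise ValidationError("cutoff must be in (0, 1]")
        if self.window_kb < 0:
            raise ValidationError("window_kb must be >= 0")


@dataclass(frozen=True)
class GeneList:
    """An ordered, duplicate-free gene list tagged with its provenance label."""

    label: str
    genes: tuple

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene list {self.label!r} contains duplicates")

    def as_set(self) -> set:
        return set(self.genes)


def gene_list_label(cutoff: float, window_kb: float) -> str:
    """Canonical label, e.g. ``0.01`` or ``0.01+20kb``."""
    base = f"{cutoff:g}"
    return base if window_kb == 0 else f"{base}+{window_kb:g}kb"


def map_snps_to_genes(
    snps: Sequence, genes: Sequence, config: AnnotationConfig
) -> dict:
    """Map SNPs to genes under the configured flank.

    Returns ``{gene_id: [SnpAssociation, ...]}`` with each gene's SNPs in
    input order; genes with no mapped SNP are absent.  Chromosome labels are
    harmonized by stripping an optional ``chr`` prefix on both sides.
    """
    flank = int(round(config.window_kb * 1000))
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        trees[normalize_chrom(g.chrom)].addi(g.start - flank, g.end + flank, g.gene_id)

    mapping: dict[str, list] = defaultdict(list)
    for snp in snps:
        tree = trees.get(normalize_chrom(snp.chrom))
        if tree is None:
            continue
        hits = tree[snp.pos - 1]  # 0-based point query into half-open windows
        for iv in sorted(hits, key=lambda iv: iv.data):
            mapping[iv.data].append(snp)
    return dict(mapping)


def best_snp_per_gene(mapping: Mapping) -> list:
    """Collapse each gene's mapped SNPs to the one with the lowest p-value.

    Ties on p break by smaller position, then lexicographic SNP id, so the
    result is deterministic.  Output is sorted by gene id.
    """
    scores: list[GeneScore] = []
    for gene_id in sorted(mapping):
        snps = mapping[gene_id]
        if not snps:
            continue
        best = min(snps, key=lambda s: (s.p, s.pos, s.snp_id))
        scores.append(
            GeneScore(gene_id=gene_id, best_p=best.p, best_snp_id=best.snp_id, n_snps=len(snps))
        )
    return scores


def make_gene_list(scores: Iterable, spec: GeneListSpec) -> GeneList:
    """Genes with best_p strictly below the cutoff, ascending by best_p
    (ties by gene id)."""
    kept = sorted(
        (s for s in scores if s.best_p < spec.cutoff), key=lambda s: (s.best_p, s.gene_id)
    )
    return GeneList(
        label=gene_list_label(spec.cutoff, spec.window_kb),
        genes=tuple(s.gene_id for s in kept),
    )


def summarize_counts(
    snps: Sequence,
    genes: Sequence,
    cutoffs: Sequence[float],
    windows: Sequence[float],
) -> pd.DataFrame:
    """Count table over the cutoff x window grid: total SNPs below each
    cutoff, SNPs mapped to at least one gene, and distinct genes."""
    if not cutoffs:
        raise ValidationError("cutoffs must be non-empty")
    rows = []
    for window_kb in windows:
        mapping = map_snps_to_genes(snps, genes, AnnotationConfig(window_kb=window_kb))
        mapped_ids = {s.snp_id for snps_ in mapping.values() for s in snps_}
        p_by_snp = {s.snp_id: s.p for s in snps}
        scores = best_snp_per_gene(mapping)
        for cutoff in cutoffs:
            n_total = sum(1 for s in snps if s.p < cutoff)
            n_mapped = sum(1 for sid in mapped_ids if p_by_snp[sid] < cutoff)
            n_genes = sum(1 for sc in scores if sc.best_p < cutoff)
            rows.append(
                {
                    "cutoff": cutoff,
                    "window_kb": window_kb,
                    "n_snps_total": n_total,
                    "n_snps_mapped": n_mapped,
                    "n_genes": n_genes,
                }
            )
    return pd.DataFrame(rows)
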