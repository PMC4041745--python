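"""Over-representation analysis (ORA) of a gene list against a collection.

For a background universe of ``N`` genes containing a category of size
``K``, a query list of size ``n`` sharing ``k`` genes with the category is
scored by the upper tail P(X >= k) of Hypergeometric(N, K, n) — identical
to the one-sided Fisher exact test on the 2x2 table [[k, n-k],
[K-k, N-K-n+k]].  Binomial and chi-square statistics are offered as
alternatives because published enrichment web tools disagree in exactly
this choice; a *method profile* (statistic, multiple-testing correction,
adjusted-p threshold) stands in for one such tool, and running several
profiles over the same lists supplies the independent verdicts the
consensus stage needs.

All counts are taken after intersecting query and category with the
background; the correction family is all categories of the collection with
at least one background gene, so collections (e.g. GO vs KEGG) supplied
separately are corrected separately.  The paper-style reporting filter —
adjusted p below alpha AND at least ``min_genes`` query genes in the
category — sets the ``enriched`` flag but never suppresses a record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .snp_annotation import GeneList

logger = logging.getLogger(__name__)

__all__ = [
    "Background",
    "MethodConfig",
    "EnrichmentRecord",
    "EnrichmentTable",
    "DEFAULT_PROFILES",
    "hypergeometric_tail",
    "binomial_tail",
    "chisq_2x2",
    "adjust_pvalues",
    "run_ora",
]

_STATISTICS = ("hypergeometric", "binomial", "chisq", "chisq_yates")
_CORRECTIONS = ("BH", "bonferroni", "holm", "none")


@dataclass(frozen=True)
class Background:
    """The reference gene universe; all counts are relative to it."""

    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("background universe is empty")

    @property
    def N(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class MethodConfig:
    """One named method profile: statistic + correction + threshold."""

    name: str
    statistic: str = "hypergeometric"
    correction: str = "BH"
    alpha: float = 0.05
    min_genes: int = 2

    def __post_init__(self) -> None:
        if self.statistic not in _STATISTICS:
            raise ValidationError(f"unknown statistic {self.statistic!r}")
        if self.correction not in _CORRECTIONS:
            raise ValidationError(f"unknown correction {self.correction!r}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValidationError("alpha must be in (0, 1]")
        if self.min_genes < 1:
            raise ValidationError("min_genes must be >= 1")


#: Four profiles spanning the stringency range observed across published
#: enrichment tools: a default adjusted-0.05 tester, a stricter BH-0.01
#: chi-square tester, and two raw-p testers at 1e-4 and 1e-6 (the working
#: cutoffs that high-output tools require to yield comparable list sizes).
DEFAULT_PROFILES: dict = {
    "default-0.05": MethodConfig("default-0.05", "hypergeometric", "BH", 0.05),
    "mid-0.01": MethodConfig("mid-0.01", "chisq", "BH", 0.01),
    "strict-1e4": MethodConfig("strict-1e4", "binomial", "none", 1e-4),
    "strict-1e6": MethodConfig("strict-1e6", "hypergeometric", "none", 1e-6),
}


@dataclass(frozen=True)
class EnrichmentRecord:
    """One category's 2x2 counts and (raw, adjusted) enrichment p-values."""

    set_id: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    enriched: bool
    overlap_genes: tuple


@dataclass(frozen=True)
class EnrichmentTable:
    """All records of one (gene list x collection x method profile) run."""

    records: tuple
    m: int  # number of categories the correction spanned
    config: MethodConfig
    list_label: str
    collection: str = ""

    def enriched_ids(self) -> set:
        return {r.set_id for r in self.records if r.enriched}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "set_id": r.set_id,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "enriched": r.enriched,
                "overlap_genes": ",".join(r.overlap_genes),
                "list_label": self.list_label,
                "collection": self.collection,
                "method": self.config.name,
            }
            for r in self.records
        ]
        columns = [
            "set_id", "k", "K", "n", "N", "p_raw", "p_adj",
            "enriched", "overlap_genes", "list_label", "collection", "method",
        ]
        return pd.DataFrame(rows, columns=columns)


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"inconsistent 2x2 counts k={k}, K={K}, n={n}, N={N}")


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n): the classic
    ORA p-value, equal to the one-sided Fisher exact test."""
    _check_counts(k, K, n, N)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def binomial_tail(k: int, K: int, n: int, N: int) -> float:
    """Binomial approximation used by several enrichment tools:
    P(Bin(n, K/N) >= k)."""
    _check_counts(k, K, n, N)
    if N == 0:
        raise ValidationError("N must be positive")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, K / N))


def chisq_2x2(k: int, K: int, n: int, N: int, yates: bool = False) -> float:
    """One-sided Pearson chi-square on the ORA 2x2 table.

    Returns p = 1 when the category is at or below its expected count
    (under-representation never scores) and when any cell expectation is
    zero (category untestable at this universe)."""
    _check_counts(k, K, n, N)
    expected_k = n * K / N if N else 0.0
    if k <= expected_k:
        return 1.0
    table = np.array([[k, n - k], [K - k, N - K - n + k]], dtype=np.float64)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / N
    if np.any(expected == 0):
        logger.warning("chisq_2x2: zero expected cell for k=%d K=%d n=%d N=%d", k, K, n, N)
        return 1.0
    delta = np.abs(table - expected)
    if yates:
        delta = np.maximum(0.0, delta - 0.5)
    x2 = float((delta * delta / expected).sum())
    return float(stats.chi2.sf(x2, df=1))


def adjust_pvalues(pvals: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment, preserving input order.

    ``BH`` is Benjamini-Hochberg step-up, ``holm`` the step-down Bonferroni,
    ``bonferroni`` the plain m-fold inflation, ``none`` the identity.
    """
    pvals = np.asarray(list(pvals), dtype=np.float64)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if method == "none":
        return pvals.copy()
    sm_method = {"BH": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}.get(method)
    if sm_method is None:
        raise ValidationError(f"unknown correction {method!r}")
    return multipletests(pvals, method=sm_method)[1]


_STAT_FUNCS = {
    "hypergeometric": hypergeometric_tail,
    "binomial": binomial_tail,
    "chisq": chisq_2x2,
    "chisq_yates": lambda k, K, n, N: chisq_2x2(k, K, n, N, yates=True),
}


def run_ora(
    gene_list: GeneList,
    collection: Iterable,
    background: Background,
    config: MethodConfig,
    collection_name: str = "",
) -> EnrichmentTable:
    """Score every category of one collection against one gene list.

    Query, categories and counts are all clipped to the background; the
    correction spans every category with K >= 1 in the background (``m`` on
    the returned table).  Record order follows collection order, and the
    result is invariant to query order and duplicate query genes.
    """
    query = set(gene_list.genes) & background.genes
    if not query:
        raise ValidationError(
            f"gene list {gene_list.label!r} has no genes in the background universe"
        )
    n, N = len(query), background.N
    stat = _STAT_FUNCS[config.statistic]

    tested: list[tuple] = []
    for gs in collection:
        members = gs.members & background.genes
        K = len(members)
        if K == 0:
            continue
        overlap = sorted(query & members)
        k = len(overlap)
        tested.append((gs.set_id, k, K, tuple(overlap), stat(k, K, n, N)))

    p_adj = adjust_pvalues([t[4] for t in tested], config.correction)
    records = tuple(
        EnrichmentRecord(
            set_id=set_id,
            k=k,
            K=K,
            n=n,
            N=N,
            p_raw=p_raw,
            p_adj=float(pa),
            enriched=bool(pa < config.alpha and k >= config.min_genes),
            overlap_genes=overlap,
        )
        for (set_id, k, K, overlap, p_raw), pa in zip(tested, p_adj)
    )
    return EnrichmentTable(
        records=records,
        m=len(records),
        config=config,
        list_label=gene_list.label,
        collection=collection_name,
    )
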