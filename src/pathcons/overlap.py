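"""Gene-overlap cross-tabulation between enriched categories.

Two views mirror the two published table styles: full category membership,
and membership restricted to a query gene list (the genes the GWAS itself
contributed).  Because "x% overlap" is ambiguous about its denominator,
percentages are reported relative to *both* categories of each pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["OverlapMatrix", "overlap_matrix", "overlap_percentages"]


@dataclass(frozen=True)
class OverlapMatrix:
    """Symmetric shared-member counts; the diagonal holds category sizes
    under the chosen restriction."""

    ids: tuple
    counts: np.ndarray
    diagonal: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("counts shape does not match ids")
        if not np.array_equal(c, c.T):
            raise ValidationError("overlap counts must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        m = self.counts.copy()
        np.fill_diagonal(m, self.diagonal)
        return pd.DataFrame(m, index=list(self.ids), columns=list(self.ids))


def overlap_matrix(categories: Sequence, restrict_to=None) -> OverlapMatrix:
    """Pairwise shared-member counts between categories.

    ``restrict_to`` (a GeneList or any iterable of gene ids) intersects
    every category first; the diagonal then holds the restricted sizes.
    """
    categories = list(categories)
    if len(categories) < 2:
        raise ValidationError("need at least two categories to cross-tabulate")
    if restrict_to is not None:
        allowed = set(restrict_to.genes) if hasattr(restrict_to, "genes") else set(restrict_to)
        memberships = [set(c.members) & allowed for c in categories]
    else:
        memberships = [set(c.members) for c in categories]
    ids = tuple(c.set_id for c in categories)
    k = len(ids)
    counts = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            counts[i, j] = counts[j, i] = len(memberships[i] & memberships[j])
    diagonal = np.array([len(m) for m in memberships], dtype=int)
    return OverlapMatrix(ids=ids, counts=counts, diagonal=diagonal)


def overlap_percentages(matrix: OverlapMatrix) -> pd.DataFrame:
    """Long-format pair table with the shared count as a percentage of each
    category's size.  A zero-size category (possible under restriction)
    yields NaN — undefined, not 0."""
    rows = []
    k = len(matrix.ids)
    for i in range(k):
        for j in range(i + 1, k):
            size_a = int(matrix.diagonal[i])
            size_b = int(matrix.diagonal[j])
            shared = int(matrix.counts[i, j])
            rows.append(
                {
                    "id_a": matrix.ids[i],
                    "id_b": matrix.ids[j],
                    "shared": shared,
                    "size_a": size_a,
                    "size_b": size_b,
                    "pct_of_a": 100.0 * shared / size_a if size_a else float("nan"),
                    "pct_of_b": 100.0 * shared / size_b if size_b else float("nan"),
                }
            )
    return pd.DataFrame(
        rows, columns=["id_a", "id_b", "shared", "size_a", "size_b", "pct_of_a", "pct_of_b"]
    )
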