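"""Cross-list / cross-method consensus over enrichment results.

A method profile *supports* a category only if it flags it enriched in
every required gene list (by default the four lists: allelic-p cutoffs 0.01
and 0.005, each with and without the ±20 kb flank).  A category is
*consistently enriched* when at least ``min_methods`` profiles support it
("more than one tool", i.e. >= 2, by default).  Both filters are
anti-monotone: adding a required list or raising ``min_methods`` can only
shrink the consistent set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError

__all__ = [
    "ConsensusSpec",
    "ConsensusRow",
    "ConsensusReport",
    "per_method_consistent",
    "consensus_across_methods",
    "build_consensus",
]

DEFAULT_REQUIRED_LISTS = ("0.01", "0.01+20kb", "0.005", "0.005+20kb")


@dataclass(frozen=True)
class ConsensusSpec:
    required_lists: tuple = DEFAULT_REQUIRED_LISTS
    min_methods: int = 2

    def __post_init__(self) -> None:
        if not self.required_lists:
            raise ValidationError("required_lists must be non-empty")
        if self.min_methods < 1:
            raise ValidationError("min_methods must be >= 1")


@dataclass(frozen=True)
class ConsensusRow:
    set_id: str
    n_methods: int
    methods: tuple
    consistent: bool


@dataclass(frozen=True)
class ConsensusReport:
    """Per-category support across method profiles.

    ``rows`` are sorted by descending support then set id;  ``matrix`` (when
    built from full tables) records the per-(list x method) enriched flag.
    """

    rows: tuple
    spec: ConsensusSpec
    matrix: pd.DataFrame | None = field(default=None, compare=False)

    def consistent_ids(self) -> set:
        return {r.set_id for r in self.rows if r.consistent}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "set_id": r.set_id,
                    "n_methods": r.n_methods,
                    "methods": ",".join(r.methods),
                    "consistent": r.consistent,
                }
                for r in self.rows
            ],
            columns=["set_id", "n_methods", "methods", "consistent"],
        )


def per_method_consistent(tables: Sequence, required_lists: Sequence[str]) -> set:
    """Categories one method flags enriched in *every* required list.

    ``tables`` must hold exactly the tables of one method profile over the
    required lists (tables from extra lists are ignored; a missing required
    list raises)."""
    by_label: dict[str, set] = {}
    names = {t.config.name for t in tables}
    if len(names) > 1:
        raise ValidationError(f"tables mix method profiles: {sorted(names)}")
    for t in tables:
        by_label.setdefault(t.list_label, set()).update(t.enriched_ids())
    missing = [lbl for lbl in required_lists if lbl not in by_label]
    if missing:
        raise ValidationError(f"no enrichment table for required list(s): {', '.join(missing)}")
    out = set(by_label[required_lists[0]])
    for lbl in required_lists[1:]:
        out &= by_label[lbl]
    return out


def consensus_across_methods(
    per_method_sets: Mapping[str, set], spec: ConsensusSpec
) -> ConsensusReport:
    """Combine per-method consistent sets into the final report."""
    if len(per_method_sets) < spec.min_methods:
        raise ValidationError(
            f"{len(per_method_sets)} method set(s) supplied but min_methods={spec.min_methods}"
        )
    union: set = set()
    for s in per_method_sets.values():
        union |= s
    rows = []
    for set_id in union:
        methods = tuple(sorted(m for m, s in per_method_sets.items() if set_id in s))
        rows.append(
            ConsensusRow(
                set_id=set_id,
                n_methods=len(methods),
                methods=methods,
                consistent=len(methods) >= spec.min_methods,
            )
        )
    rows.sort(key=lambda r: (-r.n_methods, r.set_id))
    return ConsensusReport(rows=tuple(rows), spec=spec)


def build_consensus(tables: Iterable, spec: ConsensusSpec) -> ConsensusReport:
    """Full pipeline entry: group enrichment tables by method profile,
    apply the all-required-lists rule per method, then the cross-method
    count rule; also assembles the (list x method) support matrix."""
    tables = list(tables)
    by_method: dict[str, list] = {}
    for t in tables:
        by_method.setdefault(t.config.name, []).append(t)
    per_method = {
        name: per_method_consistent(ts, spec.required_lists) for name, ts in by_method.items()
    }
    report = consensus_across_methods(per_method, spec)

    ids = sorted(report.consistent_ids() | {r.set_id for r in report.rows})
    if ids:
        cols = pd.MultiIndex.from_tuples(
            sorted({(t.config.name, t.list_label) for t in tables}),
            names=["method", "list"],
        )
        matrix = pd.DataFrame(False, index=ids, columns=cols)
        for t in tables:
            flagged = t.enriched_ids()
            for sid in ids:
                if sid in flagged:
                    matrix.loc[sid, (t.config.name, t.list_label)] = True
    else:
        matrix = pd.DataFrame()
    return ConsensusReport(rows=report.rows, spec=spec, matrix=matrix)
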