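"""Simultaneous enrichment of two gene lists against one collection.

Both lists are scored with the same ORA configuration; categories reaching
``min_genes`` overlap in *both* lists are jointly ranked by the better of
the two adjusted p-values (ties by the other p, then set id) and flagged
``dual_significant`` when both adjusted p-values pass the FDR threshold
``q``.  Swapping the lists swaps the p columns and preserves every flag.
"""

from __future__ import annotations

from dataclasses import dataclass

from .enrichment import Background, MethodConfig, run_ora

__all__ = ["ComparisonRecord", "compare_two_lists"]


@dataclass(frozen=True)
class ComparisonRecord:
    set_id: str
    k_a: int
    k_b: int
    p_adj_a: float
    p_adj_b: float
    rank: int
    dual_significant: bool


def compare_two_lists(
    list_a,
    list_b,
    collection,
    background: Background,
    config: MethodConfig,
    q: float = 0.05,
) -> list:
    """Joint ORA of two gene lists; see module docstring for the contract."""
    table_a = run_ora(list_a, collection, background, config)
    table_b = run_ora(list_b, collection, background, config)
    rec_a = {r.set_id: r for r in table_a.records}
    rec_b = {r.set_id: r for r in table_b.records}

    joint = []
    for set_id, ra in rec_a.items():
        rb = rec_b.get(set_id)
        if rb is None:
            continue
        if ra.k < config.min_genes or rb.k < config.min_genes:
            continue
        joint.append((set_id, ra, rb))

    joint.sort(
        key=lambda t: (
            min(t[1].p_adj, t[2].p_adj),
            max(t[1].p_adj, t[2].p_adj),
            t[0],
        )
    )
    return [
        ComparisonRecord(
            set_id=set_id,
            k_a=ra.k,
            k_b=rb.k,
            p_adj_a=ra.p_adj,
            p_adj_b=rb.p_adj,
            rank=i + 1,
            dual_significant=bool(ra.p_adj < q and rb.p_adj < q),
        )
        for i, (set_id, ra, rb) in enumerate(joint)
    ]
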