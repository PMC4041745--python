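"""End-to-end orchestration: simulate -> annotate -> enrich -> consensus ->
overlap, with a JSON run manifest for provenance.

The same flow is exposed twice: :func:`consensus_from_scan` works on
in-memory objects (used by the test suite and the acceptance script), and
:func:`run_pipeline` drives the file-based stages the CLI wires together,
recording config, input checksums, library versions and per-stage record
counts in ``manifest.json``.  Identical config + inputs give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .consensus import ConsensusReport, ConsensusSpec, build_consensus
from .enrichment import DEFAULT_PROFILES, Background, run_ora
from .errors import ValidationError
from .io_formats import (
    read_associations,
    read_gene_models,
    read_gmt,
    write_associations,
    write_gene_models,
    write_gmt,
    write_table,
)
from .overlap import overlap_matrix, overlap_percentages
from .snp_annotation import (
    AnnotationConfig,
    GeneListSpec,
    best_snp_per_gene,
    gene_list_label,
    make_gene_list,
    map_snps_to_genes,
    summarize_counts,
)
from .synthetic_data import SimulationSpec, simulate_genesets, simulate_genome, simulate_scan

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "consensus_from_scan", "build_gene_lists"]

DEFAULT_CUTOFFS = (0.01, 0.005)
DEFAULT_WINDOWS = (0.0, 20.0)


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run depends on.

    Either supply ``assoc``/``genes``/``gmts`` paths, or set ``simulate``
    (plus ``n_sets``/``set_size_mean``) to generate them into ``out_dir``.
    """

    out_dir: str
    assoc: str | None = None
    genes: str | None = None
    gmts: tuple = ()
    cutoffs: tuple = DEFAULT_CUTOFFS
    windows: tuple = DEFAULT_WINDOWS
    profiles: tuple = tuple(DEFAULT_PROFILES)
    min_methods: int = 2
    simulate: SimulationSpec | None = None
    n_sets: int = 200
    set_size_mean: float = 25.0

    def validate_paths(self) -> None:
        if self.simulate is None:
            for label, p in (("assoc", self.assoc), ("genes", self.genes)):
                if p is None:
                    raise ValidationError(f"config lacks {label!r} and simulate is off")
                if not Path(p).exists():
                    raise ValidationError(f"{label} path does not exist: {p}")
            if not self.gmts:
                raise ValidationError("config lists no GMT collections")
            for p in self.gmts:
                if not Path(p).exists():
                    raise ValidationError(f"GMT path does not exist: {p}")
        for name in self.profiles:
            if name not in DEFAULT_PROFILES:
                raise ValidationError(f"unknown method profile {name!r}")


def build_gene_lists(snps, genes, cutoffs: Sequence[float], windows: Sequence[float]):
    """All (cutoff x window) gene lists plus the per-window score tables."""
    lists = {}
    scores_by_window = {}
    for w in windows:
        mapping = map_snps_to_genes(snps, genes, AnnotationConfig(window_kb=w))
        scores = best_snp_per_gene(mapping)
        scores_by_window[w] = scores
        for cutoff in cutoffs:
            gl = make_gene_list(scores, GeneListSpec(cutoff=cutoff, window_kb=w))
            lists[gl.label] = gl
    return lists, scores_by_window


def consensus_from_scan(
    snps,
    genes,
    collections: Mapping[str, Sequence],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    windows: Sequence[float] = DEFAULT_WINDOWS,
    profiles: Mapping | None = None,
    min_methods: int = 2,
) -> tuple[ConsensusReport, list]:
    """In-memory pipeline core: gene lists -> ORA per (list x collection x
    profile) -> consensus.  Returns the report and all enrichment tables."""
    profiles = dict(profiles) if profiles is not None else dict(DEFAULT_PROFILES)
    lists, _ = build_gene_lists(snps, genes, cutoffs, windows)
    background = Background(genes=frozenset(g.gene_id for g in genes))
    tables = []
    for gl in lists.values():
        for coll_name, coll in collections.items():
            for prof in profiles.values():
                tables.append(run_ora(gl, coll, background, prof, collection_name=coll_name))
    required = tuple(gene_list_label(c, w) for c in cutoffs for w in windows)
    spec = ConsensusSpec(required_lists=required, min_methods=min_methods)
    return build_consensus(tables, spec), tables


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on disk under ``config.out_dir``; return the manifest."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _jsonable(config),
        "versions": {
            "pathcons": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "inputs": {},
    }

    assoc_path, genes_path, gmt_paths = config.assoc, config.genes, list(config.gmts)
    truth = None
    if config.simulate is not None:
        logger.info("[simulate] generating synthetic scan (seed=%d)", config.simulate.seed)
        spec = config.simulate
        genes = simulate_genome(spec)
        sets = simulate_genesets(genes, config.n_sets, config.set_size_mean, seed=spec.seed)
        snps, truth = simulate_scan(spec, genes, sets)
        assoc_path = str(out / "associations.tsv")
        genes_path = str(out / "genes.bed")
        gmt_paths = [str(out / "genesets.gmt")]
        write_associations(snps, assoc_path)
        write_gene_models(genes, genes_path)
        write_gmt(sets, gmt_paths[0])
        (out / "ground_truth.json").write_text(
            json.dumps(
                {
                    "causal_set_ids": sorted(truth.causal_set_ids),
                    "causal_gene_ids": sorted(truth.causal_gene_ids),
                    "causal_snp_ids": sorted(truth.causal_snp_ids),
                    "spec": _jsonable(spec),
                },
                indent=2,
                sort_keys=True,
            )
        )
        manifest["stages"]["simulate"] = {
            "n_snps": len(snps),
            "n_genes": len(genes),
            "n_sets": len(sets),
            "n_causal_genes": len(truth.causal_gene_ids),
        }

    for p in [assoc_path, genes_path, *gmt_paths]:
        manifest["inputs"][str(p)] = _sha256(p)

    logger.info("[annotate] reading %s", assoc_path)
    snps, n_dropped = read_associations(assoc_path)
    genes = read_gene_models(genes_path)
    lists, _scores = build_gene_lists(snps, genes, config.cutoffs, config.windows)
    for gl in lists.values():
        path = out / f"genelist.{gl.label}.txt"
        path.write_text("".join(f"{g}\n" for g in gl.genes))
    summary = summarize_counts(snps, genes, sorted(config.cutoffs, reverse=True), config.windows)
    write_table(summary, out / "annotation_summary.tsv")
    manifest["stages"]["annotate"] = {
        "n_snps": len(snps),
        "n_dropped_rows": n_dropped,
        "n_genes": len(genes),
        "gene_list_sizes": {lbl: len(gl.genes) for lbl, gl in lists.items()},
    }

    logger.info("[enrich] %d list(s) x %d collection(s) x %d profile(s)",
                len(lists), len(gmt_paths), len(config.profiles))
    collections = {Path(p).stem: read_gmt(p) for p in gmt_paths}
    background = Background(genes=frozenset(g.gene_id for g in genes))
    profiles = {name: DEFAULT_PROFILES[name] for name in config.profiles}
    tables = []
    for gl in lists.values():
        for coll_name, coll in collections.items():
            for prof in profiles.values():
                t = run_ora(gl, coll, background, prof, collection_name=coll_name)
                tables.append(t)
                write_table(
                    t.to_frame(), out / f"enrichment.{gl.label}.{coll_name}.{prof.name}.tsv"
                )
    manifest["stages"]["enrich"] = {
        "n_tables": len(tables),
        "n_enriched_flags": sum(len(t.enriched_ids()) for t in tables),
    }

    logger.info("[consensus] combining %d tables", len(tables))
    required = tuple(gene_list_label(c, w) for c in config.cutoffs for w in config.windows)
    cspec = ConsensusSpec(required_lists=required, min_methods=config.min_methods)
    report = build_consensus(tables, cspec)
    # Table-style report: add category name plus K (background category
    # size) and k (query genes) taken from the primary list's tables
    names = {s.set_id: s.name for coll in collections.values() for s in coll}
    primary = {
        r.set_id: r
        for t in tables
        if t.list_label == required[0] and t.config.name == config.profiles[0]
        for r in t.records
    }
    df = report.to_frame()
    df.insert(1, "name", df.set_id.map(lambda sid: names.get(sid, "")))
    df.insert(2, "n_category_genes", df.set_id.map(lambda sid: primary[sid].K))
    df.insert(3, "n_query_genes", df.set_id.map(lambda sid: primary[sid].k))
    write_table(df, out / "consensus.tsv")
    matrix = report.matrix
    support = (
        {f"{m}|{l}": {sid: bool(matrix.loc[sid, (m, l)]) for sid in matrix.index}
         for m, l in matrix.columns}
        if matrix is not None and not matrix.empty
        else {}
    )
    (out / "consensus_support.json").write_text(json.dumps(support, indent=2, sort_keys=True))
    consistent = sorted(report.consistent_ids())
    manifest["stages"]["consensus"] = {
        "n_consistent": len(consistent),
        "consistent_ids": consistent,
    }
    if truth is not None:
        manifest["stages"]["consensus"]["recovered_causal_sets"] = sorted(
            set(consistent) & truth.causal_set_ids
        )

    if len(consistent) >= 2:
        logger.info("[overlap] cross-tabulating %d consistent categories", len(consistent))
        all_sets = {s.set_id: s for coll in collections.values() for s in coll}
        cats = [all_sets[sid] for sid in consistent]
        m_full = overlap_matrix(cats)
        write_table(m_full.to_frame().reset_index(names="set_id"), out / "overlap_full.tsv")
        write_table(overlap_percentages(m_full), out / "overlap_full_pairs.tsv")
        first_label = gene_list_label(config.cutoffs[0], config.windows[0])
        m_restr = overlap_matrix(cats, restrict_to=lists[first_label])
        write_table(m_restr.to_frame().reset_index(names="set_id"), out / "overlap_restricted.tsv")
        write_table(overlap_percentages(m_restr), out / "overlap_restricted_pairs.tsv")
        manifest["stages"]["overlap"] = {"n_categories": len(consistent)}
    else:
        manifest["stages"]["overlap"] = {"n_categories": len(consistent), "skipped": True}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
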