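"""Readers and writers for every external file the pipeline touches.

Formats and conventions
-----------------------
* Association tables are PLINK-style whitespace- or tab-delimited text with
  a header containing at least ``SNP``, ``CHR``, ``BP``, ``P`` (case
  insensitive; extra columns are ignored).  SNP positions are 1-based.
* Gene models are BED4/BED6: 0-based half-open intervals, optional strand
  in column 6.
* Gene-set collections are GMT: ``set_id<TAB>description<TAB>member...``.
* All tabular output is TSV with a header; floating-point values are written
  in scientific notation with 17 significant digits so that a write/read
  round trip reproduces every record exactly and output bytes are identical
  across runs.

Chromosome labels from different files are compared after stripping an
optional ``chr`` prefix, so ``chr1`` and ``1`` refer to the same chromosome.
SNP positions are converted to 0-based (``pos - 1``) in exactly one place,
:func:`pathcons.snp_annotation.map_snps_to_genes`; each file format keeps
its native convention on disk.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SnpAssociation",
    "GeneModel",
    "GeneSet",
    "AssociationRead",
    "normalize_chrom",
    "read_associations",
    "read_gene_models",
    "read_gmt",
    "read_gene_list_file",
    "write_associations",
    "write_gene_models",
    "write_gmt",
    "write_table",
]


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's genomic position and allelic-test p-value.

    ``pos`` is 1-based (PLINK/VCF convention).
    """

    snp_id: str
    chrom: str
    pos: int
    p: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: position must be >= 1, got {self.pos}")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"{self.snp_id}: p-value {self.p} outside [0, 1]")


@dataclass(frozen=True)
class GeneModel:
    """A gene locus as a 0-based half-open interval (BED convention)."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"{self.gene_id}: empty or inverted interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class GeneSet:
    """A functional category (GO-term- or KEGG-pathway-like gene set)."""

    set_id: str
    name: str
    namespace: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"{self.set_id}: gene set has no members")


class AssociationRead(NamedTuple):
    """Result of reading an association table: the kept records plus the
    number of rows dropped for a missing/non-numeric p-value."""

    records: list
    n_dropped: int


def normalize_chrom(label: str) -> str:
    """Strip an optional ``chr`` prefix so mixed dialects compare equal."""
    label = str(label)
    return label[3:] if label.lower().startswith("chr") else label


def read_associations(path: str | PathLike) -> AssociationRead:
    """Read a PLINK-style association table.

    Rows whose P field is missing or non-numeric are dropped and counted
    (GWAS exports routinely contain NA p-values); every other malformation
    raises.  Output order equals file order.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    cols = {c.upper(): c for c in df.columns}
    missing = [name for name in ("SNP", "CHR", "BP", "P") if name not in cols]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {', '.join(missing)}")

    def _parse_p(v):
        # python float() is correctly rounded; pandas' fast parser is not
        try:
            return float(v)
        except (TypeError, ValueError):
            return float("nan")

    p = df[cols["P"]].map(_parse_p)
    keep = p.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with missing/non-numeric P", path, n_dropped)

    records: list[SnpAssociation] = []
    seen: set[str] = set()
    for snp_id, chrom, bp, pval in zip(
        df.loc[keep, cols["SNP"]],
        df.loc[keep, cols["CHR"]],
        df.loc[keep, cols["BP"]],
        p[keep],
    ):
        try:
            pos = int(bp)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-integer BP value {bp!r} for SNP {snp_id}") from exc
        if snp_id in seen:
            raise ValidationError(f"{path}: duplicate SNP id {snp_id!r}")
        seen.add(snp_id)
        records.append(SnpAssociation(snp_id=str(snp_id), chrom=str(chrom), pos=pos, p=float(pval)))
    return AssociationRead(records, n_dropped)


def read_gene_models(path: str | PathLike) -> list:
    """Read gene loci from a BED4/BED6 file.

    Half-open 0-based intervals are preserved exactly; a missing strand
    column yields ``strand='unknown'``.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED line has {len(fields)} column(s), need >= 4")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start {start} >= end {end} (empty interval)"
                )
            if name in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene id {name!r}")
            seen.add(name)
            strand = "unknown"
            if len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            genes.append(
                GeneModel(gene_id=name, symbol=name, chrom=chrom, start=start, end=end, strand=strand)
            )
    return genes


def read_gmt(path: str | PathLike, namespace: str | None = None) -> list:
    """Read a gene-set collection from a GMT file.

    Duplicate members within a line are de-duplicated; empty member fields
    are skipped.  ``namespace`` defaults to the file's stem.
    """
    if namespace is None:
        namespace = Path(path).stem
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} column(s), need >= 3"
                )
            set_id, name = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m.strip())
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {set_id!r} has no members")
            if set_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            seen.add(set_id)
            sets.append(GeneSet(set_id=set_id, name=name, namespace=namespace, members=members))
    return sets


def read_gene_list_file(path: str | PathLike) -> list:
    """Read a plain gene list: one gene id per line, optional further
    tab-separated columns (e.g. best p) ignored.  Order preserved."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.append(line.split("\t")[0].split()[0])
    return genes


def _format_value(value) -> str:
    if isinstance(value, float):
        return f"{value:.16e}"
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, (frozenset, set)):
        return ",".join(sorted(str(v) for v in value))
    if isinstance(value, (list, tuple)):
        return ",".join(str(v) for v in value)
    return str(value)


def write_table(records, path: str | PathLike, columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records (dataclasses or a DataFrame) as TSV.

    Floats are rendered as 17-significant-digit scientific notation, and
    set-valued fields as comma-joined sorted strings, so identical inputs
    always produce identical bytes and a read-back reproduces each float
    exactly.  For an empty record list, ``columns`` supplies the header.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        for col in df.columns:
            df[col] = df[col].map(_format_value)
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        return

    records = list(records)
    if not records:
        if columns is None:
            raise ValidationError("empty record list requires explicit columns for the header")
        Path(path).write_text("\t".join(columns) + "\n")
        return
    first = records[0]
    if not dataclasses.is_dataclass(first):
        raise ValidationError(f"write_table expects dataclass records, got {type(first).__name__}")
    names = [f.name for f in dataclasses.fields(first)]
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for rec in records:
            fh.write("\t".join(_format_value(getattr(rec, n)) for n in names) + "\n")


def write_associations(records: Iterable, path: str | PathLike) -> None:
    """Write SNP associations in the PLINK-style format read_associations reads."""
    with open(path, "w") as fh:
        fh.write("SNP\tCHR\tBP\tP\n")
        for r in records:
            fh.write(f"{r.snp_id}\t{r.chrom}\t{r.pos}\t{r.p:.16e}\n")


def write_gene_models(genes: Iterable, path: str | PathLike) -> None:
    """Write gene models as BED6 (score column 0; unknown strand as '.')."""
    strand_out = {"+": "+", "-": "-", "unknown": "."}
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{strand_out[g.strand]}\n")


def write_gmt(sets: Iterable, path: str | PathLike) -> None:
    """Write gene sets as GMT; members sorted for deterministic bytes."""
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.members)]) + "\n")
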