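"""Readers/writers for the pipeline's file formats and the in-memory records.

All in-memory genomic intervals are 0-based half-open. GTF input (1-based,
inclusive) is converted exactly once, at parse time. Count matrices are genes
x samples with an accompanying design table mapping each sample to a
condition label and replicate index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "GeneAnnotation",
    "ReadIntervalSet",
    "CountMatrixParseError",
    "DesignError",
    "AnnotationError",
    "read_count_matrix",
    "write_count_matrix",
    "read_design",
    "read_gene_annotation",
    "read_reads_bed",
    "write_reads_bed",
    "write_results_table",
    "read_results_table",
]


class CountMatrixParseError(ValueError):
    """A count-matrix cell failed integer parsing, or gene ids are duplicated."""


class DesignError(ValueError):
    """Sample/design mismatch."""


class AnnotationError(ValueError):
    """Malformed gene annotation input."""


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts plus the sample design.

    Attributes
    ----------
    counts : DataFrame
        Integer counts, index = gene ids, columns = sample ids, order as read.
    design : DataFrame
        Indexed by sample id with columns ``condition`` and ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise CountMatrixParseError(f"duplicate gene id {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise CountMatrixParseError(f"duplicate sample id {dup!r}")
        missing = [s for s in self.counts.columns if s not in self.design.index]
        if missing:
            raise DesignError(f"samples missing from design: {missing}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise CountMatrixParseError("counts must be integers")
        if (vals < 0).any():
            raise CountMatrixParseError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def condition_samples(self, condition: str) -> list[str]:
        sel = self.design.index[self.design["condition"] == condition]
        return [s for s in sel if s in self.counts.columns]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            c = self.design.loc[s, "condition"]
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class GeneAnnotation:
    """Per-gene chrom/strand/TSS/biotype records.

    ``table`` is indexed by gene id with columns ``chrom``, ``strand``
    (``+``/``-``), ``tss`` (0-based position of the first transcribed base)
    and ``biotype`` (``protein_coding``, ``lincRNA`` or ``other``).
    """

    table: pd.DataFrame
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise AnnotationError(f"duplicate gene id {dup!r}")
        bad = ~self.table["strand"].isin(["+", "-"])
        if bad.any():
            raise AnnotationError(
                f"invalid strand for {list(self.table.index[bad])[:5]}"
            )
        if (self.table["tss"] < 0).any():
            raise AnnotationError("tss must be >= 0")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def lincrna_ids(self) -> pd.Index:
        return self.table.index[self.table["biotype"] == "lincRNA"]

    def subset(self, gene_ids) -> "GeneAnnotation":
        return GeneAnnotation(self.table.loc[gene_ids])


@dataclass
class ReadIntervalSet:
    """Aligned-read intervals for one ChIP sample.

    ``reads`` has columns chrom, start, end (0-based half-open), name, strand,
    mapq, unique. ``library_size`` is the total record count before any
    filtering, so it never undercounts the retained reads.
    """

    reads: pd.DataFrame
    library_size: int
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if len(self.reads) and (self.reads["start"] >= self.reads["end"]).any():
            raise ValueError("read intervals must satisfy start < end")
        if self.library_size < len(self.reads):
            raise ValueError("library_size smaller than retained read count")

    def __len__(self) -> int:
        return len(self.reads)


_READ_COLUMNS = ["chrom", "start", "end", "name", "strand", "mapq", "unique"]


def read_design(path) -> pd.DataFrame:
    """Read a sample design TSV with columns sample_id, condition, replicate."""
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    for col in ("sample_id", "condition"):
        if col not in design.columns:
            raise DesignError(f"design file lacks required column {col!r}")
    if "replicate" not in design.columns:
        design["replicate"] = design.groupby("condition").cumcount() + 1
    if design["sample_id"].duplicated().any():
        raise DesignError("duplicate sample_id in design")
    return design.set_index("sample_id")


def read_count_matrix(path, design_path) -> CountMatrix:
    """Read a genes x samples TSV (first column gene id, header = sample ids).

    Every cell must parse as an integer; the offending gene/sample is named
    otherwise. Row and column order are preserved.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    parsed = {}
    for sample in raw.columns:
        col = pd.to_numeric(raw[sample], errors="coerce")
        bad = col.isna() | (col != np.floor(col))
        if bad.any():
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            cell = raw.loc[gene, sample]
            raise CountMatrixParseError(
                f"non-integer count {cell!r} at gene {gene!r}, sample {sample!r}"
            )
        parsed[sample] = col.astype(np.int64)
    counts = pd.DataFrame(parsed, index=raw.index)
    design = read_design(design_path)
    return CountMatrix(counts=counts, design=design)


def write_count_matrix(cm: CountMatrix, path, design_path=None) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")
    if design_path is not None:
        cm.design.to_csv(design_path, sep="\t", index_label="sample_id")


def read_gene_annotation(path, feature: str = "gene") -> GeneAnnotation:
    """Parse gene-level records from a GTF file into a :class:`GeneAnnotation`.

    The TSS is derived strand-aware from the 1-based inclusive GTF
    coordinates: ``start - 1`` (0-based) on ``+``, ``end - 1`` on ``-``.
    Records without a usable strand are rejected with a warning; a missing
    biotype attribute defaults to ``protein_coding``. Duplicate gene ids are
    an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    rows = []
    n_rejected = 0
    for feat in db.features_of_type(feature, order_by=None):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        if feat.strand not in ("+", "-"):
            n_rejected += 1
            continue
        biotype = (
            feat.attributes.get("gene_biotype", None)
            or feat.attributes.get("gene_type", None)
            or ["protein_coding"]
        )[0]
        if biotype not in ("protein_coding", "lincRNA"):
            biotype = "other"
        # feat.start is 1-based inclusive; feat.end inclusive.
        tss = feat.start - 1 if feat.strand == "+" else feat.end - 1
        rows.append((gene_id, feat.seqid, feat.strand, tss, biotype))
    if n_rejected:
        warnings.warn(
            f"rejected {n_rejected} annotation record(s) without a valid strand",
            stacklevel=2,
        )
    table = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "tss", "biotype"]
    ).set_index("gene_id")
    return GeneAnnotation(table=table, n_rejected=n_rejected)


def write_gene_annotation_gtf(ann: GeneAnnotation, path, source: str = "corego") -> None:
    """Write gene records as GTF (1-based inclusive), inverting the TSS rule.

    Genes are emitted as 1 kb features anchored at the TSS; sufficient for
    round-tripping the fields the pipeline uses (chrom, strand, tss, biotype).
    """
    with open(path, "w") as fh:
        for gene_id, row in ann.table.iterrows():
            if row["strand"] == "+":
                start1 = row["tss"] + 1
                end1 = start1 + 999
            else:
                end1 = row["tss"] + 1
                start1 = max(1, end1 - 999)
            attrs = f'gene_id "{gene_id}"; gene_biotype "{row["biotype"]}";'
            fh.write(
                f"{row['chrom']}\t{source}\tgene\t{start1}\t{end1}\t.\t"
                f"{row['strand']}\t.\t{attrs}\n"
            )


def read_reads_bed(path) -> ReadIntervalSet:
    """Read aligned reads from a BED6+1 file (MAPQ in column 7).

    When column 7 is absent, MAPQ falls back to the BED score column 5 —
    common aligner exports place MAPQ there. Uniqueness is not encoded in
    public BED exports, so every record is flagged unique here and
    multi-mappers are screened later by the MAPQ filter. Lines with
    start >= end are rejected and counted. ``library_size`` is the total
    number of data lines in the file.
    """
    rows = []
    total = 0
    n_rejected = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            total += 1
            parts = line.split("\t")
            if len(parts) < 6:
                n_rejected += 1
                continue
            chrom, start, end, name, score, strand = parts[:6]
            start, end = int(start), int(end)
            if start >= end:
                n_rejected += 1
                continue
            mapq = int(float(parts[6])) if len(parts) >= 7 else int(float(score))
            rows.append((chrom, start, end, name, strand, mapq, True))
    if n_rejected:
        logger.warning("rejected %d malformed BED line(s)", n_rejected)
    reads = pd.DataFrame(rows, columns=_READ_COLUMNS)
    if not len(rows):
        reads = reads.astype(
            {"start": np.int64, "end": np.int64, "mapq": np.int64, "unique": bool}
        )
    return ReadIntervalSet(reads=reads, library_size=total, n_rejected=n_rejected)


def write_reads_bed(reads: ReadIntervalSet, path) -> None:
    """Write reads as BED6+1 with MAPQ in column 7 (score column mirrors it)."""
    with open(path, "w") as fh:
        for row in reads.reads.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t"
                f"{row.mapq}\t{row.strand}\t{row.mapq}\n"
            )


def write_results_table(table: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    """Write a per-gene results table as TSV, floats at 9 significant digits."""
    if table.columns.empty:
        raise ValueError("results table must have at least one column")
    table.to_csv(path, sep="\t", index_label=index_label, float_format="%.9g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
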