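"""Promoter-level ChIP enrichment analysis.

Reads are MAPQ/uniqueness filtered, counted over strand-aware promoter
windows (2.5 kb upstream to 500 b downstream of the TSS by default), turned
into library-size-normalized IP/control enrichment ratios, and summarized as
a sorted-bin co-binding profile: genes sorted by the anchor factor's
enrichment, fixed-size bins, per-bin mean log2 ratios for the anchor and
each co-factor.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .formats_io import GeneAnnotation, ReadIntervalSet

__all__ = [
    "filter_reads",
    "promoter_windows",
    "count_reads_in_windows",
    "enrichment_ratios",
    "binned_profile",
    "chip_enrichment_table",
]


def filter_reads(
    reads: ReadIntervalSet, mapq_min: int = 5, require_unique: bool = True
) -> ReadIntervalSet:
    """Keep uniquely aligned reads with MAPQ strictly above ``mapq_min``.

    The returned set's ``library_size`` is the retained read count — the
    library the downstream normalization actually counts from.
    """
    df = reads.reads
    keep = df["mapq"] > mapq_min
    if require_unique:
        keep &= df["unique"].astype(bool)
    kept = df[keep].reset_index(drop=True)
    return ReadIntervalSet(reads=kept, library_size=len(kept))


def promoter_windows(
    annotation: GeneAnnotation, up: int = 2500, down: int = 500
) -> pd.DataFrame:
    """Strand-aware promoter windows, 0-based half-open, clipped at 0.

    ``+`` strand: [tss - up, tss + down); ``-`` strand: [tss - down + 1,
    tss + up + 1), i.e. the mirror image covering the same bases relative to
    transcription direction.
    """
    t = annotation.table
    plus = t["strand"] == "+"
    start = np.where(plus, t["tss"] - up, t["tss"] - down + 1)
    end = np.where(plus, t["tss"] + down, t["tss"] + up + 1)
    start = np.maximum(start, 0)
    return pd.DataFrame(
        {"chrom": t["chrom"], "start": start.astype(np.int64),
         "end": end.astype(np.int64), "strand": t["strand"]},
        index=t.index,
    )


def count_reads_in_windows(
    reads: ReadIntervalSet, windows: pd.DataFrame
) -> pd.Series:
    """Reads overlapping each window by >= 1 bp (strand-agnostic).

    Intervals are half-open, so a read ending exactly at a window's start
    does not count. A read spanning two windows counts in both. Runs in
    O((n + w) log n) per chromosome via sorted-endpoint bisection: the
    overlap count for [s, e) is #{start < e} - #{end <= s}, the two excluded
    groups being disjoint.
    """
    counts = pd.Series(0, index=windows.index, dtype=np.int64, name="count")
    if len(reads.reads) == 0:
        return counts
    for chrom, rsub in reads.reads.groupby("chrom", sort=False):
        wmask = windows["chrom"] == chrom
        if not wmask.any():
            continue
        starts = np.sort(rsub["start"].to_numpy())
        ends = np.sort(rsub["end"].to_numpy())
        wsub = windows[wmask]
        n_start_before = np.searchsorted(starts, wsub["end"].to_numpy(), side="left")
        n_end_before = np.searchsorted(ends, wsub["start"].to_numpy(), side="right")
        counts[wsub.index] = n_start_before - n_end_before
    return counts


def enrichment_ratios(
    ip_counts: pd.Series,
    ctrl_counts: pd.Series,
    ip_library: int,
    ctrl_library: int,
    pseudo_rpm: float = 1.0,
) -> pd.DataFrame:
    """Library-normalized IP/control enrichment per gene.

    rpm = count / library x 1e6; ratio = (rpm_ip + pseudo) / (rpm_ctrl +
    pseudo); the pseudo-RPM keeps zero-control promoters finite. Invariant
    under joint scaling of a sample's counts and library.
    """
    if ip_library <= 0 or ctrl_library <= 0:
        raise ValueError("library sizes must be positive")
    rpm_ip = ip_counts.astype(float) / ip_library * 1e6
    rpm_ctrl = ctrl_counts.reindex(ip_counts.index).astype(float) / ctrl_library * 1e6
    ratio = (rpm_ip + pseudo_rpm) / (rpm_ctrl + pseudo_rpm)
    return pd.DataFrame(
        {
            "ip_count": ip_counts,
            "ctrl_count": ctrl_counts.reindex(ip_counts.index),
            "ip_library": ip_library,
            "ctrl_library": ctrl_library,
            "ratio": ratio,
            "log2_ratio": np.log2(ratio),
        }
    )


def chip_enrichment_table(
    ip: ReadIntervalSet,
    control: ReadIntervalSet,
    annotation: GeneAnnotation,
    up: int = 2500,
    down: int = 500,
    mapq_min: int = 5,
    pseudo_rpm: float = 1.0,
) -> pd.DataFrame:
    """Filter -> window -> count -> normalize, end to end for one factor."""
    ip_f = filter_reads(ip, mapq_min=mapq_min)
    ctrl_f = filter_reads(control, mapq_min=mapq_min)
    windows = promoter_windows(annotation, up=up, down=down)
    ip_counts = count_reads_in_windows(ip_f, windows)
    ctrl_counts = count_reads_in_windows(ctrl_f, windows)
    return enrichment_ratios(
        ip_counts, ctrl_counts, max(ip_f.library_size, 1),
        max(ctrl_f.library_size, 1), pseudo_rpm=pseudo_rpm,
    )


def binned_profile(
    anchor: pd.DataFrame,
    cofactors: dict[str, pd.DataFrame],
    bin_size: int = 500,
    gene_subset: pd.Index | None = None,
) -> pd.DataFrame:
    """Mean enrichment per bin of genes sorted by the anchor's enrichment.

    Genes (optionally restricted to ``gene_subset``, e.g. protein-coding
    ids) are sorted by anchor log2 ratio descending, ties broken by gene id,
    then cut into consecutive bins of ``bin_size`` (the last bin may be
    smaller). Output rows are bins with the member count, the mean anchor
    log2 ratio, and one mean log2 ratio column per co-factor. Anchor bin
    means are non-increasing by construction and asserted.
    """
    genes = anchor.index if gene_subset is None else anchor.index.intersection(
        gene_subset
    )
    if len(genes) == 0:
        raise ValueError("empty gene subset")
    if len(genes) < bin_size:
        warnings.warn(
            "gene subset smaller than one bin; returning a single bin",
            stacklevel=2,
        )
    sub = anchor.loc[genes, "log2_ratio"]
    # ties in the descending value sort break by gene id: stable sort on a
    # pre-sorted index keeps tied ids in lexicographic order
    order = sub.sort_index(kind="stable").sort_values(ascending=False, kind="stable")
    sorted_ids = order.index
    n_bins = int(np.ceil(len(sorted_ids) / bin_size))
    rows = []
    for b in range(n_bins):
        members = sorted_ids[b * bin_size : (b + 1) * bin_size]
        row = {
            "bin": b,
            "n_genes": len(members),
            "anchor_mean": float(anchor.loc[members, "log2_ratio"].mean()),
        }
        for name, table in cofactors.items():
            row[f"{name}_mean"] = float(table.loc[members, "log2_ratio"].mean())
        rows.append(row)
    out = pd.DataFrame(rows).set_index("bin")
    means = out["anchor_mean"].to_numpy()
    assert np.all(np.diff(means) <= 1e-12), "anchor bin means must be non-increasing"
    return out
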