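"""Readers and writers for the pipeline's plain-text interchange formats.

Coordinates are BED-convention 0-based half-open throughout: BED6 read
positions, two-column chrom.sizes, BED3+ CpG-island intervals, BED12 gene
models (thickStart/thickEnd delimiting the CDS), tab-separated sample sheets,
planted-truth tables and window-count matrices.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

READS_COLUMNS = ["chrom", "start", "end", "strand"]
SAMPLE_SHEET_COLUMNS = ["sample", "group", "sex"]
TRUTH_COLUMNS = ["chrom", "start", "end", "direction", "dose_class", "multiplier"]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64})
    if (df["length"] <= 0).any():
        raise ValueError(f"{path}: chromosome lengths must be positive")
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{int(length)}\n")


def read_reads_bed(path: str | Path) -> pd.DataFrame:
    """BED6 aligned reads -> DataFrame[chrom, start, end, strand]."""
    empty = pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                          zip(READS_COLUMNS, [str, np.int64, np.int64, str])})
    with open(path) as fh:
        has_data = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_data:
        return empty
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 5],
                     names=["chrom", "start", "end", "_n", "_s", "strand"],
                     dtype={0: str, 1: np.int64, 2: np.int64, 5: str})
    df.columns = READS_COLUMNS
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: reads must satisfy end > start")
    return df


def write_reads_bed(reads: pd.DataFrame, path: str | Path, name_prefix: str = "read") -> None:
    df = reads.reset_index(drop=True)
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(np.int64),
        "end": df["end"].astype(np.int64),
        "name": [f"{name_prefix}{i}" for i in range(len(df))],
        "score": 0,
        "strand": df["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_intervals_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ intervals -> DataFrame[chrom, start, end] (extra columns ignored)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype={0: str, 1: np.int64, 2: np.int64})
    except pd.errors.EmptyDataError:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def write_intervals_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def _parse_block_list(text: str) -> np.ndarray:
    return np.array([int(x) for x in str(text).rstrip(",").split(",") if x != ""],
                    dtype=np.int64)


def read_genes_bed12(path: str | Path) -> pd.DataFrame:
    """BED12 gene models.

    Returns one row per gene with ``exon_starts``/``exon_ends`` as absolute
    coordinate arrays and ``tss`` already strand-resolved (start for +, end
    for −, both as the half-open convention's flank point).
    """
    names = ["chrom", "start", "end", "gene_id", "score", "strand",
             "thick_start", "thick_end", "rgb", "block_count",
             "block_sizes", "block_starts"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#",
                         dtype={"chrom": str, "gene_id": str, "strand": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=names)
    records = []
    for row in df.itertuples(index=False):
        sizes = _parse_block_list(row.block_sizes)
        offsets = _parse_block_list(row.block_starts)
        if len(sizes) != len(offsets) or len(sizes) != int(row.block_count):
            raise ValueError(f"{path}: malformed blocks for gene {row.gene_id}")
        exon_starts = int(row.start) + offsets
        exon_ends = exon_starts + sizes
        records.append({
            "gene_id": row.gene_id, "chrom": row.chrom, "strand": row.strand,
            "start": int(row.start), "end": int(row.end),
            "thick_start": int(row.thick_start), "thick_end": int(row.thick_end),
            "exon_starts": exon_starts, "exon_ends": exon_ends,
            "tss": int(row.start) if row.strand == "+" else int(row.end),
        })
    cols = ["gene_id", "chrom", "strand", "start", "end", "thick_start",
            "thick_end", "exon_starts", "exon_ends", "tss"]
    return pd.DataFrame(records, columns=cols)


def write_genes_bed12(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            sizes = np.asarray(row.exon_ends) - np.asarray(row.exon_starts)
            offsets = np.asarray(row.exon_starts) - row.start
            fh.write("\t".join(map(str, [
                row.chrom, row.start, row.end, row.gene_id, 0, row.strand,
                row.thick_start, row.thick_end, "0",
                len(sizes),
                ",".join(map(str, sizes)) + ",",
                ",".join(map(str, offsets)) + ",",
            ])) + "\n")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {missing}")
    return df[SAMPLE_SHEET_COLUMNS]


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples[SAMPLE_SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "direction": str,
                                            "dose_class": str})
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: truth table missing columns {missing}")
    return df[TRUTH_COLUMNS]


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def write_count_matrix_tsv(windows: pd.DataFrame, counts: np.ndarray,
                           sample_ids: list[str], path: str | Path) -> None:
    out = windows[["chrom", "start", "end"]].reset_index(drop=True)
    out = pd.concat([out, pd.DataFrame(counts, columns=sample_ids)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_count_matrix_tsv(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sample_ids = [c for c in df.columns if c not in ("chrom", "start", "end")]
    windows = df[["chrom", "start", "end"]].copy()
    counts = df[sample_ids].to_numpy(dtype=np.int64)
    return windows, counts, sample_ids
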