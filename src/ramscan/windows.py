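"""Genome tiling, per-window read counting, and the low-coverage filter.

The genome is tiled into ``window_size`` bp windows advancing by
``window_shift`` bp (defaults 100/50, so consecutive windows half-overlap).
Each aligned read is anchored at its leftmost aligned base and increments
every window containing that base — exactly ``window_size/window_shift``
windows (two by default) except near chromosome edges.  Windows are then
screened for the coverage floor: at least ``min_reads`` reads in at least
``ceil(min_sample_fraction × n_samples)`` samples (≥10 reads in 25% of
samples by default, i.e. 3 of 12).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import PipelineConfig
from . import io as _io


@dataclass
class ReadSet:
    """Aligned reads for one sample plus its design metadata."""
    sample: str
    group: str
    sex: str
    reads: pd.DataFrame  # columns chrom, start, end, strand

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class WindowCountMatrix:
    """Ordered genomic windows × samples integer read counts.

    ``library_sizes`` are the per-sample total input reads, fixed before any
    window filtering, so normalization is invariant to the coverage screen.
    """
    windows: pd.DataFrame        # columns chrom, start, end; sorted (chrom, start)
    counts: np.ndarray           # (n_windows, n_samples) int64
    samples: pd.DataFrame        # columns sample, group, sex
    library_sizes: np.ndarray    # (n_samples,) int64

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.windows), len(self.samples)):
            raise ValueError("counts shape does not match windows × samples")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample"])

    def group_indices(self, group: str, column: str = "group") -> np.ndarray:
        idx = np.flatnonzero((self.samples[column] == group).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no samples with {column} == {group!r}")
        return idx

    def subset_rows(self, mask: np.ndarray) -> "WindowCountMatrix":
        return replace(self, windows=self.windows.loc[mask].reset_index(drop=True),
                       counts=self.counts[np.asarray(mask)])

    def to_tsv(self, path) -> None:
        _io.write_count_matrix_tsv(self.windows, self.counts, self.sample_ids, path)


def tile_windows(chrom_sizes: dict[str, int],
                 cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Tile every chromosome into overlapping windows.

    Starts run 0, shift, 2·shift, … while start < length; ends are clipped at
    the chromosome end; terminal windows shorter than the shift are dropped
    (they would duplicate the previous window's tail).
    """
    cfg = cfg or PipelineConfig()
    frames = []
    for chrom, length in chrom_sizes.items():
        length = int(length)
        if length < 1:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        starts = np.arange(0, length, cfg.window_shift, dtype=np.int64)
        ends = np.minimum(starts + cfg.window_size, length)
        keep = (ends - starts) >= cfg.window_shift
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts[keep],
                                    "end": ends[keep]}))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end"])
    return out


def _windows_per_chrom(windows: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """chrom -> (row offset of first window, number of windows)."""
    out: dict[str, tuple[int, int]] = {}
    for chrom, grp in windows.groupby("chrom", sort=False):
        out[str(chrom)] = (int(grp.index[0]), len(grp))
    return out


def anchor_positions(reads: pd.DataFrame, cfg: PipelineConfig) -> np.ndarray:
    """Leftmost aligned base of each read after optional 3'-ward extension.

    With extension e, a + strand read reaches e bp further right (anchor
    unchanged) while a − strand read reaches e bp further left, so its
    leftmost base, and hence anchor, moves to max(0, start − e).
    """
    anchors = reads["start"].to_numpy(np.int64)
    if cfg.read_extension > 0:
        minus = (reads["strand"] == "-").to_numpy()
        anchors = anchors.copy()
        anchors[minus] = np.maximum(anchors[minus] - cfg.read_extension, 0)
    return anchors


def count_reads(readsets: list[ReadSet], windows: pd.DataFrame,
                cfg: PipelineConfig | None = None) -> WindowCountMatrix:
    """Count anchored reads into every window containing the anchor base."""
    cfg = cfg or PipelineConfig()
    layout = _windows_per_chrom(windows)
    n_win = len(windows)
    n_per_win = cfg.window_size // cfg.window_shift
    counts = np.zeros((n_win, len(readsets)), dtype=np.int64)
    lib_sizes = np.zeros(len(readsets), dtype=np.int64)

    for j, rs in enumerate(readsets):
        lib_sizes[j] = len(rs.reads)
        if len(rs.reads) == 0:
            continue
        unknown = sorted(set(rs.reads["chrom"]) - set(layout))
        if unknown:
            raise KeyError(
                f"sample {rs.sample}: reads on unknown chromosome(s) {unknown}")
        anchors_all = anchor_positions(rs.reads, cfg)
        chroms = rs.reads["chrom"].to_numpy()
        for chrom, (offset, n_chrom) in layout.items():
            anchors = anchors_all[chroms == chrom]
            if anchors.size == 0:
                continue
            k = anchors // cfg.window_shift
            col = np.zeros(n_chrom, dtype=np.int64)
            for back in range(n_per_win):
                kk = k - back
                valid = (kk >= 0) & (kk < n_chrom)
                if valid.any():
                    col += np.bincount(kk[valid], minlength=n_chrom)
            counts[offset:offset + n_chrom, j] += col

    samples = pd.DataFrame({"sample": [r.sample for r in readsets],
                            "group": [r.group for r in readsets],
                            "sex": [r.sex for r in readsets]})
    return WindowCountMatrix(windows.reset_index(drop=True), counts, samples, lib_sizes)


def min_samples_required(n_samples: int, fraction: float) -> int:
    return math.ceil(fraction * n_samples)


def filter_low_coverage(m: WindowCountMatrix,
                        cfg: PipelineConfig | None = None) -> WindowCountMatrix:
    """Keep windows with ≥ min_reads in ≥ ceil(min_sample_fraction·n) samples."""
    cfg = cfg or PipelineConfig()
    if m.n_windows == 0:
        raise ValueError("cannot filter an empty window matrix")
    need = min_samples_required(len(m.samples), cfg.min_sample_fraction)
    mask = (m.counts >= cfg.min_reads).sum(axis=1) >= need
    return m.subset_rows(mask)
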