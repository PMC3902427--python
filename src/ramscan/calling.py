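"""From per-window test results to regions of altered methylation (RAMs).

A window becomes a preliminary RAM when its raw p-value passes the gate
(p < alpha).  Two further screens remove single-sample artifacts:

* per-sample support — in each group, at least half the samples (minimum 2)
  must lie on their group's side of the midpoint between the two group
  medians of normalized counts;
* adjacency — another same-direction preliminary RAM of the same comparison
  must start within (adjacency_stretch − window_size) bp, i.e. both windows
  fit inside one 500 bp stretch (which subsumes the flanking-window case at
  |Δstart| = 50 bp).

Final RAMs carry all three flags; overlapping or book-ended same-direction
final windows can be merged into reportable regions.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .windows import WindowCountMatrix

RAM_COLUMNS = ["chrom", "start", "end", "comparison", "direction",
               "p", "log2FC", "prelim", "support_ok", "adjacency_ok"]


def call_preliminary_rams(diff: pd.DataFrame,
                          cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Windows with p < alpha and a definite direction."""
    cfg = cfg or PipelineConfig()
    mask = (diff["p"] < cfg.alpha) & (diff["direction"] != "none")
    rams = diff.loc[mask, ["chrom", "start", "end", "comparison",
                           "direction", "p", "log2FC"]].copy()
    rams["prelim"] = True
    rams["support_ok"] = False
    rams["adjacency_ok"] = False
    return rams.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _required_support(group_size: int, fraction: float) -> int:
    if group_size < 2:
        raise ValueError("support filter requires at least two samples per group")
    return max(2, math.ceil(fraction * group_size))


def sample_support_filter(rams: pd.DataFrame, m: WindowCountMatrix,
                          group_a: str, group_b: str,
                          sizes: np.ndarray,
                          cfg: PipelineConfig | None = None,
                          group_column: str = "group") -> pd.DataFrame:
    """Set ``support_ok`` per RAM from the group-median midpoint side test.

    Normalized counts are count/effective size.  The midpoint is the mean of
    the two group medians; a sample "supports" a hyper call if it lies above
    the midpoint (group B) or below it (group A), and conversely for hypo.
    """
    cfg = cfg or PipelineConfig()
    cols_a = m.group_indices(group_a, group_column)
    cols_b = m.group_indices(group_b, group_column)
    need_a = _required_support(len(cols_a), cfg.support_fraction)
    need_b = _required_support(len(cols_b), cfg.support_fraction)

    key = pd.MultiIndex.from_frame(m.windows[["chrom", "start"]])
    row_of = pd.Series(np.arange(m.n_windows), index=key)
    rows = row_of.loc[pd.MultiIndex.from_frame(rams[["chrom", "start"]])].to_numpy()

    norm = m.counts[rows].astype(np.float64) / np.asarray(sizes, dtype=np.float64)
    med_a = np.median(norm[:, cols_a], axis=1)
    med_b = np.median(norm[:, cols_b], axis=1)
    mid = (med_a + med_b) / 2.0

    hyper = (rams["direction"] == "hyper").to_numpy()
    above_b = (norm[:, cols_b] > mid[:, None]).sum(axis=1)
    below_b = (norm[:, cols_b] < mid[:, None]).sum(axis=1)
    above_a = (norm[:, cols_a] > mid[:, None]).sum(axis=1)
    below_a = (norm[:, cols_a] < mid[:, None]).sum(axis=1)

    ok_hyper = (above_b >= need_b) & (below_a >= need_a)
    ok_hypo = (below_b >= need_b) & (above_a >= need_a)
    out = rams.copy()
    out["support_ok"] = np.where(hyper, ok_hyper, ok_hypo)
    return out


def adjacency_filter(rams: pd.DataFrame,
                     cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Set ``adjacency_ok``: a same-direction neighbor within the stretch.

    Two windows corroborate each other when |Δstart| ≤ adjacency_stretch −
    window_size (400 bp by default), so both fit inside one stretch.
    Applied per comparison, per chromosome, per direction.
    """
    cfg = cfg or PipelineConfig()
    max_gap = cfg.adjacency_max_gap
    out = rams.copy()
    ok = np.zeros(len(out), dtype=bool)
    for _, grp in out.groupby(["comparison", "chrom", "direction"], sort=False):
        starts = grp["start"].to_numpy(np.int64)
        order = np.argsort(starts, kind="stable")
        s = starts[order]
        flag = np.zeros(len(s), dtype=bool)
        if len(s) > 1:
            gap = np.diff(s)
            near = gap <= max_gap
            flag[:-1] |= near
            flag[1:] |= near
        ok[grp.index.to_numpy()[order]] = flag
    out["adjacency_ok"] = ok
    return out


def finalize_rams(rams: pd.DataFrame) -> pd.DataFrame:
    """Rows passing every filter (prelim, support, adjacency)."""
    mask = rams["prelim"] & rams["support_ok"] & rams["adjacency_ok"]
    return rams.loc[mask].reset_index(drop=True)


def merge_rams(rams: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/book-ended same-direction final windows into regions.

    Returns chrom, start, end, comparison, direction, n_windows, min_p.
    """
    records = []
    for (comparison, chrom, direction), grp in rams.groupby(
            ["comparison", "chrom", "direction"], sort=False):
        grp = grp.sort_values("start", kind="stable")
        cur_s = cur_e = None
        n = 0
        min_p = np.inf
        for row in grp.itertuples(index=False):
            if cur_s is None or row.start > cur_e:
                if cur_s is not None:
                    records.append((chrom, cur_s, cur_e, comparison, direction, n, min_p))
                cur_s, cur_e, n, min_p = row.start, row.end, 1, row.p
            else:
                cur_e = max(cur_e, row.end)
                n += 1
                min_p = min(min_p, row.p)
        if cur_s is not None:
            records.append((chrom, cur_s, cur_e, comparison, direction, n, min_p))
    out = pd.DataFrame(records, columns=["chrom", "start", "end", "comparison",
                                         "direction", "n_windows", "min_p"])
    return out.sort_values(["comparison", "chrom", "start"],
                           kind="stable").reset_index(drop=True)


def rams_to_bed6(rams: pd.DataFrame) -> pd.DataFrame:
    """BED6 view of final RAM windows.

    name = comparison, score = −10·log10(p) capped at 1000, strand '+' for
    hyper / '−' for hypo.
    """
    score = np.minimum(-10.0 * np.log10(np.maximum(rams["p"].to_numpy(), 1e-300)),
                       1000.0)
    return pd.DataFrame({
        "chrom": rams["chrom"],
        "start": rams["start"],
        "end": rams["end"],
        "name": rams["comparison"],
        "score": np.round(score, 1),
        "strand": np.where(rams["direction"] == "hyper", "+", "-"),
    })
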