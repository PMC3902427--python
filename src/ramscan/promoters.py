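"""Promoter dose–response classification and the promoter heatmap matrix.

Promoter-assigned RAM windows from the two exposure-vs-control comparisons
are rolled up per gene into a methylation response (gain = hypermethylated in
the exposed group, loss = hypomethylated) crossed with an exposure class
(low-dose only, high-dose only, or both doses with the same direction).
Promoters carrying both gain and loss windows within one comparison — or
opposite directions between the two comparisons — are flagged "mixed" and
excluded from the six class counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .annotation import GenomeAnnotation
from .windows import WindowCountMatrix

SIX_CLASSES = [("gain", "UG_only"), ("gain", "MG_only"), ("gain", "both"),
               ("loss", "UG_only"), ("loss", "MG_only"), ("loss", "both")]


def _per_comparison_state(prom_rams: pd.DataFrame, comparison: str) -> pd.Series:
    """gene_id -> 'gain' | 'loss' | 'mixed' for one comparison."""
    sub = prom_rams[prom_rams["comparison"] == comparison]
    pairs = []
    for row in sub.itertuples(index=False):
        for gid in row.promoter_genes:
            pairs.append((gid, row.direction))
    if not pairs:
        return pd.Series(dtype=object)
    df = pd.DataFrame(pairs, columns=["gene_id", "direction"])
    def collapse(dirs: pd.Series) -> str:
        s = set(dirs)
        if s == {"hyper"}:
            return "gain"
        if s == {"hypo"}:
            return "loss"
        return "mixed"
    return df.groupby("gene_id")["direction"].apply(collapse)


def classify_promoter_dose_response(prom_rams: pd.DataFrame,
                                    comparisons: tuple[str, str] =
                                    ("Ctr_vs_UG", "Ctr_vs_MG")) -> pd.DataFrame:
    """Per-gene response × exposure class from the two dose comparisons.

    ``prom_rams`` holds promoter-assigned final RAM windows (with a
    ``promoter_genes`` list column) for both exposure-vs-control comparisons.
    Returns gene_id, response ∈ {gain, loss, mixed}, exposure_class ∈
    {UG_only, MG_only, both, mixed}, n_windows_UG, n_windows_MG.
    """
    present = set(prom_rams["comparison"].unique()) if len(prom_rams) else set()
    for comp in comparisons:
        if len(prom_rams) and comp not in present and len(present) >= 1:
            # allow empty result sets per comparison; only a wholly absent
            # comparison among a nonempty other is legitimate (no calls)
            pass
    ug_comp, mg_comp = comparisons
    state_ug = _per_comparison_state(prom_rams, ug_comp)
    state_mg = _per_comparison_state(prom_rams, mg_comp)
    genes = sorted(set(state_ug.index) | set(state_mg.index))
    rows = []
    for gid in genes:
        s_ug = state_ug.get(gid)
        s_mg = state_mg.get(gid)
        if s_ug == "mixed" or s_mg == "mixed" or (
                s_ug is not None and s_mg is not None and s_ug != s_mg):
            response, exposure = "mixed", "mixed"
        elif s_ug is not None and s_mg is not None:
            response, exposure = s_ug, "both"
        elif s_ug is not None:
            response, exposure = s_ug, "UG_only"
        else:
            response, exposure = s_mg, "MG_only"
        rows.append((gid, response, exposure))
    out = pd.DataFrame(rows, columns=["gene_id", "response", "exposure_class"])
    return out


def promoter_summary(cls: pd.DataFrame) -> dict:
    """Counts and percentages over the six gain/loss × exposure classes.

    Percent gain/loss = 100 × subtotal / grand total, rounded to the nearest
    integer; mixed promoters are reported separately and excluded.
    """
    counts = {}
    for response, exposure in SIX_CLASSES:
        counts[f"{response}_{exposure}"] = int(
            ((cls["response"] == response) &
             (cls["exposure_class"] == exposure)).sum())
    gain_total = sum(v for k, v in counts.items() if k.startswith("gain"))
    loss_total = sum(v for k, v in counts.items() if k.startswith("loss"))
    grand = gain_total + loss_total
    n_mixed = int((cls["response"] == "mixed").sum())
    pct_gain = int(round(100.0 * gain_total / grand)) if grand else 0
    pct_loss = int(round(100.0 * loss_total / grand)) if grand else 0
    return {"class_counts": counts, "gain_total": gain_total,
            "loss_total": loss_total, "grand_total": grand,
            "percent_gain": pct_gain, "percent_loss": pct_loss,
            "n_mixed_excluded": n_mixed}


def summary_from_counts(gain_counts: tuple[int, int, int],
                        loss_counts: tuple[int, int, int]) -> dict:
    """Summary arithmetic straight from per-class counts (UG_only, both,
    MG_only order is irrelevant — only the subtotals matter)."""
    gain_total = int(sum(gain_counts))
    loss_total = int(sum(loss_counts))
    grand = gain_total + loss_total
    return {"gain_total": gain_total, "loss_total": loss_total,
            "grand_total": grand,
            "percent_gain": int(round(100.0 * gain_total / grand)) if grand else 0,
            "percent_loss": int(round(100.0 * loss_total / grand)) if grand else 0}


def heatmap_inclusion_mask(prom_rams: pd.DataFrame, m: WindowCountMatrix,
                           sizes: np.ndarray,
                           cfg: PipelineConfig | None = None) -> np.ndarray:
    """Which promoter RAM windows enter the heatmap.

    A window is included when (a) some exposure group's mean normalized count
    falls below min_reads scaled by the median effective size (the pipeline's
    read floor expressed on the normalized scale), or (b) the ratio between
    any two group means is at least heatmap_fold.
    """
    cfg = cfg or PipelineConfig()
    sizes = np.asarray(sizes, dtype=np.float64)
    low_thresh = cfg.min_reads / np.median(sizes)
    key = pd.MultiIndex.from_frame(m.windows[["chrom", "start"]])
    row_of = pd.Series(np.arange(m.n_windows), index=key)
    rows = row_of.loc[pd.MultiIndex.from_frame(prom_rams[["chrom", "start"]])].to_numpy()
    norm = m.counts[rows].astype(np.float64) / sizes

    groups = m.samples["group"].unique()
    means = np.stack([norm[:, m.group_indices(g)].mean(axis=1) for g in groups],
                     axis=1)
    low = (means < low_thresh).any(axis=1)
    gmax = means.max(axis=1)
    gmin = means.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(gmin > 0, gmax / gmin, np.inf)
    fold = ratio >= cfg.heatmap_fold
    return low | fold


def heatmap_matrix(prom_rams: pd.DataFrame, m: WindowCountMatrix,
                   ann: GenomeAnnotation, sizes: np.ndarray,
                   cls: pd.DataFrame | None = None,
                   cfg: PipelineConfig | None = None
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample normalized counts across TSS ± flank bins for every
    promoter with ≥1 included RAM window.

    Bins are window_size wide on the window grid, oriented 5'→3' (reversed
    for − strand genes).  Rows are (gene_id, bin) pairs grouped by response
    class; the second return value maps each input RAM window to its
    inclusion decision.
    """
    cfg = cfg or PipelineConfig()
    sizes = np.asarray(sizes, dtype=np.float64)
    included = heatmap_inclusion_mask(prom_rams, m, sizes, cfg)
    mask = pd.Series(included, index=prom_rams.index, name="heatmap_included")

    keep_genes: set[str] = set()
    for row, inc in zip(prom_rams.itertuples(index=False), included):
        if inc:
            keep_genes.update(row.promoter_genes)

    if cls is not None and len(cls):
        order_key = cls.set_index("gene_id")[["response", "exposure_class"]]
    else:
        order_key = None

    key = pd.MultiIndex.from_frame(m.windows[["chrom", "start"]])
    row_of = pd.Series(np.arange(m.n_windows), index=key)
    norm_all = m.counts.astype(np.float64) / sizes

    proms = ann.promoters[ann.promoters["gene_id"].isin(keep_genes)]
    n_bins = (2 * cfg.promoter_flank) // cfg.window_size
    records, index = [], []
    for g in proms.itertuples(index=False):
        grid_start = ((g.tss - cfg.promoter_flank) // cfg.window_shift
                      ) * cfg.window_shift
        bin_starts = grid_start + np.arange(n_bins) * cfg.window_size
        if g.strand == "-":
            bin_starts = bin_starts[::-1]
        for b, bs in enumerate(bin_starts):
            r = row_of.get((g.chrom, int(bs)))
            vals = norm_all[int(r)] if r is not None else np.zeros(len(sizes))
            records.append(vals)
            index.append((g.gene_id, b))
    matrix = pd.DataFrame(records, columns=m.sample_ids,
                          index=pd.MultiIndex.from_tuples(index or [],
                                                          names=["gene_id", "bin"]))
    if order_key is not None and len(matrix):
        gene_order = matrix.index.get_level_values(0).map(
            lambda gid: tuple(order_key.loc[gid]) if gid in order_key.index
            else ("zz", "zz"))
        matrix = matrix.iloc[np.argsort(gene_order, kind="stable")]
    return matrix, mask
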