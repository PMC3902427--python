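"""CGI shore/shelf derivation, window context classification and promoters.

CpG-island shores are the 0–2 kb flanks of (merged) CGIs minus any CGI bases;
shelves are the next 2–4 kb minus CGIs and shores; everything farther than
4 kb from a CGI is open sea.  Windows are labeled by ≥1 bp overlap at fixed
precedence (CGI > shore > shelf for the island hierarchy; CDS exon > 5'UTR >
3'UTR > TSS-up-1kb > TSS-up-5kb > intron > intergenic for gene features,
with "upstream" strand-aware).  Promoter membership is overlap of the window
with [TSS − flank, TSS + flank).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv
from .config import PipelineConfig

CGI_CATEGORIES = ["CGI", "shore", "shelf", "open_sea"]
GENE_CATEGORIES = ["CDS_exon", "5UTR", "3UTR", "TSS_up_1kb", "TSS_up_5kb",
                   "intron", "intergenic"]

IntervalSet = dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (starts, ends)


def _df_to_sets(df: pd.DataFrame, chrom_sizes: dict[str, int]) -> IntervalSet:
    out: IntervalSet = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        length = chrom_sizes[str(chrom)]
        s, e = iv.clip_intervals(grp["start"].to_numpy(), grp["end"].to_numpy(), length)
        out[str(chrom)] = iv.merge_intervals(s, e)
    return out


def _sets_to_df(sets: IntervalSet) -> pd.DataFrame:
    frames = [pd.DataFrame({"chrom": chrom, "start": s, "end": e})
              for chrom, (s, e) in sets.items() if len(s)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus derived interval sets for classification."""
    chrom_sizes: dict[str, int]
    cgis: IntervalSet
    shores: IntervalSet
    shelves: IntervalSet
    genes: pd.DataFrame                      # as read_genes_bed12
    gene_features: dict[str, IntervalSet]    # category -> per-chrom intervals
    promoters: pd.DataFrame                  # gene_id, chrom, strand, tss, p_start, p_end

    def cgi_df(self) -> pd.DataFrame:
        return _sets_to_df(self.cgis)

    def shores_df(self) -> pd.DataFrame:
        return _sets_to_df(self.shores)

    def shelves_df(self) -> pd.DataFrame:
        return _sets_to_df(self.shelves)


def derive_shores_shelves(cgis: pd.DataFrame, chrom_sizes: dict[str, int],
                          cfg: PipelineConfig | None = None
                          ) -> tuple[IntervalSet, IntervalSet, IntervalSet]:
    """(merged CGIs, shores, shelves) per chromosome, mutually disjoint."""
    cfg = cfg or PipelineConfig()
    cgi_sets = _df_to_sets(cgis, chrom_sizes)
    shores: IntervalSet = {}
    shelves: IntervalSet = {}
    for chrom, length in chrom_sizes.items():
        c_s, c_e = cgi_sets.get(chrom, (np.array([], dtype=np.int64),) * 2)
        if c_s.size == 0:
            empty = (np.array([], dtype=np.int64), np.array([], dtype=np.int64))
            shores[chrom], shelves[chrom] = empty, empty
            continue
        sh_s = np.concatenate([c_s - cfg.shore_extent, c_e])
        sh_e = np.concatenate([c_s, c_e + cfg.shore_extent])
        sh_s, sh_e = iv.clip_intervals(sh_s, sh_e, length)
        sh_s, sh_e = iv.subtract_intervals(sh_s, sh_e, c_s, c_e)
        shores[chrom] = (sh_s, sh_e)

        far = cfg.shore_extent + cfg.shelf_extent
        sl_s = np.concatenate([c_s - far, c_e + cfg.shore_extent])
        sl_e = np.concatenate([c_s - cfg.shore_extent, c_e + far])
        sl_s, sl_e = iv.clip_intervals(sl_s, sl_e, length)
        sl_s, sl_e = iv.subtract_intervals(sl_s, sl_e, c_s, c_e)
        sl_s, sl_e = iv.subtract_intervals(sl_s, sl_e, sh_s, sh_e)
        shelves[chrom] = (sl_s, sl_e)
    return cgi_sets, shores, shelves


def _gene_feature_sets(genes: pd.DataFrame,
                       chrom_sizes: dict[str, int]) -> dict[str, IntervalSet]:
    """Raw (pre-precedence) interval sets for each gene-feature category."""
    buckets: dict[str, dict[str, list]] = {
        cat: {} for cat in GENE_CATEGORIES if cat != "intergenic"}

    def add(cat: str, chrom: str, s: int, e: int) -> None:
        if e > s:
            buckets[cat].setdefault(chrom, []).append((s, e))

    for g in genes.itertuples(index=False):
        ex_s = np.asarray(g.exon_starts, dtype=np.int64)
        ex_e = np.asarray(g.exon_ends, dtype=np.int64)
        for s, e in zip(ex_s, ex_e):
            add("CDS_exon", g.chrom, max(s, g.thick_start), min(e, g.thick_end))
        left_s, left_e = g.start, g.thick_start   # exonic bases 5' of CDS in coords
        right_s, right_e = g.thick_end, g.end
        utr5 = (left_s, left_e) if g.strand == "+" else (right_s, right_e)
        utr3 = (right_s, right_e) if g.strand == "+" else (left_s, left_e)
        for s, e in zip(ex_s, ex_e):
            add("5UTR", g.chrom, max(s, utr5[0]), min(e, utr5[1]))
            add("3UTR", g.chrom, max(s, utr3[0]), min(e, utr3[1]))
        if g.strand == "+":
            add("TSS_up_1kb", g.chrom, g.tss - 1000, g.tss)
            add("TSS_up_5kb", g.chrom, g.tss - 5000, g.tss - 1000)
        else:
            add("TSS_up_1kb", g.chrom, g.tss, g.tss + 1000)
            add("TSS_up_5kb", g.chrom, g.tss + 1000, g.tss + 5000)
        # introns: gene span minus exons
        span_minus = iv.subtract_intervals([g.start], [g.end], ex_s, ex_e)
        for s, e in zip(*span_minus):
            add("intron", g.chrom, int(s), int(e))

    out: dict[str, IntervalSet] = {}
    for cat, per_chrom in buckets.items():
        sets: IntervalSet = {}
        for chrom, pairs in per_chrom.items():
            length = chrom_sizes[chrom]
            arr = np.asarray(pairs, dtype=np.int64)
            s, e = iv.clip_intervals(arr[:, 0], arr[:, 1], length)
            sets[chrom] = iv.merge_intervals(s, e) if len(s) else (s, e)
        out[cat] = sets
    return out


def build_annotation(chrom_sizes: dict[str, int], cgis: pd.DataFrame,
                     genes: pd.DataFrame,
                     cfg: PipelineConfig | None = None) -> GenomeAnnotation:
    cfg = cfg or PipelineConfig()
    cgi_sets, shores, shelves = derive_shores_shelves(cgis, chrom_sizes, cfg)
    features = _gene_feature_sets(genes, chrom_sizes)
    promoters = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "chrom": genes["chrom"],
        "strand": genes["strand"],
        "tss": genes["tss"],
        "p_start": np.maximum(genes["tss"] - cfg.promoter_flank, 0),
        "p_end": genes["tss"] + cfg.promoter_flank,
    }) if len(genes) else pd.DataFrame(
        columns=["gene_id", "chrom", "strand", "tss", "p_start", "p_end"])
    return GenomeAnnotation(dict(chrom_sizes), cgi_sets, shores, shelves,
                            genes, features, promoters)


def _classify(windows: pd.DataFrame, layers: list[tuple[str, IntervalSet]],
              default: str) -> np.ndarray:
    labels = np.full(len(windows), default, dtype=object)
    unset = np.ones(len(windows), dtype=bool)
    chroms = windows["chrom"].to_numpy()
    starts = windows["start"].to_numpy(np.int64)
    ends = windows["end"].to_numpy(np.int64)
    for name, sets in layers:
        for chrom in np.unique(chroms):
            rows = np.flatnonzero((chroms == chrom) & unset)
            if rows.size == 0 or chrom not in sets or len(sets[chrom][0]) == 0:
                continue
            hit = iv.overlaps_any(starts[rows], ends[rows], *sets[chrom])
            labels[rows[hit]] = name
            unset[rows[hit]] = False
    return labels


def classify_cgi_context(windows: pd.DataFrame, ann: GenomeAnnotation) -> np.ndarray:
    """Label every window CGI / shore / shelf / open_sea at fixed precedence."""
    return _classify(windows, [("CGI", ann.cgis), ("shore", ann.shores),
                               ("shelf", ann.shelves)], "open_sea")


def classify_gene_context(windows: pd.DataFrame, ann: GenomeAnnotation) -> np.ndarray:
    layers = [(cat, ann.gene_features[cat])
              for cat in GENE_CATEGORIES if cat != "intergenic"]
    return _classify(windows, layers, "intergenic")


def context_distribution(labels, categories: list[str] | None = None) -> pd.Series:
    """Proportion of windows per category; proportions sum to 1."""
    labels = pd.Series(list(labels), dtype=object)
    if len(labels) == 0:
        raise ValueError("cannot compute a distribution of zero windows")
    counts = labels.value_counts()
    if categories is not None:
        counts = counts.reindex(categories, fill_value=0)
    dist = counts / counts.sum()
    dist.name = "proportion"
    return dist


def enrichment_vs_background(ram_dist: pd.Series, bg_dist: pd.Series) -> pd.Series:
    """Relative change (%) of each category's share against the background.

    change% = 100 × (p_ram − p_bg) / p_bg; categories absent from the
    background are undefined (NaN), never ±inf.
    """
    bg = bg_dist.reindex(ram_dist.index)
    out = pd.Series(np.full(len(ram_dist), np.nan), index=ram_dist.index,
                    name="relative_change_percent")
    ok = bg.to_numpy(dtype=float) > 0
    out[ok] = 100.0 * (ram_dist[ok] - bg[ok]) / bg[ok]
    return out


def assign_promoters(rams: pd.DataFrame, ann: GenomeAnnotation,
                     cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Attach promoter gene ids to RAM windows.

    A window is assigned to every gene whose promoter interval
    [TSS − flank, TSS + flank) it overlaps by ≥1 bp; multi-gene assignments
    are retained.  Returns the input plus a ``promoter_genes`` list column
    and a long (window × gene) table in ``.attrs['promoter_pairs']``.
    """
    cfg = cfg or PipelineConfig()
    out = rams.copy().reset_index(drop=True)
    gene_lists: list[list[str]] = [[] for _ in range(len(out))]
    pairs = []
    proms = ann.promoters
    for chrom, grp in out.groupby("chrom", sort=False):
        p = proms[proms["chrom"] == chrom]
        if p.empty:
            continue
        p_start = p["p_start"].to_numpy(np.int64)
        p_end = p["p_end"].to_numpy(np.int64)
        gids = p["gene_id"].to_numpy()
        order = np.argsort(p_start, kind="stable")
        p_start, p_end, gids = p_start[order], p_end[order], gids[order]
        for row in grp.itertuples():
            # candidate promoters: p_start < row.end and p_end > row.start
            hi = np.searchsorted(p_start, row.end, side="left")
            hits = np.flatnonzero(p_end[:hi] > row.start)
            for h in hits:
                gene_lists[row.Index].append(str(gids[h]))
                pairs.append((row.Index, str(gids[h])))
    out["promoter_genes"] = gene_lists
    out.attrs["promoter_pairs"] = pd.DataFrame(pairs, columns=["ram_index", "gene_id"])
    return out
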