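"""Shore/shelf derivation and context classification vs per-base oracles."""

import numpy as np
import pandas as pd
import pytest

import ramscan as rs
from ramscan.annotation import (CGI_CATEGORIES, GENE_CATEGORIES, _sets_to_df,
                                build_annotation)

CFG = rs.PipelineConfig()


def cgi_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def base_level_cgi_label(pos, cgis):
    """Distance-to-nearest-CGI classification of a single base."""
    best = np.inf
    for s, e in cgis:
        if s <= pos < e:
            return "CGI"
        best = min(best, s - pos - 1 if pos < s else pos - e)
    if best < 2000:
        return "shore"
    if best < 4000:
        return "shelf"
    return "open_sea"


class TestShoresShelves:
    def test_single_cgi_flanks(self):
        sizes = {"chr1": 30_000}
        _, shores, shelves = rs.derive_shores_shelves(
            cgi_df([("chr1", 10_000, 10_500)]), sizes, CFG)
        assert [list(a) for a in shores["chr1"]] == [[8000, 10_500], [10_000, 12_500]]
        assert [list(a) for a in shelves["chr1"]] == [[6000, 12_500], [8000, 14_500]]

    def test_boundary_clipping_truncates_left_flanks(self):
        sizes = {"chr1": 30_000}
        _, shores, shelves = rs.derive_shores_shelves(
            cgi_df([("chr1", 500, 900)]), sizes, CFG)
        assert [list(a) for a in shores["chr1"]] == [[0, 900], [500, 2900]]
        # left shelf would be [-3500, -1500): entirely off-chromosome
        assert [list(a) for a in shelves["chr1"]] == [[2900], [4900]]

    def test_close_cgis_leave_no_shelf_between(self):
        sizes = {"chr1": 40_000}
        cgis = [(10_000, 10_400), (11_400, 11_800)]  # 1 kb apart
        cgi_sets, shores, shelves = rs.derive_shores_shelves(
            cgi_df([("chr1", s, e) for s, e in cgis]), sizes, CFG)
        for pos in range(5_000, 17_000, 97):
            expected = base_level_cgi_label(pos, cgis)
            got = "open_sea"
            for name, sets in (("CGI", cgi_sets), ("shore", shores),
                               ("shelf", shelves)):
                s_arr, e_arr = sets["chr1"]
                if any(s <= pos < e for s, e in zip(s_arr, e_arr)):
                    got = name
                    break
            assert got == expected, pos

    def test_disjoint_and_idempotent(self):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.choice(np.arange(100, 195) * 1000, 12, replace=False))
        cgis = cgi_df([("chr1", int(s), int(s + rng.integers(200, 1500)))
                       for s in starts])
        sizes = {"chr1": 250_000}
        cgi_sets, shores, shelves = rs.derive_shores_shelves(cgis, sizes, CFG)
        cover = np.zeros(250_000, dtype=int)
        for sets in (cgi_sets, shores, shelves):
            for s, e in zip(*sets["chr1"]):
                cover[s:e] += 1
        assert cover.max() <= 1  # mutual disjointness
        again = rs.derive_shores_shelves(_sets_to_df(cgi_sets), sizes, CFG)
        for first, second in zip((cgi_sets, shores, shelves), again):
            assert all(np.array_equal(first["chr1"][i], second["chr1"][i])
                       for i in (0, 1))


class TestCgiClassification:
    def _ann(self, cgis, length=60_000):
        return build_annotation({"chr1": length}, cgi_df(cgis),
                                pd.DataFrame(columns=["gene_id", "chrom", "strand",
                                                      "start", "end", "thick_start",
                                                      "thick_end", "exon_starts",
                                                      "exon_ends", "tss"]), CFG)

    def test_precedence_cgi_over_shore(self):
        ann = self._ann([("chr1", 10_000, 10_500)])
        w = pd.DataFrame({"chrom": ["chr1"], "start": [9_950], "end": [10_050]})
        assert rs.classify_cgi_context(w, ann)[0] == "CGI"

    def test_far_window_is_open_sea(self):
        ann = self._ann([("chr1", 10_000, 10_500)])
        w = pd.DataFrame({"chrom": ["chr1"], "start": [20_000], "end": [20_100]})
        assert rs.classify_cgi_context(w, ann)[0] == "open_sea"

    def test_random_windows_match_base_level_oracle(self):
        rng = np.random.default_rng(1)
        cgis = [(8_000, 8_700), (12_000, 12_400), (30_000, 31_000)]
        ann = self._ann([("chr1", s, e) for s, e in cgis])
        starts = rng.integers(0, 59_900, 300)
        w = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 100})
        got = rs.classify_cgi_context(w, ann)
        rank = {c: i for i, c in enumerate(CGI_CATEGORIES)}
        for i, s in enumerate(starts):
            labels = {base_level_cgi_label(p, cgis) for p in range(s, s + 100)}
            assert got[i] == min(labels, key=rank.get)


def toy_gene(gene_id, chrom, strand, tss, exons, cds):
    """exons: absolute (start, end) pairs; cds: (thick_start, thick_end)."""
    starts = np.array([e[0] for e in exons])
    ends = np.array([e[1] for e in exons])
    return {"gene_id": gene_id, "chrom": chrom, "strand": strand,
            "start": int(starts.min()), "end": int(ends.max()),
            "thick_start": cds[0], "thick_end": cds[1],
            "exon_starts": starts, "exon_ends": ends, "tss": tss}


@pytest.fixture(scope="module")
def ann():
    genes = pd.DataFrame([
        toy_gene("gA", "chr1", "+", 20_000,
                 [(20_000, 20_400), (21_000, 21_300), (22_000, 22_500)],
                 (20_200, 22_200)),
        toy_gene("gB", "chr1", "-", 40_000,
                 [(34_000, 34_500), (36_000, 36_400), (39_500, 40_000)],
                 (34_300, 39_700)),
    ])
    return build_annotation({"chr1": 60_000, "chr2": 20_000},
                            cgi_df([]), genes, CFG)


@pytest.fixture(scope="module")
def promoter_ann():
    genes = pd.DataFrame([toy_gene("gA", "chr1", "+", 20_000,
                                   [(20_000, 21_000)], (20_200, 20_800))])
    return build_annotation({"chr1": 60_000}, cgi_df([]), genes, CFG)


class TestGeneClassification:

    def base_oracle(self, pos, ann):
        for cat in GENE_CATEGORIES[:-1]:
            sets = ann.gene_features[cat].get("chr1")
            if sets is not None and any(s <= pos < e for s, e in zip(*sets)):
                return cat
        return "intergenic"

    def test_cds_beats_neighbor_promoter(self, ann):
        # inside gA's CDS and < 1 kb upstream of nothing conflicting: craft a
        # window overlapping both gA CDS exon and gB's 5 kb upstream region
        w = pd.DataFrame({"chrom": ["chr1"], "start": [20_250], "end": [20_350]})
        assert rs.classify_gene_context(w, ann)[0] == "CDS_exon"

    def test_gene_free_chromosome_is_intergenic(self, ann):
        w = pd.DataFrame({"chrom": ["chr2"], "start": [5_000], "end": [5_100]})
        assert rs.classify_gene_context(w, ann)[0] == "intergenic"

    def test_minus_strand_upstream_is_rightward(self, ann):
        w = pd.DataFrame({"chrom": ["chr1"], "start": [40_200], "end": [40_300]})
        assert rs.classify_gene_context(w, ann)[0] == "TSS_up_1kb"
        w5 = pd.DataFrame({"chrom": ["chr1"], "start": [43_000], "end": [43_100]})
        assert rs.classify_gene_context(w5, ann)[0] == "TSS_up_5kb"

    def test_windows_match_per_base_precedence_oracle(self, ann):
        rng = np.random.default_rng(2)
        starts = rng.integers(15_000, 48_000, 250)
        w = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 100})
        got = rs.classify_gene_context(w, ann)
        rank = {c: i for i, c in enumerate(GENE_CATEGORIES)}
        for i, s in enumerate(starts):
            labels = {self.base_oracle(p, ann) for p in range(s, s + 100)}
            assert got[i] == min(labels, key=rank.get)

    def test_every_window_gets_one_label_of_each_kind(self, default_analysis):
        m = default_analysis["m"]
        ann = default_analysis["ann"]
        cgi = rs.classify_cgi_context(m.windows, ann)
        gene = rs.classify_gene_context(m.windows, ann)
        assert set(cgi) <= set(CGI_CATEGORIES)
        assert set(gene) <= set(GENE_CATEGORIES)
        assert len(cgi) == len(gene) == m.n_windows


class TestDistributionsAndEnrichment:
    def test_single_category_and_sum(self):
        d = rs.context_distribution(["CGI"] * 7, CGI_CATEGORIES)
        assert d["CGI"] == 1.0 and abs(d.sum() - 1.0) < 1e-9

    def test_hand_tally(self):
        labels = ["CGI"] * 5 + ["shore"] * 10 + ["shelf"] * 4 + ["open_sea"]
        d = rs.context_distribution(labels, CGI_CATEGORIES)
        assert d.tolist() == [0.25, 0.5, 0.2, 0.05]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rs.context_distribution([])

    @pytest.mark.parametrize("p_ram,p_bg,expected", [
        (51.0, 43.0, 18.6), (50.0, 43.0, 16.3), (38.0, 43.0, -11.6),
        (43.0, 43.0, 0.0)])
    def test_relative_change_arithmetic(self, p_ram, p_bg, expected):
        out = rs.enrichment_vs_background(pd.Series({"shore": p_ram}),
                                          pd.Series({"shore": p_bg}))
        assert round(float(out["shore"]), 1) == expected

    def test_zero_background_is_undefined_not_infinite(self):
        out = rs.enrichment_vs_background(pd.Series({"shelf": 0.2}),
                                          pd.Series({"shelf": 0.0}))
        assert np.isnan(out["shelf"])


class TestPromoterAssignment:
    def _assign(self, ann, start, end):
        rams = pd.DataFrame({"chrom": ["chr1"], "start": [start], "end": [end],
                             "comparison": ["Ctr_vs_UG"], "direction": ["hyper"],
                             "p": [0.01], "log2FC": [1.0]})
        return rs.assign_promoters(rams, ann, CFG)["promoter_genes"].iloc[0]

    def test_boundary_inclusion_half_open(self, promoter_ann):
        assert self._assign(promoter_ann, 20_000 + 1400, 20_000 + 1500) == ["gA"]

    def test_boundary_exclusion_half_open(self, promoter_ann):
        assert self._assign(promoter_ann, 20_000 + 1500, 20_000 + 1600) == []

    def test_assignments_match_distance_scan_oracle(self, default_analysis):
        ann = default_analysis["ann"]
        final = default_analysis["finals"]["Ctr_vs_MG"]
        if final.empty:
            pytest.skip("no final RAMs in fixture")
        assigned = rs.assign_promoters(final, ann, CFG)
        proms = ann.promoters
        for row in assigned.head(200).itertuples(index=False):
            cand = proms[proms["chrom"] == row.chrom]
            expected = sorted(cand.loc[
                (cand["p_start"] < row.end) & (cand["p_end"] > row.start),
                "gene_id"])
            assert sorted(row.promoter_genes) == expected
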