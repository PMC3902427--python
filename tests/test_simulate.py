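"""Synthetic-data generator: determinism, calibration and truth fidelity."""

import numpy as np
import pandas as pd
import pytest

import ramscan as rs
from ramscan import intervals as iv
from ramscan.config import ConfigError
from ramscan.simulate import TILE_SIZE, _sample_seed


class TestGenomeConstruction:
    def test_zero_length_autosome_rejected(self):
        with pytest.raises(ConfigError):
            rs.build_toy_genome(rs.GenomeConfig(autosome_lengths=(0,)), seed=1)

    def test_same_seed_is_byte_identical(self):
        a = rs.build_toy_genome(seed=5)
        b = rs.build_toy_genome(seed=5)
        assert a.chrom_sizes == b.chrom_sizes
        pd.testing.assert_frame_equal(a.cgis, b.cgis)
        assert a.genes["gene_id"].tolist() == b.genes["gene_id"].tolist()
        for col in ("start", "end", "thick_start", "thick_end", "tss"):
            assert a.genes[col].tolist() == b.genes[col].tolist()

    def test_required_chromosomes_present(self):
        g = rs.build_toy_genome(seed=2)
        assert "chrX" in g.chrom_sizes and "chrY" in g.chrom_sizes
        assert any(not c.startswith("chrX") and not c.startswith("chrY")
                   for c in g.chrom_sizes)

    def test_cgis_non_overlapping_and_in_bounds(self):
        g = rs.build_toy_genome(seed=3)
        for chrom, grp in g.cgis.groupby("chrom"):
            assert (grp["start"] >= 0).all()
            assert (grp["end"] <= g.chrom_sizes[chrom]).all()
            s = grp.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_tss_consistent_with_strand(self):
        g = rs.build_toy_genome(seed=4)
        plus = g.genes[g.genes["strand"] == "+"]
        minus = g.genes[g.genes["strand"] == "-"]
        assert (plus["tss"] == plus["start"]).all()
        assert (minus["tss"] == minus["end"]).all()

    def test_cgi_count_matches_poisson_rate_over_seeds(self):
        # 2 Mb autosome with 50 kb mean spacing -> lambda = 40 CGIs expected;
        # the mean over 100 regenerations must sit within 3*sqrt(lambda/100)
        cfg = rs.GenomeConfig(autosome_lengths=(2_000_000,), chrx_length=10_000,
                              chry_length=10_000, cgi_spacing=50_000,
                              gene_at_cgi_prob=0.0, n_intergenic_genes=0)
        lam = 2_000_000 / 50_000
        counts = [len(rs.build_toy_genome(cfg, seed=s).cgis.query("chrom=='chr1'"))
                  for s in range(100)]
        assert abs(np.mean(counts) - lam) <= 3 * np.sqrt(lam / 100)
        # and individual draws stay within the 3-sigma Poisson band mostly
        within = np.abs(np.array(counts) - lam) <= 3 * np.sqrt(lam)
        assert within.mean() > 0.95


class TestPlantedMethylome:
    def test_no_effects_means_identical_groups_and_empty_truth(self):
        g = rs.build_toy_genome(seed=6)
        land = rs.plant_methylome(g, [], seed=7)
        assert land.truth.empty
        assert np.array_equal(land.group_levels("Ctr"), land.group_levels("UG"))
        assert np.array_equal(land.group_levels("Ctr"), land.group_levels("MG"))

    def test_ug_only_doubling_from_base_point_two(self):
        g = rs.build_toy_genome(seed=6)
        eff = rs.PlantedEffect("chr1", 100_000, 100_500, "hyper", "UG_only", 2.0)
        land = rs.plant_methylome(g, [eff], seed=7, planted_base=0.2)
        row = land.tiles.query("chrom=='chr1' and start==100000").iloc[0]
        assert (row["m_Ctr"], row["m_UG"], row["m_MG"]) == (0.2, 0.4, 0.2)

    def test_off_chromosome_effect_rejected(self):
        g = rs.build_toy_genome(seed=6)
        bad = rs.PlantedEffect("chr1", 0, g.chrom_sizes["chr1"] + 500,
                               "hyper", "monotonic", 2.0)
        with pytest.raises(ConfigError):
            rs.plant_methylome(g, [bad], seed=7)

    def test_levels_bounded_and_dose_classes_ordered(self):
        g = rs.build_toy_genome(seed=8)
        effects = rs.choose_planted_sites(g, 50, 3.0, seed=9)
        land = rs.plant_methylome(g, effects, seed=10)
        for grp in ("Ctr", "UG", "MG"):
            m = land.group_levels(grp)
            assert (m >= 0).all() and (m <= 1).all()
        key = pd.MultiIndex.from_frame(land.tiles[["chrom", "start"]])
        row_of = pd.Series(np.arange(len(land.tiles)), index=key)
        for eff, row in zip(effects, land.truth.itertuples(index=False)):
            r = row_of[(row.chrom, row.start)]
            t = land.tiles.iloc[r]
            ctr, ug, mg = t["m_Ctr"], t["m_UG"], t["m_MG"]
            if row.dose_class == "monotonic":
                assert (ctr <= ug <= mg) if row.direction == "hyper" \
                    else (ctr >= ug >= mg)
            elif row.dose_class == "UG_only":
                assert mg == ctr and (ug > ctr) == (row.direction == "hyper")
            else:
                assert ug == ctr and (mg > ctr) == (row.direction == "hyper")

    def test_planted_group_means_differ_from_background_in_truth_direction(self):
        g = rs.build_toy_genome(seed=11)
        effects = rs.choose_planted_sites(g, 50, 3.0, seed=12)
        land = rs.plant_methylome(g, effects, seed=13)
        for row in land.truth.itertuples(index=False):
            t = land.tiles.query("chrom == @row.chrom and start == @row.start").iloc[0]
            exposed = t["m_MG"] if row.dose_class != "UG_only" else t["m_UG"]
            assert (exposed > t["m_Ctr"]) == (row.direction == "hyper")

    def test_truth_rows_equal_number_of_planted_effects(self):
        g = rs.build_toy_genome(seed=14)
        effects = rs.choose_planted_sites(g, 23, 3.0, seed=15)
        land = rs.plant_methylome(g, effects, seed=16)
        assert len(land.truth) == 23


class TestReadSimulation:
    def test_zero_depth_gives_empty_readset(self):
        g = rs.build_toy_genome(seed=17)
        land = rs.plant_methylome(g, [], seed=18)
        out = rs.simulate_reads(land, g, rs.SimulationConfig(reads_per_sample=0),
                                "s", "Ctr", "M", seed=19)
        assert len(out) == 0

    def test_zero_methylation_region_gets_zero_reads(self):
        g = rs.build_toy_genome(seed=17)
        land = rs.plant_methylome(g, [], seed=18)
        tile = land.tiles.query("chrom=='chr1' and start==50000").index[0]
        land.tiles.loc[tile, "m_Ctr"] = 0.0
        out = rs.simulate_reads(land, g, rs.SimulationConfig(reads_per_sample=50_000),
                                "s", "Ctr", "M", seed=19)
        reads = out.reads.query("chrom=='chr1' and 50000 <= start < 50500")
        assert len(reads) == 0

    def test_region_share_matches_binomial_expectation(self):
        # a landscape where one tile carries exactly 10% of the sampling
        # weight; with 100k reads the mean count over 20 seeds must fall
        # within 3*sqrt(npq) of 10,000
        g = rs.build_toy_genome(rs.GenomeConfig(autosome_lengths=(50_000,),
                                                chrx_length=10_000,
                                                chry_length=10_000,
                                                cgi_spacing=2_000_000,
                                                gene_at_cgi_prob=0,
                                                n_intergenic_genes=0), seed=20)
        land = rs.plant_methylome(g, [], seed=21)
        # zero weight everywhere except chr1's 100 equal 500 bp tiles, so the
        # first ten tiles [0, 5000) carry exactly 10% of the sampling weight
        land.tiles["m_Ctr"] = 0.0
        idx = land.tiles.index[land.tiles["chrom"] == "chr1"]
        land.tiles.loc[idx, "m_Ctr"] = 1.0
        n, p = 100_000, 0.1
        cfg = rs.SimulationConfig(reads_per_sample=n, depth_log10_sd=0.0)
        counts = []
        for s in range(20):
            out = rs.simulate_reads(land, g, cfg, "s", "Ctr", "M", seed=100 + s)
            hits = out.reads.query("chrom=='chr1' and start < 5000")
            counts.append(len(hits))
        assert abs(np.mean(counts) - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_enrichment_fold_calibration(self, default_experiment):
        g = default_experiment["genome"]
        land = default_experiment["landscape"]
        cfg = rs.SimulationConfig(reads_per_sample=150_000)
        out = rs.simulate_reads(land, g, cfg, "s", "Ctr", "M", seed=77)
        in_reads = out_reads = in_bp = out_bp = 0
        for chrom, L in g.chrom_sizes.items():
            if chrom == "chrY":
                continue  # single-sex chromosome, no female counterpart here
            cg = g.cgis[g.cgis["chrom"] == chrom]
            s, e = iv.clip_intervals(cg["start"].to_numpy() - 4000,
                                     cg["end"].to_numpy() + 4000, L)
            s, e = iv.merge_intervals(s, e)
            bp = int((e - s).sum())
            rr = out.reads[out.reads["chrom"] == chrom]
            hit = iv.overlaps_any(rr["start"].to_numpy(),
                                  rr["start"].to_numpy() + 1, s, e)
            in_reads += hit.sum()
            out_reads += (~hit).sum()
            in_bp += bp
            out_bp += L - bp
        fold = (in_reads / in_bp) / (out_reads / out_bp)
        assert abs(fold - 2.3) <= 0.15 * 2.3

    def test_per_sample_streams_reproducible(self):
        g = rs.build_toy_genome(seed=23)
        land = rs.plant_methylome(g, [], seed=24)
        cfg = rs.SimulationConfig(reads_per_sample=20_000)
        all_sets = rs.simulate_experiment(g, land, cfg, seed=50)
        row = all_sets[3]
        lone = rs.simulate_reads(land, g, cfg, row.sample, row.group, row.sex,
                                 seed=_sample_seed(50, 3))
        pd.testing.assert_frame_equal(row.reads, lone.reads)


class TestFixtureIo:
    def test_fixture_loads_with_expected_shape(self, small_fixture_dir):
        chrom_sizes, cgis, genes, samples, readsets, truth = \
            rs.load_fixture(small_fixture_dir)
        assert len(readsets) == 12
        assert truth is not None and len(truth) == 12  # one row per effect
        assert set(samples["group"]) == {"Ctr", "UG", "MG"}
        first = readsets[0].reads
        assert (first["end"] > first["start"]).all()
        assert set(first["chrom"]) <= set(chrom_sizes)

    def test_empty_readset_writes_valid_zero_line_bed(self, tmp_path):
        from ramscan import io as rio
        from ramscan.windows import ReadSet
        empty = pd.DataFrame({"chrom": pd.Series(dtype=str),
                              "start": pd.Series(dtype=np.int64),
                              "end": pd.Series(dtype=np.int64),
                              "strand": pd.Series(dtype=str)})
        path = tmp_path / "empty.bed"
        rio.write_reads_bed(empty, path)
        assert path.read_text() == ""
        back = rio.read_reads_bed(path)
        assert len(back) == 0

    def test_reads_round_trip_through_bed(self, tmp_path, default_experiment):
        from ramscan import io as rio
        reads = default_experiment["readsets"][0].reads.head(500)
        path = tmp_path / "r.bed"
        rio.write_reads_bed(reads, path)
        back = rio.read_reads_bed(path)
        pd.testing.assert_frame_equal(reads.reset_index(drop=True), back)

    def test_genes_round_trip_through_bed12(self, tmp_path, default_experiment):
        from ramscan import io as rio
        genes = default_experiment["genome"].genes
        path = tmp_path / "g.bed12"
        rio.write_genes_bed12(genes, path)
        back = rio.read_genes_bed12(path)
        for col in ("gene_id", "chrom", "strand", "start", "end",
                    "thick_start", "thick_end", "tss"):
            assert genes[col].tolist() == back[col].tolist()
        for a, b in zip(genes["exon_starts"], back["exon_starts"]):
            assert np.array_equal(a, b)
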