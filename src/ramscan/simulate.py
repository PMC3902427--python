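"""Synthetic methylation-enrichment sequencing data with planted ground truth.

The generator emulates a 12-sample, 3-exposure-group enrichment-seq (MeDIP/
MethylPlex-like) experiment at desk scale: a toy multi-chromosome genome
(autosomes plus chrX and chrY) with CpG islands and gene models; a
piecewise-constant methylation landscape over 500 bp tiles carrying planted
differential regions with hyper/hypo directions and monotonic, low-dose-only
(UG_only) or high-dose-only (MG_only) dose–response classes; and per-sample
reads drawn with probability proportional to (group- and sex-specific
methylation level) × (CG-density enrichment weight), calibrated so mean read
depth in CGI ± 4 kb neighborhoods exceeds the rest of the genome by a
configurable fold (2.3× by default, matching typical enrichment chemistry).

Sex is modeled as chrX dosage (female 2×, male 1×) plus chrY reads only in
males with a small female background leak, so a male-vs-female contrast has
genuine signal on the sex chromosomes and none on autosomes — the
substrate of the empirical-FDR check.

Randomness: one master seed; each sample draws from a stream seeded with
(master + sample index) mod 2^31, so single samples can be regenerated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import intervals as iv
from . import io as _io
from .config import ConfigError
from .windows import ReadSet

TILE_SIZE = 500            # landscape resolution, bp
DOSE_CLASSES = ("monotonic", "UG_only", "MG_only")
DEFAULT_GROUP_SIZES = {"Ctr": 4, "UG": 4, "MG": 4}
# sex split of the emulated design: Ctr 2M/2F, UG 2M/2F, MG 1M/3F
DEFAULT_SEXES = {"Ctr": ("M", "F", "M", "F"), "UG": ("M", "F", "M", "F"),
                 "MG": ("M", "F", "F", "F")}


@dataclass
class GenomeConfig:
    """Shape of the toy genome.

    Sex chromosomes are kept to a realistic minority share of the genome
    (chrX ~8%, chrY ~4%, echoing the mouse karyotype): an oversized chrX
    would let the female 2x dosage visibly depress the female autosomal
    read share — a library-composition artifact, not a methylation signal.
    """
    autosome_lengths: tuple[int, ...] = (2_750_000, 2_500_000)
    chrx_length: int = 500_000
    chry_length: int = 250_000
    cgi_spacing: int = 40_000        # mean bp per CGI (includes the CGI itself)
    cgi_length_range: tuple[int, int] = (400, 1400)
    gene_at_cgi_prob: float = 0.6    # fraction of CGIs seeding a gene TSS
    n_intergenic_genes: int = 10     # extra genes placed away from CGIs

    def validate(self) -> None:
        lengths = list(self.autosome_lengths) + [self.chrx_length, self.chry_length]
        if len(self.autosome_lengths) < 1:
            raise ConfigError("at least one autosome is required")
        if any(l < 10_000 for l in lengths):
            raise ConfigError("chromosome lengths must be at least 10 kb")
        if self.cgi_spacing <= self.cgi_length_range[1]:
            raise ConfigError("cgi_spacing must exceed the maximum CGI length")


@dataclass
class GenomeModel:
    chrom_sizes: dict[str, int]
    cgis: pd.DataFrame    # chrom, start, end (non-overlapping)
    genes: pd.DataFrame   # as io.read_genes_bed12


@dataclass
class PlantedEffect:
    """Specification of one planted differential region."""
    chrom: str
    start: int
    end: int
    direction: str        # 'hyper' | 'hypo'
    dose_class: str       # 'monotonic' | 'UG_only' | 'MG_only'
    multiplier: float     # fold applied to the base level in the exposed group


@dataclass
class MethylationLandscape:
    """Per-tile methylation levels per exposure group, plus the truth table."""
    tiles: pd.DataFrame   # chrom, start, end, m_Ctr, m_UG, m_MG
    truth: pd.DataFrame   # chrom, start, end, direction, dose_class, multiplier
    sex_effects: pd.DataFrame  # chrom, start, end, effect
    x_female_factor: float = 2.0
    y_female_leak: float = 0.005

    def group_levels(self, group: str) -> np.ndarray:
        return self.tiles[f"m_{group}"].to_numpy(np.float64)


@dataclass
class SimulationConfig:
    reads_per_sample: int = 200_000
    read_length: int = 80
    enrichment_fold: float = 2.3       # CGI±4kb depth over the rest
    depth_log10_sd: float = 0.1        # per-sample library-size scatter
    cgi_core_weight: float = 60.0      # sampling weight of CGI bases
    cgi_flank_weight: float = 1.5      # weight of the 0–4 kb CGI flanks
    neighborhood: int = 4000           # bp around CGIs counted as enriched

    def validate(self) -> None:
        if self.reads_per_sample < 0:
            raise ConfigError("reads_per_sample must be non-negative")
        if self.read_length < 1:
            raise ConfigError("read_length must be at least 1")
        if self.enrichment_fold < 1:
            raise ConfigError("enrichment_fold must be at least 1")


def _sample_seed(master: int, index: int) -> int:
    return (int(master) + int(index)) % (2**31)


def build_toy_genome(config: GenomeConfig | None = None, seed: int = 0) -> GenomeModel:
    """Deterministically generate chromosomes, CGIs and gene models."""
    config = config or GenomeConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    chrom_sizes: dict[str, int] = {}
    for i, length in enumerate(config.autosome_lengths, start=1):
        chrom_sizes[f"chr{i}"] = int(length)
    chrom_sizes["chrX"] = int(config.chrx_length)
    chrom_sizes["chrY"] = int(config.chry_length)

    lo, hi = config.cgi_length_range
    mean_len = (lo + hi) / 2.0
    gap_mean = config.cgi_spacing - mean_len  # so E[count] = length / spacing
    cgi_rows = []
    for chrom, length in chrom_sizes.items():
        pos = rng.exponential(gap_mean)
        while True:
            clen = int(rng.integers(lo, hi + 1))
            start = int(round(pos))
            if start + clen >= length:
                break
            cgi_rows.append((chrom, start, start + clen))
            pos = start + clen + rng.exponential(gap_mean)
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])

    genes = _place_genes(chrom_sizes, cgis, config, rng)
    return GenomeModel(chrom_sizes, cgis, genes)


def _make_gene(gene_id: str, chrom: str, tss: int, strand: str, length: int,
               rng: np.random.Generator, chrom_len: int) -> dict | None:
    """Build one gene: exon/intron chain downstream of the TSS, CDS inset so
    that terminal exon portions are UTR."""
    n_exons = int(rng.integers(3, 7))
    exon_lens = rng.integers(150, 400, n_exons)
    intron_lens = rng.integers(500, max(600, (length - exon_lens.sum()) //
                                        max(n_exons - 1, 1) + 501), n_exons - 1)
    rel = [0]
    for i in range(n_exons - 1):
        rel.append(rel[-1] + exon_lens[i] + intron_lens[i])
    rel_starts = np.array(rel, dtype=np.int64)
    rel_ends = rel_starts + exon_lens
    span = int(rel_ends[-1])
    if strand == "+":
        start = tss
        exon_starts = start + rel_starts
    else:
        start = tss - span
        exon_starts = start + rel_starts
    exon_ends = exon_starts + exon_lens
    end = start + span
    if start < 0 or end > chrom_len:
        return None
    # CDS runs from mid first exon to mid last exon -> both UTRs nonempty
    thick_start = int(exon_starts[0] + exon_lens[0] // 2)
    thick_end = int(exon_ends[-1] - exon_lens[-1] // 2)
    return {"gene_id": gene_id, "chrom": chrom, "strand": strand,
            "start": int(start), "end": int(end),
            "thick_start": thick_start, "thick_end": thick_end,
            "exon_starts": exon_starts, "exon_ends": exon_ends,
            "tss": int(tss) if strand == "+" else int(end)}


def _place_genes(chrom_sizes: dict[str, int], cgis: pd.DataFrame,
                 config: GenomeConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    gid = 0
    for cgi in cgis.itertuples(index=False):
        if cgi.chrom == "chrY" or rng.random() >= config.gene_at_cgi_prob:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int((cgi.start + cgi.end) // 2)
        g = _make_gene(f"gene{gid:04d}", cgi.chrom, tss, strand,
                       int(rng.integers(4000, 20000)), rng,
                       chrom_sizes[cgi.chrom])
        if g is not None:
            rows.append(g)
            gid += 1
    autosomes = [c for c in chrom_sizes if c not in ("chrX", "chrY")]
    for _ in range(config.n_intergenic_genes):
        chrom = autosomes[int(rng.integers(len(autosomes)))]
        tss = int(rng.integers(30_000, chrom_sizes[chrom] - 30_000))
        strand = "+" if rng.random() < 0.5 else "-"
        g = _make_gene(f"gene{gid:04d}", chrom, tss, strand,
                       int(rng.integers(4000, 20000)), rng, chrom_sizes[chrom])
        if g is not None:
            rows.append(g)
            gid += 1
    cols = ["gene_id", "chrom", "strand", "start", "end", "thick_start",
            "thick_end", "exon_starts", "exon_ends", "tss"]
    return pd.DataFrame(rows, columns=cols)


def choose_planted_sites(genome: GenomeModel, n_effects: int = 30,
                         multiplier: float = 3.0, seed: int = 0,
                         region_size: int = TILE_SIZE) -> list[PlantedEffect]:
    """Pick CGI-centered, tile-aligned autosomal regions and cycle the
    direction × dose-class combinations across them."""
    rng = np.random.default_rng(seed)
    auto_cgis = genome.cgis[~genome.cgis["chrom"].isin(["chrX", "chrY"])]
    if len(auto_cgis) < n_effects:
        raise ConfigError(f"only {len(auto_cgis)} autosomal CGIs for "
                          f"{n_effects} planted effects")
    pick = rng.choice(len(auto_cgis), size=n_effects, replace=False)
    combos = [(d, c) for d in ("hyper", "hypo") for c in DOSE_CLASSES]
    effects = []
    for i, row_i in enumerate(sorted(pick)):
        cgi = auto_cgis.iloc[row_i]
        mid = (cgi.start + cgi.end) // 2
        tile_start = (mid // TILE_SIZE) * TILE_SIZE
        direction, dose_class = combos[i % len(combos)]
        effects.append(PlantedEffect(cgi.chrom, int(tile_start),
                                     int(tile_start + region_size),
                                     direction, dose_class, multiplier))
    return effects


def _tile_frame(chrom_sizes: dict[str, int]) -> pd.DataFrame:
    frames = []
    for chrom, length in chrom_sizes.items():
        starts = np.arange(0, length, TILE_SIZE, dtype=np.int64)
        ends = np.minimum(starts + TILE_SIZE, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(frames, ignore_index=True)


def plant_methylome(genome: GenomeModel, effects: list[PlantedEffect],
                    seed: int = 0, base_level: float = 0.35,
                    jitter_sd: float = 0.05,
                    planted_base: float = 0.30) -> MethylationLandscape:
    """Lay down per-tile methylation levels and apply the planted effects.

    Background tiles share a jittered base level across groups.  Planted
    tiles start from ``planted_base`` (hyper) or ``min(planted_base *
    multiplier, 0.95)`` (hypo, so the exposed level drops by the multiplier)
    and the exposed groups move by the effect multiplier according to the
    dose class: monotonic (Ctr ≤ UG ≤ MG or reverse), UG_only (MG = Ctr) or
    MG_only (UG = Ctr).
    """
    rng = np.random.default_rng(seed)
    tiles = _tile_frame(genome.chrom_sizes)
    base = np.clip(rng.normal(base_level, jitter_sd, len(tiles)), 0.02, 0.98)
    m = {g: base.copy() for g in ("Ctr", "UG", "MG")}

    key = pd.MultiIndex.from_frame(tiles[["chrom", "start"]])
    row_of = pd.Series(np.arange(len(tiles)), index=key)

    truth_rows = []
    for eff in effects:
        if eff.chrom not in genome.chrom_sizes:
            raise ConfigError(f"planted region on unknown chromosome {eff.chrom}")
        if eff.start < 0 or eff.end > genome.chrom_sizes[eff.chrom]:
            raise ConfigError(f"planted region {eff.chrom}:{eff.start}-{eff.end} "
                              "off the end of the chromosome")
        if eff.direction not in ("hyper", "hypo"):
            raise ConfigError(f"unknown direction {eff.direction!r}")
        if eff.dose_class not in DOSE_CLASSES:
            raise ConfigError(f"unknown dose class {eff.dose_class!r}")
        if eff.direction == "hyper":
            low = planted_base
            if low * eff.multiplier > 1.0:
                raise ConfigError("effect multiplier pushes level above 1")
            high = low * eff.multiplier
            ctr = low
        else:
            high = min(planted_base * eff.multiplier, 0.95)
            low = high / eff.multiplier
            ctr = high
        first = eff.start // TILE_SIZE * TILE_SIZE
        for tstart in range(first, eff.end, TILE_SIZE):
            row = row_of.get((eff.chrom, tstart))
            if row is None:
                continue
            exposed = high if eff.direction == "hyper" else low
            mid = (ctr + exposed) / 2.0
            m["Ctr"][row] = ctr
            if eff.dose_class == "monotonic":
                m["UG"][row] = mid
                m["MG"][row] = exposed
            elif eff.dose_class == "UG_only":
                m["UG"][row] = exposed
                m["MG"][row] = ctr
            else:  # MG_only
                m["UG"][row] = ctr
                m["MG"][row] = exposed
        truth_rows.append((eff.chrom, eff.start, eff.end, eff.direction,
                           eff.dose_class, eff.multiplier))

    tiles = tiles.copy()
    for g in ("Ctr", "UG", "MG"):
        tiles[f"m_{g}"] = m[g]
    truth = pd.DataFrame(truth_rows, columns=_io.TRUTH_COLUMNS)
    sex_rows = []
    if "chrX" in genome.chrom_sizes:
        sex_rows.append(("chrX", 0, genome.chrom_sizes["chrX"], "female_dosage_2x"))
    if "chrY" in genome.chrom_sizes:
        sex_rows.append(("chrY", 0, genome.chrom_sizes["chrY"], "male_only"))
    sex_effects = pd.DataFrame(sex_rows, columns=["chrom", "start", "end", "effect"])
    return MethylationLandscape(tiles, truth, sex_effects)


def _tile_weights(landscape: MethylationLandscape, genome: GenomeModel,
                  simcfg: SimulationConfig, group: str, sex: str) -> np.ndarray:
    """Per-tile sampling weight: methylation × CG-density × sex factor,
    calibrated so the realized CGI±4kb depth fold equals the configured one.

    Calibration is done against the exact base-pair overlap of each tile
    with the CGI±neighborhood set (tiles straddling a neighborhood edge
    contribute to both sides), so the fold measured at base resolution on
    the simulated reads matches the configured value in expectation.
    """
    tiles = landscape.tiles
    m = landscape.group_levels(group)
    w = np.ones(len(tiles))
    in_bp = np.zeros(len(tiles), dtype=np.float64)  # bp of tile inside CGI±nbhd
    for chrom, grp in tiles.groupby("chrom", sort=False):
        cg = genome.cgis[genome.cgis["chrom"] == chrom]
        if cg.empty:
            continue
        rows = grp.index.to_numpy()
        t_s = grp["start"].to_numpy()
        t_e = grp["end"].to_numpy()
        core = iv.overlaps_any(t_s, t_e, cg["start"].to_numpy(),
                               cg["end"].to_numpy())
        n_s, n_e = iv.clip_intervals(cg["start"].to_numpy() - simcfg.neighborhood,
                                     cg["end"].to_numpy() + simcfg.neighborhood,
                                     genome.chrom_sizes[chrom])
        n_s, n_e = iv.merge_intervals(n_s, n_e)
        near = iv.overlaps_any(t_s, t_e, n_s, n_e)
        w[rows[near]] = simcfg.cgi_flank_weight
        w[rows[core]] = simcfg.cgi_core_weight
        for s, e in zip(n_s, n_e):  # exact overlap bp per tile
            in_bp[rows] += np.maximum(
                np.minimum(t_e, e) - np.maximum(t_s, s), 0)

    lens = (tiles["end"] - tiles["start"]).to_numpy(np.float64)
    out_bp = lens - in_bp
    dens = m * w  # expected depth per bp before calibration
    scaled = in_bp > 0  # tiles whose weight the calibration factor multiplies
    total_in = in_bp.sum()
    total_out = out_bp.sum()
    if total_in > 0 and total_out > 0:
        # solve fold = (lam*A/In) / ((lam*B + C)/Out) with A the scaled-tile
        # density mass inside, B its spill outside, C the unscaled mass outside
        A = (dens[scaled] * in_bp[scaled]).sum() / total_in
        B = (dens[scaled] * out_bp[scaled]).sum() / total_out
        C = (dens[~scaled] * out_bp[~scaled]).sum() / total_out
        f = simcfg.enrichment_fold
        if A - f * B > 0 and C > 0:
            lam = f * C / (A - f * B)
            dens = dens * np.where(scaled, lam, 1.0)

    chroms = tiles["chrom"].to_numpy()
    if sex == "F":
        dens = dens * np.where(chroms == "chrX", landscape.x_female_factor, 1.0)
        dens = dens * np.where(chroms == "chrY", landscape.y_female_leak, 1.0)
    return dens * lens


def simulate_reads(landscape: MethylationLandscape, genome: GenomeModel,
                   simcfg: SimulationConfig, sample: str, group: str, sex: str,
                   seed: int = 0) -> ReadSet:
    """Draw one sample's reads from the weighted tile landscape."""
    simcfg.validate()
    rng = np.random.default_rng(seed)
    empty = pd.DataFrame({"chrom": pd.Series(dtype=str),
                          "start": pd.Series(dtype=np.int64),
                          "end": pd.Series(dtype=np.int64),
                          "strand": pd.Series(dtype=str)})
    if simcfg.reads_per_sample == 0:
        return ReadSet(sample, group, sex, empty)
    weights = _tile_weights(landscape, genome, simcfg, group, sex)
    total = weights.sum()
    if total <= 0:
        warnings.warn(f"sample {sample}: landscape has zero total weight; "
                      "returning an empty read set")
        return ReadSet(sample, group, sex, empty)

    n_reads = int(round(simcfg.reads_per_sample
                        * 10.0 ** rng.normal(0.0, simcfg.depth_log10_sd)))
    per_tile = rng.multinomial(n_reads, weights / total)
    tiles = landscape.tiles
    hit = np.flatnonzero(per_tile)
    chrom_arr = np.repeat(tiles["chrom"].to_numpy()[hit], per_tile[hit])
    tile_start = np.repeat(tiles["start"].to_numpy(np.int64)[hit], per_tile[hit])
    tile_len = np.repeat((tiles["end"] - tiles["start"]).to_numpy(np.int64)[hit],
                         per_tile[hit])
    offset = rng.integers(0, tile_len)  # uniform within the tile
    start = tile_start + offset
    chrom_len = np.vectorize(genome.chrom_sizes.__getitem__,
                             otypes=[np.int64])(chrom_arr) if len(chrom_arr) else \
        np.array([], dtype=np.int64)
    end = np.minimum(start + simcfg.read_length, chrom_len)
    strand = np.where(rng.random(len(start)) < 0.5, "+", "-")
    reads = pd.DataFrame({"chrom": chrom_arr, "start": start, "end": end,
                          "strand": strand})
    reads = reads.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return ReadSet(sample, group, sex, reads)


def default_sample_sheet() -> pd.DataFrame:
    rows = []
    for group, n in DEFAULT_GROUP_SIZES.items():
        for k in range(n):
            rows.append((f"{group}{k + 1}", group, DEFAULT_SEXES[group][k]))
    return pd.DataFrame(rows, columns=_io.SAMPLE_SHEET_COLUMNS)


def simulate_experiment(genome: GenomeModel, landscape: MethylationLandscape,
                        simcfg: SimulationConfig | None = None,
                        samples: pd.DataFrame | None = None,
                        seed: int = 0) -> list[ReadSet]:
    """Simulate every sample in the sheet with per-sample derived seeds."""
    simcfg = simcfg or SimulationConfig()
    samples = samples if samples is not None else default_sample_sheet()
    readsets = []
    for i, row in enumerate(samples.itertuples(index=False)):
        readsets.append(simulate_reads(landscape, genome, simcfg, row.sample,
                                       row.group, row.sex,
                                       seed=_sample_seed(seed, i)))
    return readsets


def write_fixture(genome: GenomeModel, landscape: MethylationLandscape,
                  readsets: list[ReadSet], out_dir: str | Path) -> dict[str, Path]:
    """Write the complete fixture: per-sample BED6 reads, chrom.sizes, CGI
    BED, gene BED12, sample sheet and truth table.  Round-trips through the
    package's readers."""
    out = Path(out_dir)
    (out / "reads").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    _io.write_chrom_sizes(genome.chrom_sizes, out / "chrom.sizes")
    paths["chrom_sizes"] = out / "chrom.sizes"
    _io.write_intervals_bed(genome.cgis, out / "cgis.bed")
    paths["cgis"] = out / "cgis.bed"
    _io.write_genes_bed12(genome.genes, out / "genes.bed12")
    paths["genes"] = out / "genes.bed12"
    sheet = pd.DataFrame({"sample": [r.sample for r in readsets],
                          "group": [r.group for r in readsets],
                          "sex": [r.sex for r in readsets]})
    _io.write_sample_sheet(sheet, out / "samples.tsv")
    paths["samples"] = out / "samples.tsv"
    _io.write_truth_table(landscape.truth, out / "truth.tsv")
    paths["truth"] = out / "truth.tsv"
    landscape.sex_effects.to_csv(out / "sex_effects.tsv", sep="\t", index=False)
    paths["sex_effects"] = out / "sex_effects.tsv"
    for rs in readsets:
        p = out / "reads" / f"{rs.sample}.bed"
        _io.write_reads_bed(rs.reads, p, name_prefix=f"{rs.sample}_r")
        paths[f"reads/{rs.sample}"] = p
    return paths


def load_fixture(fixture_dir: str | Path):
    """Read a fixture directory back into (chrom_sizes, cgis, genes, samples,
    readsets, truth)."""
    d = Path(fixture_dir)
    chrom_sizes = _io.read_chrom_sizes(d / "chrom.sizes")
    cgis = _io.read_intervals_bed(d / "cgis.bed")
    genes = _io.read_genes_bed12(d / "genes.bed12")
    samples = _io.read_sample_sheet(d / "samples.tsv")
    truth_path = d / "truth.tsv"
    truth = _io.read_truth_table(truth_path) if truth_path.exists() else None
    readsets = []
    for row in samples.itertuples(index=False):
        reads = _io.read_reads_bed(d / "reads" / f"{row.sample}.bed")
        readsets.append(ReadSet(row.sample, row.group, row.sex, reads))
    return chrom_sizes, cgis, genes, samples, readsets, truth
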