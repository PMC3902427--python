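"""End-to-end orchestration: fixture in, RAM calls and summary tables out.

All machine-readable outputs are 0-based half-open BED-convention TSV/BED
files, written deterministically (sorted rows, fixed float formatting), so
re-running with identical inputs and configuration reproduces byte-identical
files.  A run manifest records the configuration snapshot, input digests,
per-stage row counts and the package version.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as _io
from .config import PipelineConfig, COMPARISONS, COMPARISON_GROUPS
from .windows import ReadSet, tile_windows, count_reads, filter_low_coverage, \
    WindowCountMatrix
from .nbtest import (effective_library_sizes, estimate_common_dispersion,
                     run_comparison)
from .calling import (call_preliminary_rams, sample_support_filter,
                      adjacency_filter, finalize_rams, merge_rams, rams_to_bed6)
from .annotation import (build_annotation, classify_cgi_context,
                         classify_gene_context, context_distribution,
                         enrichment_vs_background, assign_promoters,
                         CGI_CATEGORIES, GENE_CATEGORIES)
from .promoters import (classify_promoter_dose_response, promoter_summary,
                        heatmap_matrix)
from .qc import sex_based_fdr, female_chry_qc, comparison_overlap

FLOAT_FORMAT = "%.6g"


def call_rams_for_comparison(m: WindowCountMatrix, group_a: str, group_b: str,
                             cfg: PipelineConfig, phi: float | None = None,
                             sizes: np.ndarray | None = None,
                             group_column: str = "group",
                             label: str | None = None
                             ) -> tuple[pd.DataFrame, dict]:
    """Test + gate + support + adjacency for one two-group comparison.

    Returns the final RAM window table and an info dict holding the stage
    ``counts``, the full ``diff`` table and the per-window filter ``flags``.
    This single code path serves both the exposure comparisons and the
    sex-contrast QC.
    """
    if sizes is None:
        sizes = effective_library_sizes(m, cfg.normalization)
    if phi is None:
        phi = estimate_common_dispersion(
            m, groups=dict(zip(m.samples["sample"], m.samples[group_column])),
            sizes=sizes).phi
    diff = run_comparison(m, group_a, group_b, phi, cfg, sizes=sizes,
                          group_column=group_column, label=label)
    prelim = call_preliminary_rams(diff, cfg)
    supported = sample_support_filter(prelim, m, group_a, group_b, sizes, cfg,
                                      group_column=group_column)
    # adjacency is judged among preliminary RAMs, then all flags must hold
    flagged = adjacency_filter(supported, cfg)
    final = finalize_rams(flagged)
    counts = {"tested": len(diff), "preliminary": len(prelim),
              "support_ok": int(supported["support_ok"].sum()),
              "final": len(final)}
    return final, {"counts": counts, "diff": diff, "flags": flagged}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def run_pipeline(fixture_dir: str | Path, out_dir: str | Path,
                 cfg: PipelineConfig | None = None,
                 comparisons: tuple[str, ...] = COMPARISONS) -> dict:
    """Run the whole analysis on a fixture directory; returns the manifest."""
    cfg = cfg or PipelineConfig()
    fixture_dir, out_dir = Path(fixture_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    chrom_sizes, cgis, genes, samples, readsets, truth = _load_inputs(fixture_dir)

    windows = tile_windows(chrom_sizes, cfg)
    m_all = count_reads(readsets, windows, cfg)
    m = filter_low_coverage(m_all, cfg)
    sizes = effective_library_sizes(m, cfg.normalization)
    disp = estimate_common_dispersion(m, sizes=sizes)

    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "inputs": {str(p.relative_to(fixture_dir)): _sha256(p)
                   for p in sorted(fixture_dir.rglob("*")) if p.is_file()},
        "coordinate_convention": "0-based half-open (BED)",
        "stages": {"windows_tiled": len(windows),
                   "windows_retained": m.n_windows,
                   "dispersion": disp.phi,
                   "library_sizes": dict(zip(m.sample_ids,
                                             map(int, m.library_sizes)))},
        "comparisons": {},
    }

    ann = build_annotation(chrom_sizes, cgis, genes, cfg)
    bg_cgi = context_distribution(classify_cgi_context(m.windows, ann),
                                  CGI_CATEGORIES)
    bg_gene = context_distribution(classify_gene_context(m.windows, ann),
                                   GENE_CATEGORIES)
    _write_tsv(bg_cgi.rename_axis("category").reset_index(),
               out_dir / "library_cgi_context.tsv")
    _write_tsv(bg_gene.rename_axis("category").reset_index(),
               out_dir / "library_gene_context.tsv")
    _write_tsv(ann.shores_df(), out_dir / "shores.bed")
    _write_tsv(ann.shelves_df(), out_dir / "shelves.bed")

    all_final = []
    for comp in comparisons:
        ga, gb = COMPARISON_GROUPS[comp]
        final, info = call_rams_for_comparison(m, ga, gb, cfg, phi=disp.phi,
                                               sizes=sizes, label=comp)
        manifest["comparisons"][comp] = info["counts"]
        _write_tsv(info["diff"], out_dir / f"diff_{comp}.tsv")
        _write_tsv(info["flags"], out_dir / f"rams_flags_{comp}.tsv")
        if len(final):
            final = final.copy()
            final["cgi_context"] = classify_cgi_context(final, ann)
            final["gene_context"] = classify_gene_context(final, ann)
            ram_cgi = context_distribution(final["cgi_context"], CGI_CATEGORIES)
            enr = enrichment_vs_background(ram_cgi, bg_cgi)
            table = pd.DataFrame({"category": CGI_CATEGORIES,
                                  "ram_proportion": ram_cgi.values,
                                  "library_proportion": bg_cgi.values,
                                  "relative_change_percent": enr.values})
            _write_tsv(table, out_dir / f"cgi_enrichment_{comp}.tsv")
        rams_to_bed6(final).to_csv(out_dir / f"rams_{comp}.bed", sep="\t",
                                   header=False, index=False)
        merged = merge_rams(final)
        _write_tsv(merged, out_dir / f"rams_merged_{comp}.tsv")
        all_final.append(final)

    finals = {comp: df for comp, df in zip(comparisons, all_final)}

    # promoter dose-response over the two exposure-vs-control comparisons
    prom_input = pd.concat([finals[c] for c in ("Ctr_vs_UG", "Ctr_vs_MG")
                            if c in finals], ignore_index=True)
    prom_rams = assign_promoters(prom_input, ann, cfg)
    prom_rams = prom_rams[prom_rams["promoter_genes"].map(len) > 0].reset_index(drop=True)
    cls = classify_promoter_dose_response(prom_rams)
    summary = promoter_summary(cls)
    _write_tsv(cls, out_dir / "promoter_classes.tsv")
    with open(out_dir / "promoter_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    if len(prom_rams):
        hm, mask = heatmap_matrix(prom_rams, m, ann, sizes, cls, cfg)
        hm.reset_index().to_csv(out_dir / "promoter_heatmap.tsv", sep="\t",
                                index=False, float_format=FLOAT_FORMAT)
        flagged = prom_rams.drop(columns=["promoter_genes"]).assign(
            promoter_genes=prom_rams["promoter_genes"].map(",".join),
            heatmap_included=mask.values)
        _write_tsv(flagged, out_dir / "promoter_rams.tsv")
    manifest["promoter_summary"] = summary

    # QC: sex-contrast FDR bound + chrY check + overlap stats
    report, sex_rams = sex_based_fdr(m, cfg, phi=None, sizes=sizes)
    qc = report.to_dict()
    qc["female_chry_hyper"] = female_chry_qc(sex_rams)
    overlap = comparison_overlap({c: finals[c] for c in finals})
    manifest["qc"] = qc
    manifest["overlap"] = {k: overlap[k] for k in
                           ("sizes", "union", "distinct", "distinct_percent")}
    _write_tsv(pd.DataFrame([qc]), out_dir / "qc_sex_fdr.tsv")
    _write_tsv(sex_rams, out_dir / "rams_M_vs_F.tsv")
    with open(out_dir / "overlap.json", "w") as fh:
        json.dump(overlap, fh, indent=2, sort_keys=True)

    m.to_tsv(out_dir / "window_counts.tsv")
    for comp, counts in manifest["comparisons"].items():
        assert counts["preliminary"] >= counts["support_ok"] >= counts["final"]
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    _write_log(manifest, out_dir / "run_log.txt")
    return manifest


def _load_inputs(fixture_dir: Path):
    from .simulate import load_fixture
    return load_fixture(fixture_dir)


def _write_log(manifest: dict, path: Path) -> None:
    lines = [f"ramscan {manifest['version']}",
             "coordinates: 0-based half-open (BED convention)",
             f"windows tiled: {manifest['stages']['windows_tiled']}",
             f"windows retained after coverage filter: "
             f"{manifest['stages']['windows_retained']}",
             f"common dispersion: {manifest['stages']['dispersion']:.4g}"]
    for comp, c in manifest["comparisons"].items():
        lines.append(f"{comp}: {c['preliminary']} preliminary -> "
                     f"{c['support_ok']} with sample support -> "
                     f"{c['final']} final RAM windows")
    qc = manifest["qc"]
    lines.append(f"sex contrast: X={qc['n_chrx']} Y={qc['n_chry']} "
                 f"autosomal={qc['n_autosomal']} "
                 f"max FDR bound={qc['max_fdr_percent']}% "
                 f"female chrY hyper={qc['female_chry_hyper']}")
    ov = manifest["overlap"]
    lines.append(f"overlap: union={ov['union']} distinct={ov['distinct']} "
                 f"({ov['distinct_percent']}%)")
    ps = manifest["promoter_summary"]
    lines.append(f"promoters: {ps['grand_total']} classified "
                 f"({ps['percent_gain']}% gain / {ps['percent_loss']}% loss, "
                 f"{ps['n_mixed_excluded']} mixed excluded)")
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_fixture(out_dir: str | Path, seed: int = 0,
                     reads_per_sample: int = 200_000,
                     n_effects: int = 30, multiplier: float = 3.0,
                     genome_config=None, sim_config=None) -> dict:
    """Generate the default 12-sample fixture into ``out_dir``."""
    from .simulate import (GenomeConfig, SimulationConfig, build_toy_genome,
                           choose_planted_sites, plant_methylome,
                           simulate_experiment, write_fixture)
    gcfg = genome_config or GenomeConfig()
    scfg = sim_config or SimulationConfig(reads_per_sample=reads_per_sample)
    genome = build_toy_genome(gcfg, seed=seed)
    effects = choose_planted_sites(genome, n_effects=n_effects,
                                   multiplier=multiplier, seed=seed + 1)
    landscape = plant_methylome(genome, effects, seed=seed + 2)
    readsets = simulate_experiment(genome, landscape, scfg, seed=seed + 3)
    paths = write_fixture(genome, landscape, readsets, out_dir)
    return {"n_samples": len(readsets), "n_effects": len(effects),
            "paths": {k: str(v) for k, v in paths.items()}}
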