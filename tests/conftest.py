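"""Shared fixtures: one default synthetic experiment reused across tests.

The default study conditions — 12 samples in three exposure groups (control
2M/2F, low dose 2M/2F, high dose 1M/3F), ~200k reads each over a ~6 Mb
genome, 30 planted 500 bp differential regions at 3× effect — are simulated
once per session; individual tests derive what they need from the shared
analysis state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ramscan as rs
from ramscan.pipeline import call_rams_for_comparison

MASTER_SEED = 1


@pytest.fixture(scope="session")
def default_experiment():
    genome = rs.build_toy_genome(seed=MASTER_SEED)
    effects = rs.choose_planted_sites(genome, n_effects=30, multiplier=3.0,
                                      seed=MASTER_SEED + 1)
    landscape = rs.plant_methylome(genome, effects, seed=MASTER_SEED + 2)
    readsets = rs.simulate_experiment(genome, landscape,
                                      rs.SimulationConfig(),
                                      seed=MASTER_SEED + 3)
    return {"genome": genome, "effects": effects, "landscape": landscape,
            "readsets": readsets}


@pytest.fixture(scope="session")
def default_analysis(default_experiment):
    cfg = rs.PipelineConfig()
    genome = default_experiment["genome"]
    windows = rs.tile_windows(genome.chrom_sizes, cfg)
    m_all = rs.count_reads(default_experiment["readsets"], windows, cfg)
    m = rs.filter_low_coverage(m_all, cfg)
    sizes = rs.effective_library_sizes(m, cfg.normalization)
    phi = rs.estimate_common_dispersion(m, sizes=sizes).phi
    finals, stage_counts, aux = {}, {}, {}
    for comp, (a, b) in rs.COMPARISON_GROUPS.items():
        final, info = call_rams_for_comparison(m, a, b, cfg, phi=phi,
                                               sizes=sizes, label=comp)
        finals[comp] = final
        stage_counts[comp] = info["counts"]
        aux[comp] = info
    ann = rs.build_annotation(genome.chrom_sizes, genome.cgis, genome.genes, cfg)
    return {"cfg": cfg, "windows": windows, "m_all": m_all, "m": m,
            "sizes": sizes, "phi": phi, "finals": finals,
            "stage_counts": stage_counts, "aux": aux, "ann": ann,
            **default_experiment}


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """A small on-disk fixture for I/O, CLI and pipeline-determinism tests."""
    out = tmp_path_factory.mktemp("fixture")
    rs.simulate_fixture(
        out, seed=11, reads_per_sample=60_000, n_effects=12, multiplier=3.0,
        genome_config=rs.GenomeConfig(autosome_lengths=(1_200_000,),
                                      chrx_length=600_000, chry_length=300_000,
                                      n_intergenic_genes=4))
    return out


def make_count_matrix(counts: np.ndarray, groups: list[str] | None = None,
                      sexes: list[str] | None = None,
                      lib_sizes: np.ndarray | None = None,
                      chrom: str = "chr1") -> rs.WindowCountMatrix:
    """Wrap a raw count array into a WindowCountMatrix on a synthetic grid."""
    counts = np.asarray(counts, dtype=np.int64)
    n_win, n_s = counts.shape
    windows = pd.DataFrame({"chrom": chrom,
                            "start": np.arange(n_win, dtype=np.int64) * 50,
                            "end": np.arange(n_win, dtype=np.int64) * 50 + 100})
    groups = groups or (["Ctr"] * (n_s // 2) + ["UG"] * (n_s - n_s // 2))
    sexes = sexes or ["M"] * n_s
    samples = pd.DataFrame({"sample": [f"s{i}" for i in range(n_s)],
                            "group": groups, "sex": sexes})
    lib = (lib_sizes if lib_sizes is not None
           else np.full(n_s, 1_000_000)).astype(np.int64)
    return rs.WindowCountMatrix(windows, counts, samples, lib)


def simulate_nb_matrix(phi: float, mu: float, n_samples: int, n_windows: int,
                       seed: int, groups: list[str] | None = None
                       ) -> rs.WindowCountMatrix:
    """Direct NB (or Poisson at phi=0) counts with a common dispersion."""
    rng = np.random.default_rng(seed)
    if phi <= 0:
        counts = rng.poisson(mu, (n_windows, n_samples))
    else:
        counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu),
                                       (n_windows, n_samples))
    return make_count_matrix(counts, groups=groups)
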