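"""Promoter dose-response classification of RAMs near TSSs.

RAM windows within ±1.5 kb of a transcription start site are rolled up per
gene into gain/loss of methylation crossed with the exposures that elicit
the change: low dose only (UG_only, the non-monotonic signature), high dose
only (MG_only), or both doses.
"""

import pandas as pd

import ramscan as rs
from ramscan.pipeline import call_rams_for_comparison

genome = rs.build_toy_genome(seed=1)
effects = rs.choose_planted_sites(genome, n_effects=30, multiplier=3.0, seed=2)
landscape = rs.plant_methylome(genome, effects, seed=3)
readsets = rs.simulate_experiment(genome, landscape, rs.SimulationConfig(), seed=4)

cfg = rs.PipelineConfig()
m = rs.filter_low_coverage(
    rs.count_reads(readsets, rs.tile_windows(genome.chrom_sizes, cfg), cfg), cfg)
ann = rs.build_annotation(genome.chrom_sizes, genome.cgis, genome.genes, cfg)

finals = []
for comp in ("Ctr_vs_UG", "Ctr_vs_MG"):
    a, b = rs.COMPARISON_GROUPS[comp]
    final, _ = call_rams_for_comparison(m, a, b, cfg, label=comp)
    finals.append(final)
rams = pd.concat(finals, ignore_index=True)

prom = rs.assign_promoters(rams, ann, cfg)
prom = prom[prom["promoter_genes"].map(len) > 0]
cls = rs.classify_promoter_dose_response(prom)
s = rs.promoter_summary(cls)

print(f"{len(rams)} exposure-vs-control RAM windows; "
      f"{len(prom)} lie within +/-1.5 kb of a TSS; "
      f"{len(cls)} unique promoters affected")
for name, n in s["class_counts"].items():
    print(f"  {name:12s} {n}")
print(f"gain total {s['gain_total']} ({s['percent_gain']}%), "
      f"loss total {s['loss_total']} ({s['percent_loss']}%), "
      f"grand total {s['grand_total']}; {s['n_mixed_excluded']} mixed excluded")
print("UG_only classes are the non-monotonic responders: affected at the low "
      "dose but back at control level at the high dose.")
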