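"""Sex-contrast empirical FDR bound, chrY QC and comparison-overlap stats.

The male-vs-female contrast reuses the full RAM-calling code path with sex as
the grouping factor.  Significant windows on chrX/chrY reflect genuine sex
differences in coverage; autosomal calls are treated as false positives,
yielding an UPPER BOUND on the false discovery rate of the exposure analysis
(true autosomal sex differences would only lower it).  As a second check, no
chrY window should be called hypermethylated in females, whose chrY signal is
background leak only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig

SEX_CHROMS = ("chrX", "chrY")


@dataclass
class SexFdrReport:
    n_chrx: int
    n_chry: int
    n_autosomal: int

    @property
    def total(self) -> int:
        return self.n_chrx + self.n_chry + self.n_autosomal

    @property
    def max_fdr_percent(self) -> float:
        """100 × autosomal / total, one-decimal rounding; an upper bound."""
        if self.total == 0:
            return 0.0
        return round(100.0 * self.n_autosomal / self.total, 1)

    @classmethod
    def from_counts(cls, n_chrx: int, n_chry: int, n_autosomal: int) -> "SexFdrReport":
        return cls(int(n_chrx), int(n_chry), int(n_autosomal))

    def to_dict(self) -> dict:
        return {"n_chrx": self.n_chrx, "n_chry": self.n_chry,
                "n_autosomal": self.n_autosomal, "total": self.total,
                "max_fdr_percent": self.max_fdr_percent}


def tally_by_chromosome_class(rams: pd.DataFrame) -> SexFdrReport:
    chrom = rams["chrom"].astype(str)
    n_x = int((chrom == "chrX").sum())
    n_y = int((chrom == "chrY").sum())
    return SexFdrReport(n_x, n_y, int(len(rams) - n_x - n_y))


def sex_based_fdr(m, cfg: PipelineConfig | None = None,
                  phi: float | None = None,
                  sizes: np.ndarray | None = None
                  ) -> tuple[SexFdrReport, pd.DataFrame]:
    """Run the RAM pipeline on male vs female and tally by chromosome class.

    This is exactly the exposure pipeline applied to a relabeled design: it
    delegates to the same ``call_rams_for_comparison`` used for the three
    exposure comparisons, with the sample sheet's sex column as the grouping
    factor (A = M, B = F, so 'hyper' means female-elevated).
    """
    from .pipeline import call_rams_for_comparison  # shared code path

    cfg = cfg or PipelineConfig()
    sexes = m.samples["sex"]
    if (sexes == "M").sum() < 2 or (sexes == "F").sum() < 2:
        raise ValueError("sex-contrast QC needs at least two samples of each sex")
    rams, _info = call_rams_for_comparison(m, "M", "F", cfg, phi=phi,
                                           sizes=sizes, group_column="sex",
                                           label="M_vs_F")
    return tally_by_chromosome_class(rams), rams


def female_chry_qc(sex_rams: pd.DataFrame) -> int:
    """Count of chrY windows called hypermethylated in females (QC passes at 0)."""
    return int(((sex_rams["chrom"] == "chrY")
                & (sex_rams["direction"] == "hyper")).sum())


def comparison_overlap(window_sets: dict[str, set | pd.DataFrame]) -> dict:
    """Distinct-RAM statistics across the three comparisons.

    Window identity is (chrom, start).  Returns per-comparison sizes, the
    union, the count of windows unique to exactly one comparison, their
    integer-rounded percentage of the union, and the 7-cell Venn partition.
    """
    sets: dict[str, set] = {}
    for label, val in window_sets.items():
        if isinstance(val, pd.DataFrame):
            sets[label] = set(zip(val["chrom"], val["start"]))
        else:
            sets[label] = set(val)
    labels = list(sets)
    union = set().union(*sets.values()) if sets else set()
    venn = {}
    for w in union:
        member = "".join("1" if w in sets[l] else "0" for l in labels)
        venn[member] = venn.get(member, 0) + 1
    exclusive_cells = ["".join("1" if i == j else "0" for j in range(len(labels)))
                       for i in range(len(labels))]
    distinct = sum(venn.get(c, 0) for c in exclusive_cells)
    pct = int(round(100.0 * distinct / len(union))) if union else 0
    return {"labels": labels,
            "sizes": {l: len(sets[l]) for l in labels},
            "union": len(union),
            "distinct": distinct,
            "distinct_percent": pct,
            "venn": venn}


def distinct_percent_from_counts(distinct: int, union: int) -> int:
    """Integer-rounded 100 × distinct / union (the printed-count arithmetic)."""
    if union <= 0:
        raise ValueError("union must be positive")
    return int(round(100.0 * distinct / union))
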