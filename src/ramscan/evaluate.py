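"""Scoring called RAMs against a simulation's planted truth.

Used by the package's own power/error studies: a planted region is
*recovered* when at least one comparison in which its dose class produces a
difference contains an overlapping final RAM window with the expected
direction; a called window is a *false call* when it overlaps neither a
planted region nor a sex-effect interval (the sex-dosage signal on chrX/chrY
is genuine coverage difference, not error).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import intervals as iv
from .config import COMPARISON_GROUPS


def expected_direction(comparison: str, direction: str, dose_class: str) -> str | None:
    """Direction a planted effect should show in a comparison, or None if
    the dose class produces no difference there.

    Directions are stated with the comparison's higher-dose group as B, so
    a low-dose-only (UG_only) hyper effect appears *hypo* in UG_vs_MG.
    """
    group_a, group_b = COMPARISON_GROUPS[comparison]
    level = {"Ctr": 0.0}
    if dose_class == "monotonic":
        level.update({"UG": 0.5, "MG": 1.0})
    elif dose_class == "UG_only":
        level.update({"UG": 1.0, "MG": 0.0})
    elif dose_class == "MG_only":
        level.update({"UG": 0.0, "MG": 1.0})
    else:
        raise ValueError(f"unknown dose class {dose_class!r}")
    delta = level[group_b] - level[group_a]
    if delta == 0:
        return None
    sign = direction if delta > 0 else ("hypo" if direction == "hyper" else "hyper")
    return sign


def _overlap_mask(windows: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(len(windows), dtype=bool)
    chroms = windows["chrom"].to_numpy()
    starts = windows["start"].to_numpy(np.int64)
    ends = windows["end"].to_numpy(np.int64)
    for chrom, grp in regions.groupby("chrom", sort=False):
        rows = np.flatnonzero(chroms == chrom)
        if rows.size == 0:
            continue
        mask[rows] = mask[rows] | iv.overlaps_any(
            starts[rows], ends[rows], grp["start"].to_numpy(), grp["end"].to_numpy())
    return mask


def score_recovery(finals: dict[str, pd.DataFrame], truth: pd.DataFrame,
                   sex_effects: pd.DataFrame | None = None) -> dict:
    """Sensitivity over planted regions and the false-call window fraction.

    ``finals`` maps comparison label -> final RAM window table.  Returns
    sensitivity_percent (planted regions recovered in ≥1 responsive
    comparison with the expected direction), false_window_percent (called
    windows outside planted ∪ sex-effect regions), and the raw tallies.
    """
    recovered = 0
    for region in truth.itertuples(index=False):
        hit = False
        for comp, rams in finals.items():
            want = expected_direction(comp, region.direction, region.dose_class)
            if want is None or rams.empty:
                continue
            sub = rams[(rams["chrom"] == region.chrom)
                       & (rams["direction"] == want)]
            if sub.empty:
                continue
            ov = (sub["start"].to_numpy() < region.end) & \
                 (sub["end"].to_numpy() > region.start)
            if ov.any():
                hit = True
                break
        recovered += hit
    sens = 100.0 * recovered / len(truth) if len(truth) else float("nan")

    allowed = truth[["chrom", "start", "end"]]
    if sex_effects is not None and len(sex_effects):
        allowed = pd.concat([allowed, sex_effects[["chrom", "start", "end"]]],
                            ignore_index=True)
    n_called = 0
    n_false = 0
    for rams in finals.values():
        if rams.empty:
            continue
        inside = _overlap_mask(rams, allowed)
        n_called += len(rams)
        n_false += int((~inside).sum())
    fp = 100.0 * n_false / n_called if n_called else 0.0
    return {"n_planted": int(len(truth)), "n_recovered": int(recovered),
            "sensitivity_percent": sens,
            "n_called_windows": n_called, "n_false_windows": n_false,
            "false_window_percent": fp}
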