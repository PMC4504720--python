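"""Bead-calibrated axis-signal intensity comparison.

Immunofluorescence intensities vary with acquisition gain from slide to
slide; co-imaged calibration microspheres share that gain, so dividing
each ROI mean by the slide's bead mean yields gain-free values that can
be compared across cells. The paired comparison asks whether the
synapsed stretch of a chromosome axis carries less signal than the
unsynapsed axis of the same cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tetracross.errors import ConfigError, DataError


@dataclass(frozen=True)
class PairedReductionResult:
    percent_reduction: float
    percent_reduction_per_cell: float
    t: float
    p: float
    n_pairs: int
    n_dropped: int


def normalize(roi_mean: float, bead_mean: float):
    """Bead-normalized intensity: roi_mean / bead_mean (dimensionless)."""
    bead = np.asarray(bead_mean, dtype=float)
    if np.any(bead <= 0):
        raise ConfigError("bead_mean must be positive")
    return np.asarray(roi_mean, dtype=float) / bead


def paired_reduction(table: pd.DataFrame) -> PairedReductionResult:
    """Percent reduction of synapsed vs unsynapsed normalized intensity.

    Expects columns cell_id, region (synapsed|unsynapsed), roi_mean,
    bead_mean, one row per cell and region. Reduction is defined on the
    means of normalized values, 100 * (1 - mean(syn)/mean(unsyn)); the
    mean of per-cell ratios is also reported. Significance is a
    two-tailed paired t-test on the per-cell normalized pairs. Cells
    missing either region are dropped with a warning.
    """
    required = {"cell_id", "region", "roi_mean", "bead_mean"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"intensity table missing columns: {sorted(missing)}")
    bad_region = set(table["region"]) - {"synapsed", "unsynapsed"}
    if bad_region:
        raise DataError(f"unknown region labels: {sorted(bad_region)}")
    df = table.copy()
    df["norm"] = normalize(df["roi_mean"].to_numpy(), df["bead_mean"].to_numpy())
    wide = df.pivot_table(index="cell_id", columns="region", values="norm", aggfunc="mean")
    complete = wide.dropna(subset=["synapsed", "unsynapsed"]) if {
        "synapsed",
        "unsynapsed",
    } <= set(wide.columns) else wide.iloc[0:0]
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} cells lacking a paired region", stacklevel=2)
    if len(complete) < 2:
        raise DataError("need at least 2 complete synapsed/unsynapsed pairs")
    syn = complete["synapsed"].to_numpy()
    unsyn = complete["unsynapsed"].to_numpy()
    reduction = 100.0 * (1.0 - syn.mean() / unsyn.mean())
    per_cell = 100.0 * (1.0 - (syn / unsyn)).mean()
    diffs = syn - unsyn
    if np.allclose(diffs, 0.0):
        t, p = 0.0, 1.0
    elif np.ptp(diffs) == 0.0:
        # constant non-zero difference: perfectly separated pairs
        t, p = float(np.sign(diffs[0]) * np.inf), 0.0
    else:
        res = stats.ttest_rel(syn, unsyn)
        t, p = float(res.statistic), float(res.pvalue)
    return PairedReductionResult(
        percent_reduction=float(reduction),
        percent_reduction_per_cell=float(per_cell),
        t=t,
        p=p,
        n_pairs=len(complete),
        n_dropped=n_dropped,
    )
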