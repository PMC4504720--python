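"""Calibration and recovery studies over the synthetic meiosis generator.

Each function runs a replicated simulation-plus-analysis experiment and
returns summary numbers: Perkins map-distance recovery, the
interference-ratio/CoC null and its monotone response to interference
strength, Poisson goodness-of-fit calibration and power, and recovery of
a known synapsed/unsynapsed intensity reduction. These are the
package's evidence that the analysis stages measure what they claim to
measure; the analysis drivers and the acceptance script both run them.

All replication counts are chosen to keep Monte-Carlo error comfortably
inside the bands being checked while the full set of studies runs in a
few minutes on one CPU.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from tetracross.chiasma import poisson_gof
from tetracross.intensity import paired_reduction
from tetracross.simulate import (
    SimConfig,
    simulate_chiasma_counts,
    simulate_ftl_tetrads,
    simulate_intensity_dataset,
)
from tetracross.tetrads import (
    coefficient_of_coincidence,
    interference_ratio,
    perkins_distance,
    tally,
    tetrads_from_table,
)


def _analyse(config: SimConfig):
    return tally(tetrads_from_table(simulate_ftl_tetrads(config)))


def perkins_recovery(
    seed: int,
    n_reps: int = 100,
    n_tetrads: int = 5000,
    interval_lengths_cM: tuple[float, float] = (6.1, 5.5),
    interference_shape: float = 1.0,
) -> dict:
    """Do Perkins estimates recover the simulated interval lengths?

    Simulates two adjacent intervals (defaults mirror the wild-type
    I5c/I5d geometry, 6.1 and 5.5 cM) n_reps times and scores each
    replicate by whether both interval estimates fall within 3 reported
    standard errors of the simulated truth.
    """
    a, b = interval_lengths_cM
    markers = (0.0, a, a + b)
    hits = 0
    est1, est2 = [], []
    for r in range(n_reps):
        cfg = SimConfig(
            marker_positions_cM=markers,
            interference_shape=interference_shape,
            n_tetrads=n_tetrads,
            seed=seed + r,
        )
        t = _analyse(cfg)
        d1 = perkins_distance(t.margin(1))
        d2 = perkins_distance(t.margin(2))
        est1.append(d1.cM)
        est2.append(d2.cM)
        if abs(d1.cM - a) <= 3 * d1.se_cM and abs(d2.cM - b) <= 3 * d2.se_cM:
            hits += 1
    return {
        "percent_within_3se": 100.0 * hits / n_reps,
        "mean_interval1_cM": float(np.mean(est1)),
        "mean_interval2_cM": float(np.mean(est2)),
        "true_interval1_cM": a,
        "true_interval2_cM": b,
        "n_reps": n_reps,
        "n_tetrads": n_tetrads,
    }


def interference_calibration(
    seed: int,
    n_tetrads: int = 20_000,
    n_reps_strong: int = 20,
    interval_lengths_cM: tuple[float, float] = (10.0, 10.0),
    strong_shape: float = 10.0,
) -> dict:
    """IR/CoC null at nu=1 and their response to strong interference.

    One large no-interference run (the null: IR and CoC should sit near
    1) plus n_reps_strong runs at a strongly interfering shape; reports
    how many strong-interference replicates fall below the null values
    (all of them should — IR and CoC decrease with interference).
    """
    a, b = interval_lengths_cM
    markers = (0.0, a, a + b)
    null_cfg = SimConfig(marker_positions_cM=markers, interference_shape=1.0, n_tetrads=n_tetrads, seed=seed)
    t_null = _analyse(null_cfg)
    ir_null = interference_ratio(t_null).ir
    coc_null = coefficient_of_coincidence(t_null).coc
    irs, cocs = [], []
    for r in range(n_reps_strong):
        cfg = dataclasses.replace(null_cfg, interference_shape=strong_shape, seed=seed + 1 + r)
        t = _analyse(cfg)
        irs.append(interference_ratio(t).ir)
        cocs.append(coefficient_of_coincidence(t).coc)
    irs_a, cocs_a = np.array(irs), np.array(cocs)
    return {
        "ir_null": float(ir_null),
        "coc_null": float(coc_null),
        "ir_strong_mean": float(irs_a.mean()),
        "coc_strong_mean": float(cocs_a.mean()),
        "n_strong_below_null_ir": int((irs_a < ir_null).sum()),
        "n_strong_below_null_coc": int((cocs_a < coc_null).sum()),
        "n_reps_strong": n_reps_strong,
        "n_tetrads": n_tetrads,
    }


def gof_calibration_and_power(
    seed: int,
    n_cells: int = 50,
    null_mean: float = 6.9,
    n_reps_null: int = 1000,
    n_reps_power: int = 200,
    strong_shape: float = 10.0,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the pooled Poisson GOF and its power against an
    obligate-crossover, strongly interfering chiasma process."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps_null):
        sample = rng.poisson(null_mean, size=n_cells)
        if sample.mean() <= 0:
            continue
        if poisson_gof(sample, mode="pooled").p < alpha:
            rejections += 1
    type1 = rejections / n_reps_null

    power_rej = 0
    for r in range(n_reps_power):
        cfg = SimConfig(
            interference_shape=strong_shape,
            obligate_co=True,
            n_cells=n_cells,
            seed=seed + 10_000 + r,
        )
        sample = simulate_chiasma_counts(cfg)
        if poisson_gof(sample, mode="pooled").p < alpha:
            power_rej += 1
    return {
        "type1_error_rate": type1,
        "power_strong_interference": power_rej / n_reps_power,
        "alpha": alpha,
        "n_cells": n_cells,
        "n_reps_null": n_reps_null,
        "n_reps_power": n_reps_power,
    }


def intensity_recovery(
    seed: int,
    n_reps: int = 500,
    n_pairs_effect: int = 23,
    n_pairs_null: int = 22,
    true_reduction: float = 0.67,
    noise: float = 0.1,
    alpha: float = 0.05,
) -> dict:
    """Recovery of a known synapsed-axis intensity reduction.

    Effect arm: true reduction (default 67%, n=23 pairs) — reports the
    mean estimated percent reduction and how often the paired t-test
    reaches P < 0.001. Null arm: no reduction (n=22) — reports the
    rejection rate at alpha, which should sit near alpha.
    """
    rng = np.random.default_rng(seed)
    estimates = []
    strong_sig = 0
    for _ in range(n_reps):
        df = simulate_intensity_dataset(n_pairs_effect, true_reduction, noise, rng=rng)
        res = paired_reduction(df)
        estimates.append(res.percent_reduction)
        if res.p < 0.001:
            strong_sig += 1
    null_rej = 0
    for _ in range(n_reps):
        df = simulate_intensity_dataset(n_pairs_null, 0.0, noise, rng=rng)
        if paired_reduction(df).p < alpha:
            null_rej += 1
    return {
        "mean_reduction_pct": float(np.mean(estimates)),
        "true_reduction_pct": 100.0 * true_reduction,
        "frac_p_below_0.001": strong_sig / n_reps,
        "null_rejection_rate": null_rej / n_reps,
        "alpha": alpha,
        "n_reps": n_reps,
        "n_pairs_effect": n_pairs_effect,
        "n_pairs_null": n_pairs_null,
    }
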