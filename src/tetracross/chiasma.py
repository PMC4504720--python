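"""Distribution analysis of per-cell chiasma counts.

Without crossover control the number of chiasmata per cell should be
Poisson; the obligate crossover and interference make real counts
under-dispersed. This module provides Poisson goodness-of-fit (with the
field's conventional fine binning as well as a pooled-bin and a
parametric-bootstrap variant), Poisson range probabilities, descriptive
summaries including univalent frequency, and rank-based comparison of
count samples between genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from tetracross.errors import ConfigError, DataError

#: bivalents per cell in Arabidopsis (5 chromosome pairs); the
#: denominator of the univalent-pair frequency.
BIVALENTS_PER_CELL = 5


@dataclass
class ChiasmaSample:
    """Per-cell chiasma counts, optional univalent counts, genotype label."""

    counts: np.ndarray
    univalents: np.ndarray | None = None
    genotype: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise DataError("chiasma counts must be non-negative")
        if self.univalents is not None:
            self.univalents = np.asarray(self.univalents, dtype=int)
            if len(self.univalents) != len(self.counts):
                raise DataError("univalent vector length must match counts")
            if (self.univalents < 0).any() or (self.univalents % 2).any():
                raise DataError("univalents must be non-negative and even")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class GofResult:
    """Chi-square goodness-of-fit outcome against a Poisson model."""

    chi2: float
    df: int
    p: float
    binning: str
    bins: list[str] = field(default_factory=list)
    observed: np.ndarray = field(default_factory=lambda: np.empty(0))
    expected: np.ndarray = field(default_factory=lambda: np.empty(0))


def poisson_range_proportion(mean: float, lo: int, hi: int | None) -> float:
    """P(lo <= K <= hi) for K ~ Poisson(mean); hi=None means unbounded."""
    if mean <= 0:
        raise ConfigError(f"mean must be > 0, got {mean}")
    if lo < 0 or (hi is not None and hi < lo):
        raise ConfigError(f"invalid bounds [{lo}, {hi}]")
    upper = 1.0 if hi is None else stats.poisson.cdf(hi, mean)
    return float(upper - stats.poisson.cdf(lo - 1, mean))


def _observed_per_bin(counts: np.ndarray, edges: list[tuple[int, int | None]]) -> np.ndarray:
    obs = np.empty(len(edges))
    for i, (lo, hi) in enumerate(edges):
        if hi is None:
            obs[i] = (counts >= lo).sum()
        else:
            obs[i] = ((counts >= lo) & (counts <= hi)).sum()
    return obs


def _expected_per_bin(
    mean: float, n: int, edges: list[tuple[int, int | None]]
) -> np.ndarray:
    return np.array([n * poisson_range_proportion(mean, lo, hi) for lo, hi in edges])


def _bin_label(lo: int, hi: int | None) -> str:
    if hi is None:
        return f">={lo}"
    return str(lo) if lo == hi else f"{lo}-{hi}"


def _pooled_edges(mean: float, n: int, min_expected: float = 5.0) -> list[tuple[int, int | None]]:
    """Merge adjacent unit bins of the Poisson(mean) support until every
    bin's expected count reaches min_expected; the last bin is open."""
    # generous upper cut: far beyond any appreciable mass
    kmax = int(stats.poisson.ppf(1 - 1e-9, mean)) + 1
    edges: list[tuple[int, int | None]] = []
    lo = 0
    acc = 0.0
    for k in range(kmax):
        acc += n * stats.poisson.pmf(k, mean)
        if acc >= min_expected:
            edges.append((lo, k))
            lo, acc = k + 1, 0.0
    edges.append((lo, None))
    # the open tail may be light; merge it into the previous bin if so
    if len(edges) >= 2 and n * poisson_range_proportion(mean, edges[-1][0], None) < min_expected:
        prev_lo = edges[-2][0]
        edges = edges[:-2] + [(prev_lo, None)]
    return edges


def poisson_gof(
    sample: ChiasmaSample | Sequence[int],
    mode: Literal["conventional", "pooled", "bootstrap"] = "pooled",
    n_boot: int = 10_000,
    seed: int | None = None,
) -> GofResult:
    """Chi-square test of per-cell counts against Poisson(sample mean).

    Modes:

    - ``conventional``: unit bins 0..10 plus an open ``>=11`` tail (12
      categories) with df = 11, the conventional presentation for
      Arabidopsis chiasma counts (no df subtracted for the estimated
      mean).
    - ``pooled``: adjacent bins merged until each expects >= 5 counts,
      df = k - 2 (one df for the estimated mean) — the statistically
      defensible default.
    - ``bootstrap``: the pooled statistic calibrated by parametric
      bootstrap from Poisson(sample mean), seeded and reproducible.
    """
    counts = sample.counts if isinstance(sample, ChiasmaSample) else np.asarray(sample, dtype=int)
    n = len(counts)
    if n < 2:
        raise DataError("need at least 2 cells for a goodness-of-fit test")
    mean = counts.mean()
    if mean <= 0:
        raise DataError("degenerate sample: all counts are zero")

    if mode == "conventional":
        edges = [(k, k) for k in range(11)] + [(11, None)]
        df = len(edges) - 1
        binning = "unit bins 0-10 plus >=11 tail; df = k-1 (mean not charged)"
    elif mode in ("pooled", "bootstrap"):
        edges = _pooled_edges(mean, n)
        df = max(1, len(edges) - 2)
        binning = "adjacent bins pooled to expected >= 5; df = k-2"
    else:
        raise ConfigError(f"unknown mode {mode!r}")

    obs = _observed_per_bin(counts, edges)
    exp = _expected_per_bin(mean, n, edges)
    # bins partition the support, so this rescale is a no-op up to
    # floating error; it guards both margins summing to n exactly
    exp = exp * (n / exp.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (obs - exp) ** 2 / exp
    chi2 = float(np.nansum(np.where(exp > 0, terms, 0.0)))

    if mode == "bootstrap":
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_boot):
            bs = rng.poisson(mean, size=n)
            bmean = bs.mean()
            if bmean <= 0:
                continue
            bedges = _pooled_edges(bmean, n)
            bobs = _observed_per_bin(bs, bedges)
            bexp = _expected_per_bin(bmean, n, bedges)
            bexp = bexp * (n / bexp.sum())
            bchi = float((((bobs - bexp) ** 2) / bexp).sum())
            if bchi >= chi2:
                exceed += 1
        p = (exceed + 1) / (n_boot + 1)
        binning += f"; parametric bootstrap p (B={n_boot})"
    else:
        p = float(stats.chi2.sf(chi2, df))

    return GofResult(
        chi2=chi2,
        df=df,
        p=float(p),
        binning=binning,
        bins=[_bin_label(lo, hi) for lo, hi in edges],
        observed=obs,
        expected=exp,
    )


def summarize(
    sample: ChiasmaSample,
    lo: int = 6,
    hi: int = 8,
    univalent_definition: Literal["per-bivalent", "per-cell"] = "per-bivalent",
) -> dict:
    """Descriptive statistics of a chiasma sample.

    Reports the mean, observed range, the percentage of cells with
    counts in [lo, hi] (defaults bracket the mutant mean of ~7), and —
    when univalent counts are present — the univalent frequency.
    ``per-bivalent`` (default) counts univalent pairs per bivalent
    opportunity (5 per cell); ``per-cell`` reports the fraction of cells
    with at least one univalent.
    """
    if len(sample) == 0:
        raise DataError("empty sample")
    counts = sample.counts
    out = {
        "n_cells": int(len(counts)),
        "mean": float(counts.mean()),
        "range": (int(counts.min()), int(counts.max())),
        "percent_in_range": float(
            100.0 * ((counts >= lo) & (counts <= hi)).mean()
        ),
        "range_bounds": (lo, hi),
    }
    if sample.univalents is not None:
        pairs = sample.univalents / 2
        if univalent_definition == "per-bivalent":
            freq = pairs.sum() / (BIVALENTS_PER_CELL * len(sample))
        elif univalent_definition == "per-cell":
            freq = (sample.univalents > 0).mean()
        else:
            raise ConfigError(f"unknown univalent definition {univalent_definition!r}")
        out["univalent_frequency_percent"] = float(100.0 * freq)
        out["univalent_definition"] = univalent_definition
    return out


def rank_test_counts(
    a: Sequence[int],
    b: Sequence[int],
    paired: bool = False,
) -> dict:
    """Rank-based comparison of two count samples.

    Default is the unpaired Wilcoxon rank-sum (Mann-Whitney U) with
    exact tie handling via the normal approximation with tie correction;
    ``paired=True`` runs the Wilcoxon signed-rank test on per-item
    differences. The result records which test was run.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise DataError("paired test requires equal-length samples")
        if np.all(a == b):
            warnings.warn("all pairs tied; p = 1", stacklevel=2)
            return {"test": "wilcoxon-signed-rank", "statistic": 0.0, "p": 1.0}
        res = stats.wilcoxon(a, b)
        return {"test": "wilcoxon-signed-rank", "statistic": float(res.statistic), "p": float(res.pvalue)}
    if min(len(a), len(b)) < 5:
        raise DataError("need >= 5 observations per group for the rank-sum test")
    if np.all(a == a[0]) and np.all(b == a[0]):
        warnings.warn("all observations tied; p = 1", stacklevel=2)
        return {"test": "wilcoxon-rank-sum", "statistic": float(len(a) * len(b) / 2), "p": 1.0}
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"test": "wilcoxon-rank-sum", "statistic": float(res.statistic), "p": float(res.pvalue)}
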