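"""Synthetic meiosis: crossovers on a four-chromatid bivalent.

Crossover placement follows a stationary gamma renewal process on genetic
distance, the standard counting-model description of crossover
interference: inter-event distances are Gamma(shape=nu, mean=1/rate), so
nu = 1 recovers a homogeneous Poisson process (no interference) and
larger nu gives increasingly regular spacing (under-dispersed counts).
The process runs at the bivalent (four-chromatid) level with rate
2 events per Morgan, so that with each event recombining two of the four
chromatids the expected recombinant-gamete frequency per Morgan is the
map distance.

Two crossover pathways are superposed: an interference-sensitive stream
(gamma renewal, fraction 1 - class2_fraction of the total rate) and an
interference-insensitive stream (homogeneous Poisson, fraction
class2_fraction), mirroring the Class I / Class II division in
Arabidopsis where roughly 85% of crossovers show interference.

Chromatids are labelled 0,1 (homolog carrying the fluorophore
transgenes) and 2,3; each crossover joins one chromatid from each
homolog, chosen uniformly among the four non-sister pairings (no
chromatid interference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from tetracross.chiasma import ChiasmaSample
from tetracross.errors import ConfigError

logger = logging.getLogger(__name__)

# the four non-sister chromatid pairings, indexed 0..3
_PAIRINGS: tuple[tuple[int, int], ...] = ((0, 2), (0, 3), (1, 2), (1, 3))

#: default per-bivalent genetic lengths (cM) for whole-genome chiasma
#: simulation; proportioned like the five Arabidopsis chromosomes and
#: summing to 480 cM so the expected chiasma count at rate 2/Morgan is
#: 9.6 per cell, the wild-type mean.
DEFAULT_BIVALENT_LENGTHS_CM: tuple[float, ...] = (120.0, 85.0, 95.0, 90.0, 90.0)


@dataclass(frozen=True)
class CrossoverEvent:
    """One crossover on the bivalent.

    position is in Morgans from the left end; chromatid_pair is one of
    the four non-sister pairings (chromatids 0,1 from the transgenic
    homolog, 2,3 from the other); pathway records which stream placed
    the event.
    """

    position: float
    chromatid_pair: tuple[int, int] | None = None
    pathway: Literal["interfering", "non-interfering"] = "interfering"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ConfigError(f"crossover position must be >= 0, got {self.position}")
        if self.chromatid_pair is not None and self.chromatid_pair not in _PAIRINGS:
            raise ConfigError(
                f"chromatid_pair must pair non-sister chromatids, got {self.chromatid_pair}"
            )


@dataclass(frozen=True)
class Tetrad:
    """Four pollen grains, each a tuple of fluorophore presence calls."""

    grains: tuple[tuple[int, ...], ...]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.grains) != 4:
            raise ConfigError(f"a tetrad has exactly 4 grains, got {len(self.grains)}")
        n_markers = {len(g) for g in self.grains}
        if len(n_markers) != 1:
            raise ConfigError("all grains must score the same markers")

    @property
    def n_markers(self) -> int:
        return len(self.grains[0])


@dataclass
class SimConfig:
    """Parameters of the synthetic meiosis generator.

    marker_positions_cM: 2-3 strictly increasing genetic positions on
        one linkage group (three markers define two adjacent intervals).
    interference_shape: gamma shape nu > 0; nu=1 means no interference.
    class2_fraction: fraction of crossovers from the non-interfering
        (Class II) pathway; default 0.15.
    obligate_co: condition each bivalent on >= 1 crossover by rejection.
        None selects the context default: off for FTL tetrad simulation,
        on for whole-genome chiasma simulation.
    viability_filter: drop tetrads flagged unbalanced (see
        unbalanced_fraction) before output, as pollen scoring only sees
        viable tetrads.
    """

    marker_positions_cM: Sequence[float] = (0.0, 6.1, 11.6)
    interference_shape: float = 1.0
    class2_fraction: float = 0.15
    obligate_co: bool | None = None
    n_tetrads: int = 1000
    n_cells: int = 50
    bivalent_lengths_cM: Sequence[float] = DEFAULT_BIVALENT_LENGTHS_CM
    viability_filter: bool = False
    unbalanced_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        pos = list(self.marker_positions_cM)
        if not 2 <= len(pos) <= 3:
            raise ConfigError("marker_positions_cM must list 2 or 3 positions")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ConfigError("marker positions must be strictly increasing")
        if self.interference_shape <= 0:
            raise ConfigError("interference_shape must be > 0")
        if not 0 <= self.class2_fraction < 1:
            raise ConfigError("class2_fraction must be in [0, 1)")
        if self.n_tetrads <= 0:
            raise ConfigError("n_tetrads must be positive")
        if self.n_cells <= 0:
            raise ConfigError("n_cells must be positive")
        if any(L <= 0 for L in self.bivalent_lengths_cM):
            raise ConfigError("bivalent lengths must be positive")
        if not 0 <= self.unbalanced_fraction <= 1:
            raise ConfigError("unbalanced_fraction must be in [0, 1]")


def _stationary_renewal_matrix(
    n: int, length_m: float, shape: float, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Cumulative event positions for n independent stationary renewals.

    Returns an (n, K) matrix of cumulative positions whose last column
    exceeds length_m in every row; entries <= length_m are the events.
    The first arrival is drawn from the equilibrium forward-recurrence
    distribution (uniform fraction of a length-biased Gamma(shape+1)
    interval) so the process is stationary rather than anchored at 0.
    """
    theta = 1.0 / (shape * rate)  # gamma scale: mean spacing 1/rate
    mu = rate * length_m
    k = max(4, int(np.ceil(mu + 8.0 * np.sqrt(max(mu, 1.0) / shape) + 6)))
    steps = np.empty((n, k))
    steps[:, 0] = rng.random(n) * rng.gamma(shape + 1.0, theta, n)
    steps[:, 1:] = rng.gamma(shape, theta, (n, k - 1))
    cum = np.cumsum(steps, axis=1)
    # k is sized so crossing within k steps is near-certain; on the rare
    # miss, append further increment blocks (exact, just wider storage)
    while (cum[:, -1] <= length_m).any():
        extra = rng.gamma(shape, theta, (n, max(4, k // 2)))
        cum = np.hstack([cum, cum[:, -1:] + np.cumsum(extra, axis=1)])
    return cum


def _renewal_positions(
    n: int, length_m: float, shape: float, rate: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Event positions in [0, length_m] for n stationary gamma renewals."""
    if rate <= 0 or length_m <= 0:
        return [np.empty(0) for _ in range(n)]
    cum = _stationary_renewal_matrix(n, length_m, shape, rate, rng)
    mask = cum <= length_m
    return [cum[i, mask[i]] for i in range(n)]


def _renewal_counts(
    n: int, length_m: float, shape: float, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Event counts in [0, length_m] for n stationary gamma renewals."""
    if rate <= 0 or length_m <= 0:
        return np.zeros(n, dtype=int)
    cum = _stationary_renewal_matrix(n, length_m, shape, rate, rng)
    return (cum <= length_m).sum(axis=1)


def simulate_crossovers(
    length_m: float,
    shape: float,
    rate_scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[CrossoverEvent]:
    """Place crossovers on one bivalent of genetic length length_m Morgans.

    Events form a stationary gamma renewal process with shape nu and
    rate 2 * rate_scale per Morgan (expected count 2 * length at
    rate_scale 1). Chromatid pairs are left unassigned.
    """
    if length_m <= 0:
        raise ConfigError(f"bivalent length must be > 0, got {length_m}")
    if shape <= 0:
        raise ConfigError(f"interference shape must be > 0, got {shape}")
    if rate_scale < 0:
        raise ConfigError(f"rate_scale must be >= 0, got {rate_scale}")
    rng = np.random.default_rng() if rng is None else rng
    positions = _renewal_positions(1, length_m, shape, 2.0 * rate_scale, rng)[0]
    return [CrossoverEvent(position=float(p)) for p in positions]


def assign_chromatids(
    events: Sequence[CrossoverEvent], rng: np.random.Generator
) -> list[CrossoverEvent]:
    """Assign each event one of the 4 non-sister pairings, uniformly.

    Independent uniform choice encodes the no-chromatid-interference
    assumption.
    """
    picks = rng.integers(0, 4, size=len(events))
    return [
        CrossoverEvent(
            position=ev.position,
            chromatid_pair=_PAIRINGS[p],
            pathway=ev.pathway,
        )
        for ev, p in zip(events, picks)
    ]


def events_to_tetrad(
    events: Sequence[CrossoverEvent],
    marker_positions_m: Sequence[float],
    meta: dict | None = None,
) -> Tetrad:
    """Resolve crossovers into the four grains' fluorophore patterns.

    Markers are hemizygous in coupling: bundle positions 0 and 1 (the
    transgenic homolog) carry every fluorophore, 2 and 3 none. Each
    event names a pair of parental chromatids (bundle positions); the
    four grains are the product molecules obtained by following each
    strand through every junction it participates in, switching to the
    partner chromatid at each of its crossovers. A grain therefore
    carries the fluorophore at a marker iff the number of its crossovers
    left of the marker is even (for products starting on the transgenic
    homolog) or odd (for the others); since every junction trades one
    carrier against one non-carrier, 2:2 segregation per marker is
    automatic.
    """
    markers = np.asarray(marker_positions_m, dtype=float)
    if markers.ndim != 1 or len(markers) < 1:
        raise ConfigError("at least one marker position required")
    if (markers < 0).any():
        raise ConfigError("marker positions must lie on the bivalent (>= 0)")
    for ev in events:
        if ev.chromatid_pair is None:
            raise ConfigError("events must have chromatid pairs assigned")
    ordered = sorted(events, key=lambda e: e.position)
    # product p starts on bundle position p; at each junction the two
    # products currently occupying the event's chromatid pair trade
    # places, and a product's allele is the homolog of the position it
    # occupies (0,1 = transgenic homolog)
    line_of = [0, 1, 2, 3]
    occupant = [0, 1, 2, 3]
    grains: list[list[int]] = [[] for _ in range(4)]
    ei = 0
    for m in markers:
        while ei < len(ordered) and ordered[ei].position < m:
            i, j = ordered[ei].chromatid_pair  # type: ignore[misc]
            pi, pj = occupant[i], occupant[j]
            occupant[i], occupant[j] = pj, pi
            line_of[pi], line_of[pj] = j, i
            ei += 1
        for p in range(4):
            grains[p].append(int(line_of[p] < 2))
    return Tetrad(grains=tuple(tuple(g) for g in grains), meta=meta or {})


def _simulate_events_batch(
    n: int,
    span_m: float,
    shape: float,
    class2_fraction: float,
    rng: np.random.Generator,
) -> list[list[CrossoverEvent]]:
    """Superposed Class I (gamma renewal) and Class II (Poisson) events
    with chromatid pairs assigned, for n bivalents."""
    class1 = _renewal_positions(n, span_m, shape, 2.0 * (1.0 - class2_fraction), rng)
    n2 = rng.poisson(2.0 * class2_fraction * span_m, size=n)
    out: list[list[CrossoverEvent]] = []
    for i in range(n):
        evs = [CrossoverEvent(float(p)) for p in class1[i]]
        if n2[i]:
            evs.extend(
                CrossoverEvent(float(p), pathway="non-interfering")
                for p in rng.random(n2[i]) * span_m
            )
        out.append(assign_chromatids(evs, rng) if evs else [])
    return out


def simulate_ftl_tetrads(config: SimConfig) -> pd.DataFrame:
    """Simulate a three-colour FTL tetrad table.

    Returns a tidy table with one row per grain: columns tetrad_id,
    grain (1-4), then one 0/1 presence column per fluorophore (c1..).
    Reproducible from config.seed; the optional viability filter is
    applied last and the number of dropped tetrads is logged and stored
    in ``df.attrs["n_dropped"]``.
    """
    markers_cm = np.asarray(config.marker_positions_cM, dtype=float)
    rng = np.random.default_rng(config.seed)
    span_m = (markers_cm[-1] - markers_cm[0]) / 100.0
    rel_markers = (markers_cm - markers_cm[0]) / 100.0
    obligate = bool(config.obligate_co) if config.obligate_co is not None else False

    n = config.n_tetrads
    batches = _simulate_events_batch(
        n, span_m, config.interference_shape, config.class2_fraction, rng
    )
    if obligate:
        for i in range(n):
            while not batches[i]:
                batches[i] = _simulate_events_batch(
                    1, span_m, config.interference_shape, config.class2_fraction, rng
                )[0]

    unbalanced = (
        rng.random(n) < config.unbalanced_fraction
        if config.unbalanced_fraction > 0
        else np.zeros(n, dtype=bool)
    )

    rows = []
    n_dropped = 0
    for i, evs in enumerate(batches):
        if config.viability_filter and unbalanced[i]:
            n_dropped += 1
            continue
        tet = events_to_tetrad(evs, rel_markers)
        for g in range(4):
            rows.append((i, g + 1) + tet.grains[g])
    cols = ["tetrad_id", "grain"] + [f"c{j + 1}" for j in range(len(rel_markers))]
    df = pd.DataFrame(rows, columns=cols)
    if n_dropped:
        logger.info("viability filter dropped %d of %d tetrads", n_dropped, n)
    df.attrs["n_dropped"] = n_dropped
    df.attrs["true_interval_cM"] = tuple(np.diff(markers_cm))
    return df


def simulate_chiasma_counts(config: SimConfig) -> ChiasmaSample:
    """Simulate per-cell chiasma and univalent counts over five bivalents.

    Each bivalent's crossover count comes from the superposed two-pathway
    process; the cell total is the sum over bivalents. With obligate_co
    (the default here) zero-crossover bivalents are resampled until they
    receive at least one event; otherwise each crossover-less bivalent
    contributes one univalent pair (2 univalents).
    """
    lengths_m = np.asarray(config.bivalent_lengths_cM, dtype=float) / 100.0
    rng = np.random.default_rng(config.seed)
    obligate = bool(config.obligate_co) if config.obligate_co is not None else True
    n = config.n_cells
    rate1 = 2.0 * (1.0 - config.class2_fraction)
    rate2 = 2.0 * config.class2_fraction
    per_biv = np.empty((n, len(lengths_m)), dtype=int)
    for b, L in enumerate(lengths_m):
        counts = _renewal_counts(n, L, config.interference_shape, rate1, rng)
        counts = counts + rng.poisson(rate2 * L, size=n)
        if obligate:
            zero = np.nonzero(counts == 0)[0]
            while zero.size:
                redraw = _renewal_counts(
                    zero.size, L, config.interference_shape, rate1, rng
                ) + rng.poisson(rate2 * L, size=zero.size)
                counts[zero] = redraw
                zero = zero[redraw == 0]
        per_biv[:, b] = counts
    chiasmata = per_biv.sum(axis=1)
    univalents = 2 * (per_biv == 0).sum(axis=1)
    return ChiasmaSample(
        counts=chiasmata, univalents=univalents, genotype="simulated"
    )


def simulate_intensity_dataset(
    n_cells: int,
    true_reduction_fraction: float,
    noise: float = 0.1,
    bead_mean: float = 100.0,
    rng: np.random.Generator | None = None,
    cells_per_slide: int = 6,
    gain_sigma: float = 0.3,
    base_intensity: float = 150.0,
) -> pd.DataFrame:
    """Paired synapsed/unsynapsed ROI intensities with bead calibration.

    Each cell yields two ROI means (regions ``synapsed`` and
    ``unsynapsed``); the synapsed true level is (1 - reduction) times the
    unsynapsed one. Cells are grouped onto slides sharing a lognormal
    acquisition gain applied to ROI and bead values alike, so bead
    normalization cancels it exactly. ``noise`` is the lognormal sigma of
    multiplicative per-ROI measurement error (beads, being averages over
    many microspheres, are taken as noise-free).
    """
    if not 0 <= true_reduction_fraction < 1:
        raise ConfigError("true_reduction_fraction must be in [0, 1)")
    if n_cells < 1:
        raise ConfigError("n_cells must be positive")
    rng = np.random.default_rng() if rng is None else rng
    slide = np.arange(n_cells) // cells_per_slide
    gains = np.exp(rng.normal(0.0, gain_sigma, size=slide.max() + 1))[slide]
    zeros = np.zeros(n_cells)
    unsyn = base_intensity * np.exp(rng.normal(0.0, noise, n_cells) if noise else zeros)
    syn = (
        (1.0 - true_reduction_fraction)
        * base_intensity
        * np.exp(rng.normal(0.0, noise, n_cells) if noise else zeros)
    )
    rows = []
    for i in range(n_cells):
        rows.append((i, "synapsed", syn[i] * gains[i], bead_mean * gains[i]))
        rows.append((i, "unsynapsed", unsyn[i] * gains[i], bead_mean * gains[i]))
    return pd.DataFrame(rows, columns=["cell_id", "region", "roi_mean", "bead_mean"])
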