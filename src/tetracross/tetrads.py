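"""FTL tetrad classification and tetrad-based recombination statistics.

A three-colour fluorescent-tagged line marks three linked positions in
coupling, so each pollen tetrad scores two adjacent genetic intervals.
Per interval a tetrad is a parental ditype (PD, 0 recombinant grains),
tetratype (TT, 2) or non-parental ditype (NPD, 4). From PD/TT/NPD
counts the Perkins equation estimates map distance,

    cM = 100 * (TT/2 + 3*NPD) / n,

and the joint classification of the two intervals supports two
interference statistics: the interference ratio (IR; Malkova-style
ratio of the test interval's map distance among tetrads with vs without
a crossover in the adjacent interval) and the coefficient of
coincidence (CoC; observed double-crossover frequency over the product
of single-interval crossover frequencies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy import stats

from tetracross.errors import (
    AmbiguousTetradError,
    ConfigError,
    DataError,
    UndefinedStatisticError,
)
from tetracross.simulate import Tetrad

logger = logging.getLogger(__name__)

State = Literal["PD", "TT", "NPD"]

#: Letter labels for the canonical joint patterns of two adjacent
#: intervals, following the field's A-L group nomenclature for
#: three-colour tetrads. TT/TT splits by the number of grains
#: recombinant in both intervals: 2 = two-strand, 1 = three-strand,
#: 0 = four-strand double crossover. Presence data distinguish 11
#: patterns; anything else reports as OTHER. Reports use these letters;
#: no computation depends on them.
CLASS_LETTERS: dict[tuple[State, State, int | None], str] = {
    ("PD", "PD", None): "A",
    ("TT", "PD", None): "B",
    ("PD", "TT", None): "C",
    ("TT", "TT", 0): "D",
    ("TT", "TT", 1): "E",
    ("TT", "TT", 2): "F",
    ("NPD", "PD", None): "G",
    ("PD", "NPD", None): "H",
    ("TT", "NPD", None): "I",
    ("NPD", "TT", None): "J",
    ("NPD", "NPD", None): "K",
}

_STATE_FROM_COUNT = {0: "PD", 2: "TT", 4: "NPD"}


@dataclass(frozen=True)
class IntervalState:
    state: State
    recombinant_grains: frozenset[int]


@dataclass(frozen=True)
class TetradClass:
    joint: tuple[State, State]
    overlap: int | None  # TT x TT only: grains recombinant in both intervals
    label: str


@dataclass(frozen=True)
class IntervalCounts:
    """PD/TT/NPD tallies for one interval — the Perkins sufficient statistic."""

    PD: int
    TT: int
    NPD: int

    @property
    def n(self) -> int:
        return self.PD + self.TT + self.NPD


@dataclass(frozen=True)
class MapDistance:
    cM: float
    se_cM: float
    n: int

    def __str__(self) -> str:  # report style: one decimal place
        return f"{self.cM:.1f} ± {self.se_cM:.1f} cM (n={self.n})"


@dataclass
class JointTetradTally:
    """Joint classification counts for two adjacent intervals.

    counts maps (state1, state2, overlap) to tetrad counts; margins and
    the conditional sub-tallies needed by the interference ratio are
    derived views. excluded counts tetrads dropped as ambiguous.
    """

    counts: dict[tuple[State, State, int | None], int] = field(default_factory=dict)
    other: int = 0
    excluded: int = 0
    exclusion_reasons: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return sum(self.counts.values()) + self.other

    def margin(self, interval: int) -> IntervalCounts:
        if interval not in (1, 2):
            raise ConfigError("interval must be 1 or 2")
        idx = interval - 1
        acc = {"PD": 0, "TT": 0, "NPD": 0}
        for key, c in self.counts.items():
            acc[key[idx]] += c
        return IntervalCounts(PD=acc["PD"], TT=acc["TT"], NPD=acc["NPD"])

    def conditional(self, test_interval: int, conditioning_interval: int, with_co: bool) -> IntervalCounts:
        """Test-interval tallies among tetrads with (TT or NPD) or
        without (PD) a crossover in the conditioning interval."""
        if {test_interval, conditioning_interval} != {1, 2}:
            raise ConfigError("intervals must be 1 and 2 in some order")
        t, c = test_interval - 1, conditioning_interval - 1
        acc = {"PD": 0, "TT": 0, "NPD": 0}
        for key, cnt in self.counts.items():
            has_co = key[c] in ("TT", "NPD")
            if has_co == with_co:
                acc[key[t]] += cnt
        return IntervalCounts(PD=acc["PD"], TT=acc["TT"], NPD=acc["NPD"])


@dataclass(frozen=True)
class InterferenceResult:
    ir: float
    d_with: MapDistance
    d_without: MapDistance
    z: float
    p: float


@dataclass(frozen=True)
class CoCResult:
    f1: float
    f2: float
    observed_dco: float
    expected_dco: float
    coc: float
    definition: str


def interval_state(tetrad: Tetrad, marker_a: int, marker_b: int) -> IntervalState:
    """State of one marked interval from per-grain presence calls.

    A grain is recombinant for the interval iff its calls at the two
    flanking markers differ (markers are in coupling). Odd recombinant
    counts indicate a mis-scored grain and raise AmbiguousTetradError.
    """
    rec = frozenset(
        g for g in range(4) if tetrad.grains[g][marker_a] != tetrad.grains[g][marker_b]
    )
    if len(rec) not in _STATE_FROM_COUNT:
        raise AmbiguousTetradError(
            f"{len(rec)} recombinant grains for markers ({marker_a},{marker_b}); "
            "a balanced tetrad has 0, 2 or 4"
        )
    return IntervalState(state=_STATE_FROM_COUNT[len(rec)], recombinant_grains=rec)


def classify_tetrad(tetrad: Tetrad) -> TetradClass:
    """Joint class of a three-marker tetrad over its two intervals.

    TT/TT tetrads subdivide by overlap — the number of grains
    recombinant in both intervals — which identifies two-, three- and
    four-strand double crossovers (overlap 2, 1, 0). The letter label
    comes from CLASS_LETTERS; unlisted patterns are OTHER.
    """
    if tetrad.n_markers != 3:
        raise DataError(f"three scored markers required, got {tetrad.n_markers}")
    s1 = interval_state(tetrad, 0, 1)
    s2 = interval_state(tetrad, 1, 2)
    overlap: int | None = None
    if s1.state == "TT" and s2.state == "TT":
        overlap = len(s1.recombinant_grains & s2.recombinant_grains)
    key = (s1.state, s2.state, overlap)
    return TetradClass(joint=(s1.state, s2.state), overlap=overlap, label=CLASS_LETTERS.get(key, "OTHER"))


def tally(tetrads: Iterable[Tetrad]) -> JointTetradTally:
    """Classify and tally a collection of tetrads.

    Ambiguous tetrads (odd recombinant count in either interval) are
    excluded with a logged reason rather than guessed at.
    """
    out = JointTetradTally()
    n_seen = 0
    for i, tet in enumerate(tetrads):
        n_seen += 1
        try:
            cls = classify_tetrad(tet)
        except AmbiguousTetradError as exc:
            out.excluded += 1
            out.exclusion_reasons.append(f"tetrad {i}: {exc}")
            continue
        key = (cls.joint[0], cls.joint[1], cls.overlap)
        if cls.label == "OTHER":
            out.other += 1
        else:
            out.counts[key] = out.counts.get(key, 0) + 1
    if n_seen == 0:
        raise DataError("empty tetrad table")
    if out.n == 0:
        raise DataError("no classifiable tetrads")
    if out.excluded:
        logger.info("excluded %d ambiguous tetrads of %d", out.excluded, n_seen)
    return out


def perkins_distance(counts: IntervalCounts) -> MapDistance:
    """Perkins map distance with a multinomial delta-method standard error.

    cM = 100 (TT/2 + 3 NPD)/n. Per tetrad the contribution is 0 (PD),
    1/2 (TT) or 3 (NPD); the SE is the standard error of that mean,
    se = 100 * sqrt[(TT/4 + 9 NPD)/n - ((TT/2 + 3 NPD)/n)^2] / sqrt(n).
    """
    n = counts.n
    if n <= 0:
        raise DataError("cannot estimate a map distance from zero tetrads")
    x = (counts.TT / 2 + 3 * counts.NPD) / n
    var = (counts.TT / 4 + 9 * counts.NPD) / n - x**2
    se = 100.0 * np.sqrt(max(var, 0.0) / n)
    return MapDistance(cM=100.0 * x, se_cM=float(se), n=n)


def interference_ratio(
    tally: JointTetradTally,
    test_interval: int = 1,
    conditioning_interval: int = 2,
) -> InterferenceResult:
    """Malkova-style interference ratio with a delta-method Z-test.

    IR = (map distance of the test interval among tetrads with a
    crossover in the adjacent interval) / (same among tetrads without).
    IR = 1 means no interference, 0 complete interference, > 1 negative
    interference. Z = (d_without - d_with)/sqrt(se_with^2 + se_without^2)
    with a two-sided normal p-value.
    """
    with_co = tally.conditional(test_interval, conditioning_interval, with_co=True)
    without_co = tally.conditional(test_interval, conditioning_interval, with_co=False)
    if with_co.n == 0 or without_co.n == 0:
        raise UndefinedStatisticError(
            f"empty conditioning subset (with: n={with_co.n}, without: n={without_co.n})"
        )
    d_with = perkins_distance(with_co)
    d_without = perkins_distance(without_co)
    if d_without.cM == 0:
        raise UndefinedStatisticError(
            f"map distance without adjacent CO is zero (subset {without_co})"
        )
    pooled_se = np.sqrt(d_with.se_cM**2 + d_without.se_cM**2)
    z = (d_without.cM - d_with.cM) / pooled_se if pooled_se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return InterferenceResult(
        ir=d_with.cM / d_without.cM,
        d_with=d_with,
        d_without=d_without,
        z=float(z),
        p=float(min(p, 1.0)),
    )


def coefficient_of_coincidence(
    tally: JointTetradTally,
    definition: Literal["tetrad", "gamete"] = "tetrad",
) -> CoCResult:
    """CoC: observed double-crossover frequency over its no-interference
    expectation f1*f2.

    ``tetrad`` (default): f_i is the fraction of tetrads with a
    crossover (TT or NPD) in interval i; observed is the fraction
    non-PD in both. ``gamete``: f_i is the recombinant-gamete fraction
    (TT/2 + NPD)/n and observed is the fraction of grains recombinant
    in both intervals, resolved through the TT/TT overlap subtypes.
    """
    n = tally.n - tally.other
    if n == 0:
        raise DataError("no classified tetrads")
    m1, m2 = tally.margin(1), tally.margin(2)
    if definition == "tetrad":
        f1 = (m1.TT + m1.NPD) / n
        f2 = (m2.TT + m2.NPD) / n
        dco = sum(
            c
            for (s1, s2, _), c in tally.counts.items()
            if s1 != "PD" and s2 != "PD"
        )
        observed = dco / n
    elif definition == "gamete":
        f1 = (m1.TT / 2 + m1.NPD) / n
        f2 = (m2.TT / 2 + m2.NPD) / n
        # grains recombinant in both intervals: overlap for TT/TT, 2 for
        # TT/NPD and NPD/TT, 4 for NPD/NPD
        grains = 0
        for (s1, s2, ov), c in tally.counts.items():
            if s1 == "TT" and s2 == "TT":
                grains += c * (ov or 0)
            elif "NPD" in (s1, s2) and "PD" not in (s1, s2):
                grains += c * (2 if "TT" in (s1, s2) else 4)
        observed = grains / (4 * n)
    else:
        raise ConfigError(f"unknown CoC definition {definition!r}")
    if f1 <= 0 or f2 <= 0:
        raise UndefinedStatisticError(
            f"single-interval CO frequency is zero (f1={f1}, f2={f2})"
        )
    expected = f1 * f2
    return CoCResult(
        f1=float(f1),
        f2=float(f2),
        observed_dco=float(observed),
        expected_dco=float(expected),
        coc=float(observed / expected),
        definition=definition,
    )


def compare_map_distances(a: MapDistance, b: MapDistance) -> tuple[float, float]:
    """Two-sample Z comparison of two independent Perkins estimates."""
    pooled = np.sqrt(a.se_cM**2 + b.se_cM**2)
    if not np.isfinite(pooled) or pooled == 0:
        raise UndefinedStatisticError("pooled standard error is zero or non-finite")
    z = (a.cM - b.cM) / pooled
    p = float(min(2.0 * stats.norm.sf(abs(z)), 1.0))
    return float(z), p


def tetrads_from_table(df) -> list[Tetrad]:
    """Build Tetrad objects from a tidy grain table.

    Expects columns tetrad_id, grain, and one 0/1 presence column per
    fluorophore (all remaining columns, in order). Tetrads with a grain
    count other than 4 raise DataError (callers wanting row-level
    diagnostics should use tetracross.io.read_tetrad_table).
    """
    marker_cols = [c for c in df.columns if c not in ("tetrad_id", "grain")]
    d = df.sort_values(["tetrad_id", "grain"], kind="stable")
    ids = d["tetrad_id"].to_numpy()
    grain_no = d["grain"].to_numpy()
    # fast path: every tetrad a clean block of grains 1-4
    if len(d) % 4 == 0 and len(d):
        ids4 = ids.reshape(-1, 4)
        regular = (
            (ids4 == ids4[:, :1]).all()
            and (grain_no.reshape(-1, 4) == np.array([1, 2, 3, 4])).all()
            and len(np.unique(ids4[:, 0])) == ids4.shape[0]
        )
        if regular:
            blocks = d[marker_cols].to_numpy().astype(int).reshape(-1, 4, len(marker_cols))
            return [
                Tetrad(
                    grains=tuple(tuple(g) for g in block.tolist()),
                    meta={"tetrad_id": tid},
                )
                for tid, block in zip(ids4[:, 0].tolist(), blocks)
            ]
    out = []
    for tid, grp in df.groupby("tetrad_id", sort=True):
        if len(grp) != 4:
            raise DataError(f"tetrad {tid} has {len(grp)} grains, expected 4")
        grp = grp.sort_values("grain")
        grains = tuple(
            tuple(int(v) for v in row) for row in grp[marker_cols].to_numpy()
        )
        out.append(Tetrad(grains=grains, meta={"tetrad_id": tid}))
    return out
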