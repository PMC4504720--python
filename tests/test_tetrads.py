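"""Tests of tetrad classification, Perkins mapping, IR and CoC."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import PAIRINGS, make_events
from tetracross.errors import (
    AmbiguousTetradError,
    DataError,
    UndefinedStatisticError,
)
from tetracross.simulate import SimConfig, Tetrad, events_to_tetrad, simulate_ftl_tetrads
from tetracross.tetrads import (
    CLASS_LETTERS,
    IntervalCounts,
    JointTetradTally,
    MapDistance,
    classify_tetrad,
    coefficient_of_coincidence,
    compare_map_distances,
    interference_ratio,
    interval_state,
    perkins_distance,
    tally,
    tetrads_from_table,
)


def _tet(*grains):
    return Tetrad(grains=tuple(tuple(g) for g in grains))


class TestIntervalState:
    @pytest.mark.parametrize(
        "grains,state",
        [
            ([(1, 1), (1, 1), (0, 0), (0, 0)], "PD"),
            ([(1, 0), (0, 1), (1, 1), (0, 0)], "TT"),
            ([(1, 0), (1, 0), (0, 1), (0, 1)], "NPD"),
        ],
    )
    def test_states_from_recombinant_counts(self, grains, state):
        assert interval_state(_tet(*grains), 0, 1).state == state

    def test_odd_recombinant_count_is_ambiguous(self):
        bad = _tet((1, 0), (1, 1), (0, 0), (0, 0))
        with pytest.raises(AmbiguousTetradError):
            interval_state(bad, 0, 1)


class TestClassify:
    def test_all_parental_is_class_a(self):
        tet = _tet((1, 1, 1), (1, 1, 1), (0, 0, 0), (0, 0, 0))
        cls = classify_tetrad(tet)
        assert cls.joint == ("PD", "PD") and cls.label == "A"

    @pytest.mark.parametrize("pair", PAIRINGS)
    def test_single_co_interval1_is_tt_pd(self, pair):
        tet = events_to_tetrad(make_events((0.02, pair)), [0.0, 0.05, 0.1])
        cls = classify_tetrad(tet)
        assert cls.joint == ("TT", "PD") and cls.label == "B"

    def test_same_pair_double_co_overlap_two(self):
        tet = events_to_tetrad(
            make_events((0.02, (0, 2)), (0.08, (0, 2))), [0.0, 0.05, 0.1]
        )
        cls = classify_tetrad(tet)
        assert cls.joint == ("TT", "TT") and cls.overlap == 2

    def test_double_co_overlap_ratio_4_8_4(self):
        """The 16 chromatid pairings of a one-CO-per-interval double
        crossover split TT/TT overlap 2:1:0 as 4:8:4 (two-, three- and
        four-strand doubles in ratio 1:2:1)."""
        overlaps = []
        for p1, p2 in itertools.product(PAIRINGS, repeat=2):
            tet = events_to_tetrad(make_events((0.02, p1), (0.08, p2)), [0.0, 0.05, 0.1])
            cls = classify_tetrad(tet)
            assert cls.joint == ("TT", "TT")
            overlaps.append(cls.overlap)
        assert sorted(overlaps).count(2) == 4
        assert sorted(overlaps).count(1) == 8
        assert sorted(overlaps).count(0) == 4

    def test_every_canonical_pattern_has_a_letter(self):
        assert len(CLASS_LETTERS) == 11
        assert sorted(CLASS_LETTERS.values()) == list("ABCDEFGHIJK")

    @settings(max_examples=60, deadline=None)
    @given(perm=st.permutations([0, 1, 2, 3]), seed=st.integers(0, 10_000))
    def test_classification_invariant_under_grain_permutation(self, perm, seed):
        rng = np.random.default_rng(seed)
        events = [
            e
            for e in make_events(
                *(
                    (float(rng.uniform(0, 0.1)), PAIRINGS[rng.integers(4)])
                    for _ in range(rng.integers(0, 4))
                )
            )
        ]
        tet = events_to_tetrad(events, [0.0, 0.05, 0.1])
        permuted = Tetrad(grains=tuple(tet.grains[i] for i in perm))
        a, b = classify_tetrad(tet), classify_tetrad(permuted)
        assert (a.joint, a.overlap, a.label) == (b.joint, b.overlap, b.label)


class TestTally:
    def test_homogeneous_class_a_margins(self):
        tet = _tet((1, 1, 1), (1, 1, 1), (0, 0, 0), (0, 0, 0))
        t = tally([tet] * 10)
        assert t.margin(1) == IntervalCounts(PD=10, TT=0, NPD=0)
        assert t.margin(2) == IntervalCounts(PD=10, TT=0, NPD=0)

    def test_hand_tallied_mixture(self):
        """Six known tetrads: 2x A, 1x B, 1x C, 1x two-strand DCO (F),
        1x four-strand DCO (D)."""
        a = _tet((1, 1, 1), (1, 1, 1), (0, 0, 0), (0, 0, 0))
        b = events_to_tetrad(make_events((0.02, (0, 2))), [0.0, 0.05, 0.1])
        c = events_to_tetrad(make_events((0.08, (0, 2))), [0.0, 0.05, 0.1])
        f = events_to_tetrad(make_events((0.02, (0, 2)), (0.08, (0, 2))), [0.0, 0.05, 0.1])
        d = events_to_tetrad(make_events((0.02, (0, 2)), (0.08, (1, 3))), [0.0, 0.05, 0.1])
        t = tally([a, a, b, c, f, d])
        assert t.counts[("PD", "PD", None)] == 2
        assert t.counts[("TT", "PD", None)] == 1
        assert t.counts[("PD", "TT", None)] == 1
        assert t.counts[("TT", "TT", 2)] == 1
        assert t.counts[("TT", "TT", 0)] == 1
        assert t.n == 6 and t.excluded == 0

    def test_ambiguous_tetrads_excluded_and_counted(self):
        good = _tet((1, 1, 1), (1, 1, 1), (0, 0, 0), (0, 0, 0))
        bad = _tet((1, 0, 1), (1, 1, 1), (0, 0, 0), (0, 0, 0))
        t = tally([good, bad, good])
        assert t.n == 2 and t.excluded == 1
        assert "tetrad 1" in t.exclusion_reasons[0]

    def test_empty_table_rejected(self):
        with pytest.raises(DataError):
            tally([])

    def test_margins_match_direct_interval_tallies(self, two_interval_config):
        df = simulate_ftl_tetrads(two_interval_config)
        tets = tetrads_from_table(df)
        t = tally(tets)
        for interval, (ma, mb) in zip((1, 2), [(0, 1), (1, 2)]):
            states = [interval_state(x, ma, mb).state for x in tets]
            direct = IntervalCounts(
                PD=states.count("PD"), TT=states.count("TT"), NPD=states.count("NPD")
            )
            assert t.margin(interval) == direct
        assert sum(t.counts.values()) + t.other + t.excluded == len(tets)


class TestPerkins:
    @pytest.mark.parametrize(
        "counts,cm",
        [
            (IntervalCounts(100, 0, 0), 0.0),
            (IntervalCounts(0, 100, 0), 50.0),
            (IntervalCounts(880, 115, 5), 7.25),
        ],
    )
    def test_map_distance_values(self, counts, cm):
        assert perkins_distance(counts).cM == pytest.approx(cm)

    def test_standard_error_matches_delta_method(self):
        c = IntervalCounts(880, 115, 5)
        n = c.n
        x = (c.TT / 2 + 3 * c.NPD) / n
        se = 100 * np.sqrt(((c.TT / 4 + 9 * c.NPD) / n - x**2) / n)
        assert perkins_distance(c).se_cM == pytest.approx(se)

    def test_zero_tetrads_rejected(self):
        with pytest.raises(DataError):
            perkins_distance(IntervalCounts(0, 0, 0))

    @given(
        pd_=st.integers(0, 500),
        tt=st.integers(0, 500),
        npd=st.integers(0, 50),
        extra=st.integers(1, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_tt_and_npd_at_fixed_n(self, pd_, tt, npd, extra):
        """Replacing PD tetrads by TT or NPD can only increase cM."""
        base = IntervalCounts(pd_ + extra, tt, npd)
        more_tt = IntervalCounts(pd_, tt + extra, npd)
        more_npd = IntervalCounts(pd_, tt, npd + extra)
        d0 = perkins_distance(base).cM
        assert perkins_distance(more_tt).cM >= d0
        assert perkins_distance(more_npd).cM >= d0


class TestInterferenceRatio:
    def test_identical_subsets_give_unit_ratio(self):
        t = JointTetradTally(
            counts={
                ("PD", "PD", None): 80,
                ("TT", "PD", None): 20,
                ("PD", "TT", None): 80,
                ("TT", "TT", 1): 20,
            }
        )
        r = interference_ratio(t, test_interval=1, conditioning_interval=2)
        assert r.ir == pytest.approx(1.0)
        assert r.z == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_no_double_cos_gives_zero_ratio(self):
        t = JointTetradTally(
            counts={
                ("PD", "PD", None): 60,
                ("TT", "PD", None): 20,
                ("PD", "TT", None): 20,
            }
        )
        r = interference_ratio(t, test_interval=1, conditioning_interval=2)
        assert r.ir == 0.0

    def test_empty_conditioning_subset_rejected(self):
        t = JointTetradTally(counts={("PD", "PD", None): 50, ("TT", "PD", None): 10})
        with pytest.raises(UndefinedStatisticError):
            interference_ratio(t, test_interval=1, conditioning_interval=2)


class TestCoC:
    def test_exact_independence_gives_unit_coc(self):
        # joint = product of margins: f1 = f2 = 0.2, dco = 0.04
        t = JointTetradTally(
            counts={
                ("PD", "PD", None): 64,
                ("TT", "PD", None): 16,
                ("PD", "TT", None): 16,
                ("TT", "TT", 1): 4,
            }
        )
        r = coefficient_of_coincidence(t)
        assert r.coc == pytest.approx(1.0)
        assert r.expected_dco == pytest.approx(r.f1 * r.f2)

    def test_no_observed_dco_gives_zero(self):
        t = JointTetradTally(
            counts={
                ("PD", "PD", None): 60,
                ("TT", "PD", None): 20,
                ("PD", "TT", None): 20,
            }
        )
        assert coefficient_of_coincidence(t).coc == 0.0

    def test_zero_single_interval_frequency_rejected(self):
        t = JointTetradTally(counts={("PD", "PD", None): 50})
        with pytest.raises(UndefinedStatisticError):
            coefficient_of_coincidence(t)

    def test_gamete_definition_near_one_without_interference(self):
        cfg = SimConfig(marker_positions_cM=(0.0, 10.0, 20.0), n_tetrads=20_000, seed=21)
        t = tally(tetrads_from_table(simulate_ftl_tetrads(cfg)))
        r = coefficient_of_coincidence(t, definition="gamete")
        assert r.definition == "gamete"
        assert r.coc == pytest.approx(1.0, abs=0.15)


class TestCompareMapDistances:
    def test_identical_estimates(self):
        d = MapDistance(cM=10.0, se_cM=0.5, n=1000)
        z, p = compare_map_distances(d, d)
        assert z == 0.0 and p == 1.0

    def test_null_calibration(self):
        """Same simulated truth in both samples: rejection near alpha."""
        rej = 0
        reps = 60
        for r in range(reps):
            cfgs = [
                SimConfig(marker_positions_cM=(0.0, 8.0, 16.0), n_tetrads=1500, seed=1000 + 2 * r + i)
                for i in (0, 1)
            ]
            ds = [
                perkins_distance(tally(tetrads_from_table(simulate_ftl_tetrads(c))).margin(1))
                for c in cfgs
            ]
            if compare_map_distances(*ds)[1] < 0.05:
                rej += 1
        assert rej / reps < 0.17  # binomial noise around 0.05 at 60 reps

    def test_large_true_difference_detected(self):
        """27.7 vs 15.1 cM at n=1500 per genotype is overwhelmingly
        significant."""
        for r in range(5):
            ds = []
            for i, length in enumerate((27.7, 15.1)):
                cfg = SimConfig(
                    marker_positions_cM=(0.0, length, length + 5.0),
                    n_tetrads=1500,
                    seed=2000 + 10 * r + i,
                )
                ds.append(
                    perkins_distance(tally(tetrads_from_table(simulate_ftl_tetrads(cfg))).margin(1))
                )
            assert compare_map_distances(*ds)[1] < 0.001
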