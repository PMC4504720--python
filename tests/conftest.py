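import numpy as np
import pytest

from tetracross.simulate import CrossoverEvent, SimConfig

#: the four non-sister chromatid pairings, used by enumeration tests
PAIRINGS = ((0, 2), (0, 3), (1, 2), (1, 3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_interval_config():
    """I5c/I5d-like geometry: adjacent 6.1 and 5.5 cM intervals."""
    return SimConfig(marker_positions_cM=(0.0, 6.1, 11.6), n_tetrads=5000, seed=11)


def make_events(*pairs_and_positions):
    """CrossoverEvents from (position, pair) tuples."""
    return [CrossoverEvent(pos, pair) for pos, pair in pairs_and_positions]


def oracle_tetrad_patterns(events, markers):
    """Brute-force oracle: build each grain's fluorophore string by
    following its strand left-to-right through every junction drawn
    between two bundle positions, switching position at each junction it
    meets. Positions 0 and 1 carry the transgenes. Independent of the
    package's bookkeeping.
    """
    events = sorted(events, key=lambda e: e.position)
    patterns = []
    for start in range(4):
        line = start
        calls = []
        ei = 0
        for m in markers:
            while ei < len(events) and events[ei].position < m:
                i, j = events[ei].chromatid_pair
                if line == i:
                    line = j
                elif line == j:
                    line = i
                ei += 1
            calls.append(int(line < 2))
        patterns.append(tuple(calls))
        # a grain's path is independent of the others', so reset and
        # replay events for the next start
    return sorted(patterns)
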