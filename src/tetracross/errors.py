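"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
anything else -> 4.
"""


class TetracrossError(Exception):
    """Base class for all package errors."""


class ConfigError(TetracrossError):
    """Invalid parameter or configuration value."""


class DataError(TetracrossError):
    """Malformed or inconsistent input data."""


class AmbiguousTetradError(DataError):
    """A tetrad whose per-interval recombinant-grain count is odd.

    With three markers in coupling every balanced tetrad has 0, 2 or 4
    recombinant grains per interval; an odd count means a mis-scored
    grain, and the tetrad is excluded rather than guessed at.
    """


class UndefinedStatisticError(TetracrossError):
    """A statistic whose defining ratio has an empty or zero denominator."""
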