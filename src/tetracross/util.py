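"""Small shared helpers."""

from __future__ import annotations

from tetracross.errors import ConfigError


def ratio_percent(numerator: float, denominator: float, digits: int = 0) -> float:
    """100 * numerator/denominator, rounded.

    Used for worked-example ratios such as the mutant/wild-type
    synaptonemal-complex length comparison (57 vs 179 um -> 32%).
    """
    if denominator == 0:
        raise ConfigError("denominator must be non-zero")
    return round(100.0 * numerator / denominator, digits if digits > 0 else None)
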