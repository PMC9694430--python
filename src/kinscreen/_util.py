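"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import UndefinedRateError


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (``2.25 -> 2.3``), not banker's style."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``ndigits`` decimals.

    The division is done in decimal arithmetic so printed rates are exact for
    integer counts (e.g. 5 hits / 627 compounds -> 0.8).
    """
    if denominator == 0:
        raise UndefinedRateError("percentage undefined: denominator is zero")
    quantum = Decimal(1).scaleb(-ndigits)
    value = Decimal(100) * Decimal(repr(numerator)) / Decimal(repr(denominator))
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent RNG substream addressed by an integer key path.

    Fanning a single root seed out through ``SeedSequence`` spawn keys makes
    every sub-generator reproducible regardless of the order in which other
    substreams are consumed.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))
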