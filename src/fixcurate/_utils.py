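"""Small shared helpers: error types, rounding, RNG stream derivation."""

from __future__ import annotations

import math

import numpy as np


class FixcurateError(Exception):
    """Base class for package errors."""


class ConfigError(FixcurateError):
    """Invalid configuration."""


class NormalizationError(FixcurateError):
    """Raised when size factors or per-cell normalization cannot be computed."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (prints 28 for 27.5)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def pct(numer: int, denom: int) -> int:
    """Integer percentage, rounded half away from zero."""
    if denom == 0:
        raise ValueError("percentage of an empty reference")
    return round_half_away(100.0 * numer / denom)


def derive_rng(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic child RNG stream for (seed, keys).

    Every source of randomness in the package flows through this so a single
    config seed reproduces a run bit for bit.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=keys))
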