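"""Shared numerics: percentile convention, lifetime weights, seeded RNG streams."""

from __future__ import annotations

import logging
import math
import zlib

import numpy as np

logger = logging.getLogger("ulex")


def get_logger(name: str | None = None) -> logging.Logger:
    return logger if name is None else logger.getChild(name)


def nearest_rank_percentile(a: np.ndarray, percentile: float, axis: int = -1) -> np.ndarray:
    """Empirical percentile by the nearest-rank rule.

    Returns the element at rank ``ceil((percentile/100) * n)`` of the sorted
    sample along ``axis`` — always an element of the sample, never an
    interpolated value.
    """
    a = np.asarray(a)
    n = a.shape[axis]
    if n == 0:
        raise ValueError("empty sample")
    if not 0.0 < percentile <= 100.0:
        raise ValueError(f"percentile must lie in (0, 100], got {percentile}")
    rank = int(math.ceil(percentile / 100.0 * n))  # 1-based
    rank = min(max(rank, 1), n)
    return np.partition(a, rank - 1, axis=axis).take(rank - 1, axis=axis)


def year_weights(birth_year: int, life_expectancy: float) -> tuple[np.ndarray, np.ndarray]:
    """Calendar years lived by a cohort and the fraction of each year lived.

    A person born at the start of year ``b`` with life expectancy ``L`` fully
    lives years ``b .. b+floor(L)-1`` and a fraction ``L - floor(L)`` of year
    ``b + floor(L)``.  Returns ``(years, weights)``; the partial year is
    omitted when ``L`` is an integer.
    """
    if life_expectancy <= 0:
        raise ValueError(f"life expectancy must be positive, got {life_expectancy}")
    nfull = int(math.floor(life_expectancy))
    frac = life_expectancy - nfull
    if frac > 1e-12:
        years = np.arange(birth_year, birth_year + nfull + 1)
        weights = np.ones(nfull + 1)
        weights[-1] = frac
    else:
        years = np.arange(birth_year, birth_year + nfull)
        weights = np.ones(nfull)
    return years, weights


def _key_to_ints(key: tuple) -> tuple[int, ...]:
    out = []
    for k in key:
        if isinstance(k, (int, np.integer)):
            out.append(int(k) & 0xFFFFFFFF)
        else:
            out.append(zlib.crc32(str(k).encode("utf8")))
    return tuple(out)


def child_rng(master_seed: int, *key) -> np.random.Generator:
    """Deterministic child RNG stream for a (stage, run, ...) key.

    Streams derived from the same master seed but different keys are
    statistically independent; the derivation does not depend on execution
    order, so parallel or re-ordered stages reproduce bit-identically.
    """
    ss = np.random.SeedSequence(int(master_seed), spawn_key=_key_to_ints(key))
    return np.random.default_rng(ss)
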