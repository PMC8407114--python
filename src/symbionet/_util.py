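"""Shared helpers: seeded generator streams and percentage rounding."""

from __future__ import annotations

import zlib
from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def stream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random stream derived from a single master seed.

    Every stochastic component draws from its own stream so that adding a
    draw in one component never perturbs another component's output for the
    same master seed.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def round_pct(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used in the report tables."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)
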