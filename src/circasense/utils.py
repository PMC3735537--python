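"""Small shared helpers: half-up percentage rounding and reproducible seeding."""

from __future__ import annotations

import zlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: float, total: float, ndigits: int = 1) -> float:
    """``count / total * 100`` rounded half-up; 0.0 for an empty total."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)


def probe_rng(seed: int, probe_id: str, direction: str = "", stream: int = 0) -> np.random.Generator:
    """Content-keyed per-probe random generator.

    The stream is derived from the pipeline seed and a CRC of the probe
    identity, so per-probe randomness does not depend on the order in which
    probes are processed.
    """
    key = zlib.crc32(f"{probe_id}:{direction}:{stream}".encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), key)))
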