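"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np


def truncate(value: float, decimals: int = 2) -> float:
    """Truncate (not round) a non-negative value to ``decimals`` places.

    Reported rates and indices are conventionally truncated for display
    (0.818 -> 0.81), while full precision is retained internally.
    """
    if value < 0:
        raise ValueError("truncate expects a non-negative value")
    scale = 10**decimals
    return math.floor(value * scale + 1e-12) / scale


def format_truncated(value: float, decimals: int = 2) -> str:
    return f"{truncate(value, decimals):.{decimals}f}"


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]
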