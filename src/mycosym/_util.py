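"""Small shared helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["round_half_up", "as_rng"]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero toward +inf (printed-table style).

    Python's builtin ``round`` is banker's rounding; detection rates and
    per-sample ratios follow the half-up convention used in printed summary
    tables (e.g. 12.5% -> 13%).
    """
    scale = 10**decimals
    v = np.floor(x * scale + 0.5) / scale
    return float(v) if decimals else int(v)


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed / Generator / None into a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
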