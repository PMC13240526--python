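"""Small shared helpers: seed handling and symbol normalization."""

from __future__ import annotations

import numpy as np

_MAX_SEED = 2**31 - 1


def split_seed(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent stage seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(int(master_seed))
    return [int(s) % _MAX_SEED for s in ss.generate_state(n, dtype=np.uint64)]


def norm_symbol(symbol: str) -> str:
    """Case-insensitive, whitespace-stripped gene symbol key.

    Display case is preserved everywhere; only comparisons go through this
    (mouse symbols are capitalized differently from human, e.g. Ccn1 vs CCN1).
    """
    return str(symbol).strip().casefold()
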