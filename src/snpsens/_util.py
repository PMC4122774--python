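"""Small shared helpers: seed derivation and validation."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master: int, *labels) -> int:
    """Derive a substream seed from a master seed and a label path.

    Stable across processes and Python versions (sha256, not hash()).
    Result is always in [0, 2**31) so it is safe for any RNG API.
    """
    key = "|".join([str(int(master))] + [str(x) for x in labels])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(master: int, *labels) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *labels))


def check_fraction(name: str, value: float, lo: float = 0.0, hi: float = 1.0,
                   lo_open: bool = False, hi_open: bool = False) -> None:
    ok = (value > lo if lo_open else value >= lo) and (value < hi if hi_open else value <= hi)
    if not ok:
        lob, hib = "(" if lo_open else "[", ")" if hi_open else "]"
        raise ValueError(f"{name}={value!r} outside {lob}{lo}, {hi}{hib}")


def check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name}={value!r} must be > 0")
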