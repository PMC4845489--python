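"""Shared helpers: sequence manipulation, fixed-mode rounding, seeded streams."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

# Reverse-complement table over the 5-letter DNA alphabet (N maps to N).
_RC = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

# Fixed sub-stream ids so that adding a new consumer of randomness never
# perturbs the draws of an existing one.
STREAMS = {
    "genome": 1,
    "variants": 2,
    "reads": 3,
    "annotations": 4,
    "transcripts": 5,
}


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Named random stream derived from a single pipeline seed."""
    return np.random.default_rng([int(seed), STREAMS[stream]])


def revcomp(seq: bytes) -> bytes:
    return seq.translate(_RC)[::-1]


def gc_fraction(seq: bytes) -> float:
    n = len(seq) - seq.count(b"N") - seq.count(b"n")
    if n == 0:
        return 0.0
    return (seq.count(b"G") + seq.count(b"C") + seq.count(b"g") + seq.count(b"c")) / n


def round_half_up(value, ndigits: int = 2) -> float:
    """Round with ties away from zero (the reporting convention used
    throughout; Python's built-in round is banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Exact-rational percentage, rounded half-up to `ndigits` decimals."""
    if denominator <= 0:
        raise ZeroDivisionError("percentage with non-positive denominator")
    q = Decimal(1).scaleb(-ndigits)
    return float(
        (Decimal(100 * numerator) / Decimal(denominator)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> bytes:
    """I.i.d. bases at the stated GC fraction."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return codes.tobytes()
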