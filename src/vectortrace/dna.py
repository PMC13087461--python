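"""Small DNA-string helpers shared across the package.

Sequences are plain upper-case ``str`` over the alphabet ACGT; all
coordinates in the package are 0-based, half-open.  Conversion to 1-based
happens only at SAM/BED boundaries.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


class InvalidSequenceError(ValueError):
    """A sequence contains characters outside {A,C,G,T}."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, name: str = "sequence") -> str:
    """Validate that *seq* is a nonempty ACGT string; return it unchanged."""
    if not seq:
        raise InvalidSequenceError(f"{name} is empty")
    if set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise InvalidSequenceError(f"{name} contains non-ACGT characters: {bad}")
    return seq


def random_dna(n: int, rng: np.random.Generator) -> str:
    """Uniform-random DNA string of length *n*."""
    return _BASE_ARR[rng.integers(0, 4, size=n)].tobytes().decode()


def seq_to_codes(seq: str) -> np.ndarray:
    """Map ACGT to integer codes 0..3 (vectorised)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        codes[arr == b] = i
    return codes


def gc_fraction(seq: str) -> float:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return float(np.mean((arr == ord("G")) | (arr == ord("C"))))
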