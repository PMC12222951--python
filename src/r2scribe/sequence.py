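"""Small nucleotide-sequence helpers shared across the package.

Sequences are plain upper-case strings over {A, C, G, T} (plus N for
masked bases).  Coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Fixed base order used by every encoded array in the package.
BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq``."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array (A=0, C=1, G=2, T=3, N=4).

    N is a masking sentinel: the aligner scores it as a mismatch against
    everything, including another N.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    bad = ~np.isin(arr, [ord(b) for b in _CODE])
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-ACGTN character {seq[pos]!r} at position {pos}")
    return out


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def random_seq(length: int, rng: np.random.Generator) -> str:
    """Uniform random nucleotide sequence of the given length."""
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))
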