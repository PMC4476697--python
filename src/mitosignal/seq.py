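"""Low-level DNA sequence primitives shared by the genome simulator and the primer screen.

Sequences are plain uppercase ACGT strings at the API surface; internally they are
encoded as uint8 arrays (A=0, C=1, G=2, T=3) so that window identities and k-mer
codes vectorise. The complement of code b is 3 - b.
"""
from __future__ import annotations

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE[_b] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array; non-ACGT characters raise ValueError."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    arr = _ENCODE[raw]
    if (arr == 255).any():
        bad = chr(raw[int(np.argmax(arr == 255))])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(arr: np.ndarray) -> str:
    return _BASES[np.asarray(arr, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return (3 - np.asarray(arr, dtype=np.uint8))[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    arr = encode(seq)
    return float(np.count_nonzero((arr == 1) | (arr == 2)) / arr.size)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    """Uniform-composition random DNA of the given length."""
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer codes of every k-mer of an encoded sequence (exact, no hashing)."""
    arr = np.asarray(arr, dtype=np.int64)
    if arr.size < k:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    return windows @ powers


def window_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of matching positions between two equal-length encoded windows."""
    if a.size != b.size or a.size == 0:
        raise ValueError("windows must be equal-length and non-empty")
    return float(np.count_nonzero(a == b) / a.size)
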