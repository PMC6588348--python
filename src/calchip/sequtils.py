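"""Low-level nucleotide-sequence helpers shared by the simulator and the read assigner."""
from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# ASCII -> 2-bit code; A=0 C=1 G=2 T=3. Anything else maps to 0 and is caught
# later by exact string verification, never by the hash alone.
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

MAX_KMER = 31  # 4**31 < 2**63: a k-mer is an exact uint64 encoding, not a lossy hash


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(rng: np.random.Generator, length: int) -> str:
    """I.i.d. uniform A/C/G/T string of the given length."""
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return _BASES[codes].tobytes().decode("ascii")


def encode_bases(seq: str) -> np.ndarray:
    """2-bit codes for each base of ``seq`` as a uint8 vector."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_kmers(seq: str, k: int) -> np.ndarray:
    """Exact uint64 encodings of every k-mer of ``seq`` (empty if len(seq) < k).

    Requires k <= 31 so the encoding is injective over A/C/G/T.
    """
    if not 1 <= k <= MAX_KMER:
        raise ValueError(f"k must be in [1, {MAX_KMER}], got {k}")
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = encode_bases(seq).astype(np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = out * np.uint64(4) + codes[j : j + n]
    return out


def encode_kmer_matrix(codes: np.ndarray) -> np.ndarray:
    """Encode an (n, k) matrix of 2-bit codes into n uint64 k-mer values."""
    n, k = codes.shape
    if k > MAX_KMER:
        raise ValueError(f"k must be <= {MAX_KMER}")
    out = np.zeros(n, dtype=np.uint64)
    c = codes.astype(np.uint64)
    for j in range(k):
        out = out * np.uint64(4) + c[:, j]
    return out
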