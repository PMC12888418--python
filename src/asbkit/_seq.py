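"""Low-level sequence utilities: encoding, reverse complement, de Bruijn sequences.

Bases are encoded as A=0, C=1, G=2, T=3; any other character maps to 4 and is
treated as an unscorable position by the scanners.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as a uint8 array (A,C,G,T -> 0..3, other -> 4)."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def revcomp_matrix(matrix: np.ndarray) -> np.ndarray:
    """Reverse complement of an (L, 4) base-probability matrix."""
    return matrix[::-1, ::-1]


@lru_cache(maxsize=4)
def de_bruijn_cycle(k: int, alphabet: str = BASES) -> str:
    """Lexicographically-smallest de Bruijn cycle of order ``k`` over ``alphabet``.

    Built with the Fredricksen-Kessler-Maiorana (Lyndon word) construction, so
    the output is fully deterministic across runs and platforms. The returned
    string has length ``len(alphabet)**k`` and, read cyclically, contains every
    k-mer exactly once.
    """
    n = len(alphabet)
    sequence: list[int] = []
    a = [0] * (k + 1)

    def db(t: int, p: int) -> None:
        if t > k:
            if k % p == 0:
                sequence.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, n):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    return "".join(alphabet[i] for i in sequence)


def de_bruijn_sequence(k: int, overhang: int = 0) -> str:
    """Linearized de Bruijn sequence of order k, wrapping ``k-1+overhang`` chars.

    With ``overhang=0`` the result has length ``4**k + k - 1`` and contains every
    k-mer exactly once as a substring.
    """
    cycle = de_bruijn_cycle(k)
    wrap = k - 1 + overhang
    reps, rem = divmod(wrap, len(cycle))
    return cycle * (reps + 1) + cycle[:rem] if reps else cycle + cycle[:wrap]
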