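"""Low-level nucleotide helpers shared across the package.

Sequences are handled internally in the DNA alphabet (U normalized to T);
mature small-RNA sequences are converted back to the RNA alphabet only at
report time.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def to_dna(seq: str) -> str:
    """Normalize to uppercase DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase RNA alphabet (T -> U), used for reported mature sequences."""
    return seq.upper().replace("T", "U")


def as_bytes(seq: str) -> np.ndarray:
    """Sequence as a uint8 numpy array for vectorized comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def mismatch_scan(reference: str, query: str, max_mismatches: int) -> list[tuple[int, int]]:
    """All ungapped placements of ``query`` on ``reference`` (forward strand).

    Returns ``(start, mismatches)`` for every offset with at most
    ``max_mismatches`` substitutions.  Vectorized over offsets, so the cost
    is O(len(query)) passes over the reference.
    """
    m, n = len(query), len(reference)
    if m == 0 or m > n:
        return []
    ref = as_bytes(reference)
    q = as_bytes(query)
    n_pos = n - m + 1
    counts = np.zeros(n_pos, dtype=np.int32)
    for j in range(m):
        counts += ref[j : j + n_pos] != q[j]
    hits = np.nonzero(counts <= max_mismatches)[0]
    return [(int(p), int(counts[p])) for p in hits]


_WOBBLE = {("C", "T"), ("A", "G")}  # (expected complement base, observed target base)


def pairing_symbol(srna_base: str, target_base: str) -> str:
    """Classify one small-RNA/target base pair: '|' match, 'o' G:U wobble, 'x' mismatch.

    ``srna_base`` is the small-RNA base (DNA alphabet), ``target_base`` the
    sense-strand target base it sits opposite.
    """
    expected = complement(srna_base)
    if target_base == expected:
        return "|"
    # G:U wobble: sRNA G pairs target T, sRNA T(=U) pairs target G
    if (srna_base == "G" and target_base == "T") or (srna_base == "T" and target_base == "G"):
        return "o"
    return "x"
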