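"""k-mer spectrum features.

The composition block of the feature vector is the relative frequency of
every oligonucleotide of length k = 2..5, giving 4^2 + 4^3 + 4^4 + 4^5 =
1360 features. Frequencies are normalized per k: each k-block of the vector
sums to 1 whenever the sequence has at least one valid window of that
length. Windows containing N contribute to neither numerator nor
denominator.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .alphabet import BASES, encode_bases
from .exceptions import ValidationError

__all__ = ["KmerRegistry", "enumerate_kmers", "count_kmers", "kmer_frequency_vector"]


@dataclass(frozen=True)
class KmerRegistry:
    """Ordered catalogue of k-mers: k ascending, lexicographic within each k."""

    k_min: int
    k_max: int
    kmers: tuple[str, ...]
    block_slices: dict[int, slice] = field(compare=False)

    def __len__(self) -> int:
        return len(self.kmers)

    @property
    def column_names(self) -> list[str]:
        return [f"kmer_{km}" for km in self.kmers]


def enumerate_kmers(k_min: int = 2, k_max: int = 5) -> KmerRegistry:
    """Enumerate all k-mers over {A,C,G,T} for k in [k_min, k_max].

    Ordering is deterministic: k ascending, lexicographic within each k
    (itertools.product on the alphabet in A<C<G<T order).
    """
    if k_min < 1:
        raise ValidationError(f"k_min must be >= 1, got {k_min}")
    if k_max < k_min:
        raise ValidationError(f"k_max ({k_max}) < k_min ({k_min})")
    kmers: list[str] = []
    slices: dict[int, slice] = {}
    for k in range(k_min, k_max + 1):
        start = len(kmers)
        kmers.extend("".join(p) for p in itertools.product(BASES, repeat=k))
        slices[k] = slice(start, len(kmers))
    return KmerRegistry(k_min=k_min, k_max=k_max, kmers=tuple(kmers), block_slices=slices)


def _count_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """Counts over all length-k windows free of N, as a 4**k bincount.

    Returns (counts, number of valid windows).
    """
    n = codes.size
    if n < k:
        return np.zeros(4**k, dtype=np.int64), 0
    win = sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return np.zeros(4**k, dtype=np.int64), 0
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = win[valid].astype(np.int64) @ weights
    counts = np.bincount(idx, minlength=4**k)
    return counts, n_valid


def count_kmers(sequence: str, k: int) -> Counter:
    """Count every k-mer over {A,C,G,T} in `sequence` with a step-1 window.

    Windows containing N are skipped. A sequence shorter than k yields an
    empty counter (not an error). Only observed k-mers appear as keys.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    counts, _ = _count_codes(encode_bases(sequence), k)
    observed = np.nonzero(counts)[0]
    result: Counter = Counter()
    for code in observed:
        kmer = "".join(BASES[(int(code) >> (2 * (k - 1 - j))) & 3] for j in range(k))
        result[kmer] = int(counts[code])
    return result


def kmer_frequency_vector(
    sequence: str, registry: KmerRegistry, mode: str = "frequency"
) -> np.ndarray:
    """k-mer feature vector aligned to `registry` order.

    mode="frequency" (default): within each k, count / (valid windows of
    that k), so each k-block sums to 1. mode="count": raw counts. If a
    sequence has no valid window for some k, that block is all zeros and a
    warning is raised.
    """
    if mode not in ("frequency", "count"):
        raise ValidationError(f"unknown kmer mode {mode!r}")
    codes = encode_bases(sequence)
    vec = np.zeros(len(registry), dtype=np.float64)
    for k, block in registry.block_slices.items():
        counts, n_valid = _count_codes(codes, k)
        if n_valid == 0:
            warnings.warn(
                f"sequence has no valid window at k={k}; k-mer block left at zero",
                stacklevel=2,
            )
            continue
        if mode == "frequency":
            vec[block] = counts / n_valid
        else:
            vec[block] = counts
    return vec
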