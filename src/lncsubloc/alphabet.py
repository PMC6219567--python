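"""Nucleotide alphabet helpers shared by the k-mer and motif scanners.

Canonical sequences are DNA-alphabet uppercase strings over {A, C, G, T, N}.
`N` marks an uninformative position; windows containing it are skipped by
both the k-mer counter and the PWM scanner.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# byte-level lookup table: A/C/G/T -> 0..3, everything else (incl. N) -> -1
_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _LUT[ord(_b)] = _i


def encode_bases(sequence: str) -> np.ndarray:
    """Map a canonical sequence to an int8 array (A=0, C=1, G=2, T=3, N=-1)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]
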