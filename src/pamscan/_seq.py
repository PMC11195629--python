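"""Low-level DNA string and array helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")

# fixed byte codes for vectorised comparisons
_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_ENC_TABLE = np.full(256, 4, dtype=np.uint8)
for _b, _c in _BASE_TO_CODE.items():
    _ENC_TABLE[ord(_b)] = _c

N_CODE = 4


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode DNA text as a uint8 code array (A=0,C=1,G=2,T=3,N=4)."""
    return _ENC_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def is_valid_dna(seq: str) -> bool:
    return set(seq) <= VALID_BASES
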