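"""Small sequence utilities shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes -> set of matching bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# byte value -> 0..3 index; everything else (incl. N) -> 4
_ENC = np.full(256, 4, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENC[ord(_b)] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a plain A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC degenerate pattern."""
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 indices (A=0,C=1,G=2,T=3; other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def iupac_match(base: str, code: str) -> bool:
    return base in IUPAC.get(code, "")
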