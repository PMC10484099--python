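"""Small helpers for reference sequence access.

A "reference" anywhere in this package is either a plain mapping of
sequence name -> string (as produced by the simulator) or a
:class:`pyfaidx.Fasta` handle; both support name lookup and slicing.
"""

from __future__ import annotations

import numpy as np

BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in BASE_CODES.items():
    _ENCODE_LUT[ord(_b)] = _c
    _ENCODE_LUT[ord(_b.lower())] = _c

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def fetch(reference, chrom: str, start: int, end: int) -> str:
    """Fetch ``reference[chrom][start:end]`` as an uppercase string."""
    seq = reference[chrom][start:end]
    return str(seq).upper()


def chrom_length(reference, chrom: str) -> int:
    return len(reference[chrom])


def chrom_names(reference) -> list[str]:
    if hasattr(reference, "keys"):
        return list(reference.keys())
    return list(reference.references)  # pragma: no cover - pysam-style


def encode(seq: str) -> np.ndarray:
    """Encode a base string to uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def decode(codes: np.ndarray) -> str:
    return CODE_BASES[codes].tobytes().decode("ascii")


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    codes = encode(seq)
    return float(np.mean((codes == 1) | (codes == 2)))


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))
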