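"""Byte-level sequence codecs shared by the simulator and the pipeline.

Sequences are held as ``uint8`` arrays with the encoding A=0, C=1, G=2,
T=3, N=4.  All hot loops (merging, collapsing, pileups) operate on these
code matrices; strings only appear at I/O boundaries.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

BASES = "ACGTN"

#: ASCII byte -> code (unknown bytes map to N)
_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

#: code -> ASCII byte
DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8).copy()

#: code -> complement code (N stays N)
COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string into a 1-D code array."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a 1-D code array back into a string."""
    return DECODE[codes].tobytes().decode()


def decode_rows(mat: np.ndarray) -> list[str]:
    """Decode each row of a 2-D code matrix."""
    as_bytes = DECODE[mat].tobytes()
    width = mat.shape[1]
    return [as_bytes[i : i + width].decode() for i in range(0, len(as_bytes), width)]


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement along the last axis (rows of a matrix, or a vector)."""
    return COMPLEMENT[codes][..., ::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def rows_as_void(mat: np.ndarray) -> np.ndarray:
    """View matrix rows as opaque scalars so np.unique can group identical rows."""
    arr = np.ascontiguousarray(mat, dtype=np.uint8)
    return arr.view(np.dtype((np.void, arr.shape[1]))).ravel()
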