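"""Small DNA-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# A,C,G,T -> 0..3; N (and anything else) -> 4
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def mono_di_frequencies(seqs: list[str]) -> np.ndarray:
    """Pooled mono- (4) and di-nucleotide (16) frequency vector, length 20.

    Each block is normalised to sum to 1; N-containing positions are skipped.
    """
    mono = np.zeros(4)
    di = np.zeros(16)
    for s in seqs:
        codes = encode(s)
        valid = codes < 4
        mono += np.bincount(codes[valid], minlength=4)[:4]
        a, b = codes[:-1], codes[1:]
        ok = (a < 4) & (b < 4)
        di += np.bincount((a[ok] * 4 + b[ok]).astype(np.int64), minlength=16)[:16]
    if mono.sum() > 0:
        mono = mono / mono.sum()
    if di.sum() > 0:
        di = di / di.sum()
    return np.concatenate([mono, di])
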