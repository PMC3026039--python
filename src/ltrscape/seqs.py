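"""Nucleotide sequence primitives.

Sequences are held as numpy ``uint8`` code arrays (A=0, C=1, G=2, T=3, N=4);
all genomic coordinates inside the package are 0-based half-open.  Emitted
tables convert to the 1-based inclusive convention at the I/O layer.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4
GAP = 5  # only used in alignment column arrays

_ALPHABET = np.frombuffer(b"ACGTN-", dtype=np.uint8)
_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN-"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array (unknown chars -> N)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw].copy()


def decode(codes: np.ndarray) -> str:
    return _ALPHABET[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def gc_fraction(codes: np.ndarray) -> float:
    real = codes[codes < 4]
    if real.size == 0:
        return float("nan")
    return float(np.mean((real == C) | (real == G)))


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> np.ndarray:
    """I.i.d. random sequence at the requested GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def read_fasta(path) -> dict[str, np.ndarray]:
    from Bio import SeqIO

    return {rec.id: encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, np.ndarray], width: int = 60) -> None:
    """Deterministic FASTA writer (fixed wrap, insertion order preserved)."""
    with open(path, "w") as fh:
        for name, codes in records.items():
            fh.write(f">{name}\n")
            s = decode(codes)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
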