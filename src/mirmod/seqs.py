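"""Small RNA-alphabet helpers shared across modules (internal)."""

from __future__ import annotations

import numpy as np

BASES = "ACGU"
_COMP = {"A": "U", "C": "G", "G": "C", "U": "A", "N": "N"}

# Watson-Crick pairs plus the G:U wobble, on RNA.
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}
CAN_PAIR = WC_PAIRS | GU_PAIRS


def complement(base: str) -> str:
    return _COMP[base]


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def encode(seq: str) -> np.ndarray:
    """A,C,G,U -> 0..3; N -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(BASES):
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)
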