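"""Small nucleotide-sequence helpers shared across modules.

Coordinates are 1-based inclusive everywhere in this package; BED export
converts to 0-based half-open at write time only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: canonical + wobble pairs (DNA alphabet, T plays U)
PAIRABLE = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def can_pair(a: str, b: str) -> bool:
    return (a.upper(), b.upper()) in PAIRABLE


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA), size=length))


def mutate_seq(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protect: set[int] | None = None,
) -> str:
    """Point-mutate ``seq`` at per-site probability ``rate``.

    A mutated site always changes to one of the three other bases.
    ``protect`` is a set of 0-based indices that are never touched.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mutation rate {rate} outside [0, 1]")
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        if protect and int(i) in protect:
            continue
        alternatives = [b for b in DNA if b != out[i].upper()]
        out[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end}]")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlap(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)
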