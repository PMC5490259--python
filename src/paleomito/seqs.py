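"""Core sequence containers shared across the pipeline.

Two containers cover every sequence the pipeline touches: :class:`CircularSequence`
for truth genomes, bait references and working references (strict ACGT alphabet,
optionally circular), and :class:`ConsensusSequence` for consensus calls, which
additionally admit ``N`` (missing data) and carry provenance describing which
bait / mismatch value / consolidation stage produced them.

Internally sequences are held both as Python strings (for slicing and I/O) and
lazily as ``numpy`` uint8 code arrays (A=0, C=1, G=2, T=3, N=4) for the mapper
and consensus arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_BASES = "ACGTN"

# byte-level lookup tables
_ENC = np.full(256, 255, dtype=np.uint8)
for _b, _c in _CODE.items():
    _ENC[ord(_b)] = _c
    _ENC[ord(_b.lower())] = _c

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string into a uint8 code array."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        bad = int(np.argmax(arr == 255))
        raise ValueError(f"invalid base {seq[bad]!r} at position {bad}")
    return arr


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into an ACGTN string."""
    return _BASE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


@dataclass
class CircularSequence:
    """A DNA sequence over the strict {A,C,G,T} alphabet.

    ``circular=True`` marks mitogenome-like topology: coordinates are taken
    modulo ``len(self)`` and reads may span the origin.
    """

    id: str
    bases: str
    circular: bool = True
    _codes: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("empty sequence")
        codes = encode(self.bases)
        if codes.max() > 3:
            pos = int(np.argmax(codes > 3))
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGT base at position {pos}"
            )
        self._codes = codes

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = encode(self.bases)
        return self._codes

    def fragment(self, start: int, length: int) -> str:
        """Extract ``length`` bases starting at ``start`` (modulo the origin
        when circular)."""
        n = len(self.bases)
        start %= n
        if start + length <= n:
            return self.bases[start : start + length]
        if not self.circular:
            raise ValueError("fragment runs off the end of a linear sequence")
        doubled = self.bases + self.bases
        return doubled[start : start + length]


@dataclass
class ConsensusSequence:
    """A consensus call over {A,C,G,T,N} with provenance.

    ``stage`` is 1 (per-assembly), 2 (per-mismatch-value, across baits) or
    3 (final, across mismatch values). ``bait_id`` / ``mismatch_value`` are
    filled in where they still identify a unique source.
    """

    bases: str
    stage: int = 1
    bait_id: Optional[str] = None
    mismatch_value: Optional[float] = None

    def __post_init__(self) -> None:
        if any(b not in _BASES for b in set(self.bases)):
            bad = set(self.bases) - set(_BASES)
            raise ValueError(f"consensus contains invalid symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.bases)

    @property
    def n_called(self) -> int:
        return len(self.bases) - self.bases.count("N")

    @property
    def called_fraction(self) -> float:
        return self.n_called / len(self.bases) if self.bases else 0.0

    @property
    def label(self) -> str:
        parts = [f"stage{self.stage}"]
        if self.bait_id is not None:
            parts.append(self.bait_id)
        if self.mismatch_value is not None:
            parts.append(f"mm{self.mismatch_value:.2f}")
        return "_".join(parts)
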