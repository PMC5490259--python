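"""Synthetic ancient-DNA data with known ground truth.

This module generates everything the downstream stages consume, so the whole
pipeline can be exercised without any external data: a random circular
"truth" mitogenome, bait references diverged from it by substitutions and
small indels (emulating references from lineages separated by tens of
millions of years), and short single-end reads carrying the ancient-DNA
signature — short lognormal fragment lengths, terminal cytosine deamination
(C→T) decaying geometrically away from the fragment ends, uniform base-call
error, and a configurable fraction of reads drawn from an unrelated
contaminant genome.

Every stochastic operation takes an explicit integer seed; there is no
hidden global state, and identical configuration + seed reproduces output
byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .seqs import CircularSequence, decode, encode, revcomp_codes

_C, _T, _G, _A = 1, 3, 2, 0


@dataclass
class DamageModel:
    """Terminal deamination + base-call error model.

    C→T substitution probability at distance ``k`` from a fragment end is
    ``delta * decay**k``.  Under the single-strand library convention
    (``library="ss"``) C→T is applied at both the 5' and the 3' end of the
    read-sense sequence; under ``library="ds"`` the 3' end instead receives
    G→A (the double-strand library signature).  ``error_rate`` is a uniform
    per-base substitution probability applied after damage.
    """

    delta5: float = 0.3
    delta3: float = 0.3
    decay: float = 0.9
    error_rate: float = 0.001
    library: str = "ss"

    def __post_init__(self) -> None:
        for name in ("delta5", "delta3", "decay", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.library not in ("ss", "ds"):
            raise ValueError("library must be 'ss' or 'ds'")

    @classmethod
    def none(cls) -> "DamageModel":
        """A noise-free model (no damage, no error)."""
        return cls(delta5=0.0, delta3=0.0, decay=0.0, error_rate=0.0)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic data set.

    Defaults describe a mammal-mitogenome-scale experiment: a ~16.5 kb
    circular genome at 40% GC, four bait references at 10–18% divergence
    with occasional 1–3 bp indels, reads of modal length ~60 bp (lognormal,
    floor 31 bp), ~40× target endogenous depth and 2% contaminant reads.
    """

    genome_length: int = 16500
    gc_content: float = 0.4
    n_references: int = 4
    divergences: List[float] = field(default_factory=lambda: [0.10, 0.12, 0.15, 0.18])
    indel_rate: float = 0.001
    read_length_mean: float = 60.0
    read_length_sd: float = 15.0
    min_read_length: int = 31
    target_depth: float = 40.0
    contaminant_fraction: float = 0.02
    contaminant_gc: float = 0.44
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_read_length < 1:
            raise ValueError("min_read_length must be >= 1")
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValueError("contaminant_fraction must be in [0, 1)")
        for d in self.divergences:
            if not 0.0 <= d < 0.5:
                raise ValueError(f"divergence {d} outside [0, 0.5)")
        if len(self.divergences) != self.n_references:
            raise ValueError("need one divergence per reference")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimRead:
    """One simulated (or loaded) read; truth fields are None for real data."""

    id: str
    sequence: str
    origin: Optional[str] = None  # "endogenous" | "contaminant" | None
    start: Optional[int] = None  # fragment start on the source genome (fwd strand)
    strand: Optional[str] = None  # "+" | "-"


@dataclass
class ReadSet:
    reads: List[SimRead]
    min_read_length: int = 31

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    @property
    def simulated(self) -> bool:
        return bool(self.reads) and self.reads[0].origin is not None


def generate_genome(length: int, gc: float, seed: int) -> CircularSequence:
    """Generate a random circular genome of exactly ``length`` bases.

    Bases are i.i.d. with P(C)=P(G)=gc/2 and P(A)=P(T)=(1-gc)/2, which is a
    deliberately featureless stand-in for a mitogenome: no repeats beyond
    chance, so mapping ambiguity in tests reflects the mapper, not the
    simulator.
    """
    if length < 1000:
        raise ValueError(f"length {length} too short to be mitogenome-like (>=1000)")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return CircularSequence(id=f"genome_seed{seed}", bases=decode(codes))


def evolve_reference(
    truth: CircularSequence,
    divergence: float,
    indel_rate: float,
    seed: int,
    ref_id: Optional[str] = None,
) -> CircularSequence:
    """Derive a diverged bait reference from a truth genome.

    Substitutions: each site independently mutates with probability
    ``divergence`` to one of the three other bases, uniformly (a single
    realisation of a Jukes–Cantor-like process — the realised Hamming
    fraction is therefore binomial around ``divergence``).

    Indels: a Poisson(indel_rate × length) number of events at uniform
    positions; each is an insertion or deletion (50/50) of 1–3 random bases.
    Indels are applied after substitutions, right to left, so event
    coordinates never shift each other.
    """
    if not 0.0 <= divergence < 0.5:
        raise ValueError("divergence must be in [0, 0.5)")
    if indel_rate < 0:
        raise ValueError("indel_rate must be >= 0")
    rng = np.random.default_rng(seed)
    codes = truth.codes.copy()
    n = len(codes)

    hit = rng.random(n) < divergence
    if hit.any():
        # shift by 1..3 mod 4 guarantees a different base, uniform over the other 3
        shifts = rng.integers(1, 4, size=int(hit.sum())).astype(np.uint8)
        codes[hit] = (codes[hit] + shifts) % 4

    n_events = rng.poisson(indel_rate * n)
    if n_events:
        positions = np.sort(rng.integers(0, n, size=n_events))[::-1]
        kinds = rng.random(n_events) < 0.5
        sizes = rng.integers(1, 4, size=n_events)
        out = codes
        for pos, is_ins, size in zip(positions, kinds, sizes):
            if is_ins:
                ins = rng.integers(0, 4, size=int(size)).astype(np.uint8)
                out = np.concatenate([out[:pos], ins, out[pos:]])
            else:
                out = out[: int(pos)] if pos + size >= len(out) else np.concatenate(
                    [out[:pos], out[pos + size :]]
                )
        codes = out

    rid = ref_id or f"{truth.id}_div{divergence:g}_seed{seed}"
    return CircularSequence(id=rid, bases=decode(codes))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return mu, float(np.sqrt(sigma2))


def _apply_damage(
    codes: np.ndarray, damage: DamageModel, rng: np.random.Generator
) -> np.ndarray:
    """Apply terminal deamination then uniform error, on the read-sense strand."""
    n = len(codes)
    out = codes.copy()
    if damage.delta5 > 0 or damage.delta3 > 0:
        k5 = np.arange(n)
        p5 = damage.delta5 * damage.decay**k5
        p3 = damage.delta3 * damage.decay**k5[::-1]
        u5 = rng.random(n)
        u3 = rng.random(n)
        if damage.library == "ss":
            # C->T at both ends of the read-sense sequence
            flip = (out == _C) & ((u5 < p5) | (u3 < p3))
            out[flip] = _T
        else:
            flip5 = (out == _C) & (u5 < p5)
            flip3 = (out == _G) & (u3 < p3)
            out[flip5] = _T
            out[flip3] = _A
    if damage.error_rate > 0:
        err = rng.random(n) < damage.error_rate
        if err.any():
            shifts = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
            out[err] = (out[err] + shifts) % 4
    return out


def simulate_reads(
    truth: CircularSequence,
    contaminant: Optional[CircularSequence],
    cfg: SimulationConfig,
    damage: DamageModel,
    damage_contaminant: bool = False,
) -> ReadSet:
    """Simulate a merged single-end aDNA read set with truth labels.

    Fragment starts are uniform on the circle (sampled on the doubled
    sequence, coordinates reduced modulo length); lengths are lognormal
    clipped to ``min_read_length``; strands uniform. Damage is applied to
    the read-sense sequence, then uniform error. The endogenous read count
    is ``round(target_depth × genome_length / read_length_mean)`` so that
    mean endogenous depth ≈ ``target_depth``; contaminant reads (undamaged
    by default — a modern-contaminant assumption) are added on top so that
    they form ``contaminant_fraction`` of the total.
    """
    if cfg.contaminant_fraction > 0 and contaminant is None:
        raise ValueError("contaminant_fraction > 0 requires a contaminant sequence")

    rng = np.random.default_rng(cfg.seed)
    n_end = int(round(cfg.target_depth * len(truth) / cfg.read_length_mean))
    f = cfg.contaminant_fraction
    n_cont = int(round(n_end * f / (1.0 - f))) if f > 0 else 0

    mu, sigma = _lognormal_params(cfg.read_length_mean, cfg.read_length_sd)
    reads: List[SimRead] = []

    def emit(source: CircularSequence, origin: str, count: int, damaged: bool) -> None:
        if count == 0:
            return
        lengths = np.maximum(
            np.rint(rng.lognormal(mu, sigma, size=count)).astype(int),
            cfg.min_read_length,
        )
        lengths = np.minimum(lengths, len(source))  # a fragment cannot exceed the molecule
        starts = rng.integers(0, len(source), size=count)
        strands = rng.random(count) < 0.5
        src = np.concatenate([source.codes, source.codes])  # doubled for wrap-around
        for i in range(count):
            length = int(lengths[i])
            start = int(starts[i])
            frag = src[start : start + length]
            if strands[i]:
                frag = revcomp_codes(frag)
            if damaged:
                frag = _apply_damage(frag, damage, rng)
            reads.append(
                SimRead(
                    id=f"{origin[:4]}_{len(reads):06d}",
                    sequence=decode(frag),
                    origin=origin,
                    start=start,
                    strand="-" if strands[i] else "+",
                )
            )

    emit(truth, "endogenous", n_end, damaged=True)
    if n_cont:
        assert contaminant is not None
        emit(contaminant, "contaminant", n_cont, damaged=damage_contaminant)
    return ReadSet(reads=reads, min_read_length=cfg.min_read_length)


def simulate_study(
    cfg: SimulationConfig, damage: DamageModel
) -> tuple[CircularSequence, List[CircularSequence], CircularSequence, ReadSet]:
    """Build a complete synthetic study: truth genome, bait references,
    contaminant genome and read set, all deterministically derived from
    ``cfg.seed``.

    Returns ``(truth, baits, contaminant, reads)``.
    """
    truth = generate_genome(cfg.genome_length, cfg.gc_content, cfg.seed)
    baits = [
        evolve_reference(
            truth, d, cfg.indel_rate, cfg.seed + 1000 + i, ref_id=f"bait{i}_div{d:g}"
        )
        for i, d in enumerate(cfg.divergences)
    ]
    contaminant = generate_genome(
        cfg.genome_length, cfg.contaminant_gc, cfg.seed + 999983
    )
    contaminant.id = "contaminant"
    reads = simulate_reads(truth, contaminant, cfg, damage)
    return truth, baits, contaminant, reads
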