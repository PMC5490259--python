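"""Validation harness: direct-mapping oracle and sequence comparison.

The logic mirrors how an iterative-mapping pipeline is certified when a
same-species reference happens to exist: map the *same* reads directly to
that reference in a single pass, call a consensus with the identical
coverage/agreement filters, and demand that the iteratively reconstructed
sequence matches it perfectly at every mutually called position.  On
synthetic data the same-species reference is simply the truth genome, so
the harness additionally checks every called base against truth.

``endogenous_fraction`` implements the retrospective-mapping screen: the
fraction of a read set accepted by the aligner against a given reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .consensus import (
    GAP,
    ConsensusParams,
    coverage_thresholds,
    merge_alignment,
    stage1_consensus,
)
from .mapper import Assembly, Mapper, Pileup, ReadBatch
from .seqs import CircularSequence, ConsensusSequence
from .simdata import ReadSet

SequenceLike = Union[ConsensusSequence, CircularSequence]


def _as_consensus(s: SequenceLike) -> ConsensusSequence:
    if isinstance(s, ConsensusSequence):
        return s
    return ConsensusSequence(bases=s.bases, stage=1, bait_id=s.id)


def direct_consensus(
    reads: ReadSet,
    same_species_reference: CircularSequence,
    params: ConsensusParams = ConsensusParams(),
    max_mismatch_frac: float = 0.06,
    band: int = 3,
    k: int = 13,
    batch: Optional[ReadBatch] = None,
) -> ConsensusSequence:
    """Single-pass direct-mapping consensus (the oracle).

    Maps all reads once to the reference — no iteration — and applies the
    stage-1 coverage/agreement filters with thresholds from this mapping's
    own mean depth.  An empty or unmappable read set yields an all-N
    consensus.
    """
    if batch is None:
        batch = ReadBatch(reads, k=k)
    mapper = Mapper(same_species_reference, max_mismatch_frac, band=band, k=k)
    alns = mapper.map_batch(batch)
    pileup = Pileup.from_alignments(alns, len(same_species_reference))
    asm = Assembly(
        bait_id=same_species_reference.id,
        mismatch_value=max_mismatch_frac,
        working_sequence=same_species_reference,
        alignments=alns,
        pileup=pileup,
        n_iterations=1,
        converged=True,
    )
    mean = pileup.mean_depth()
    if mean <= 0:
        return ConsensusSequence(
            bases="N" * len(same_species_reference),
            stage=1,
            bait_id=same_species_reference.id,
            mismatch_value=max_mismatch_frac,
        )
    lo, hi = coverage_thresholds(mean, params)
    return stage1_consensus(asm, lo, hi, params.agreement)


@dataclass
class SequenceComparison:
    n_compared: int
    n_mismatch: int
    n_incomparable: int

    @property
    def perfect(self) -> bool:
        return self.n_mismatch == 0


def compare_sequences(
    a: SequenceLike,
    b: SequenceLike,
    guide_a: Optional[str] = None,
    guide_b: Optional[str] = None,
) -> SequenceComparison:
    """Position-wise comparison of two (aligned) sequences.

    Positions where both carry an A/C/G/T call are compared; differing
    bases count as mismatches; positions where either side is N or gapped
    are incomparable.  Sequences of unequal length are aligned first.

    For heavily masked sequences the alignment inside N runs is ambiguous;
    passing fully informative ``guide_a``/``guide_b`` strings (same lengths
    as ``a``/``b``, e.g. the working references the consensuses were called
    on) makes the column pairing follow the guides instead.
    """
    ca, cb = _as_consensus(a), _as_consensus(b)
    if guide_a is not None and guide_b is not None:
        rows = merge_alignment(
            [ca, cb], center_index=0, guides=[guide_a, guide_b]
        )
        return _count_columns(rows)
    if len(ca) == len(cb):
        ar = np.frombuffer(ca.bases.encode(), dtype=np.uint8)
        br = np.frombuffer(cb.bases.encode(), dtype=np.uint8)
        both = (ar != ord("N")) & (br != ord("N"))
        n_comp = int(both.sum())
        n_mm = int(((ar != br) & both).sum())
        # equal lengths normally mean a shared frame; if the ungapped
        # comparison disagrees heavily the frames are probably shifted by
        # residual indels — align properly instead
        if n_comp == 0 or n_mm / n_comp <= 0.05:
            return SequenceComparison(
                n_compared=n_comp,
                n_mismatch=n_mm,
                n_incomparable=len(ca) - n_comp,
            )
    rows = merge_alignment([ca, cb], center_index=0)
    return _count_columns(rows)


def _count_columns(rows) -> SequenceComparison:
    n_comp = n_mm = n_inc = 0
    for x, y in zip(rows[0], rows[1]):
        if x in "ACGT" and y in "ACGT":
            n_comp += 1
            if x != y:
                n_mm += 1
        else:
            n_inc += 1
    return SequenceComparison(n_compared=n_comp, n_mismatch=n_mm, n_incomparable=n_inc)


def endogenous_fraction(
    reads: ReadSet,
    reference: CircularSequence,
    max_mismatch_frac: float = 0.06,
    band: int = 3,
    k: int = 13,
) -> Optional[float]:
    """Fraction of reads the aligner accepts against ``reference``.

    The retrospective-mapping screen: a sample with no endogenous material
    yields a near-zero fraction.  Returns None (undefined) for an empty
    read set.
    """
    if len(reads) == 0:
        return None
    batch = ReadBatch(reads, k=k)
    mapper = Mapper(reference, max_mismatch_frac, band=band, k=k)
    n_mapped = sum(
        1 for i in range(len(batch)) if mapper.align_batch_read(batch, i) is not None
    )
    return n_mapped / len(batch)
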