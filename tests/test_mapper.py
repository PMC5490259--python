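"""Mapper: acceptance rules, tie-breaks, circular placement, iteration."""

import numpy as np
import pytest

from paleomito import (
    CircularSequence,
    DamageModel,
    Mapper,
    Pileup,
    ReadBatch,
    SimulationConfig,
    align_read,
    iterate_assembly,
    simulate_reads,
)
from paleomito.seqs import revcomp

SUB = {"A": "C", "C": "G", "G": "T", "T": "A"}


def brute_force_best(read: str, reference: CircularSequence):
    """Exhaustive ungapped alignment oracle: every circular offset, both
    strands; returns (min mismatches, set of best (start, strand))."""
    doubled = reference.bases * 2
    n = len(reference)
    best = None
    hits = set()
    for seq, strand in ((read, "+"), (revcomp(read), "-")):
        for s in range(n):
            mm = sum(a != b for a, b in zip(seq, doubled[s : s + len(seq)]))
            if best is None or mm < best:
                best = mm
                hits = {(s, strand)}
            elif mm == best:
                hits.add((s, strand))
    return best, hits


def mutate(read: str, positions) -> str:
    out = list(read)
    for p in positions:
        out[p] = SUB[out[p]]
    return "".join(out)


class TestAlignRead:
    def test_exact_substring_accepted_at_zero(self, small_truth):
        read = small_truth.fragment(1000, 50)
        a = align_read(read, small_truth, 0.0)
        assert a is not None
        assert (a.ref_start, a.n_mismatch, a.strand) == (1000, 0, "+")

    def test_one_substitution_rejected_at_zero(self, small_truth):
        read = mutate(small_truth.fragment(1000, 50), [20])
        assert align_read(read, small_truth, 0.0) is None

    def test_boundary_three_in_fifty_accepted_at_six_percent(self, small_truth):
        # 3/50 = 0.06 is inclusive; verified against the exhaustive oracle
        read = mutate(small_truth.fragment(700, 50), [5, 25, 40])
        a = align_read(read, small_truth, 0.06)
        assert a is not None and a.n_mismatch == 3
        oracle_mm, oracle_hits = brute_force_best(read, small_truth)
        assert oracle_mm == 3
        assert (a.ref_start, a.strand) in oracle_hits

    def test_four_in_fifty_rejected_at_six_percent(self, small_truth):
        read = mutate(small_truth.fragment(700, 50), [5, 15, 25, 40])
        assert align_read(read, small_truth, 0.06) is None

    def test_reverse_strand_placement(self, small_truth):
        read = revcomp(small_truth.fragment(2000, 60))
        a = align_read(read, small_truth, 0.0)
        assert a is not None
        assert (a.ref_start, a.strand) == (2000, "-")

    def test_origin_spanning_read(self, small_truth):
        read = small_truth.fragment(len(small_truth) - 20, 50)
        a = align_read(read, small_truth, 0.0)
        assert a is not None
        assert a.ref_start == len(small_truth) - 20

    def test_ambiguous_repeat_rejected(self):
        # a perfect repeat at two non-overlapping loci: no random placement
        core = generate_unique(1200)
        unit = core[:50]
        genome = CircularSequence(
            id="rep", bases=core[:400] + unit + core[400:800] + unit + core[800:]
        )
        assert align_read(unit, genome, 0.0) is None

    def test_gapped_rescue_counts_indels(self, small_truth):
        read = small_truth.fragment(500, 52)
        read_del = read[:20] + read[22:]  # 2-base deletion
        a = align_read(read_del, small_truth, 0.02, band=3)
        assert a is not None
        assert a.n_mismatch == 0
        assert a.n_indel_bases == 2

    def test_indels_beyond_band_rejected(self, small_truth):
        read = small_truth.fragment(500, 58)
        read_del = read[:20] + read[26:]  # 6-base deletion > band 3
        assert align_read(read_del, small_truth, 0.02, band=3) is None

    def test_threshold_soundness_recount(self, small_truth, noisefree_batch):
        mapper = Mapper(small_truth, 0.06)
        for i in range(0, 300, 7):
            a = mapper.align_batch_read(noisefree_batch, i)
            if a is None:
                continue
            assert a.n_mismatch / a.read_length <= 0.06 + 1e-12
            assert a.recount_mismatches(small_truth) == a.n_mismatch


def generate_unique(n: int) -> str:
    from paleomito import generate_genome

    return generate_genome(max(n, 1000), 0.5, seed=77).bases[:n]


class TestIterateAssembly:
    def test_truth_bait_noise_free_fixed_point(self, small_truth, noisefree_reads):
        asm = iterate_assembly(noisefree_reads, small_truth, 0.0)
        assert asm.converged
        assert asm.working_sequence.bases == small_truth.bases
        assert len(asm.alignments) == len(noisefree_reads)

    def test_diverged_bait_converges_to_truth(self, small_truth, noisefree_reads):
        from paleomito import evolve_reference

        bait = evolve_reference(small_truth, 0.05, 0.0, seed=42)
        asm = iterate_assembly(noisefree_reads, bait, 0.06)
        assert asm.converged
        depth = asm.pileup.depth
        same = np.array(
            [a == b for a, b in zip(asm.working_sequence.bases, small_truth.bases)]
        )
        assert same[depth > 0].all()

    def test_strict_mapped_set_subset_of_relaxed(self, small_truth, noisefree_reads):
        from paleomito import evolve_reference

        bait = evolve_reference(small_truth, 0.10, 0.0, seed=43)
        strict = iterate_assembly(noisefree_reads, bait, 0.0)
        relaxed = iterate_assembly(noisefree_reads, bait, 0.06)
        assert strict.mapped_read_ids <= relaxed.mapped_read_ids

    def test_monotone_recruitment(self, small_truth, noisefree_reads):
        # on noise-free data, reads once recruited stay recruited
        from paleomito import evolve_reference
        from paleomito.mapper import Mapper as M

        bait = evolve_reference(small_truth, 0.08, 0.0, seed=44)
        batch = ReadBatch(noisefree_reads)
        from paleomito.mapper import _interim_consensus
        from paleomito.seqs import decode

        working = bait.codes.copy()
        prev = frozenset()
        for _ in range(8):
            ref = CircularSequence(id="w", bases=decode(working))
            alns = M(ref, 0.06).map_batch(batch)
            ids = frozenset(a.read_id for a in alns)
            assert prev <= ids
            if ids == prev:
                break
            pile = Pileup.from_alignments(alns, len(working))
            working = _interim_consensus(working, pile)
            prev = ids

    def test_oracle_equivalence_iterative_vs_direct(
        self, small_truth, noisefree_reads, noisefree_batch
    ):
        asm = iterate_assembly(noisefree_reads, small_truth, 0.06)
        direct = Mapper(small_truth, 0.06).map_batch(noisefree_batch)
        direct_pileup = Pileup.from_alignments(direct, len(small_truth))
        assert np.array_equal(asm.pileup.counts, direct_pileup.counts)

    def test_reproducible(self, small_truth, noisefree_reads):
        a = iterate_assembly(noisefree_reads, small_truth, 0.03)
        b = iterate_assembly(noisefree_reads, small_truth, 0.03)
        assert a.working_sequence.bases == b.working_sequence.bases
        assert [x.ref_start for x in a.alignments] == [x.ref_start for x in b.alignments]

    def test_empty_read_set_converges_trivially(self, small_truth):
        from paleomito import ReadSet

        asm = iterate_assembly(ReadSet(reads=[]), small_truth, 0.06)
        assert asm.converged
        assert asm.alignments == []

    def test_pileup_is_tally_of_alignments(self, small_truth, noisefree_reads):
        asm = iterate_assembly(noisefree_reads, small_truth, 0.06)
        assert int(asm.pileup.counts.sum()) == sum(
            sum(n for op, n in a.cigar if op in "=XM") for a in asm.alignments
        )

    def test_deletion_in_bait_resolved(self, small_truth, noisefree_reads):
        # bait missing 2 bases: iteration should reinsert them from reads
        b = small_truth.bases
        bait = CircularSequence(id="del2", bases=b[:1500] + b[1502:])
        asm = iterate_assembly(noisefree_reads, bait, 0.06)
        assert asm.working_sequence.bases == small_truth.bases

    def test_insertion_in_bait_resolved(self, small_truth, noisefree_reads):
        b = small_truth.bases
        bait = CircularSequence(id="ins2", bases=b[:1500] + "AC" + b[1500:])
        asm = iterate_assembly(noisefree_reads, bait, 0.06)
        assert asm.working_sequence.bases == small_truth.bases
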