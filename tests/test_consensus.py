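"""Consolidation stages: thresholds, column rules, alignment, invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleomito import (
    Assembly,
    CircularSequence,
    ConsensusParams,
    ConsensusSequence,
    Pileup,
    coverage_thresholds,
    merge_alignment,
    run_grid,
    stage1_consensus,
    stage2_consensus,
    stage3_consensus,
)
from paleomito.consensus import GAP, _column_consensus, _pairwise_align


def toy_assembly(count_rows, dels=None):
    """Assembly with a hand-written pileup (one row per position: A,C,G,T)."""
    counts = np.array(count_rows, dtype=np.int32)
    length = len(counts)
    p = Pileup(length)
    p.counts += counts
    if dels is not None:
        p.deletions += np.asarray(dels, dtype=np.int32)
    seq = CircularSequence(id="toy", bases="A" * length)
    return Assembly(
        bait_id="toy",
        mismatch_value=0.0,
        working_sequence=seq,
        alignments=[],
        pileup=p,
        n_iterations=1,
        converged=True,
    )


def cons(bases, stage=1, mm=0.0, bait=None):
    return ConsensusSequence(bases=bases, stage=stage, mismatch_value=mm, bait_id=bait)


class TestCoverageThresholds:
    @pytest.mark.parametrize(
        "mean,params,expected",
        [
            (43, ConsensusParams(), (34, 86)),  # the 80%-floor / 2x-cap corridor
            (10, ConsensusParams(), (8, 20)),
            (1, ConsensusParams(min_cov_frac=1.0, max_cov_mult=1.0), (1, 1)),
            (40.5, ConsensusParams(), (32, 81)),
        ],
    )
    def test_floor_arithmetic(self, mean, params, expected):
        assert coverage_thresholds(mean, params) == expected

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            coverage_thresholds(0.0)


class TestStage1:
    def test_supermajority_called(self):
        asm = toy_assembly([[39, 1, 0, 0]])  # 39/40 = 0.975 >= 0.95
        assert stage1_consensus(asm, 34, 86).bases == "A"

    def test_below_coverage_floor_masked(self):
        asm = toy_assembly([[33, 0, 0, 0]])
        assert stage1_consensus(asm, 34, 86).bases == "N"

    def test_above_coverage_cap_masked(self):
        asm = toy_assembly([[100, 0, 0, 0]])
        assert stage1_consensus(asm, 34, 86).bases == "N"

    def test_agreement_boundary_inclusive(self):
        asm = toy_assembly([[38, 2, 0, 0]])  # exactly 0.95
        assert stage1_consensus(asm, 34, 86).bases == "A"

    def test_below_agreement_masked(self):
        asm = toy_assembly([[37, 3, 0, 0]])  # 0.925 < 0.95
        assert stage1_consensus(asm, 34, 86).bases == "N"

    def test_tie_masked(self):
        asm = toy_assembly([[20, 20, 0, 0]])
        assert stage1_consensus(asm, 34, 86).bases == "N"

    def test_deletion_majority_removes_position(self):
        asm = toy_assembly([[40, 0, 0, 0], [1, 0, 0, 0], [0, 40, 0, 0]], dels=[0, 39, 0])
        assert stage1_consensus(asm, 34, 86).bases == "AC"

    def test_deletion_minority_spoils_agreement(self):
        # 38 A + 2 del: the base claim has only 38/40 = 0.95 support
        asm = toy_assembly([[38, 0, 0, 0]], dels=[2])
        assert stage1_consensus(asm, 34, 86).bases == "A"
        asm = toy_assembly([[37, 0, 0, 0]], dels=[3])  # 37/40 < 0.95
        assert stage1_consensus(asm, 34, 86).bases == "N"


def brute_force_nw(a, b, match=1, mismatch=-1, gap=-2):
    """Full (unbanded) Needleman-Wunsch oracle with N-wildcard scoring."""
    la, lb = len(a), len(b)
    F = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        F[i][0] = i * gap
    for j in range(1, lb + 1):
        F[0][j] = j * gap
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = 0 if "N" in (a[i - 1], b[j - 1]) else (match if a[i - 1] == b[j - 1] else mismatch)
            F[i][j] = max(F[i - 1][j - 1] + s, F[i - 1][j] + gap, F[i][j - 1] + gap)
    return F[la][lb]


def alignment_score(arow, brow):
    s = 0
    for x, y in zip(arow, brow):
        if GAP in (x, y):
            s -= 2
        elif "N" in (x, y):
            s += 0
        else:
            s += 1 if x == y else -1
    return s


class TestMergeAlignment:
    def test_identical_sequences_no_gaps(self):
        seqs = [cons("ACGTACGT") for _ in range(3)]
        rows = merge_alignment(seqs)
        assert rows == ["ACGTACGT"] * 3

    def test_two_base_deletion_yields_one_gap_block(self):
        a = cons("ACGTACGTACGTACGTACGT")
        b = cons("ACGTACGTCGTACGTACGT"[:18])  # 2-base deletion
        a2 = cons("ACGTACGTACAGTACGTACG")
        b2 = cons(a2.bases[:8] + a2.bases[10:])
        rows = merge_alignment([a2, b2])
        gap_cols = [i for i, ch in enumerate(rows[1]) if ch == GAP]
        assert len(gap_cols) == 2
        assert gap_cols[1] - gap_cols[0] == 1  # contiguous block
        # banded result matches the exhaustive DP optimum
        assert alignment_score(rows[0], rows[1]) == brute_force_nw(a2.bases, b2.bases)

    def test_all_n_sequence_contributes_no_disagreement(self):
        rows = merge_alignment([cons("ACGTACGT"), cons("ACGTACGT"), cons("N" * 8)])
        assert _column_consensus(rows) == "ACGTACGT"

    def test_low_identity_rejected(self):
        a = cons("ACGT" * 30)
        b = cons("TTGA" * 30)
        with pytest.raises(ValueError, match="identity"):
            merge_alignment([a, b])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_banded_matches_exhaustive_dp_score(self, data):
        alpha = "ACGTN"
        a = data.draw(st.text(alphabet=alpha, min_size=5, max_size=25))
        # b = a with small edits so the pair stays alignable
        b = list(a)
        for _ in range(data.draw(st.integers(0, 3))):
            op = data.draw(st.sampled_from(["sub", "del", "ins"]))
            if not b:
                break
            i = data.draw(st.integers(0, len(b) - 1))
            if op == "sub":
                b[i] = data.draw(st.sampled_from(alpha))
            elif op == "del":
                del b[i]
            else:
                b.insert(i, data.draw(st.sampled_from(alpha)))
        b = "".join(b)
        if not b:
            return
        arow, brow = _pairwise_align(a, b)
        assert arow.replace(GAP, "") == a
        assert brow.replace(GAP, "") == b
        assert alignment_score(arow, brow) >= brute_force_nw(a, b)


class TestColumnRule:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ("AAAA", "A"),
            ("AAAC", "N"),  # variable -> missing data
            ("ANNA", "A"),  # N is absence of evidence
            ("NNNN", "N"),
            ("A-AA", "N"),  # gap coexisting with a base
            ("A---", "N"),
            ("----", "N"),
        ],
    )
    def test_single_column(self, column, expected):
        assert _column_consensus(list(column)) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("ACGTN-"), min_size=2, max_size=6))
    def test_rule_matches_brute_force_enumeration(self, column):
        calls = {c for c in column if c in "ACGT"}
        if not calls:
            expected = "N"
        elif GAP in column or len(calls) > 1:
            expected = "N"
        else:
            expected = calls.pop()
        assert _column_consensus(["".join(column[i]) for i in range(len(column))]) == expected


class TestStages23:
    def test_stage2_unanimity_and_masking(self):
        s = [cons("ACGT", bait=f"b{i}") for i in range(4)]
        s[3] = cons("ACTT", bait="b3")
        out = stage2_consensus(s)
        assert out.bases == "ACNT"
        assert out.stage == 2

    def test_stage2_n_is_missing(self):
        s = [cons("ANGT"), cons("NNGT"), cons("ANGN"), cons("ANGT")]
        assert stage2_consensus(s).bases == "ANGT"

    def test_stage3_identical_passthrough(self):
        layers = [cons("ACGTACGT", stage=2, mm=m / 100) for m in range(7)]
        assert stage3_consensus(layers).bases == "ACGTACGT"

    def test_stage3_single_disagreement_masks_one_column(self):
        layers = [cons("ACGTACGT", stage=2, mm=m / 100) for m in range(6)]
        layers.append(cons("ACGTACGA", stage=2, mm=0.06))
        assert stage3_consensus(layers).bases == "ACGTACGN"

    def test_stage3_base_called_only_in_low_mismatch_layers(self):
        layers = [cons("ACGT", stage=2, mm=m / 100) for m in range(3)]
        layers += [cons("NNNN", stage=2, mm=m / 100) for m in range(3, 7)]
        assert stage3_consensus(layers).bases == "ACGT"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        seqs = []
        base = "".join(rng.choice(list("ACGT"), size=40))
        for i in range(4):
            chars = list(base)
            for j in rng.choice(40, size=6, replace=False):
                chars[j] = "N"
            seqs.append(cons("".join(chars), bait=f"b{i}"))
        out1 = stage2_consensus(seqs).bases
        for perm in itertools.permutations(range(4)):
            assert stage2_consensus([seqs[i] for i in perm]).bases == out1

    def test_conservativeness_masking_only_grows(self):
        rng = np.random.default_rng(9)
        base = "".join(rng.choice(list("ACGT"), size=60))
        grid = {}
        for b in range(3):
            for m in range(4):
                chars = list(base)
                for j in rng.choice(60, size=10, replace=False):
                    chars[j] = "N"
                if rng.random() < 0.5:  # sprinkle disagreements
                    j = int(rng.integers(0, 60))
                    chars[j] = "ACGT"[(("ACGT".index(chars[j]) + 1) % 4)] if chars[j] in "ACGT" else chars[j]
                grid[(b, m)] = cons("".join(chars), bait=f"b{b}", mm=m / 100)
        stage2s = [stage2_consensus([grid[(b, m)] for b in range(3)]) for m in range(4)]
        final = stage3_consensus(stage2s)
        for m in range(4):
            s2 = stage2s[m]
            called2 = {i for i, ch in enumerate(s2.bases) if ch != "N"}
            # stage2 calls only where no contributing stage1 disagrees
            for i in called2:
                for b in range(3):
                    c1 = grid[(b, m)].bases[i]
                    assert c1 in ("N", s2.bases[i])
        called_final = {i for i, ch in enumerate(final.bases) if ch != "N"}
        for i in called_final:
            for m in range(4):
                assert stage2s[m].bases[i] in ("N", final.bases[i])

    def test_agreement_monotonicity(self):
        rng = np.random.default_rng(13)
        counts = rng.multinomial(40, [0.9, 0.05, 0.03, 0.02], size=80)
        asm = toy_assembly(counts)
        fractions = []
        for agreement in (0.8, 0.9, 0.95, 1.0):
            c = stage1_consensus(asm, 30, 80, agreement)
            fractions.append(c.called_fraction)
        assert fractions == sorted(fractions, reverse=True)


class TestRunGrid:
    def test_grid_cardinality_and_degenerate_case(self, small_truth, noisefree_reads):
        from paleomito import evolve_reference

        baits = [
            evolve_reference(small_truth, d, 0.0, seed=50 + i, ref_id=f"b{i}")
            for i, d in enumerate([0.05, 0.08])
        ]
        params = ConsensusParams(mismatch_grid=[0.0, 0.06])
        grid = run_grid(noisefree_reads, baits, params, max_iters=6)
        assert grid.n_assemblies == 4
        # degenerate 1x1 grid: final == stage2 == stage1
        params1 = ConsensusParams(mismatch_grid=[0.06])
        grid1 = run_grid(noisefree_reads, baits[:1], params1, max_iters=6)
        only_stage1 = grid1.stage1[(baits[0].id, 0.06)]
        assert grid1.final.bases == grid1.stage2[0.06].bases == only_stage1.bases

    def test_noise_free_final_matches_truth(self, small_truth, noisefree_reads):
        from paleomito import compare_sequences, evolve_reference

        baits = [
            evolve_reference(small_truth, d, 0.0, seed=60 + i, ref_id=f"b{i}")
            for i, d in enumerate([0.05, 0.08])
        ]
        params = ConsensusParams(mismatch_grid=[0.04, 0.06])
        grid = run_grid(noisefree_reads, baits, params, max_iters=8)
        comparison = compare_sequences(grid.final, small_truth)
        assert comparison.n_mismatch == 0
        assert grid.final.called_fraction > 0.5
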