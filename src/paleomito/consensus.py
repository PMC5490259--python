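"""Three-stage consolidation of the assembly grid into one final consensus.

The grid holds one iterative assembly per (bait reference, mismatch value)
pair — 4 baits x 7 mismatch values = 28 cells with the defaults.  Three
successive consolidation stages distil the grid into a single conservative
sequence:

1. *Per-assembly*: each assembly's pileup is reduced to a consensus, keeping
   a base only where spanning depth lies inside the coverage corridor
   (floor(0.8 x mean depth) .. floor(2.0 x mean depth), the 80%-of-mean
   floor / twice-mean cap rule) and at least 95% of spanning reads agree;
   everything else is masked as N.
2. *Per-mismatch-value*: the per-bait consensuses at one mismatch value are
   aligned and any column that is variable among them is masked as N.
3. *Final*: the per-mismatch-value consensuses are aligned and masked the
   same way.

N is treated throughout stages 2-3 as *missing data*, not as a conflicting
call: a column with calls {A, N, N, A} yields A.  A gap coexisting with a
base is a length disagreement and yields N.  Masking therefore only ever
grows through the stages — a position called in the final consensus was
called, identically, in every assembly that covered it adequately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .mapper import Assembly, Pileup, ReadBatch, iterate_assembly
from .seqs import CircularSequence, ConsensusSequence
from .simdata import ReadSet

GAP = "-"


@dataclass
class ConsensusParams:
    """Thresholds of the consolidation stages.

    min_cov_frac: coverage floor as a fraction of the assembly's own mean
        depth (floored to an integer count).
    max_cov_mult: coverage cap as a multiple of mean depth (floored).
    agreement: minimum fraction of spanning reads supporting the modal base
        for it to be called (inclusive boundary: exactly 95% calls).
    mismatch_grid: the mapper mismatch values making up the grid.
    """

    min_cov_frac: float = 0.8
    max_cov_mult: float = 2.0
    agreement: float = 0.95
    mismatch_grid: List[float] = field(
        default_factory=lambda: [0.00, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06]
    )

    def __post_init__(self) -> None:
        if not 0 < self.min_cov_frac <= 1 <= self.max_cov_mult:
            raise ValueError("need 0 < min_cov_frac <= 1 <= max_cov_mult")
        if not 0.5 < self.agreement <= 1:
            raise ValueError("agreement must be in (0.5, 1]")
        if not self.mismatch_grid:
            raise ValueError("mismatch_grid must be non-empty")


def coverage_thresholds(
    mean_depth: float, params: ConsensusParams = ConsensusParams()
) -> Tuple[int, int]:
    """Integer coverage corridor for one assembly's mean depth.

    min_cov = floor(min_cov_frac x mean), max_cov = floor(max_cov_mult x mean);
    e.g. mean 43 with defaults gives (34, 86).
    """
    if mean_depth <= 0:
        raise ValueError(f"mean depth must be positive, got {mean_depth}")
    min_cov = math.floor(params.min_cov_frac * mean_depth + 1e-9)
    max_cov = math.floor(params.max_cov_mult * mean_depth + 1e-9)
    return min_cov, max_cov


def stage1_consensus(
    assembly: Assembly,
    min_cov: int,
    max_cov: int,
    agreement: float = 0.95,
) -> ConsensusSequence:
    """Reduce one assembly's pileup to a coverage- and agreement-filtered
    consensus.

    Per position, with ``total`` = spanning reads (base calls + deletion
    calls): outside [min_cov, max_cov] -> N; deletion fraction >= agreement
    -> position removed; modal base fraction >= agreement -> that base
    (inclusive boundary); otherwise (including ties) -> N.
    """
    bases, _ = _stage1_call(assembly, min_cov, max_cov, agreement)
    return ConsensusSequence(
        bases=bases,
        stage=1,
        bait_id=assembly.bait_id,
        mismatch_value=assembly.mismatch_value,
    )


def _stage1_call(
    assembly: Assembly, min_cov: int, max_cov: int, agreement: float
) -> Tuple[str, str]:
    """Shared stage-1 machinery: returns (consensus bases, guide).

    The guide is the working-reference string restricted to the same kept
    positions, so it has the stage-1 coordinate frame but stays fully
    informative (ACGT) — it later drives the cross-bait and cross-mismatch
    alignments reliably where the consensus itself is N.
    """
    p = assembly.pileup
    counts = p.counts
    total = p.depth + p.deletions
    top = counts.max(axis=1)
    tie = (counts == top[:, None]).sum(axis=1) > 1
    maj = counts.argmax(axis=1)

    in_range = (total >= min_cov) & (total <= max_cov)
    # float guard: compare counts, not ratios
    base_ok = in_range & ~tie & (top >= agreement * total - 1e-9) & (top > 0)
    del_ok = in_range & (p.deletions >= agreement * total - 1e-9) & (p.deletions > 0)

    # a called base implicitly asserts "no insertion at my flanking
    # junctions"; that assertion needs the same super-majority as the base
    # itself, so a junction with more than (1 - agreement) insertion
    # evidence masks both its neighbours
    ins_bad = np.zeros(p.length, dtype=bool)
    for pos, counter in p.insertions.items():
        jc = int(p.junctions[pos])
        if jc > 0 and sum(counter.values()) > (1 - agreement) * jc + 1e-9:
            ins_bad[pos] = True
            ins_bad[pos - 1] = True  # -1 wraps to the last position (circular)
    base_ok &= ~ins_bad

    out = np.full(p.length, "N", dtype="<U1")
    letters = np.array(["A", "C", "G", "T"])
    out[base_ok] = letters[maj[base_ok]]
    keep = ~del_ok
    work = assembly.working_sequence.bases
    guide = "".join(ch for ch, k in zip(work, keep) if k)
    return "".join(out[keep]), guide


def _pairwise_align(a: str, b: str, band_pad: int = 32) -> Tuple[str, str]:
    """Global pairwise alignment (match +1, mismatch -1, gap -2, N matches
    anything at 0) of two near-identical sequences.

    Equal-length inputs that are already near-identical ungapped are
    returned as-is (the optimum under this scoring); otherwise a banded
    dynamic programme around the main diagonal is solved, with the band
    wide enough for the length difference plus ``band_pad``.
    """
    la, lb = len(a), len(b)
    if la == lb:
        ac = np.frombuffer(a.encode(), dtype=np.uint8)
        bc = np.frombuffer(b.encode(), dtype=np.uint8)
        informative = (ac != ord("N")) & (bc != ord("N"))
        n_inf = int(informative.sum())
        if n_inf == 0:
            return a, b
        mism = int(((ac != bc) & informative).sum())
        if mism / n_inf <= 0.1:
            return a, b
    return _banded_nw(a, b, band=abs(la - lb) + band_pad)


def _banded_nw(a: str, b: str, band: int) -> Tuple[str, str]:
    la, lb = len(a), len(b)
    width = 2 * band + 1
    NEG = np.int32(-(10**9))
    # F[i, w] = best score aligning a[:i] with b[:j], j = i + w - band
    F = np.full((la + 1, width), NEG, dtype=np.int32)
    ws = np.arange(width)
    pen = np.int32(2) * ws.astype(np.int32)
    j0 = np.arange(width) - band  # j at row 0
    valid0 = (j0 >= 0) & (j0 <= lb)
    F[0, valid0] = (-2 * j0[valid0]).astype(np.int32)

    an = np.frombuffer(a.encode(), dtype=np.uint8)
    bn = np.frombuffer(b.encode(), dtype=np.uint8)
    ordN = ord("N")
    for i in range(1, la + 1):
        j = i + ws - band
        jv = (j >= 1) & (j <= lb)
        sub = np.full(width, NEG, dtype=np.int32)
        bj = bn[np.clip(j - 1, 0, lb - 1)]
        isn = (an[i - 1] == ordN) | (bj == ordN)
        sc = np.where(isn, 0, np.where(bj == an[i - 1], 1, -1)).astype(np.int32)
        diag = F[i - 1]
        up = np.concatenate([F[i - 1, 1:], [NEG]])  # gap in b (consume a)
        row = np.maximum(
            np.where(jv & (diag > NEG), diag + sc, NEG),
            np.where(up > NEG, up - 2, NEG),
        )
        row[~jv & (j != 0)] = NEG
        if np.any(j == 0):
            w0 = int(np.nonzero(j == 0)[0][0])
            row[w0] = max(row[w0], F[i - 1, w0 + 1] - 2 if w0 + 1 < width else NEG)
            if i <= band:
                row[w0] = max(row[w0], np.int32(-2 * i))
        # left moves (gap in a) within the row: max-plus prefix scan
        row = np.maximum.accumulate(row + pen) - pen
        F[i] = row

    # traceback
    out_a: List[str] = []
    out_b: List[str] = []
    i, j = la, lb
    while i > 0 or j > 0:
        w = j - i + band
        here = F[i, w]
        if i > 0 and j > 0 and 0 <= w < width:
            isn = an[i - 1] == ordN or bn[j - 1] == ordN
            sc = 0 if isn else (1 if an[i - 1] == bn[j - 1] else -1)
            if F[i - 1, w] > NEG and F[i - 1, w] + sc == here:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and w + 1 < width and F[i - 1, w + 1] > NEG and F[i - 1, w + 1] - 2 == here:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
            continue
        if j > 0 and w - 1 >= 0 and F[i, w - 1] > NEG and F[i, w - 1] - 2 == here:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
            continue
        raise RuntimeError("banded alignment traceback failed (band too narrow)")
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _center_star(
    keys: Sequence[str],
    payloads: Sequence[Sequence[str]],
    center_index: int,
    min_center_identity: float = 0.5,
) -> List[List[str]]:
    """Center-star projection shared by all multiple alignments here.

    ``keys`` drive the pairwise alignments; each channel in ``payloads``
    holds per-sequence strings of the same lengths as ``keys`` and is
    projected through the key alignment into the merged column frame.
    Returns one list of aligned row strings per channel.

    The identity check (against ``min_center_identity``, over mutually
    called A/C/G/T columns of the *keys*) guards against aligning
    unrelated sequences; all-N keys are exempt.
    """
    n = len(keys)
    center = keys[center_index]
    lc = len(center)
    aligned_sym: List[Optional[List[List[str]]]] = [None] * n
    inserted: List[Optional[List[List[str]]]] = [None] * n
    max_ins = [0] * (lc + 1)
    for idx in range(n):
        if idx == center_index:
            continue
        if len(keys[idx]) != len(payloads[0][idx]):
            raise ValueError("payload length must match key length")
        arow, brow = _pairwise_align(center, keys[idx])
        # per channel: symbol per center base + insertions per junction
        syms: List[List[str]] = [[] for _ in payloads]
        ins: List[List[str]] = [["" for _ in range(lc + 1)] for _ in payloads]
        cpos = 0
        opos = 0
        cur: List[List[str]] = [[] for _ in payloads]
        n_match = n_comp = 0
        for ca, cb in zip(arow, brow):
            if ca == GAP:
                for ch, payload in enumerate(payloads):
                    cur[ch].append(payload[idx][opos])
                opos += 1
            else:
                for ch in range(len(payloads)):
                    ins[ch][cpos] = "".join(cur[ch])
                    cur[ch] = []
                    syms[ch].append(
                        payloads[ch][idx][opos] if cb != GAP else GAP
                    )
                if cb != GAP:
                    if ca in "ACGT" and cb in "ACGT":
                        n_comp += 1
                        if ca == cb:
                            n_match += 1
                    opos += 1
                cpos += 1
        for ch in range(len(payloads)):
            ins[ch][lc] = "".join(cur[ch])
        if n_comp > 0 and n_match / n_comp < min_center_identity:
            raise ValueError(
                f"sequence {idx} aligns to the center at "
                f"{n_match / n_comp:.1%} identity "
                f"(< {min_center_identity:.0%}): grid corruption?"
            )
        aligned_sym[idx] = syms
        inserted[idx] = ins
        for t in range(lc + 1):
            max_ins[t] = max(max_ins[t], len(ins[0][t]))

    out: List[List[str]] = []
    for ch, payload in enumerate(payloads):
        rows: List[List[str]] = [[] for _ in range(n)]
        for t in range(lc + 1):
            m = max_ins[t]
            if m:
                for idx in range(n):
                    if idx == center_index:
                        rows[idx].append(GAP * m)
                    else:
                        seg = inserted[idx][ch][t]  # type: ignore[index]
                        rows[idx].append(seg + GAP * (m - len(seg)))
            if t < lc:
                for idx in range(n):
                    if idx == center_index:
                        rows[idx].append(payload[idx][t])
                    else:
                        rows[idx].append(aligned_sym[idx][ch][t])  # type: ignore[index]
        out.append(["".join(r) for r in rows])
    return out


def merge_alignment(
    consensuses: Sequence[ConsensusSequence],
    center_index: Optional[int] = None,
    guides: Optional[Sequence[str]] = None,
    min_center_identity: float = 0.5,
) -> List[str]:
    """Center-star multiple alignment of near-identical consensuses.

    The sequence with the most called (non-N) bases is the center unless
    ``center_index`` is given; every other sequence is pairwise-aligned to
    it (match +1, mismatch -1, gap -2, N matches anything at 0) and the
    pairwise gaps are merged into one column frame.  Rows come back in
    input order as equal-length strings over {A,C,G,T,N,-}.

    Masked consensuses carry little alignment information inside N runs,
    where the wildcard scoring lets segments slide; when equal-length,
    fully informative ``guides`` are available (the working references the
    consensuses were called on), the pairwise alignments are computed on
    the guides instead and the consensus strings are projected through
    them.

    Raises if any input aligns to the center at < ``min_center_identity``
    over mutually called positions (a sign the grid is corrupt) — all-N
    inputs are exempt (they carry no evidence).
    """
    if len(consensuses) < 2:
        raise ValueError("need at least two sequences to align")
    seqs = [c.bases for c in consensuses]
    if center_index is None:
        center_index = max(range(len(seqs)), key=lambda i: consensuses[i].n_called)
    keys = list(guides) if guides is not None else seqs
    (rows,) = _center_star(
        keys, [seqs], center_index, min_center_identity=min_center_identity
    )
    return rows


def _column_consensus(rows: Sequence[str]) -> str:
    """The shared column rule of stages 2 and 3.

    Per column: collect non-N, non-gap base calls; all absent -> N; a gap
    coexisting with a base -> N (length disagreement); two or more distinct
    bases -> N; otherwise the single agreed base.
    """
    ncol = len(rows[0])
    out = []
    for t in range(ncol):
        col = [r[t] for r in rows]
        calls = {c for c in col if c in "ACGT"}
        has_gap = GAP in col
        if not calls:
            out.append("N")
        elif has_gap or len(calls) > 1:
            out.append("N")
        else:
            out.append(next(iter(calls)))
    return "".join(out)


# columns masked on each side of a frame (length) disagreement between the
# input layers' reference frames; inside such a neighbourhood the column
# pairing of sparse calls is not trustworthy
INDEL_SHADOW = 8


def _cross_consensus_with_guide(
    consensuses: Sequence[ConsensusSequence],
    guides: Optional[Sequence[str]],
    shadow: int = INDEL_SHADOW,
) -> Tuple[str, str]:
    """Column-rule consolidation of several consensuses; returns
    (consensus bases, merged guide for the output frame).

    Calls within ``shadow`` columns of any gap column are masked: a gap
    means the layers' frames disagree in length there (an unresolved indel
    in at least one working reference), and cross-layer projection of the
    surrounding sparse calls can misplace them by up to the indel width.
    Where the assemblies converged the frames agree exactly, no gap
    columns exist, and nothing is lost.
    """
    seqs = [c.bases for c in consensuses]
    center = max(range(len(seqs)), key=lambda i: consensuses[i].n_called)
    keys = list(guides) if guides is not None else seqs
    rows, guide_rows = _center_star(keys, [seqs, keys], center)
    bases = _column_consensus(rows)
    if shadow > 0 and guides is not None:
        bases = _mask_frame_hazards(bases, rows, center, shadow)
    # output-frame guide: center's key where present, else any other key base
    guide_chars: List[str] = []
    ncol = len(guide_rows[0])
    for t in range(ncol):
        ch = guide_rows[center][t]
        if ch == GAP:
            ch = next((r[t] for r in guide_rows if r[t] != GAP), "A")
        guide_chars.append(ch)
    return bases, "".join(guide_chars)


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    out = mask.copy()
    for off in range(1, radius + 1):
        out[off:] |= mask[:-off]
        out[:-off] |= mask[off:]
    return out


def _mask_frame_hazards(
    bases: str, rows: Sequence[str], center: int, shadow: int
) -> str:
    """Mask calls whose only supporting layers are frame-hazardous nearby.

    A non-center layer is "hazardous" at the columns where its own pairwise
    alignment to the center needed an indel (its insertions are the columns
    where the center row is gapped and it is not; its deletions are center
    columns where it is gapped), dilated by ``shadow``.  Cross-layer
    projection can misplace that layer's sparse calls within such a
    neighbourhood by up to the indel width.  Between two nearby indels of
    the same layer the whole intervening segment has an arbitrary register
    (sparse calls inside can slide as a block), so hazard marks closer
    than ``40 x shadow`` columns are merged into one span before dilation.
    A call anchored by the center layer, or by any layer whose frame
    agrees with the center there, is kept; a call asserted only by
    frame-hazardous layers becomes N.
    """
    ncol = len(bases)
    arr = [np.frombuffer(r.encode(), dtype=np.uint8) for r in rows]
    gap = ord(GAP)
    is_call = [np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8)) for a in arr]
    ins_col = arr[center] == gap
    safe = is_call[center].copy()
    hazardous_call = np.zeros(ncol, dtype=bool)
    close_span = 40 * shadow
    for i in range(len(rows)):
        if i == center:
            continue
        hazard = (ins_col & (arr[i] != gap)) | (~ins_col & (arr[i] == gap))
        marks = np.nonzero(hazard)[0]
        for a, b in zip(marks[:-1], marks[1:]):
            if b - a < close_span:
                hazard[a:b] = True
        hazard = _dilate(hazard, shadow)
        safe |= is_call[i] & ~hazard
        hazardous_call |= is_call[i] & hazard
    drop = hazardous_call & ~safe
    if not drop.any():
        return bases
    return "".join(
        "N" if drop[t] and ch in "ACGT" else ch for t, ch in enumerate(bases)
    )


def stage2_consensus(
    stage1_per_bait: Sequence[ConsensusSequence],
    guides: Optional[Sequence[str]] = None,
) -> ConsensusSequence:
    """Cross-bait consolidation at one mismatch value: mask every column
    that is variable among the per-bait consensuses; N is missing data.

    ``guides`` (working-reference strings in each consensus's frame) make
    the underlying alignment robust inside N runs; without them the
    consensus strings themselves are aligned.
    """
    mm = stage1_per_bait[0].mismatch_value
    if len(stage1_per_bait) == 1:
        return ConsensusSequence(
            bases=stage1_per_bait[0].bases, stage=2, mismatch_value=mm
        )
    bases, _ = _cross_consensus_with_guide(stage1_per_bait, guides)
    return ConsensusSequence(bases=bases, stage=2, mismatch_value=mm)


def stage3_consensus(
    stage2_per_mismatch: Sequence[ConsensusSequence],
    guides: Optional[Sequence[str]] = None,
) -> ConsensusSequence:
    """Final consolidation across mismatch values, identical column rule."""
    if len(stage2_per_mismatch) == 1:
        return ConsensusSequence(bases=stage2_per_mismatch[0].bases, stage=3)
    bases, _ = _cross_consensus_with_guide(stage2_per_mismatch, guides)
    return ConsensusSequence(bases=bases, stage=3)


@dataclass
class AssemblyGrid:
    """All assemblies plus the per-stage consensuses."""

    bait_ids: List[str]
    mismatch_grid: List[float]
    assemblies: Dict[Tuple[str, float], Assembly]
    stage1: Dict[Tuple[str, float], ConsensusSequence]
    stage2: Dict[float, ConsensusSequence]
    final: ConsensusSequence
    final_guide: str = ""

    @property
    def n_assemblies(self) -> int:
        return len(self.assemblies)

    def report_rows(self) -> List[dict]:
        rows = []
        for (bait, mm), asm in self.assemblies.items():
            s1 = self.stage1[(bait, mm)]
            rows.append(
                dict(
                    bait=bait,
                    mismatch=mm,
                    n_iterations=asm.n_iterations,
                    converged=asm.converged,
                    n_reads_mapped=len(asm.alignments),
                    mean_depth=round(asm.pileup.mean_depth(), 2),
                    called_fraction=round(s1.called_fraction, 4),
                )
            )
        return rows


def run_grid(
    reads: ReadSet,
    baits: Sequence[CircularSequence],
    params: ConsensusParams = ConsensusParams(),
    max_iters: int = 20,
    band: int = 3,
    k: int = 13,
) -> AssemblyGrid:
    """Run the full grid: one iterative assembly per (bait, mismatch value),
    then stages 1-3.  Deterministic; a cell that fails to converge within
    ``max_iters`` is kept (flagged on the assembly), not fatal.

    An assembly recruiting no reads yields an all-N stage-1 consensus, which
    by the missing-data rule constrains nothing downstream.
    """
    if not baits:
        raise ValueError("need at least one bait reference")
    batch = ReadBatch(reads, k=k)
    assemblies: Dict[Tuple[str, float], Assembly] = {}
    stage1: Dict[Tuple[str, float], ConsensusSequence] = {}
    for bait in baits:
        for mm in params.mismatch_grid:
            asm = iterate_assembly(
                reads, bait, mm, max_iters=max_iters, band=band, k=k, batch=batch
            )
            assemblies[(bait.id, mm)] = asm

    # One study-wide mean depth feeds the coverage corridor of every cell:
    # the best-recruiting assembly's mean approximates the depth the data
    # actually provide for the molecule.  Using each starved cell's own tiny
    # mean would shrink its corridor towards 1x and let single (possibly
    # damaged or misplaced) reads call bases.
    study_mean = max(a.pileup.mean_depth() for a in assemblies.values())
    guides1: Dict[Tuple[str, float], str] = {}
    for (bait_id, mm), asm in assemblies.items():
        if study_mean > 0:
            lo, hi = coverage_thresholds(study_mean, params)
            bases, guide = _stage1_call(asm, lo, hi, params.agreement)
            stage1[(bait_id, mm)] = ConsensusSequence(
                bases=bases, stage=1, bait_id=bait_id, mismatch_value=mm
            )
            guides1[(bait_id, mm)] = guide
        else:
            stage1[(bait_id, mm)] = ConsensusSequence(
                bases="N" * len(asm.working_sequence),
                stage=1,
                bait_id=bait_id,
                mismatch_value=mm,
            )
            guides1[(bait_id, mm)] = asm.working_sequence.bases
    stage2: Dict[float, ConsensusSequence] = {}
    guides2: Dict[float, str] = {}
    for mm in params.mismatch_grid:
        cells = [stage1[(b.id, mm)] for b in baits]
        cell_guides = [guides1[(b.id, mm)] for b in baits]
        if len(cells) == 1:
            stage2[mm] = stage2_consensus(cells)
            guides2[mm] = cell_guides[0]
        else:
            bases, guide = _cross_consensus_with_guide(cells, cell_guides)
            stage2[mm] = ConsensusSequence(bases=bases, stage=2, mismatch_value=mm)
            guides2[mm] = guide
    layers = [stage2[mm] for mm in params.mismatch_grid]
    layer_guides = [guides2[mm] for mm in params.mismatch_grid]
    if len(layers) == 1:
        final = stage3_consensus(layers)
        final_guide = layer_guides[0]
    else:
        bases, final_guide = _cross_consensus_with_guide(layers, layer_guides)
        final = ConsensusSequence(bases=bases, stage=3)
    return AssemblyGrid(
        bait_ids=[b.id for b in baits],
        mismatch_grid=list(params.mismatch_grid),
        assemblies=assemblies,
        stage1=stage1,
        stage2=stage2,
        final=final,
        final_guide=final_guide,
    )
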