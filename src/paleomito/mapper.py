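"""Iterative bait-mapping assembler.

The assembler alternates two steps until the recruited read set stops
changing: (1) map every read to the current working reference with a
seed-and-extend aligner under a per-read mismatch-fraction threshold, and
(2) rebuild the working reference as an interim majority consensus of the
mapped reads.  Starting from a bait sequence that may be 10–20% diverged
from the sampled organism, the working reference moves toward the organism
with each round, recruiting reads that the bait itself could not.

Aligner design
--------------
Exact k-mer seeds (default k=13, non-overlapping offsets along the read) are
located on the doubled reference (circular topology) on both strands, giving
candidate placements.  Each candidate is scored ungapped first (vectorised
mismatch count); candidates that fail the threshold ungapped are rescued by
a banded gapped alignment (edlib, unit costs) allowing at most ``band``
indel bases (default 3).  An alignment is accepted iff

    n_mismatch / read_length <= max_mismatch_frac  and  n_indel_bases <= band.

Among accepted placements the fewest mismatches wins (ties: fewest indel
bases, then leftmost reference coordinate); if the best score is achieved at
two non-overlapping loci the read is rejected outright rather than placed
arbitrarily.  The mapper is fully deterministic.

With the default mismatch grid (<= 6%) and k=13, a read with m allowed
mismatches always retains at least one clean seed among its floor(len/13)
non-overlapping seeds (pigeonhole: 0.06 < 1/13), so seeding never loses a
threshold-passing ungapped placement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .seqs import CircularSequence, decode, encode, revcomp_codes
from .simdata import ReadSet

_CIGAR_OPS = frozenset("=XIDM")

# a read votes on the junction between positions i-1 and i only if it
# overhangs it by this many aligned bases on both sides; shorter overhangs
# cannot represent an indel there (the aligner absorbs it as mismatches)
JUNCTION_MARGIN = 4


@dataclass
class Alignment:
    """A gapped placement of one read on the working reference.

    ``oriented`` holds the read codes in reference-forward orientation
    (reverse-complemented for '-' strand reads); ``cigar`` is a list of
    (op, length) with ops '=', 'X', 'I', 'D' ('M' for ungapped placements,
    meaning aligned columns that may match or mismatch).
    """

    read_id: str
    ref_start: int
    strand: str
    oriented: np.ndarray
    cigar: List[Tuple[str, int]]
    n_mismatch: int
    n_indel_bases: int

    @property
    def read_length(self) -> int:
        return int(len(self.oriented))

    @property
    def ref_span(self) -> int:
        span = 0
        for op, length in self.cigar:
            if op in ("=", "X", "M", "D"):
                span += length
        return span

    def aligned_pairs(self) -> List[Tuple[Optional[int], Optional[int]]]:
        """(read_pos, ref_pos) pairs in the oriented frame; None marks a gap.

        ref_pos is an unreduced offset from ``ref_start`` added to it — callers
        on circular references reduce modulo the reference length.
        """
        pairs: List[Tuple[Optional[int], Optional[int]]] = []
        q, r = 0, self.ref_start
        for op, length in self.cigar:
            if op in ("=", "X", "M"):
                for _ in range(length):
                    pairs.append((q, r))
                    q += 1
                    r += 1
            elif op == "I":
                for _ in range(length):
                    pairs.append((q, None))
                    q += 1
            elif op == "D":
                for _ in range(length):
                    pairs.append((None, r))
                    r += 1
        return pairs

    def recount_mismatches(self, reference: CircularSequence) -> int:
        """Recompute the mismatch count from the stored correspondence
        (independent check of the threshold invariant)."""
        n = len(reference)
        refc = reference.codes
        mm = 0
        for q, r in self.aligned_pairs():
            if q is not None and r is not None and self.oriented[q] != refc[r % n]:
                mm += 1
        return mm


class Pileup:
    """Per-reference-position base tallies for a set of alignments.

    ``counts`` is (L, 4) for A/C/G/T, ``deletions`` the per-position count of
    reads aligning a deletion across the position, ``insertions`` maps a
    position to a Counter of sequences inserted *before* it, and
    ``junctions`` counts reads spanning the junction between position i-1
    and i with at least ``JUNCTION_MARGIN`` aligned bases on each side
    (the denominator for insertion support).
    """

    def __init__(self, length: int):
        self.length = length
        self.counts = np.zeros((length, 4), dtype=np.int32)
        self.deletions = np.zeros(length, dtype=np.int32)
        self.insertions: Dict[int, Counter] = {}
        self.junctions = np.zeros(length, dtype=np.int32)

    @classmethod
    def from_alignments(cls, alignments: Sequence[Alignment], length: int) -> "Pileup":
        p = cls(length)
        L2 = 2 * length
        flat_chunks: List[np.ndarray] = []
        del_chunks: List[np.ndarray] = []
        junc_start = np.zeros(L2 + 1, dtype=np.int32)
        for a in alignments:
            q, r = 0, a.ref_start
            for op, oplen in a.cigar:
                if op in ("=", "X", "M"):
                    pos = np.arange(r, r + oplen)
                    flat_chunks.append(pos * 4 + a.oriented[q : q + oplen])
                    q += oplen
                    r += oplen
                elif op == "I":
                    ins = decode(a.oriented[q : q + oplen])
                    p.insertions.setdefault(r % length, Counter())[ins] += 1
                    q += oplen
                elif op == "D":
                    del_chunks.append(np.arange(r, r + oplen))
                    r += oplen
            span = r - a.ref_start
            if span >= 2 * JUNCTION_MARGIN:
                junc_start[a.ref_start + JUNCTION_MARGIN] += 1
                junc_start[a.ref_start + span - JUNCTION_MARGIN + 1] -= 1
        if flat_chunks:
            flat = np.concatenate(flat_chunks)
            acc = np.bincount(flat, minlength=L2 * 4).reshape(L2, 4)
            p.counts += (acc[:length] + acc[length:]).astype(np.int32)
        if del_chunks:
            dels = np.concatenate(del_chunks)
            acc = np.bincount(dels, minlength=L2)
            p.deletions += (acc[:length] + acc[length:]).astype(np.int32)
        junc2 = np.cumsum(junc_start[:L2])
        p.junctions += (junc2[:length] + junc2[length:]).astype(np.int32)
        return p

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def mean_depth(self) -> float:
        """Mean depth over covered positions (depth >= 1); 0.0 if nothing maps."""
        d = self.depth
        covered = d > 0
        return float(d[covered].mean()) if covered.any() else 0.0


@dataclass
class Assembly:
    """One cell of the bait x mismatch-value grid."""

    bait_id: str
    mismatch_value: float
    working_sequence: CircularSequence
    alignments: List[Alignment]
    pileup: Pileup
    n_iterations: int
    converged: bool

    @property
    def mapped_read_ids(self) -> frozenset:
        return frozenset(a.read_id for a in self.alignments)


class ReadBatch:
    """Read encodings and seed k-mer codes, computed once and reused across
    every grid cell and iteration (reads never change; only the reference
    does)."""

    def __init__(self, reads: ReadSet, k: int = 13):
        self.k = k
        self.ids: List[str] = []
        self.fwd: List[np.ndarray] = []
        self.rev: List[np.ndarray] = []
        self.fwd_bytes: List[bytes] = []
        self.rev_bytes: List[bytes] = []
        self.seed_codes: List[Tuple[np.ndarray, np.ndarray]] = []
        for r in reads:
            f = encode(r.sequence)
            b = revcomp_codes(f)
            self.ids.append(r.id)
            self.fwd.append(f)
            self.rev.append(b)
            self.fwd_bytes.append(r.sequence.encode("ascii"))
            self.rev_bytes.append(decode(b).encode("ascii"))
            self.seed_codes.append((_seed_kmers(f, k), _seed_kmers(b, k)))
        # flat seed table for one-shot batch lookup
        codes, rids, strands, offs = [], [], [], []
        for i, (sf, sr) in enumerate(self.seed_codes):
            for strand, arr in ((0, sf), (1, sr)):
                codes.append(arr)
                rids.append(np.full(len(arr), i, dtype=np.int32))
                strands.append(np.full(len(arr), strand, dtype=np.uint8))
                offs.append(np.arange(len(arr), dtype=np.int32) * k)
        self.flat_codes = np.concatenate(codes) if codes else np.empty(0, np.int64)
        self.flat_read = np.concatenate(rids) if rids else np.empty(0, np.int32)
        self.flat_strand = (
            np.concatenate(strands) if strands else np.empty(0, np.uint8)
        )
        self.flat_offset = np.concatenate(offs) if offs else np.empty(0, np.int32)

    def __len__(self) -> int:
        return len(self.ids)


def _seed_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Codes of non-overlapping k-mers at offsets 0, k, 2k, ... ; empty if the
    read is shorter than k."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64)
    offsets = np.arange(0, n - k + 1, k)
    vals = np.zeros(len(offsets), dtype=np.int64)
    for i in range(k):
        vals = vals * 4 + codes[offsets + i]
    return vals


class ReferenceIndex:
    """Sorted k-mer table over one circular rotation of the reference."""

    def __init__(self, codes: np.ndarray, k: int = 13):
        self.k = k
        self.length = len(codes)
        self.doubled = np.concatenate([codes, codes])
        self.doubled_bytes = decode(self.doubled).encode("ascii")
        ext = self.doubled[: self.length + k - 1]
        vals = np.zeros(self.length, dtype=np.int64)
        for i in range(k):
            vals = vals * 4 + ext[i : i + self.length]
        order = np.argsort(vals, kind="stable")
        self._sorted = vals[order]
        self._pos = order

    def lookup(self, code: int) -> np.ndarray:
        lo = int(np.searchsorted(self._sorted, code, side="left"))
        hi = int(np.searchsorted(self._sorted, code, side="right"))
        return self._pos[lo:hi]


def _left_align_cigar(
    cigar: List[Tuple[str, int]],
    oriented: np.ndarray,
    refd: np.ndarray,
    ref_start: int,
) -> List[Tuple[str, int]]:
    """Shift indels to their leftmost equivalent placement.

    Within a repeat run an indel can sit at several equivalent positions;
    the aligner's choice depends on where the read happens to start, which
    splits pileup indel votes across columns.  Shifting is done only when
    the displaced aligned column keeps its base value (ref char for D,
    read char for I), so mismatch and indel counts are untouched and the
    placement becomes canonical.
    """
    segs: List[List] = [[op, n] for op, n in cigar]
    changed = True
    while changed:
        changed = False
        q = 0
        r = ref_start
        for i, seg in enumerate(segs):
            op, n = seg
            if op in ("=", "X", "M"):
                q += n
                r += n
            elif op == "I":
                if (
                    i > 0
                    and segs[i - 1][0] in ("=", "X", "M")
                    and segs[i - 1][1] > 0
                    and oriented[q - 1] == oriented[q + n - 1]
                ):
                    segs[i - 1][1] -= 1
                    if i + 1 < len(segs) and segs[i + 1][0] in ("=", "X", "M"):
                        segs[i + 1][1] += 1
                    else:
                        segs.insert(i + 1, ["M", 1])
                    changed = True
                    break
                q += n
            elif op == "D":
                if (
                    i > 0
                    and segs[i - 1][0] in ("=", "X", "M")
                    and segs[i - 1][1] > 0
                    and refd[r - 1] == refd[r + n - 1]
                ):
                    segs[i - 1][1] -= 1
                    if i + 1 < len(segs) and segs[i + 1][0] in ("=", "X", "M"):
                        segs[i + 1][1] += 1
                    else:
                        segs.insert(i + 1, ["M", 1])
                    changed = True
                    break
                r += n
    out: List[Tuple[str, int]] = []
    for op, n in segs:
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def _parse_cigar(cig: str) -> List[Tuple[str, int]]:
    out: List[Tuple[str, int]] = []
    num = 0
    for ch in cig:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            if ch not in _CIGAR_OPS:
                raise ValueError(f"unexpected cigar op {ch!r}")
            out.append((ch, num))
            num = 0
    return out


class Mapper:
    """Maps reads against one (fixed) working reference."""

    def __init__(
        self,
        reference: CircularSequence,
        max_mismatch_frac: float,
        band: int = 3,
        k: int = 13,
    ):
        if band < 0:
            raise ValueError("band must be >= 0")
        self.reference = reference
        self.max_mismatch_frac = max_mismatch_frac
        self.band = band
        self.k = k
        self.index = ReferenceIndex(reference.codes, k)

    def _candidates(self, seeds: np.ndarray) -> set:
        L = self.index.length
        starts: set = set()
        k = self.k
        for j, code in enumerate(seeds):
            for pos in self.index.lookup(int(code)):
                starts.add((int(pos) - j * k) % L)
        return starts

    def _score(
        self, oriented: np.ndarray, obytes: bytes, start: int
    ) -> Optional[Tuple[int, int, int, List[Tuple[str, int]]]]:
        """Score one candidate placement; returns (n_mismatch, n_indel,
        ref_start, cigar) or None."""
        L = self.index.length
        rl = len(oriented)
        allowed = int(self.max_mismatch_frac * rl + 1e-9)
        seg = self.index.doubled[start : start + rl]
        if len(seg) < rl:  # can only happen for reads longer than the reference
            return None
        mm = int(np.count_nonzero(seg != oriented))
        ungapped = (mm, 0, start, [("M", rl)]) if mm <= allowed else None
        if mm == 0 or self.band == 0:
            return ungapped
        # gapped rescue: a small indel absorbed as ungapped mismatches must
        # surface as I/D so the pileup sees it — and by the fewest-mismatches
        # rule a gapped placement with fewer X beats the ungapped one
        ws = start + L if start < self.band else start
        lo = ws - self.band
        hi = min(ws + rl + self.band, 2 * L)
        res = edlib.align(
            query=obytes,
            target=self.index.doubled_bytes[lo:hi],
            mode="HW",
            task="path",
            k=allowed + self.band,
        )
        gapped = None
        if res["editDistance"] >= 0:
            cig = _parse_cigar(res["cigar"])
            n_mm = sum(n for op, n in cig if op == "X")
            n_ind = sum(n for op, n in cig if op in ("I", "D"))
            # a terminal indel is a degenerate re-encoding of a terminal
            # mismatch (it would erase exactly the damage signal the
            # profile measures) — only internal indels are real
            degenerate = cig[0][0] in ("I", "D") or cig[-1][0] in ("I", "D")
            if n_mm <= allowed and n_ind <= self.band and n_ind > 0 and not degenerate:
                abs_start = lo + res["locations"][0][0]
                cig = _left_align_cigar(cig, oriented, self.index.doubled, abs_start)
                gapped = (n_mm, n_ind, abs_start % L, cig)
        if gapped is None:
            return ungapped
        if ungapped is None:
            return gapped
        # same candidate locus, two encodings: take the gapped one only if
        # it strictly reduces the total number of edits
        if gapped[0] + gapped[1] < ungapped[0]:
            return gapped
        return ungapped

    def align_batch_read(self, batch: ReadBatch, i: int) -> Optional[Alignment]:
        cands = {
            "+": self._candidates(batch.seed_codes[i][0]),
            "-": self._candidates(batch.seed_codes[i][1]),
        }
        return self._best_from_candidates(batch, i, cands)

    def _best_from_candidates(
        self, batch: ReadBatch, i: int, cands: Dict[str, set]
    ) -> Optional[Alignment]:
        L = self.index.length
        rl = len(batch.fwd[i])
        best: List[Tuple[int, int, int, List[Tuple[str, int]], str, np.ndarray]] = []
        best_key: Optional[Tuple[int, int]] = None
        for strand, oriented, obytes in (
            ("+", batch.fwd[i], batch.fwd_bytes[i]),
            ("-", batch.rev[i], batch.rev_bytes[i]),
        ):
            for start in cands.get(strand, ()):
                sc = self._score(oriented, obytes, start)
                if sc is None:
                    continue
                key = (sc[0], sc[1])
                if best_key is None or key < best_key:
                    best_key = key
                    best = [(*sc, strand, oriented)]
                elif key == best_key:
                    best.append((*sc, strand, oriented))
        if not best:
            return None
        if len(best) > 1:
            starts = sorted({b[2] for b in best})
            if len(starts) > 1:
                # distinct placements with equal score: reject if any two are
                # non-overlapping loci (circular separation >= read length)
                for a in range(len(starts)):
                    for b in range(a + 1, len(starts)):
                        d = starts[b] - starts[a]
                        d = min(d, L - d)
                        if d >= rl:
                            return None
            else:
                # same locus reported on both strands with equal score:
                # genuinely ambiguous orientation
                if len({b[4] for b in best}) > 1:
                    return None
            best = [min(best, key=lambda b: (b[2], b[4]))]
        n_mm, n_ind, ref_start, cig, strand, oriented = best[0]
        return Alignment(
            read_id=batch.ids[i],
            ref_start=ref_start,
            strand=strand,
            oriented=oriented,
            cigar=cig,
            n_mismatch=n_mm,
            n_indel_bases=n_ind,
        )

    def map_batch(self, batch: ReadBatch) -> List[Alignment]:
        """Map every read in the batch; seed lookup is done in one
        vectorised pass over the whole batch's seed table."""
        L = self.index.length
        lo = np.searchsorted(self.index._sorted, batch.flat_codes, side="left")
        hi = np.searchsorted(self.index._sorted, batch.flat_codes, side="right")
        hit_idx = np.nonzero(hi > lo)[0]
        cand: Dict[int, Dict[str, set]] = {}
        pos_tab = self.index._pos
        flat_read = batch.flat_read
        flat_strand = batch.flat_strand
        flat_offset = batch.flat_offset
        for t in hit_idx:
            starts = (pos_tab[lo[t] : hi[t]] - flat_offset[t]) % L
            d = cand.setdefault(int(flat_read[t]), {"+": set(), "-": set()})
            d["+" if flat_strand[t] == 0 else "-"].update(starts.tolist())
        out = []
        for i in sorted(cand):
            a = self._best_from_candidates(batch, i, cand[i])
            if a is not None:
                out.append(a)
        return out


def align_read(
    read: str,
    reference: CircularSequence,
    max_mismatch_frac: float,
    band: int = 3,
    k: int = 13,
) -> Optional[Alignment]:
    """Align a single read; convenience wrapper over :class:`Mapper`.

    Returns None for unmappable or ambiguously placed reads.
    """
    from .simdata import ReadSet, SimRead

    batch = ReadBatch(ReadSet([SimRead(id="read", sequence=read)], 1), k=k)
    return Mapper(reference, max_mismatch_frac, band=band, k=k).align_batch_read(
        batch, 0
    )


MIN_INDEL_VOTES = 4


def _interim_consensus(
    working: np.ndarray,
    pileup: Pileup,
    indel_agreement: float = 0.95,
) -> np.ndarray:
    """Majority consensus used *between* iterations.

    Plain per-position majority wherever depth >= 1; ties and uncovered
    positions keep the previous base (stability across iterations). Indels
    are applied only on a >= ``indel_agreement`` supermajority of at least
    ``MIN_INDEL_VOTES`` spanning reads: enough that a coincidence of
    independent errors is implausible, yet low enough that frame defects in
    coverage troughs still heal (an unhealed frame locks in permanent local
    misassembly).  Final authenticity is enforced by the consensus stages,
    not here.
    """
    counts = pileup.counts
    depth = pileup.depth
    top = counts.max(axis=1)
    tie = (counts == top[:, None]).sum(axis=1) > 1
    maj = counts.argmax(axis=1).astype(np.uint8)
    out = np.where((depth > 0) & ~tie, maj, working).astype(np.uint8)

    min_cov = MIN_INDEL_VOTES

    edits: List[Tuple[int, str, np.ndarray]] = []
    # deletion votes are judged against reads that span the position with
    # margin (the junction count): reads barely overlapping the site cannot
    # express an indel and must not dilute the supermajority
    span = pileup.junctions
    del_pos = np.nonzero(
        (span >= min_cov) & (pileup.deletions >= indel_agreement * span)
    )[0]
    for pos in del_pos:
        edits.append((int(pos), "D", np.empty(0, dtype=np.uint8)))
    for pos, counter in pileup.insertions.items():
        jc = int(pileup.junctions[pos])
        if jc < min_cov:
            continue
        ins, support = counter.most_common(1)[0]
        if support >= indel_agreement * jc:
            edits.append((int(pos), "I", encode(ins)))

    if edits:
        edits.sort(key=lambda e: e[0], reverse=True)
        pieces = out
        for pos, kind, ins in edits:
            if kind == "D":
                pieces = np.concatenate([pieces[:pos], pieces[pos + 1 :]])
            else:
                pieces = np.concatenate([pieces[:pos], ins, pieces[pos:]])
        out = pieces
    return out


def iterate_assembly(
    reads: ReadSet,
    bait: CircularSequence,
    max_mismatch_frac: float,
    max_iters: int = 20,
    band: int = 3,
    k: int = 13,
    batch: Optional[ReadBatch] = None,
) -> Assembly:
    """Run the iterative bait-mapping loop for one grid cell.

    Stops when the recruited read-id set is unchanged between consecutive
    iterations (``converged=True``) or after ``max_iters`` mapping passes.
    The returned assembly's pileup and alignments are always consistent with
    its ``working_sequence`` (the reference used in the final mapping pass).
    """
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    if batch is None:
        batch = ReadBatch(reads, k=k)

    working = bait.codes.copy()
    prev_ids: Optional[frozenset] = None
    alns: List[Alignment] = []
    pileup = Pileup(len(working))
    seq_used = working
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iters + 1):
        seq_used = working
        mapper = Mapper(
            CircularSequence(id=bait.id, bases=decode(working)),
            max_mismatch_frac,
            band=band,
            k=k,
        )
        alns = mapper.map_batch(batch)
        pileup = Pileup.from_alignments(alns, len(working))
        ids = frozenset(a.read_id for a in alns)
        new_working = _interim_consensus(working, pileup)
        # converged only when neither the recruited read set nor the
        # working sequence itself would change any further — a stable read
        # set alone can hide a pending consensus edit
        if ids == prev_ids and np.array_equal(new_working, working):
            converged = True
            break
        working = new_working
        prev_ids = ids

    return Assembly(
        bait_id=bait.id,
        mismatch_value=max_mismatch_frac,
        working_sequence=CircularSequence(
            id=f"{bait.id}_mm{max_mismatch_frac:.2f}", bases=decode(seq_used)
        ),
        alignments=alns,
        pileup=pileup,
        n_iterations=n_iter,
        converged=converged,
    )
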