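"""Sequence-authentication analytics.

Three orthogonal checks that a reconstructed mitogenome is what it claims
to be:

* sliding-window pairwise identity against the bait references and an
  unrelated outgroup/contaminant track — a chimeric or contaminant-derived
  block shows up as a local spike of identity to the wrong sequence;
* the terminal C→T deamination profile and read-length histogram of the
  mapped reads — the ancient-DNA authenticity signature;
* a premature-stop-codon scan of annotated protein-coding genes under the
  vertebrate mitochondrial genetic code (TAA, TAG, AGA, AGG are stops).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .consensus import GAP, merge_alignment
from .mapper import Alignment
from .seqs import CircularSequence, ConsensusSequence, revcomp

VERTEBRATE_MITO_STOPS = frozenset({"TAA", "TAG", "AGA", "AGG"})

# mapping threshold for QC (damage profiling, retrospective screening of a
# sample's own reads): permissive on purpose — at the strict assembly
# thresholds, heavily damaged reads are preferentially rejected, which
# deflates the terminal misincorporation rates being measured
QC_MISMATCH = 0.10

_COMP_STR = str.maketrans("ACGTN", "TGCAN")


@dataclass
class WindowParams:
    window: int = 500
    step: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window:
            raise ValueError("need 0 < step <= window")


@dataclass
class IdentityTrack:
    """Per-window identity of the query against each comparison sequence,
    computed on the shared degapped, N-free column frame."""

    params: WindowParams
    comparison_ids: List[str]
    starts: np.ndarray  # window start, frame coordinates
    identities: np.ndarray  # (n_windows, n_comparisons)
    frame_length: int

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def to_rows(self) -> List[dict]:
        rows = []
        for w in range(self.n_windows):
            row = {"window_index": w, "start": int(self.starts[w])}
            for c, cid in enumerate(self.comparison_ids):
                row[cid] = float(self.identities[w, c])
            rows.append(row)
        return rows


def window_identity(
    query: ConsensusSequence,
    comparisons: Sequence[CircularSequence],
    params: WindowParams = WindowParams(),
) -> IdentityTrack:
    """Sliding-window identity of a consensus against comparison sequences.

    The query is aligned (as center) to every comparison; columns where the
    query is N or where any sequence is gapped are removed; windows of
    ``params.window`` columns at ``params.step`` intervals are scored as
    matching columns / window on what remains.  The number of windows is
    floor((L - window)/step) + 1 for a frame of L >= window columns.
    """
    if not comparisons:
        raise ValueError("need at least one comparison sequence")
    comps = [
        ConsensusSequence(bases=c.bases, stage=1, bait_id=c.id) for c in comparisons
    ]
    # no identity floor here: an unrelated outgroup/contaminant track is a
    # legitimate comparison (it should simply score low everywhere)
    rows = merge_alignment([query] + comps, center_index=0, min_center_identity=0.0)
    qrow = np.array(list(rows[0]))
    crows = np.array([list(r) for r in rows[1:]])
    keep = (qrow != "N") & (qrow != GAP) & ~(crows == GAP).any(axis=0)
    qf = qrow[keep]
    cf = crows[:, keep]
    L = len(qf)
    w, s = params.window, params.step
    if L < w:
        raise ValueError(
            f"only {L} ungapped, N-free columns remain; window of {w} impossible"
        )
    n_win = (L - w) // s + 1
    match = (cf == qf[None, :]).astype(np.float64)  # (n_comp, L)
    csum = np.concatenate(
        [np.zeros((len(comps), 1)), np.cumsum(match, axis=1)], axis=1
    )
    starts = np.arange(n_win) * s
    ident = (csum[:, starts + w] - csum[:, starts]).T / w
    return IdentityTrack(
        params=params,
        comparison_ids=[c.id for c in comparisons],
        starts=starts,
        identities=ident,
        frame_length=L,
    )


@dataclass
class DamageProfile:
    """Terminal misincorporation frequencies and read-length histogram.

    ``ct5[k]`` / ``ct3[k]`` are the C→T frequencies at distance k from the
    5'/3' read end (read-sense, relative to the mapped reference), NaN where
    no reference C was observed at that distance.  With ``track_ga`` the
    double-strand-library G→A track at the 3' end is filled in as well.
    """

    max_distance: int
    ct5: np.ndarray
    ct3: np.ndarray
    n_ref_c5: np.ndarray
    n_ref_c3: np.ndarray
    ga3: Optional[np.ndarray]
    read_lengths: Counter

    def length_histogram(self) -> Dict[int, int]:
        return dict(sorted(self.read_lengths.items()))


def damage_profile(
    alignments: Sequence[Alignment],
    reference: CircularSequence,
    max_distance: int = 25,
    track_ga: bool = False,
) -> DamageProfile:
    """Measure terminal C→T misincorporation against a mapped reference.

    For each end, frequency(k) = (# reads where the reference has C and the
    read has T at read-sense distance k from that end) / (# reads where the
    reference has C there).  Reverse-strand alignments are complemented back
    to read sense, so damage bookkeeping is end-of-molecule, not
    end-of-reference.  Zero-denominator distances are NaN (undefined).
    """
    md = max_distance
    num5 = np.zeros(md, dtype=np.int64)
    den5 = np.zeros(md, dtype=np.int64)
    num3 = np.zeros(md, dtype=np.int64)
    den3 = np.zeros(md, dtype=np.int64)
    ga_num3 = np.zeros(md, dtype=np.int64)
    ga_den3 = np.zeros(md, dtype=np.int64)
    lengths: Counter = Counter()
    n = len(reference)
    refc = reference.codes
    C, T, G, A = 1, 3, 2, 0

    for aln in alignments:
        lengths[aln.read_length] += 1
        # oriented-frame arrays of (read base, ref base) for aligned columns
        q_idx: List[int] = []
        r_idx: List[int] = []
        q, r = 0, aln.ref_start
        for op, oplen in aln.cigar:
            if op in ("=", "X", "M"):
                q_idx.extend(range(q, q + oplen))
                r_idx.extend(range(r, r + oplen))
                q += oplen
                r += oplen
            elif op == "I":
                q += oplen
            elif op == "D":
                r += oplen
        qa = np.asarray(q_idx)
        read_b = aln.oriented[qa]
        ref_b = refc[np.asarray(r_idx) % n]
        rl = aln.read_length
        if aln.strand == "+":
            d5 = qa
            d3 = rl - 1 - qa
        else:
            # oriented is the reverse complement of the read: read-sense
            # distance from 5' is rl-1-q, and bases complement
            d5 = rl - 1 - qa
            d3 = qa
            read_b = 3 - read_b.astype(np.int16)
            ref_b = 3 - ref_b.astype(np.int16)
        for dist, num, den, want_ref, want_read in (
            (d5, num5, den5, C, T),
            (d3, num3, den3, C, T),
        ):
            sel = (dist < md) & (ref_b == want_ref)
            if sel.any():
                np.add.at(den, dist[sel], 1)
                hit = sel & (read_b == want_read)
                if hit.any():
                    np.add.at(num, dist[hit], 1)
        if track_ga:
            sel = (d3 < md) & (ref_b == G)
            if sel.any():
                np.add.at(ga_den3, d3[sel], 1)
                hit = sel & (read_b == A)
                if hit.any():
                    np.add.at(ga_num3, d3[hit], 1)

    with np.errstate(invalid="ignore"):
        ct5 = np.where(den5 > 0, num5 / np.maximum(den5, 1), np.nan)
        ct3 = np.where(den3 > 0, num3 / np.maximum(den3, 1), np.nan)
        ga3 = (
            np.where(ga_den3 > 0, ga_num3 / np.maximum(ga_den3, 1), np.nan)
            if track_ga
            else None
        )
    return DamageProfile(
        max_distance=md,
        ct5=ct5,
        ct3=ct3,
        n_ref_c5=den5,
        n_ref_c3=den3,
        ga3=ga3,
        read_lengths=lengths,
    )


@dataclass
class GeneAnnotation:
    """A protein-coding gene on the consensus, 1-based inclusive coordinates."""

    name: str
    start: int
    end: int
    strand: str = "+"
    code_id: int = 2  # vertebrate mitochondrial

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.name}: end {self.end} < start {self.start}")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class StopHit:
    gene: str
    codon_index: int  # 1-based
    codon: str


@dataclass
class StopScanResult:
    hits: List[StopHit]
    n_skipped_codons: Dict[str, int]  # codons containing N, unevaluable
    annotation_errors: List[str]  # genes whose length is not divisible by 3

    @property
    def clean(self) -> bool:
        return not self.hits


def premature_stop_scan(
    consensus: ConsensusSequence,
    genes: Sequence[GeneAnnotation],
) -> StopScanResult:
    """Scan annotated genes for in-frame stop codons before the final codon.

    Under the vertebrate mitochondrial code TAA, TAG, AGA and AGG are stops.
    Codons containing N are unevaluable and counted separately; a gene whose
    length is not a multiple of 3 is reported as an annotation error and
    scanned over its complete codons.
    """
    hits: List[StopHit] = []
    skipped: Dict[str, int] = {}
    errors: List[str] = []
    seq = consensus.bases
    for gene in genes:
        if gene.end > len(seq):
            errors.append(f"{gene.name}: coordinates exceed sequence length")
            continue
        sub = seq[gene.start - 1 : gene.end]
        if gene.strand == "-":
            sub = sub.translate(_COMP_STR)[::-1]
        if len(sub) % 3 != 0:
            errors.append(
                f"{gene.name}: length {len(sub)} not divisible by 3"
            )
        n_codons = len(sub) // 3
        n_skip = 0
        for ci in range(n_codons - 1):  # exclude the final (terminal) codon
            codon = sub[3 * ci : 3 * ci + 3]
            if "N" in codon:
                n_skip += 1
            elif codon in VERTEBRATE_MITO_STOPS:
                hits.append(StopHit(gene=gene.name, codon_index=ci + 1, codon=codon))
        skipped[gene.name] = n_skip
    return StopScanResult(hits=hits, n_skipped_codons=skipped, annotation_errors=errors)


def plot_identity_track(track: IdentityTrack, path: str) -> None:
    """Write a simple identity-track figure (one line per comparison)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    for c, cid in enumerate(track.comparison_ids):
        ax.plot(track.starts, track.identities[:, c], label=cid)
    ax.set_xlabel("window start (degapped frame)")
    ax.set_ylabel("pairwise identity")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
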