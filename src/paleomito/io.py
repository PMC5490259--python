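"""Format readers/writers and run configuration.

FASTA/FASTQ parsing is delegated to Biopython; this layer adds the
pipeline's validation rules (uppercase normalisation, U→T, strict
{A,C,G,T,N} alphabet with the offending position reported, duplicate-id
and empty-file errors, the 31 bp minimum-length read filter) and the
sidecar formats: truth-label TSV, grid report TSV, pileup TSV, BED-like
gene annotation TSV, SAM export and YAML run configs.

User-facing coordinates are 1-based inclusive; everything internal is
0-based half-open.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .authcheck import GeneAnnotation, WindowParams
from .consensus import ConsensusParams
from .mapper import Assembly
from .seqs import CircularSequence, ConsensusSequence
from .simdata import DamageModel, ReadSet, SimRead, SimulationConfig

logger = logging.getLogger("paleomito")

_VALID = set("ACGTN")


def _normalise(seq: str, label: str) -> str:
    s = seq.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in _VALID:
            raise ValueError(
                f"{label}: invalid character {ch!r} at position {i + 1}"
            )
    return s


def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    """Read a multi-FASTA into an ordered {id: sequence} dict.

    Sequences are uppercased, U is mapped to T, and any character outside
    {A,C,G,T,N} is rejected with its position. Empty files and duplicate
    ids are errors.
    """
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = _normalise(str(rec.seq), f"{path}:{rec.id}")
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    path: Union[str, Path], records: Iterable[Tuple[str, str]], width: int = 70
) -> None:
    """Write (id, sequence) records as FASTA wrapped at ``width`` columns."""
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=width).write_file(recs)


def load_references(path: Union[str, Path], circular: bool = True) -> List[CircularSequence]:
    """Load strict-ACGT reference sequences (truth genomes, baits)."""
    return [
        CircularSequence(id=rid, bases=seq, circular=circular)
        for rid, seq in read_fasta(path).items()
    ]


def read_fastq(
    path: Union[str, Path], min_length: int = 31
) -> Tuple[ReadSet, int]:
    """Read single-end FASTQ; reads shorter than ``min_length`` are dropped
    and counted. Returns (readset, n_dropped). Qualities are parsed (format
    errors surface) but unused downstream."""
    reads: List[SimRead] = []
    n_dropped = 0
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            seq = _normalise(str(rec.seq), f"{path}:record {i + 1}")
            if len(seq) < min_length:
                n_dropped += 1
                continue
            reads.append(SimRead(id=rec.id, sequence=seq))
    except ValueError as e:
        raise ValueError(f"{path}: malformed FASTQ record: {e}") from e
    if not reads:
        logger.warning("%s: no reads retained (min_length=%d)", path, min_length)
    return ReadSet(reads=reads, min_read_length=min_length), n_dropped


def write_fastq(path: Union[str, Path], reads: ReadSet) -> None:
    """Write reads as 4-line FASTQ with constant quality 'I' (qualities are
    not modelled and not used downstream)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_truth_labels(path: Union[str, Path], reads: ReadSet) -> None:
    """Sidecar TSV of simulation truth: read_id, origin, start (1-based), strand."""
    rows = [
        dict(
            read_id=r.id,
            origin=r.origin,
            start=(r.start + 1) if r.start is not None else None,
            strand=r.strand,
        )
        for r in reads
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_labels(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_grid_report(path: Union[str, Path], rows: List[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pileup_tsv(path: Union[str, Path], assembly: Assembly) -> None:
    """Pileup as TSV: pos (1-based), A, C, G, T, del, depth."""
    p = assembly.pileup
    df = pd.DataFrame(
        {
            "pos": range(1, p.length + 1),
            "A": p.counts[:, 0],
            "C": p.counts[:, 1],
            "G": p.counts[:, 2],
            "T": p.counts[:, 3],
            "del": p.deletions,
            "depth": p.depth,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_sam(path: Union[str, Path], assembly: Assembly) -> None:
    """Export an assembly's alignments as SAM.

    The header carries the (circular) reference; CIGARs use M/I/D; the NM
    tag records the mismatch count (the quantity the mapper thresholds).
    """
    ref = assembly.working_sequence
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{ref.id}\tLN:{len(ref)}\tTP:circular\n")
        fh.write("@PG\tID:paleomito\tPN:paleomito\n")
        from .seqs import decode

        for a in assembly.alignments:
            flag = 16 if a.strand == "-" else 0
            cigar = "".join(
                f"{n}{'M' if op in '=XM' else op}" for op, n in a.cigar
            )
            seq = decode(a.oriented)
            fh.write(
                f"{a.read_id}\t{flag}\t{ref.id}\t{a.ref_start + 1}\t255\t{cigar}"
                f"\t*\t0\t0\t{seq}\t{'I' * len(seq)}\tNM:i:{a.n_mismatch}\n"
            )


def read_region_mask(path: Union[str, Path]) -> List[Tuple[int, int]]:
    """BED-like TSV of regions to mask on export: columns name, start, end
    (1-based inclusive). Returns (start, end) tuples."""
    df = pd.read_csv(path, sep="\t")
    if not {"start", "end"}.issubset(df.columns):
        raise ValueError(f"{path}: need columns start, end")
    return [(int(r["start"]), int(r["end"])) for _, r in df.iterrows()]


def mask_regions(bases: str, regions: Iterable[Tuple[int, int]]) -> str:
    """Replace the given 1-based inclusive regions with N (e.g. dropping the
    control region before phylogenetic use)."""
    out = list(bases)
    for start, end in regions:
        if not 1 <= start <= end <= len(out):
            raise ValueError(f"region {start}-{end} outside sequence of {len(out)} bp")
        out[start - 1 : end] = "N" * (end - start + 1)
    return "".join(out)


def read_gene_annotations(path: Union[str, Path]) -> List[GeneAnnotation]:
    """BED-like TSV with columns: name, start, end, strand (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return [
        GeneAnnotation(
            name=str(r["name"]),
            start=int(r["start"]),
            end=int(r["end"]),
            strand=str(r["strand"]),
        )
        for _, r in df.iterrows()
    ]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; round-trips via YAML."""

    outdir: str = "paleomito_run"
    reads_path: Optional[str] = None  # None => simulate
    baits_path: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"
    max_iters: int = 20
    band: int = 3
    kmer: int = 13
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    damage: DamageModel = field(default_factory=DamageModel)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    windows: WindowParams = field(default_factory=WindowParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("simulation", SimulationConfig),
            ("damage", DamageModel),
            ("consensus", ConsensusParams),
            ("windows", WindowParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
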