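"""FASTA/FASTQ input and output.

References travel as plain FASTA; simulated paired-end reads are written as
gzipped FASTQ with an ``_R1``/``_R2`` file-name convention.  The simulator does
not model base-call qualities, so FASTQ qualities are a constant configurable
character (default ``'I'``, Phred 40).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

from .pools import DNA_ALPHABET, ReferencePool


@dataclass
class ReadSet:
    """Simulated paired-end reads with read-direction provenance.

    ``r1`` holds forward reads (5' prefix of the oligo), ``r2`` reverse reads
    (5' prefix of the oligo's reverse complement).  ``true_ref`` records the
    originating reference index for each pair; it exists for simulator
    bookkeeping only and must not be consulted by the analysis toolkit.
    """

    r1: list[str]
    r2: list[str]
    ids: list[str] = field(default_factory=list)
    true_ref: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.r1) != len(self.r2):
            raise ValueError("r1 and r2 must be paired")
        if not self.ids:
            self.ids = [f"read_{i:07d}" for i in range(len(self.r1))]

    def __len__(self) -> int:
        return len(self.r1)


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a FASTA file into (id, sequence) tuples."""
    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}:{lineno}: sequence before first header")
                chunks.append(line.strip())
        if header is not None:
            records.append((header, "".join(chunks)))
    return records


def reference_pool_from_fasta(path: str | Path) -> ReferencePool:
    records = read_fasta(path)
    return ReferencePool(ids=[r[0] for r in records], sequences=[r[1] for r in records])


def write_fasta(path: str | Path, records) -> None:
    """Write (id, sequence) tuples or a ReferencePool to FASTA."""
    if isinstance(records, ReferencePool):
        records = records.entries
    with _open_text(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(
    reads: ReadSet,
    prefix: str | Path,
    quality_char: str = "I",
    gzipped: bool = True,
) -> tuple[Path, Path]:
    """Write a ReadSet as paired FASTQ files ``<prefix>_R1/_R2.fastq[.gz]``."""
    if len(quality_char) != 1:
        raise ValueError("quality_char must be a single character")
    suffix = ".fastq.gz" if gzipped else ".fastq"
    prefix = Path(prefix)
    paths = (Path(f"{prefix}_R1{suffix}"), Path(f"{prefix}_R2{suffix}"))
    for path, seqs in zip(paths, (reads.r1, reads.r2)):
        with _open_text(path, "w") as fh:
            for rid, seq in zip(reads.ids, seqs):
                fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")
    return paths


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTQ into (id, sequence) tuples; qualities are discarded."""
    records: list[tuple[str, str]] = []
    with _open_text(path, "r") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln]
    if len(lines) % 4 != 0:
        raise ValueError(f"{path}: truncated FASTQ (line count not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise ValueError(f"{path}: line {i + 1}: expected '@' header, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise ValueError(f"{path}: line {i + 3}: expected '+' separator")
        if len(seq) != len(qual):
            raise ValueError(f"{path}: line {i + 2}: sequence/quality length mismatch")
        if set(seq) - set(DNA_ALPHABET + "N"):
            raise ValueError(f"{path}: line {i + 2}: non-nucleotide characters")
        records.append((head[1:].split()[0], seq))
    return records


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> ReadSet:
    r1 = read_fastq(r1_path)
    r2 = read_fastq(r2_path)
    if len(r1) != len(r2):
        raise ValueError("paired FASTQ files differ in read count")
    return ReadSet(r1=[s for _, s in r1], r2=[s for _, s in r2], ids=[i for i, _ in r1])
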