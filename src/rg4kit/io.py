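"""Plain-text I/O: FASTA, FASTQ (optionally gzipped), BED6 and TSV tables.

Conventions used throughout the package (stated once, enforced by round-trip
tests): BED intervals are 0-based half-open on transcript coordinates with
strand ``+``; FASTQ quality is Phred+33; TSV files carry a header row.
Gzipped output is written with a zeroed mtime so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import gzip
import io as _io
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "BedRecord",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "FastqRead",
    "read_fastq",
    "write_fastq",
    "read_table",
    "write_table",
    "open_text",
]


@contextmanager
def open_text(path: str | Path, mode: str = "r"):
    """Open a text file, transparently gzipped if the name ends in ``.gz``.

    Gzip members are written with ``mtime=0`` for reproducible bytes.
    """
    path = Path(path)
    if path.suffix == ".gz":
        if "r" in mode:
            with gzip.open(path, "rt") as fh:
                yield fh
        else:
            raw = path.open("wb")
            gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
            txt = _io.TextIOWrapper(gz, encoding="ascii", newline="\n")
            try:
                yield txt
            finally:
                txt.flush()
                gz.close()
                raw.close()
    else:
        with path.open(mode) as fh:
            yield fh


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "+"
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty/inverted BED interval {self.start}-{self.end}")


def write_bed(records: Iterable[BedRecord], path: str | Path) -> None:
    with open_text(path, "w") as fh:
        for r in records:
            fields = [r.chrom, str(r.start), str(r.end), r.name, f"{r.score:g}", r.strand]
            fields.extend(r.extra)
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | Path) -> list[BedRecord]:
    out: list[BedRecord] = []
    with open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            out.append(
                BedRecord(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    name=f[3] if len(f) > 3 else ".",
                    score=float(f[4]) if len(f) > 4 else 0.0,
                    strand=f[5] if len(f) > 5 else "+",
                    extra=tuple(f[6:]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> sequence mapping (order-preserving)."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open_text(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"sequence/quality length mismatch in {self.read_id!r}")


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open_text(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Iterate FASTQ records; raises on truncated or malformed input."""
    with open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record near {header!r}")
            yield FastqRead(read_id=header[1:].split()[0], sequence=seq, quality=qual)


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------


# ---------------------------------------------------------------------------
# SAM (minimal, for real data)
# ---------------------------------------------------------------------------


def read_sam_reads(
    path: str | Path, condition: str, replicate: int = 1, input_ng: float = 0.0
) -> pd.DataFrame:
    """Minimal SAM import for real aligned data: mate-1, forward-strand
    (template-strand) primary alignments become aligned-read table rows.

    Only strand and position semantics are interpreted; the UMI is taken
    from the read name suffix after the last ``_`` (the usual extraction
    convention).  Untested against any public dataset — the aligned-read
    TSV is the supported interchange format.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_reverse or (aln.is_paired and not aln.is_read1):
                continue
            name = aln.query_name
            umi = name.rsplit("_", 1)[1] if "_" in name else "."
            rows.append(
                {
                    "read_id": name,
                    "transcript_id": aln.reference_name,
                    "strand": "+",
                    "stop_pos": aln.reference_start,
                    "end_pos": aln.reference_end,
                    "umi": umi,
                    "condition": condition,
                    "replicate": replicate,
                    "input_ng": input_ng,
                    "fate": "usable",
                    "molecule_id": ".",
                    "is_duplicate_of": ".",
                }
            )
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    with open_text(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    with open_text(path) as fh:
        return pd.read_csv(fh, sep="\t", **kwargs)
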