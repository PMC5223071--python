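"""FASTA ingestion and tabular output.

Reading accepts plain or gzip FASTA, line-wrapped or single-line, with
blank lines tolerated between records.  Sequences are normalized on
ingest (uppercase, U→T).  Malformed files fail with the offending line
number; duplicate record ids are rejected by name.

Output tables use "." decimals and 6 significant digits for
frequencies and scores, so identical inputs give byte-identical files.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, TextIO

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as _bio_write
from Bio.SeqRecord import SeqRecord

from .errors import FastaParseError
from .orf import Sequence, find_orfs

FLOAT_FORMAT = "%.6g"


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a multi-record FASTA file into normalized Sequences.

    Raises :class:`~lncsieve.errors.FastaParseError` with a line number
    for structural problems and lists the id on duplicates.
    """
    seqs: list[Sequence] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        if not chunks:
            raise FastaParseError(
                f"line {header_line}: record {header!r} has an empty sequence"
            )
        if header in seen:
            raise FastaParseError(f"duplicate sequence id {header!r}")
        seen.add(header)
        seqs.append(Sequence(header, "".join(chunks)))

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaParseError(f"line {lineno}: header has no id")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                chunks.append(line)
    _flush()
    if header is None:
        raise FastaParseError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: str | Path) -> None:
    """Write sequences as 60-column-wrapped FASTA (gzip if path ends .gz)."""
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    with _open_text(path, "wt") as fh:
        _bio_write(records, fh, "fasta")


def orf_table(seqs: Iterable[Sequence]) -> pd.DataFrame:
    """ORF report: one row per ORF, 1-based inclusive coordinates.

    Frames are reported as +1/+2/+3 following the usual reading-frame
    convention for the forward strand.
    """
    rows = []
    for seq in seqs:
        for orf in find_orfs(seq):
            rows.append(
                {
                    "id": seq.id,
                    "frame": f"+{orf.frame + 1}",
                    "start": orf.start + 1,
                    "end": orf.end,
                    "length": orf.length,
                }
            )
    return pd.DataFrame(rows, columns=["id", "frame", "start", "end", "length"])


def orf_bed(seqs: Iterable[Sequence]) -> pd.DataFrame:
    """ORF intervals as BED6 (0-based half-open, strand '+')."""
    rows = []
    for seq in seqs:
        for orf in find_orfs(seq):
            rows.append(
                {
                    "chrom": seq.id,
                    "start": orf.start,
                    "end": orf.end,
                    "name": f"{seq.id}_orf_f{orf.frame + 1}_{orf.start + 1}",
                    "score": orf.length,
                    "strand": "+",
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a table as TSV with the package-wide float format."""
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)
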