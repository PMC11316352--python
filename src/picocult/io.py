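"""File-format helpers: FASTA/FASTQ via Biopython, BED intervals, TSV tables."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered ``{id: sequence}`` mapping."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write sequences wrapped at 80 columns."""
    items = sequences.items() if isinstance(sequences, dict) else sequences
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(read_id, sequence, quality_string)`` from a FASTQ(.gz) file."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield rec.id, str(rec.seq).upper(), qual


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    return list(iter_fastq(path))


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write ``(read_id, sequence, quality)`` triples as Phred+33 FASTQ."""
    with _open_text(path, "wt") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read 3-column BED (0-based, half-open) as ``(chrom, start, end)``."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
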