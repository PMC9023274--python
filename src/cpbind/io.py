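"""File I/O: FASTA sequences, interval files, profile and report tables.

Internal coordinates are 1-based inclusive throughout the package (the
convention every genome position is printed in); BED input/output is
converted at this boundary (0-based half-open) and nowhere else.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .evaluation import IntervalSet
from .profiles import ProteinSequence, RnaSequence

__all__ = [
    "read_fasta",
    "read_rna_fasta",
    "read_protein_fasta",
    "read_intervals",
    "write_intervals",
    "write_report",
    "read_report",
    "write_profile_tsv",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Raw (id, sequence) pairs from a FASTA file; error if empty."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_rna_fasta(path: str | Path) -> list[RnaSequence]:
    return [RnaSequence(rid, seq) for rid, seq in read_fasta(path)]


def read_protein_fasta(path: str | Path) -> list[ProteinSequence]:
    return [ProteinSequence(rid, seq) for rid, seq in read_fasta(path)]


def read_intervals(path: str | Path, style: str = "bed",
                   genome_id: str | None = None,
                   label: str = "") -> IntervalSet:
    """Read intervals from BED (0-based half-open) or 1-based TSV.

    ``style="bed"``: columns chrom/start/end; converted to 1-based
    inclusive (BED line ``chr 101 114`` becomes 102..114).
    ``style="tsv1"``: columns are 1-based inclusive start/end, either
    ``start<TAB>end`` or ``chrom<TAB>start<TAB>end``; an optional header is
    skipped.
    """
    if style not in ("bed", "tsv1"):
        raise ValueError(f"style must be 'bed' or 'tsv1', got {style!r}")
    intervals = []
    chrom_seen = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                if style == "bed":
                    if len(parts) < 3:
                        raise ValueError("need >= 3 columns")
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    if end <= start:
                        raise ValueError("empty or inverted BED interval")
                    intervals.append((start + 1, end))
                else:
                    if len(parts) == 2:
                        chrom = genome_id or ""
                        start, end = int(parts[0]), int(parts[1])
                    elif len(parts) >= 3:
                        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    else:
                        raise ValueError("need 2 or 3 columns")
                    if start < 1 or end < start:
                        raise ValueError("invalid 1-based interval")
                    intervals.append((start, end))
            except ValueError as exc:
                if lineno == 1:
                    continue  # tolerate a header line
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
            chrom_seen = chrom_seen or chrom
    if not intervals:
        raise ValueError(f"no intervals found in {path}")
    return IntervalSet(genome_id=genome_id or chrom_seen or "",
                       intervals=tuple(intervals), label=label or Path(path).stem)


def write_intervals(ivs: IntervalSet, path: str | Path,
                    style: str = "bed") -> None:
    """Write an interval set as BED (0-based half-open) or 1-based TSV."""
    if style not in ("bed", "tsv1"):
        raise ValueError(f"style must be 'bed' or 'tsv1', got {style!r}")
    with open(path, "w") as fh:
        for s, e in ivs.intervals:
            if style == "bed":
                fh.write(f"{ivs.genome_id}\t{s - 1}\t{e}\t{ivs.label}\n")
            else:
                fh.write(f"{ivs.genome_id}\t{s}\t{e}\n")


def write_report(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a report table as TSV (round-trips through :func:`read_report`)."""
    rows.to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_profile_tsv(positions: Iterable[int], columns: dict[str, Sequence],
                      path: str | Path) -> None:
    """Write per-position profile values (undefined margins omitted)."""
    df = pd.DataFrame({"position": list(positions), **columns})
    df.to_csv(path, sep="\t", index=False)
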