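"""Readers/writers for the standard formats the pipeline touches.

This module is the single source of truth for coordinate and strand
conventions:

* All in-memory coordinates are **1-based inclusive** on the forward
  genome.  Minus-strand features keep forward coordinates plus a strand
  flag; a 3' end position ``x`` always denotes the 3'-terminal
  transcribed nucleotide, on either strand.
* BED and bedGraph files on disk are 0-based half-open, per the
  standards.  Conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

STRANDS = ("+", "-")
TRACK_KINDS = ("rnaseq", "termseq_ends", "rnet_ends")

_DNA = set("ACGT")
_DNA_PERMISSIVE = set("ACGTN")


class FormatError(ValueError):
    """Raised on malformed input files or inconsistent records."""


@dataclass(frozen=True)
class GenomeSeq:
    """A reference chromosome held as an uppercase ACGT string."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError("empty genome sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos`` (forward strand)."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside genome 1..{self.length}")
        return self.sequence[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """Forward-strand sequence for the 1-based inclusive span [start, end]."""
        if start < 1 or end > self.length or start > end:
            raise IndexError(f"span [{start}, {end}] outside genome 1..{self.length}")
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class CoverageTrack:
    """Strand-specific per-nucleotide non-negative signal.

    ``values[i]`` is the signal at 1-based genome position ``i + 1``;
    the array therefore has exactly genome length entries.  ``kind`` is
    one of :data:`TRACK_KINDS` and is immutable after construction.
    """

    genome_id: str
    strand: str
    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"kind must be one of {TRACK_KINDS}, got {self.kind!r}")
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("coverage values must be finite and >= 0")
        object.__setattr__(self, "values", arr)

    @property
    def length(self) -> int:
        return int(self.values.size)

    def value_at(self, pos: int) -> float:
        """Signal at 1-based position ``pos``; 0 outside the genome."""
        if 1 <= pos <= self.length:
            return float(self.values[pos - 1])
        return 0.0

    def window(self, start: int, end: int) -> np.ndarray:
        """Values over the 1-based inclusive span [start, end] (must be in bounds)."""
        if start < 1 or end > self.length or start > end:
            raise IndexError(f"window [{start}, {end}] outside track 1..{self.length}")
        return self.values[start - 1 : end]


@dataclass(frozen=True)
class ThreePrimeEnd:
    """A called transcript 3' terminus.

    ``x`` is the 1-based genome position of the 3'-terminal nucleotide,
    ``cv`` the coverage-variation magnitude supporting the call and
    ``end_count`` the raw 3'-end pileup there (equal to ``cv`` when the
    call was made directly on an end-count landscape).
    """

    x: int
    strand: str
    cv: float
    end_count: float

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")
        if self.cv < 0 or self.end_count < 0:
            raise ValueError("cv and end_count must be >= 0")


def read_fasta(path: str | Path, permissive: bool = False) -> GenomeSeq:
    """Load the first record of a FASTA file as a :class:`GenomeSeq`.

    Sequences are uppercased.  Non-ACGT characters raise
    :class:`FormatError` unless ``permissive`` is set, in which case N
    is tolerated (it never pairs and never counts as U/A/T downstream).
    Extra records trigger a warning and are ignored.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path} holds {len(records)} records; using the first "
            f"({records[0].id}) only",
            stacklevel=2,
        )
    seq = str(records[0].seq).upper()
    alphabet = _DNA_PERMISSIVE if permissive else _DNA
    bad = set(seq) - alphabet
    if bad:
        raise FormatError(f"non-nucleotide character(s) {sorted(bad)} in {path}")
    return GenomeSeq(id=records[0].id, sequence=seq)


def read_bedgraph(
    path: str | Path, genome: GenomeSeq, strand: str, kind: str
) -> CoverageTrack:
    """Densify a bedGraph file into a per-nucleotide :class:`CoverageTrack`.

    bedGraph intervals are 0-based half-open; positions not covered by
    any interval get 0.  Overlapping intervals with conflicting values
    and out-of-bounds intervals raise :class:`FormatError`.
    """
    values = np.zeros(genome.length, dtype=float)
    assigned = np.zeros(genome.length, dtype=bool)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 bedGraph columns")
            start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            if start < 0 or end > genome.length or start >= end:
                raise FormatError(
                    f"{path}:{ln}: interval [{start}, {end}) outside genome "
                    f"of length {genome.length}"
                )
            seg = slice(start, end)
            clash = assigned[seg] & (values[seg] != value)
            if np.any(clash):
                raise FormatError(
                    f"{path}:{ln}: overlapping interval with conflicting values"
                )
            values[seg] = value
            assigned[seg] = True
    return CoverageTrack(genome_id=genome.id, strand=strand, kind=kind, values=values)


def write_bedgraph(track: CoverageTrack, path: str | Path, comment: str | None = None) -> None:
    """Write a track as bedGraph, run-length compressing equal values.

    Zero runs are omitted (absent positions read back as 0), so a
    write/read round trip reproduces ``values`` exactly.
    """
    vals = track.values
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        i = 0
        n = vals.size
        while i < n:
            j = i + 1
            while j < n and vals[j] == vals[i]:
                j += 1
            if vals[i] != 0.0:
                fh.write(f"{track.genome_id}\t{i}\t{j}\t{vals[i]:g}\n")
            i = j


def write_bed_ends(
    ends: Sequence[ThreePrimeEnd], path: str | Path, genome_id: str = "."
) -> None:
    """Write called 3' ends as BED6 (start = x-1, end = x, score = C_V)."""
    with open(path, "w") as fh:
        fh.write("# termtk 3' ends: chrom start end name score(C_V) strand\n")
        for end in ends:
            fh.write(
                f"{genome_id}\t{end.x - 1}\t{end.x}\t.\t{end.cv:g}\t{end.strand}\n"
            )


def read_bed_ends(path: str | Path) -> list[ThreePrimeEnd]:
    """Read BED6 3'-end records written by :func:`write_bed_ends`."""
    ends: list[ThreePrimeEnd] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{ln}: expected BED6 columns")
            start, end = int(parts[1]), int(parts[2])
            if end != start + 1:
                raise FormatError(f"{path}:{ln}: 3'-end records must span 1 nt")
            cv = float(parts[4])
            ends.append(ThreePrimeEnd(x=end, strand=parts[5], cv=cv, end_count=cv))
    return ends


def write_fasta(genome: GenomeSeq, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def transcript_upstream(
    genome: GenomeSeq, x: int, n: int, strand: str, include_x: bool = True
) -> str:
    """Transcript-sense DNA sequence of the ``n`` nt ending at ``x``.

    Returns the sequence 5'->3' in the direction of transcription; for
    the minus strand this is the reverse complement of the forward
    genome.  Truncated at the genome edge (may be shorter than ``n``).
    ``include_x=False`` shifts the window one nt upstream so it ends at
    the position immediately before ``x``.
    """
    if strand == "+":
        end = x if include_x else x - 1
        start = max(1, end - n + 1)
        if end < 1:
            return ""
        return genome.slice(start, end)
    start = x if include_x else x + 1
    end = min(genome.length, start + n - 1)
    if start > genome.length:
        return ""
    return revcomp(genome.slice(start, end))


def transcript_pos(x: int, offset: int, strand: str) -> int:
    """Genomic position of transcript offset ``offset`` relative to ``x``.

    Offsets follow the pause-register convention: the 3' end itself is
    offset -1, the nucleotide transcribed before it is -2, and so on;
    offset 0 is the first nucleotide downstream of the 3' end.
    """
    step = offset + 1
    return x + step if strand == "+" else x - step
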