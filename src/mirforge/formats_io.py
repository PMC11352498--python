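"""Readers and writers for every on-disk format the pipeline touches.

No science lives here.  Sequences are stored internally in the DNA alphabet
(U folded onto T, uppercase); conversion back to RNA happens only where a
format demands it (precursor/hairpin FASTA, folding input).  Internal
coordinates are 0-based half-open; every on-disk coordinate is 1-based
inclusive, following miRBase/GFF convention.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "SequenceRecord",
    "MatureCoordinateSidecar",
    "read_fastq",
    "read_fasta",
    "write_fasta",
    "read_vienna_fold",
    "write_count_matrix",
    "read_count_matrix",
    "read_mature_coords",
    "write_mature_coords",
    "write_gff3",
]

_FASTA_WRAP = 60
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence with optional per-base Phred qualities."""

    id: str
    sequence: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureCoordinateSidecar:
    """Annotated mature-arm interval on a precursor (1-based inclusive)."""

    precursor_id: str
    arm: str  # "5p" | "3p"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise FormatError(f"arm must be 5p or 3p, got {self.arm!r}")
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"{self.precursor_id}: bad interval {self.start}-{self.end}"
            )

    @property
    def slice0(self) -> tuple[int, int]:
        """The interval as 0-based half-open (start, end)."""
        return self.start - 1, self.end


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream Phred+33 FASTQ records in file order.

    A manual 4-line parser so malformed blocks can be reported with the
    offending line number (Biopython's fast iterator discards it).
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FormatError(f"{path}: line {lineno}: expected '@', got {header[:20]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise FormatError(f"{path}: line {lineno}: truncated record")
            lineno += 3
            if not plus.startswith("+"):
                raise FormatError(f"{path}: line {lineno - 1}: expected '+', got {plus[:20]!r}")
            if len(qual) != len(seq):
                raise FormatError(
                    f"{path}: line {lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            yield SequenceRecord(
                id=header[1:].split()[0] if len(header) > 1 else "",
                sequence=to_dna(seq),
                quality=tuple(ord(c) - 33 for c in qual),
            )


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            qual = rec.quality or (40,) * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{''.join(chr(q + 33) for q in qual)}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream FASTA records; duplicate ids are an error; U normalised to T."""
    seen: set[str] = set()
    with _open_text(path) as fh:
        name: str | None = None
        chunks: list[str] = []
        first = True
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    yield SequenceRecord(id=name, sequence=to_dna("".join(chunks)))
                name = line[1:].split()[0]
                if name in seen:
                    raise FormatError(f"{path}: duplicate FASTA id {name!r}")
                seen.add(name)
                chunks = []
                first = False
            else:
                if first:
                    raise FormatError(f"{path}: sequence data before first '>' header")
                chunks.append(line.strip())
        if name is not None:
            yield SequenceRecord(id=name, sequence=to_dna("".join(chunks)))


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, alphabet: str = "dna"
) -> None:
    """Write records wrapped at 60 columns; alphabet 'rna' emits U, 'dna' T."""
    conv = to_rna if alphabet == "rna" else to_dna
    with _open_text(path, "wt") as fh:
        for rec in records:
            seq = conv(rec.sequence)
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), _FASTA_WRAP):
                fh.write(seq[i : i + _FASTA_WRAP] + "\n")


# ---------------------------------------------------------------------------
# Vienna (RNAfold) 3-line fold output
# ---------------------------------------------------------------------------

_ENERGY_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def read_vienna_fold(path: str | Path) -> list:
    """Parse RNAfold-style output: optional '>id', sequence, then the
    dot-bracket line with a trailing '( -12.30 )' energy in kcal/mol.

    Returns :class:`~mirforge.hairpin.HairpinStructure` objects; unbalanced
    brackets or a sequence/structure length mismatch raise FormatError.
    """
    from .hairpin import HairpinStructure  # local import avoids cycle at module load

    structures = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    n_rec = 0
    while i < len(lines):
        rec_id = None
        if lines[i].startswith(">"):
            rec_id = lines[i][1:].split()[0]
            i += 1
        if i + 1 >= len(lines):
            raise FormatError(f"{path}: truncated fold record at line {i + 1}")
        seq = to_dna(lines[i].strip())
        struct_line = lines[i + 1].strip()
        i += 2
        n_rec += 1
        m = _ENERGY_RE.search(struct_line)
        if not m:
            raise FormatError(f"{path}: fold record {n_rec}: missing trailing energy")
        energy = float(m.group(1))
        db = struct_line[: m.start()].strip()
        if len(db) != len(seq):
            raise FormatError(
                f"{path}: fold record {n_rec}: structure length {len(db)} "
                f"!= sequence length {len(seq)}"
            )
        try:
            structures.append(
                HairpinStructure.from_dotbracket(seq, db, energy, id=rec_id)
            )
        except ValueError as exc:
            raise FormatError(f"{path}: fold record {n_rec}: {exc}") from exc
    return structures


# ---------------------------------------------------------------------------
# Count matrices (TSV)
# ---------------------------------------------------------------------------

def write_count_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """TSV with the miRNA name as first column; floats at 6 decimals."""
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].tolist()
        raise FormatError(f"duplicated miRNA name(s): {dupes}")
    out = matrix.copy()
    out.index.name = "miRNA"
    out.to_csv(path, sep="\t", float_format="%.6f")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicated miRNA name(s): {dupes}")
    return df


# ---------------------------------------------------------------------------
# Mature-coordinate sidecar (TSV) and GFF3 annotation export
# ---------------------------------------------------------------------------

def read_mature_coords(path: str | Path) -> list[MatureCoordinateSidecar]:
    df = pd.read_csv(path, sep="\t", dtype={"precursor_id": str, "arm": str})
    required = {"precursor_id", "arm", "start", "end"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    coords = [
        MatureCoordinateSidecar(r.precursor_id, r.arm, int(r.start), int(r.end))
        for r in df.itertuples()
    ]
    seen = set()
    for c in coords:
        key = (c.precursor_id, c.arm)
        if key in seen:
            raise FormatError(f"{path}: duplicate interval for {key}")
        seen.add(key)
    return coords


def write_mature_coords(coords: Iterable[MatureCoordinateSidecar], path: str | Path) -> None:
    pd.DataFrame(
        [(c.precursor_id, c.arm, c.start, c.end) for c in coords],
        columns=["precursor_id", "arm", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


def write_gff3(rows: Iterable[dict], path: str | Path) -> None:
    """Write annotation rows as GFF3 (type miRNA / miRNA_primary_transcript).

    Each row: seqid, source, type, start, end (1-based inclusive), strand,
    attributes (dict).
    """
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            attrs = ";".join(f"{k}={v}" for k, v in r["attributes"].items())
            fh.write(
                "\t".join(
                    [
                        str(r["seqid"]),
                        r.get("source", "mirforge"),
                        r["type"],
                        str(r["start"]),
                        str(r["end"]),
                        ".",
                        r.get("strand", "+"),
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
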