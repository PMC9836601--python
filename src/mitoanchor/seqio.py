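"""Sequence and annotation I/O over the IUPAC nucleotide alphabet.

Internal coordinates are 0-based half-open; every file boundary (FASTA
headers aside, annotation TSV and GenBank 5-column feature tables) is
1-based inclusive. Lowercase input is canonicalized to uppercase and U is
mapped to T on the way in.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from .errors import ParseError, ValidationError

#: IUPAC code -> set of bases it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: set of bases -> IUPAC code (inverse of IUPAC_SETS).
SETS_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMPLEMENT_TABLE = str.maketrans(_COMPLEMENT)

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "D-loop")


def code_for_bases(bases: Iterable[str]) -> str:
    """Return the IUPAC symbol denoting exactly this set of bases."""
    key = frozenset(bases)
    try:
        return SETS_TO_CODE[key]
    except KeyError:
        raise ValidationError(f"no IUPAC code for base set {sorted(key)}") from None


def canonicalize(residues: str, *, context: str = "sequence") -> str:
    """Uppercase, map U->T, and validate against the IUPAC alphabet.

    Raises ValidationError naming the 1-based position of the first
    illegal character.
    """
    s = residues.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in IUPAC_ALPHABET:
            raise ValidationError(
                f"illegal character {ch!r} at position {i + 1} in {context}"
            )
    return s


def reverse_complement(residues: str) -> str:
    """Reverse-complement an IUPAC string (ambiguity codes map to the
    code of the complemented base set; involution)."""
    s = canonicalize(residues, context="reverse_complement input")
    return s.translate(_COMPLEMENT_TABLE)[::-1]


@dataclass
class NamedSequence:
    """A named nucleotide sequence, optionally circular."""

    id: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.residues = canonicalize(self.residues, context=f"sequence {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def slice_circular(self, start: int, length: int) -> str:
        """Extract `length` residues starting at `start`, wrapping the
        origin when the sequence is circular."""
        n = len(self.residues)
        start %= n
        if not self.circular and start + length > n:
            raise ValidationError(
                f"slice [{start}, {start + length}) exceeds linear sequence {self.id!r}"
            )
        reps = (start + length + n - 1) // n
        return (self.residues * reps)[start:start + length]


@dataclass
class FeatureRecord:
    """A genome feature; internal coordinates 0-based half-open."""

    name: str
    ftype: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValidationError(
                f"unknown feature type {self.ftype!r} for {self.name!r} "
                f"(expected one of {FEATURE_TYPES})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"feature {self.name!r}: invalid interval [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Annotation:
    """Ordered feature list for one genome."""

    genome_id: str
    genome_length: int
    features: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.end > self.genome_length:
                raise ValidationError(
                    f"feature {f.name!r} interval [{f.start}, {f.end}) exceeds "
                    f"genome length {self.genome_length}"
                )
            if f.name in seen:
                raise ValidationError(f"duplicate feature name {f.name!r}")
            seen.add(f.name)

    def count_by_type(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.features:
            out[f.ftype] = out.get(f.ftype, 0) + 1
        return out


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[NamedSequence]:
    """Parse a multi-record FASTA file into NamedSequences.

    Errors on empty files, non-IUPAC residues (position reported) and
    sequence data before the first header (line reported).
    """
    path = Path(path)
    seqs: list[NamedSequence] = []
    cur_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if cur_id is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise ParseError(f"{path}: record {cur_id!r} has no sequence")
        seqs.append(NamedSequence(id=cur_id, residues=residues))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0] if line[1:].strip() else ""
                if not cur_id:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if cur_id is None:
                    raise ParseError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                chunks.append(line)
    flush()
    if not seqs:
        raise ParseError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Sequence[NamedSequence], path: str | Path, line_width: int = 70) -> None:
    """Write sequences as FASTA wrapped at `line_width` columns."""
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            r = seq.residues
            for i in range(0, len(r), line_width):
                fh.write(r[i:i + line_width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (plain-text, 4-line records; qualities are carried but unused)

def read_fastq(path: str | Path) -> list[NamedSequence]:
    """Read a plain (uncompressed) FASTQ file; qualities discarded."""
    path = Path(path)
    seqs: list[NamedSequence] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = [ln for ln in lines if ln]
    if len(body) % 4 != 0:
        raise ParseError(f"{path}: truncated FASTQ (line count not a multiple of 4)")
    for i in range(0, len(body), 4):
        head, seq, plus, _qual = body[i:i + 4]
        if not head.startswith("@"):
            raise ParseError(f"{path}: expected '@' header near record {i // 4 + 1}")
        if not plus.startswith("+"):
            raise ParseError(f"{path}: expected '+' separator near record {i // 4 + 1}")
        rid = head[1:].split()[0]
        seqs.append(NamedSequence(id=rid, residues=seq))
    return seqs


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "F") -> None:
    """Write (id, residues) pairs as FASTQ with a constant quality string.

    'F' is Phred+33 Q37; base qualities are unused downstream.
    """
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# Annotation TSV and GenBank 5-column feature table

def read_annotation(path: str | Path, genome_id: str | None = None,
                    genome_length: int | None = None) -> Annotation:
    """Read a feature TSV: columns name, type, start, end, strand
    (1-based inclusive coordinates; '#'-prefixed comment lines allowed).

    Two optional header directives set genome metadata:
        #genome_id=<id>
        #genome_length=<bp>
    Both may instead be given as arguments; genome_length defaults to the
    maximum feature end.
    """
    path = Path(path)
    features: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#genome_id=") and genome_id is None:
                    genome_id = line.split("=", 1)[1].strip()
                elif line.startswith("#genome_length=") and genome_length is None:
                    genome_length = int(line.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(
                    f"{path}: expected 5 tab-separated fields at line {lineno}, "
                    f"got {len(parts)}"
                )
            name, ftype, start_s, end_s, strand = (p.strip() for p in parts)
            if name.lower() == "name" and ftype.lower() == "type":
                continue  # header row
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}: non-integer coordinate at line {lineno}"
                ) from None
            features.append(
                FeatureRecord(name=name, ftype=ftype, start=start1 - 1, end=end1,
                              strand=strand)
            )
    if genome_length is None:
        genome_length = max((f.end for f in features), default=0)
    return Annotation(genome_id=genome_id or path.stem,
                      genome_length=genome_length, features=features)


def write_annotation(annotation: Annotation, path: str | Path) -> None:
    """Write an annotation back to the TSV dialect read_annotation accepts."""
    with open(path, "w") as fh:
        fh.write(f"#genome_id={annotation.genome_id}\n")
        fh.write(f"#genome_length={annotation.genome_length}\n")
        fh.write("name\ttype\tstart\tend\tstrand\n")
        for f in annotation.features:
            fh.write(f"{f.name}\t{f.ftype}\t{f.start + 1}\t{f.end}\t{f.strand}\n")


_TBL_KEYS = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "D-loop"}
_TBL_QUALIFIER = {"CDS": "gene", "tRNA": "product", "rRNA": "product",
                  "D-loop": "note"}


def write_feature_table(annotation: Annotation, path: str | Path | None = None) -> str:
    """Render the GenBank 5-column feature table (.tbl) dialect.

    Minus-strand features are emitted with start and end swapped, per the
    dialect. Returns the text; writes it to `path` when given.
    """
    buf = io.StringIO()
    buf.write(f">Feature {annotation.genome_id}\n")
    for f in annotation.features:
        lo, hi = f.start + 1, f.end  # 1-based inclusive
        if f.strand == "-":
            lo, hi = hi, lo
        buf.write(f"{lo}\t{hi}\t{_TBL_KEYS[f.ftype]}\n")
        buf.write(f"\t\t\t{_TBL_QUALIFIER[f.ftype]}\t{f.name}\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
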