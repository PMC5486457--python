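"""Reading and writing RepeatMasker ``.out`` annotations and FASTA libraries.

The ``.out`` dialect handled here is the classic tabular one: three header
lines followed by whitespace-delimited records, one per annotated repeat
copy.  Minus-strand hits are flagged ``C`` and carry their repeat
coordinates in ``(left) end begin`` order; both quirks are normalized on
input and restored on output so that parse -> write -> parse is the
identity on record lists.

Records are classified into a TE taxonomy (type and clade) through an
ordered rule table; the default table reflects the avian TE taxonomy used
throughout this package (CR1/R2/RTE LINEs, ERV1/ERV2/ERV3 LTR elements,
SINEs, DNA transposons, everything else unclassified).
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "RepeatRecord",
    "TaxonomyMap",
    "GenomeIndex",
    "RepeatMaskerParseError",
    "HighDivergenceWarning",
    "default_taxonomy",
    "parse_repeatmasker_out",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_fasta",
    "write_fasta",
]

TE_TYPES = ("SINE", "LINE", "LTR", "DNA", "Unclassified")
CLADES = ("CR1", "R2", "RTE", "OtherLINE", "ERV1", "ERV2", "ERV3", "OtherLTR")

#: Upper bound of the Jukes-Cantor domain in percent-divergence units.
JC_DOMAIN_MAX = 75.0

OUT_HEADER = (
    "   SW  perc perc perc  query     position in query           "
    "matching repeat         position in repeat\n"
    "score  div. del. ins.  sequence  begin  end        (left)    "
    "repeat   class/family  begin  end    (left)  ID\n"
    "\n"
)


class RepeatMaskerParseError(ValueError):
    """Raised for a malformed annotation line; the message names the line."""


class HighDivergenceWarning(UserWarning):
    """A record's divergence is at or beyond the Jukes-Cantor domain bound.

    Such records are kept (they still occupy genome sequence and count
    toward coverage) but are excluded from age estimation, whose correction
    formula is undefined at D >= 75%.
    """


@dataclass
class RepeatRecord:
    """One annotated TE copy on the genome.

    Coordinates are 1-based inclusive, as in the ``.out`` format itself.
    ``divergence_percent`` is the percent of mismatching sites between the
    copy and its family consensus (symbol D elsewhere in this package).
    ``linkage_id`` groups fragments that RepeatMasker considers pieces of
    a single insertion.
    """

    sw_score: int
    divergence_percent: float
    deletion_percent: float
    insertion_percent: float
    query_name: str
    query_begin: int
    query_end: int
    strand: str
    repeat_name: str
    repeat_class_family: str
    linkage_id: int
    query_left: int = 0
    repeat_begin: int = 1
    repeat_end: int = 1
    repeat_left: int = 0
    overlap_star: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.query_begin <= self.query_end):
            raise ValueError(
                f"require 1 <= query_begin <= query_end, got "
                f"[{self.query_begin}, {self.query_end}]"
            )
        if self.divergence_percent < 0:
            raise ValueError("divergence_percent must be >= 0")

    @property
    def length(self) -> int:
        """Span on the genome in bp (inclusive coordinates)."""
        return self.query_end - self.query_begin + 1

    @property
    def ageable(self) -> bool:
        """Whether the divergence lies inside the Jukes-Cantor domain."""
        return self.divergence_percent < JC_DOMAIN_MAX


def _fmt_pct(x: float) -> str:
    """Format a percent field without losing sub-decimal precision."""
    s = f"{x:.2f}"
    return s


def _parse_out_line(line: str, lineno: int) -> RepeatRecord:
    fields = line.split()
    star = False
    if fields and fields[-1] == "*":
        star = True
        fields = fields[:-1]
    if len(fields) != 15:
        raise RepeatMaskerParseError(
            f"line {lineno}: expected 15 fields (+ optional '*'), "
            f"got {len(fields)}: {line.rstrip()!r}"
        )
    try:
        score = int(fields[0])
        div, dele, ins = (float(f) for f in fields[1:4])
        qname = fields[4]
        qbeg, qend = int(fields[5]), int(fields[6])
        qleft = int(fields[7].strip("()"))
        strand_raw = fields[8]
        rname, rclass = fields[9], fields[10]
        p1, p2, p3 = fields[11], fields[12], fields[13]
        linkage = int(fields[14])
    except ValueError as exc:
        raise RepeatMaskerParseError(f"line {lineno}: {exc}") from None
    if strand_raw == "+":
        strand = "+"
        rbeg, rend, rleft = int(p1), int(p2), int(p3.strip("()"))
    elif strand_raw == "C":
        strand = "-"
        rleft, rend, rbeg = int(p1.strip("()")), int(p2), int(p3)
    else:
        raise RepeatMaskerParseError(
            f"line {lineno}: strand must be '+' or 'C', got {strand_raw!r}"
        )
    rec = RepeatRecord(
        sw_score=score,
        divergence_percent=div,
        deletion_percent=dele,
        insertion_percent=ins,
        query_name=qname,
        query_begin=qbeg,
        query_end=qend,
        strand=strand,
        repeat_name=rname,
        repeat_class_family=rclass,
        linkage_id=linkage,
        query_left=qleft,
        repeat_begin=rbeg,
        repeat_end=rend,
        repeat_left=rleft,
        overlap_star=star,
    )
    if rec.divergence_percent >= JC_DOMAIN_MAX:
        warnings.warn(
            f"line {lineno}: divergence {rec.divergence_percent}% is outside "
            f"the Jukes-Cantor domain [0, {JC_DOMAIN_MAX}); the record is "
            "kept for coverage but will be excluded from age estimation",
            HighDivergenceWarning,
            stacklevel=3,
        )
    return rec


def parse_repeatmasker_out(stream: Union[IO[str], Iterable[str]]) -> list[RepeatRecord]:
    """Parse a RepeatMasker ``.out`` stream into :class:`RepeatRecord` s.

    The first three lines are treated as the standard header block when
    they are not record-shaped.  Order is preserved.  A malformed record
    raises :class:`RepeatMaskerParseError` naming the offending line.
    """
    records: list[RepeatRecord] = []
    for lineno, line in enumerate(stream, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        first = stripped.split(None, 1)[0]
        if lineno <= 3 and not first.lstrip("-").isdigit():
            continue  # header block
        records.append(_parse_out_line(stripped, lineno))
    return records


def read_repeatmasker_out(path: Union[str, Path]) -> list[RepeatRecord]:
    with open(path) as fh:
        return parse_repeatmasker_out(fh)


def format_record(rec: RepeatRecord) -> str:
    if rec.strand == "+":
        strand = "+"
        rpos = (str(rec.repeat_begin), str(rec.repeat_end), f"({rec.repeat_left})")
    else:
        strand = "C"
        rpos = (f"({rec.repeat_left})", str(rec.repeat_end), str(rec.repeat_begin))
    fields = [
        f"{rec.sw_score:>5d}",
        f"{_fmt_pct(rec.divergence_percent):>6s}",
        f"{_fmt_pct(rec.deletion_percent):>5s}",
        f"{_fmt_pct(rec.insertion_percent):>5s}",
        f"{rec.query_name:<10s}",
        f"{rec.query_begin:>8d}",
        f"{rec.query_end:>8d}",
        f"({rec.query_left})",
        strand,
        f"{rec.repeat_name:<15s}",
        f"{rec.repeat_class_family:<16s}",
        *rpos,
        str(rec.linkage_id),
    ]
    if rec.overlap_star:
        fields.append("*")
    return " ".join(fields)


def write_repeatmasker_out(
    records: Iterable[RepeatRecord], stream: IO[str], header: bool = True
) -> None:
    """Write records in the ``.out`` dialect; inverse of the parser."""
    if header:
        stream.write(OUT_HEADER)
    for rec in records:
        stream.write(format_record(rec) + "\n")


# ---------------------------------------------------------------------------
# Taxonomy


@dataclass(frozen=True)
class TaxonomyRule:
    """One ordered classification rule.

    ``class_pattern`` and ``name_pattern`` are shell-style globs matched
    case-insensitively against ``repeat_class_family`` and ``repeat_name``.
    """

    class_pattern: str
    name_pattern: str
    te_type: str
    clade: str | None

    def matches(self, record: RepeatRecord) -> bool:
        return fnmatch.fnmatch(
            record.repeat_class_family.lower(), self.class_pattern.lower()
        ) and fnmatch.fnmatch(record.repeat_name.lower(), self.name_pattern.lower())


@dataclass
class TaxonomyMap:
    """Ordered rule table mapping repeat labels to (te_type, clade).

    ``classify`` is total: the first matching rule wins and anything left
    unmatched falls through to ``("Unclassified", None)``.
    """

    rules: list[TaxonomyRule] = field(default_factory=list)

    def classify(self, record: RepeatRecord) -> tuple[str, str | None]:
        for rule in self.rules:
            if rule.matches(record):
                return rule.te_type, rule.clade
        return "Unclassified", None

    @classmethod
    def from_tsv(cls, stream: Union[IO[str], Iterable[str]]) -> "TaxonomyMap":
        rules = []
        for line in stream:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(
                    "taxonomy rows need 4 tab-separated columns "
                    f"(class_pattern, name_pattern, te_type, clade): {line!r}"
                )
            cpat, npat, te_type, clade = (p.strip() for p in parts)
            if te_type not in TE_TYPES:
                raise ValueError(f"unknown te_type {te_type!r}")
            clade_val = None if clade in ("None", "-", "") else clade
            if clade_val is not None and clade_val not in CLADES:
                raise ValueError(f"unknown clade {clade!r}")
            rules.append(TaxonomyRule(cpat, npat, te_type, clade_val))
        return cls(rules)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "TaxonomyMap":
        with open(path) as fh:
            return cls.from_tsv(fh)


def default_taxonomy() -> TaxonomyMap:
    """The avian TE taxonomy shipped with the package."""
    text = resources.files("telandscape.data").joinpath("taxonomy.tsv").read_text()
    return TaxonomyMap.from_tsv(text.splitlines())


def classify(record: RepeatRecord, taxonomy: TaxonomyMap) -> tuple[str, str | None]:
    """Classify one record; convenience wrapper for ``taxonomy.classify``."""
    return taxonomy.classify(record)


# ---------------------------------------------------------------------------
# Genome index


@dataclass
class GenomeIndex:
    """Sequence name -> length map; denominator of coverage percentages."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"sequence {name!r} has non-positive length")

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def __getitem__(self, name: str) -> int:
        return self.lengths[name]

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    @classmethod
    def from_tsv(cls, stream: Union[IO[str], Iterable[str]]) -> "GenomeIndex":
        lengths: dict[str, int] = {}
        for line in stream:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            lengths[name] = int(length)
        return cls(lengths)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "GenomeIndex":
        with open(path) as fh:
            return cls.from_tsv(fh)

    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "GenomeIndex":
        return cls({name: len(seq) for name, seq in sequences.items()})

    def to_tsv(self, stream: IO[str]) -> None:
        for name, length in self.lengths.items():
            stream.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source: Union[str, Path, IO[str]]) -> dict[str, str]:
    """Read a FASTA file into an identifier -> sequence dict.

    Sequences are upper-cased on input.  Duplicate identifiers are an
    error: a repeat library must name each family once.
    """
    library: dict[str, str] = {}
    for record in SeqIO.parse(source, "fasta"):
        if record.id in library:
            raise ValueError(f"duplicate FASTA identifier {record.id!r}")
        library[record.id] = str(record.seq).upper()
    return library


def write_fasta(
    library: dict[str, str], dest: Union[str, Path, IO[str]], width: int = 60
) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in library.items()
    ]
    SeqIO.write(records, dest, "fasta")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
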