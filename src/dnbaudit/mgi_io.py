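"""Reading, writing and naming of MGI/DNBSEQ-style FASTQ records.

MGI read names are transparent: they encode the flow-cell lane, the camera
field of view (FOV, the ``CxxRxx`` token) and an ordinal read identifier
that reflects the physical position of the DNA nanoball within the FOV.
Nearby nanoballs receive nearby ordinals, which is what makes optical
(signal-splitting) duplicates recognisable from the FASTQ alone.

The name grammar — token order ``<run>L<lane>C<col>R<row><ordinal>[/<mate>]``
with fixed digit widths — is configurable so archives with other widths
parse too.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Tuple, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import (
    FovMismatchError,
    ForeignHeaderError,
    MgiNameError,
    PairSyncError,
    TruncationError,
)

__all__ = [
    "NameGrammar",
    "CANONICAL_GRAMMAR",
    "MgiReadName",
    "ReadRecord",
    "ReadPair",
    "parse_read_name",
    "id_difference",
    "stream_pairs",
    "read_fastq",
    "write_fastq",
    "write_fastq_pairs",
]

# Loose probe for any FOV token; used only to distinguish "malformed MGI
# name" from "not an MGI name at all" (e.g. Illumina/SRA headers).
_FOV_PROBE = re.compile(r"C\d+R\d+")


@dataclass(frozen=True)
class NameGrammar:
    """Digit widths of the canonical MGI name layout.

    ``ordinal_digits=None`` consumes all remaining digits (real archives
    vary); the parsed width is retained on the name so formatting
    round-trips exactly.
    """

    lane_digits: int = 1
    col_digits: int = 3
    row_digits: int = 3
    ordinal_digits: Optional[int] = 7

    def regex(self) -> re.Pattern:
        ordinal = (
            rf"(?P<ordinal>\d{{{self.ordinal_digits}}})"
            if self.ordinal_digits is not None
            else r"(?P<ordinal>\d+)"
        )
        return re.compile(
            rf"^(?P<run>\S*?)"
            rf"L(?P<lane>\d{{{self.lane_digits}}})"
            rf"C(?P<col>\d{{{self.col_digits}}})"
            rf"R(?P<row>\d{{{self.row_digits}}})"
            + ordinal
            + r"(?:/(?P<mate>[12]))?$"
        )


CANONICAL_GRAMMAR = NameGrammar()


@dataclass(frozen=True, order=False)
class MgiReadName:
    """Structured MGI read identifier.

    ``(lane, fov_col, fov_row)`` jointly form the FOV key; the ordinal is
    unique — and comparable — only within one FOV. Digit widths are stored
    so that formatting reproduces the original string byte for byte.
    """

    run_token: str
    lane: int
    fov_col: int
    fov_row: int
    ordinal: int
    mate: Optional[int] = None
    lane_width: int = 1
    col_width: int = 3
    row_width: int = 3
    ordinal_width: int = 7

    def __post_init__(self) -> None:
        if self.lane < 1 or self.fov_col < 1 or self.fov_row < 1:
            raise MgiNameError(f"lane/col/row must be >= 1 in {self!r}")
        if self.ordinal < 0:
            raise MgiNameError(f"ordinal must be non-negative in {self!r}")
        if self.mate not in (None, 1, 2):
            raise MgiNameError(f"mate must be 1, 2 or None in {self!r}")

    @property
    def fov_key(self) -> Tuple[int, int, int]:
        return (self.lane, self.fov_col, self.fov_row)

    @property
    def stem(self) -> str:
        """The name without the mate suffix (shared by both mates)."""
        return self.format(with_mate=False)

    def format(self, with_mate: bool = True) -> str:
        s = (
            f"{self.run_token}"
            f"L{self.lane:0{self.lane_width}d}"
            f"C{self.fov_col:0{self.col_width}d}"
            f"R{self.fov_row:0{self.row_width}d}"
            f"{self.ordinal:0{self.ordinal_width}d}"
        )
        if with_mate and self.mate is not None:
            s += f"/{self.mate}"
        return s

    def with_mate(self, mate: Optional[int]) -> "MgiReadName":
        return replace(self, mate=mate)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


def parse_read_name(header: str, grammar: NameGrammar = CANONICAL_GRAMMAR) -> MgiReadName:
    """Parse a raw FASTQ header into an :class:`MgiReadName`.

    The leading ``@`` and any post-whitespace description are stripped.
    Headers without any ``CxxRxx`` token raise :class:`ForeignHeaderError`
    (distinct from a malformed-but-MGI-looking name).
    """
    if not header or not header.strip():
        raise MgiNameError("empty read header")
    token = header.strip().lstrip("@").split()[0]
    m = grammar.regex().match(token)
    if m is None:
        if _FOV_PROBE.search(token) is None:
            raise ForeignHeaderError(
                f"no CxxRxx field-of-view token in header {token!r} "
                "(not an MGI-style read name)"
            )
        probe = _FOV_PROBE.search(token)
        raise MgiNameError(
            f"header {token!r} does not match the name grammar: "
            f"first unmatched token near {token[probe.start():]!r}"
        )
    mate = m.group("mate")
    return MgiReadName(
        run_token=m.group("run"),
        lane=int(m.group("lane")),
        fov_col=int(m.group("col")),
        fov_row=int(m.group("row")),
        ordinal=int(m.group("ordinal")),
        mate=int(mate) if mate else None,
        lane_width=len(m.group("lane")),
        col_width=len(m.group("col")),
        row_width=len(m.group("row")),
        ordinal_width=len(m.group("ordinal")),
    )


def id_difference(a: MgiReadName, b: MgiReadName) -> int:
    """Absolute ordinal difference between two reads of the same FOV.

    Ordinal arithmetic is meaningless across FOVs (each FOV numbers its
    nanoballs independently), so differing FOV keys raise
    :class:`FovMismatchError`.
    """
    if a.fov_key != b.fov_key:
        raise FovMismatchError(
            f"id difference undefined across FOVs {a.fov_key} vs {b.fov_key}"
        )
    return abs(a.ordinal - b.ordinal)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """One FASTQ record with a parsed MGI name."""

    name: MgiReadName
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise MgiNameError(f"empty sequence for read {self.name}")
        if len(self.sequence) != len(self.quality):
            raise MgiNameError(
                f"sequence/quality length mismatch for read {self.name}: "
                f"{len(self.sequence)} vs {len(self.quality)}"
            )


@dataclass(frozen=True)
class ReadPair:
    """A forward/reverse mate pair sharing one name stem."""

    forward: ReadRecord
    reverse: ReadRecord

    def __post_init__(self) -> None:
        f, r = self.forward.name, self.reverse.name
        if f.stem != r.stem:
            raise PairSyncError(f"mate name stems differ: {f.stem} vs {r.stem}")
        if (f.mate, r.mate) not in ((1, 2), (None, None)):
            if f.mate == r.mate:
                raise PairSyncError(f"mates do not differ for {f.stem}")

    @property
    def name(self) -> MgiReadName:
        return self.forward.name


PathLike = Union[str, Path]


def _open_text(path: PathLike) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(
    path: PathLike, grammar: NameGrammar = CANONICAL_GRAMMAR
) -> Iterator[ReadRecord]:
    """Stream parsed records from a (possibly gzipped) FASTQ file."""
    with _open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield ReadRecord(parse_read_name(title, grammar), seq, qual)


def stream_pairs(
    path_forward: PathLike,
    path_reverse: PathLike,
    grammar: NameGrammar = CANONICAL_GRAMMAR,
) -> Iterator[ReadPair]:
    """Lazily pair two order-matched FASTQ files.

    Raises :class:`PairSyncError` on the first stem mismatch (reporting the
    0-based record index) and :class:`TruncationError` if one file runs out
    before the other.
    """
    _SENTINEL = object()
    with _open_text(path_forward) as hf, _open_text(path_reverse) as hr:
        it_f = FastqGeneralIterator(hf)
        it_r = FastqGeneralIterator(hr)
        index = 0
        while True:
            rec_f = next(it_f, _SENTINEL)
            rec_r = next(it_r, _SENTINEL)
            if rec_f is _SENTINEL and rec_r is _SENTINEL:
                return
            if rec_f is _SENTINEL or rec_r is _SENTINEL:
                raise TruncationError(
                    f"unequal record counts: one mate file ended at record index {index}"
                )
            name_f = parse_read_name(rec_f[0], grammar)
            name_r = parse_read_name(rec_r[0], grammar)
            if name_f.stem != name_r.stem:
                raise PairSyncError(
                    f"mate name stems differ at record index {index}: "
                    f"{name_f.stem} vs {name_r.stem}"
                )
            yield ReadPair(
                ReadRecord(name_f, rec_f[1], rec_f[2]),
                ReadRecord(name_r, rec_r[1], rec_r[2]),
            )
            index += 1


def write_fastq(records: Iterable[ReadRecord], path: PathLike) -> int:
    """Write records as plain 4-line FASTQ (gzipped if path ends in .gz)."""
    n = 0
    path = Path(path)
    handle = gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "wt")
    with handle:
        for rec in records:
            handle.write(f"@{rec.name.format()}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n


def write_fastq_pairs(
    pairs: Iterable[ReadPair], path_forward: PathLike, path_reverse: PathLike
) -> int:
    """Write the two mates of each pair to their respective FASTQ files."""
    pairs = list(pairs)
    write_fastq((p.forward for p in pairs), path_forward)
    write_fastq((p.reverse for p in pairs), path_reverse)
    return len(pairs)
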