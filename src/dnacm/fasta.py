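"""Layout-preserving FASTA reading and writing.

The compressor's round-trip contract is byte-exact *file* identity, not
just sequence identity, so the reader records everything writers normally
discard: header text verbatim, the width of every sequence line (run-length
encoded in practice), the newline convention and whether the file ends
with a newline.  ``write_fasta(read_fasta(path))`` reproduces the input
byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["SequenceRecord", "FastaError", "read_fasta", "write_fasta",
           "records_to_bytes", "records_from_bytes"]


class FastaError(ValueError):
    """Malformed FASTA input; message carries the offending line number."""


@dataclass
class SequenceRecord:
    """One FASTA record plus the layout needed to reproduce it exactly.

    ``header`` is the text after ``>``; ``line_lengths`` the widths of the
    sequence lines in order; ``newline`` the line terminator;
    ``no_final_newline`` marks a record whose last line (necessarily the
    file's last) has no terminator.
    """

    header: str
    sequence: str
    line_lengths: list[int] = field(default_factory=list)
    newline: str = "\n"
    no_final_newline: bool = False

    def __post_init__(self) -> None:
        if not self.line_lengths and self.sequence:
            # default layout: 60-column lines
            n = len(self.sequence)
            self.line_lengths = [60] * (n // 60) + ([n % 60] if n % 60 else [])
        if sum(self.line_lengths) != len(self.sequence):
            raise ValueError("line_lengths do not sum to the sequence length")

    @property
    def crc(self) -> int:
        return zlib.crc32(self.sequence.encode("latin-1"))


def records_from_bytes(data: bytes) -> list[SequenceRecord]:
    """Parse FASTA from raw bytes (see :func:`read_fasta`)."""
    text = data.decode("latin-1")
    if not text:
        raise FastaError("line 1: empty file")
    newline = "\r\n" if "\r\n" in text.partition("\n")[0] + "\n" else "\n"
    ends_with_newline = text.endswith(newline)
    # reject mixed conventions up front: normalizing and re-joining must be
    # the identity
    lines = text.split(newline)
    if ends_with_newline:
        lines = lines[:-1]
    for i, ln in enumerate(lines, 1):
        if "\r" in ln or "\n" in ln:
            raise FastaError(f"line {i}: inconsistent line endings")
    records: list[SequenceRecord] = []
    header: str | None = None
    seq_parts: list[str] = []
    widths: list[int] = []

    def _emit(last: bool) -> None:
        if header is None:
            return
        records.append(
            SequenceRecord(
                header=header,
                sequence="".join(seq_parts),
                line_lengths=list(widths),
                newline=newline,
                no_final_newline=last and not ends_with_newline,
            )
        )

    for i, ln in enumerate(lines, 1):
        if ln.startswith(">"):
            _emit(last=False)
            header = ln[1:]
            seq_parts = []
            widths = []
        elif header is None:
            raise FastaError(f"line {i}: expected '>' header, got {ln[:30]!r}")
        elif ln == "":
            raise FastaError(f"line {i}: blank line inside record")
        else:
            seq_parts.append(ln)
            widths.append(len(ln))
    _emit(last=True)
    if not records:
        raise FastaError("line 1: no FASTA records found")
    return records


def records_to_bytes(records: list[SequenceRecord]) -> bytes:
    out: list[str] = []
    for ri, rec in enumerate(records):
        nl = rec.newline
        out.append(">" + rec.header)
        if not (rec.no_final_newline and not rec.line_lengths
                and ri == len(records) - 1):
            out.append(nl)
        pos = 0
        for wi, w in enumerate(rec.line_lengths):
            out.append(rec.sequence[pos : pos + w])
            pos += w
            last_line = ri == len(records) - 1 and wi == len(rec.line_lengths) - 1
            if not (last_line and rec.no_final_newline):
                out.append(nl)
    return "".join(out).encode("latin-1")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly multi-record) FASTA file, keeping layout."""
    return records_from_bytes(Path(path).read_bytes())


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    """Write records byte-exactly as they were read."""
    Path(path).write_bytes(records_to_bytes(records))
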