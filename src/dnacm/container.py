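"""The compressed container format and the top-level compress/decompress
operations.

Layout of a container::

    magic b"DNACM\\x01" | uint32 header length | JSON header | blocks

The JSON header carries everything the decoder needs to rebuild an
identical model bank and token reader: mode, first-pass parameters (L and
W, or the reference window per record), the model-bank configuration
(orders, masks, table size), the mixer learning rate, verbatim FASTA
metadata (header text and line layout), per-record block sizes and CRCs,
and — in reference mode — the reference's name, length and CRC, verified
before decoding.  Blocks are, per record: the token side-band bits, then
the arithmetic payload.

Records are compressed independently (model state resets between records,
matching per-chromosome usage).  FASTA metadata is stored uncompressed:
the sequence payload dominates and byte-exact file round trip is the
contract.
"""

from __future__ import annotations

import json
import struct
import zlib
from dataclasses import dataclass

import numpy as np

from . import engine
from .fasta import SequenceRecord
from .mixer import DEFAULT_ETA
from .models import DEFAULT_MASKS, DEFAULT_ORDERS
from .noref import (
    MatchParams,
    Quadruplet,
    TokenStream,
    emc_decode,
    emc_encode,
    seq_to_codes,
)
from .refpass import (
    RefMatchToken,
    RefTokenStream,
    WindowRange,
    diff_percentage,
    rlz_decode,
    rlz_encode,
    select_window,
)

__all__ = ["Container", "ContainerError", "compress", "decompress", "report_bpb"]

MAGIC = b"DNACM\x01"


class ContainerError(ValueError):
    """Corrupt, unknown-version or mismatched-reference container."""


@dataclass
class Container:
    """Parsed compressed artifact: JSON header plus per-record blocks."""

    header: dict
    blocks: list[tuple[bytes, bytes]]  # (token bytes, payload bytes) per record

    def to_bytes(self) -> bytes:
        hjson = json.dumps(self.header, separators=(",", ":")).encode("utf-8")
        parts = [MAGIC, struct.pack("<I", len(hjson)), hjson]
        for tok, pay in self.blocks:
            parts.append(tok)
            parts.append(pay)
        return b"".join(parts)

    @classmethod
    def from_bytes(cls, data: bytes) -> "Container":
        if data[: len(MAGIC) - 1] != MAGIC[:-1]:
            raise ContainerError("not a dnacm container (bad magic)")
        if data[len(MAGIC) - 1] != MAGIC[-1]:
            raise ContainerError(
                f"unsupported container version {data[len(MAGIC) - 1]}"
            )
        off = len(MAGIC)
        (hlen,) = struct.unpack_from("<I", data, off)
        off += 4
        try:
            header = json.loads(data[off : off + hlen].decode("utf-8"))
        except ValueError as e:
            raise ContainerError(f"corrupt header: {e}") from None
        off += hlen
        blocks = []
        for rec in header["records"]:
            tok = data[off : off + rec["token_bytes"]]
            off += rec["token_bytes"]
            pay = data[off : off + rec["payload_bytes"]]
            off += rec["payload_bytes"]
            if len(pay) != rec["payload_bytes"]:
                raise ContainerError("truncated container")
            blocks.append((tok, pay))
        return cls(header=header, blocks=blocks)

    @property
    def size(self) -> int:
        return len(self.to_bytes())


def _rle(widths: list[int]) -> list[list[int]]:
    out: list[list[int]] = []
    for w in widths:
        if out and out[-1][0] == w:
            out[-1][1] += 1
        else:
            out.append([w, 1])
    return out


def _unrle(pairs: list[list[int]]) -> list[int]:
    out: list[int] = []
    for w, n in pairs:
        out.extend([w] * n)
    return out


def _items_to_arrays(items: list) -> tuple[np.ndarray, np.ndarray]:
    """Pass-1 items -> (kinds, codes) for the engine.  Base literals become
    bit-model items; the reserved exception byte 0 marks a repeat token;
    any other symbol is an exception byte."""
    n = len(items)
    kinds = np.zeros(n, dtype=np.uint8)
    codes = np.zeros(n, dtype=np.uint8)
    for i, it in enumerate(items):
        if isinstance(it, (Quadruplet, RefMatchToken)):
            kinds[i] = 1
            codes[i] = 0
        else:
            b = ord(it)
            if b == 0:
                raise ContainerError("NUL byte in sequence")
            c = int(seq_to_codes(it)[0])
            if c < 4:
                kinds[i] = 0
                codes[i] = c
            else:
                kinds[i] = 1
                codes[i] = b
    return kinds, codes


_CODE_CHAR = "TAGC"


def compress(
    records: list[SequenceRecord],
    mode: str = "noref",
    params: MatchParams | None = None,
    reference: SequenceRecord | str | None = None,
    window: WindowRange | None = None,
    eta: float = DEFAULT_ETA,
    table_bits: int = engine.DEFAULT_TABLE_BITS,
    orders=DEFAULT_ORDERS,
    masks=DEFAULT_MASKS,
) -> Container:
    """Compress FASTA records into a container.

    In ``ref`` mode a reference sequence is required; unless ``window`` is
    given, each record's search window follows the adaptive
    difference-percentage rule.
    """
    if mode not in ("noref", "ref"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or MatchParams()
    ref_seq = None
    ref_name = ""
    if mode == "ref":
        if reference is None:
            raise ValueError("ref mode requires a reference")
        if isinstance(reference, SequenceRecord):
            ref_seq = reference.sequence
            ref_name = reference.header.split()[0] if reference.header else ""
        else:
            ref_seq = str(reference)
        if not ref_seq:
            raise ValueError("empty reference")

    orders_a, moffs, mstart = engine.bank_arrays(orders, masks)
    header: dict = {
        "mode": mode,
        "L": params.L,
        "W": params.W,
        "eta": eta,
        "table_bits": table_bits,
        "orders": list(orders),
        "masks": list(masks),
        "records": [],
    }
    if mode == "ref":
        header["ref"] = {
            "name": ref_name,
            "length": len(ref_seq),
            "crc": zlib.crc32(ref_seq.encode("latin-1")),
        }
    blocks: list[tuple[bytes, bytes]] = []
    for rec in records:
        seq = rec.sequence
        rh: dict = {
            "header": rec.header,
            "lines": _rle(rec.line_lengths),
            "newline": rec.newline,
            "length": len(seq),
            "crc": rec.crc,
        }
        if rec.no_final_newline:
            rh["no_final_newline"] = True
        if mode == "noref":
            ts = emc_encode(seq, params)
            rh["n_quads"] = ts.n_quadruplets
        else:
            win = window
            if win is None:
                win = (
                    select_window(diff_percentage(seq, ref_seq))
                    if seq
                    else WindowRange()
                )
            ts = rlz_encode(seq, ref_seq, win, params)
            rh["window"] = [ts.window.left, ts.window.right]
            rh["n_quads"] = ts.n_tokens
        tok_bytes, tok_nbits = ts.serialize_tokens()
        kinds, codes = _items_to_arrays(ts.items)
        payload = bytes(
            engine.pass2_encode(kinds, codes, orders_a, moffs, mstart, table_bits, eta)
        )
        rh["n_items"] = len(ts.items)
        rh["token_nbits"] = tok_nbits
        rh["token_bytes"] = len(tok_bytes)
        rh["payload_bytes"] = len(payload)
        header["records"].append(rh)
        blocks.append((tok_bytes, payload))
    return Container(header=header, blocks=blocks)


def decompress(
    container: Container | bytes,
    reference: SequenceRecord | str | None = None,
) -> list[SequenceRecord]:
    """Invert :func:`compress`; byte-exact, checksum-verified."""
    if isinstance(container, (bytes, bytearray)):
        container = Container.from_bytes(bytes(container))
    h = container.header
    mode = h["mode"]
    params = MatchParams(L=h["L"], W=h["W"])
    ref_seq = None
    if mode == "ref":
        if reference is None:
            raise ContainerError(
                f"reference required: {h['ref']['name'] or '<unnamed>'} "
                f"({h['ref']['length']} bases)"
            )
        ref_seq = (
            reference.sequence
            if isinstance(reference, SequenceRecord)
            else str(reference)
        )
        if len(ref_seq) != h["ref"]["length"] or (
            zlib.crc32(ref_seq.encode("latin-1")) != h["ref"]["crc"]
        ):
            raise ContainerError(
                f"reference mismatch: container expects "
                f"{h['ref']['name'] or '<unnamed>'} of {h['ref']['length']} bases "
                f"(crc 0x{h['ref']['crc']:08x})"
            )
    orders_a, moffs, mstart = engine.bank_arrays(h["orders"], h["masks"])
    out: list[SequenceRecord] = []
    for rh, (tok_bytes, payload) in zip(h["records"], container.blocks):
        kinds, codes = engine.pass2_decode(
            np.frombuffer(payload, dtype=np.uint8),
            rh["n_items"],
            orders_a,
            moffs,
            mstart,
            h["table_bits"],
            h["eta"],
        )
        if mode == "noref":
            quads = TokenStream.deserialize_tokens(
                tok_bytes, rh["token_nbits"], rh["n_quads"], params
            )
        else:
            quads = RefTokenStream.deserialize_tokens(
                tok_bytes, rh["token_nbits"], rh["n_quads"]
            )
        qi = 0
        items: list = []
        for k, c in zip(kinds, codes):
            if k == 0:
                items.append(_CODE_CHAR[c])
            elif c == 0:
                items.append(quads[qi])
                qi += 1
            else:
                items.append(chr(c))
        if qi != len(quads):
            raise ContainerError("token count mismatch")
        if mode == "noref":
            seq = emc_decode(TokenStream(items=items, params=params))
        else:
            seq = rlz_decode(RefTokenStream(items=items, params=params), ref_seq)
        if len(seq) != rh["length"] or zlib.crc32(seq.encode("latin-1")) != rh["crc"]:
            raise ContainerError(f"checksum mismatch in record {rh['header']!r}")
        out.append(
            SequenceRecord(
                header=rh["header"],
                sequence=seq,
                line_lengths=_unrle(rh["lines"]),
                newline=rh["newline"],
                no_final_newline=rh.get("no_final_newline", False),
            )
        )
    return out


def report_bpb(container: Container | bytes, n_bases: int | None = None) -> float:
    """Bits per base: 8 × container bytes ÷ base count (the headline
    compression metric)."""
    if isinstance(container, (bytes, bytearray)):
        size = len(container)
        if n_bases is None:
            n_bases = sum(
                r["length"] for r in Container.from_bytes(bytes(container)).header["records"]
            )
    else:
        size = container.size
        if n_bases is None:
            n_bases = sum(r["length"] for r in container.header["records"])
    if n_bases <= 0:
        raise ValueError("bits per base undefined for zero bases")
    return 8.0 * size / n_bases
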