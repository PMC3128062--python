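"""Lossless bitstream container around the range-coded model output.

Layout (all integers little-endian):

    magic   4s   b"DFCM"
    version u16  (currently 1)
    config  u32 length + UTF-8 JSON of CompetitionConfig
    nrec    u32
    per record:
        id       u16 length + UTF-8
        nsym     u64   number of retained (coded) bases
        payload  u64 length + range-coded bytes
        pay_crc  u32   CRC32 of the payload bytes
        sym_crc  u32   CRC32 of the 2-bit code bytes (decode check)

Per block the winning depth index is coded first (adaptive side model),
then the block's symbols under the winning model's count-derived integer
frequencies; every model updates its counters after every symbol, so the
decoder replays the exact adaptive state of the encoder.
"""

from __future__ import annotations

import json
import struct
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from dnafcm import _kernels
from dnafcm.competition import CompetitionConfig, RunResult, _Engine, run_multi, run_records
from dnafcm.seqio import FilteredSequence

MAGIC = b"DFCM"
VERSION = 1


class CodecError(ValueError):
    """Container/bitstream corruption or format mismatch."""


@dataclass
class EncodedRecord:
    record_id: str
    n_symbols: int
    payload: bytes
    block_digests: np.ndarray  # per-block model-state digests (test hook)

    @property
    def payload_bits(self) -> int:
        return 8 * len(self.payload)


@dataclass
class BitstreamContainer:
    config: CompetitionConfig
    records: list[EncodedRecord]

    @property
    def payload_bits(self) -> int:
        return sum(r.payload_bits for r in self.records)

    def to_bytes(self) -> bytes:
        out = bytearray()
        out += MAGIC
        out += struct.pack("<H", VERSION)
        cfg_json = json.dumps(self.config.to_dict()).encode()
        out += struct.pack("<I", len(cfg_json)) + cfg_json
        out += struct.pack("<I", len(self.records))
        for rec in self.records:
            rid = rec.record_id.encode()
            out += struct.pack("<H", len(rid)) + rid
            out += struct.pack("<Q", rec.n_symbols)
            out += struct.pack("<Q", len(rec.payload)) + rec.payload
            out += struct.pack("<I", zlib.crc32(rec.payload))
            out += struct.pack("<I", 0)  # sym_crc placeholder, patched below
        return bytes(out)


class _Reader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise CodecError("truncated container")
        chunk = self.data[self.pos : self.pos + n]
        self.pos += n
        return chunk

    def unpack(self, fmt: str):
        return struct.unpack(fmt, self.take(struct.calcsize(fmt)))


def _encode_one(engine_cfg: CompetitionConfig, seq: FilteredSequence, chosen: np.ndarray):
    """Range-encode one record from a fresh model bank."""
    from dnafcm.competition import _kernel_args

    cfg = engine_cfg
    alphas = [cfg.alpha_for(d) for d in cfg.depths]
    b = _kernel_args(cfg, cfg.depths, alphas)
    payload, _, digests = _kernels.encode_payload(
        np.ascontiguousarray(seq.codes, dtype=np.int8),
        np.ascontiguousarray(chosen, dtype=np.int64),
        b["ks"],
        b["a_num"],
        b["a_den"],
        b["backend"],
        b["dense"],
        b["hmaps"],
        b["hrows"],
        b["hlens"],
        cfg.use_ir,
        cfg.block_size,
        np.int64(cfg.side_alpha.numerator),
        np.int64(cfg.side_alpha.denominator),
        b["side_counts"],
        np.int64(0),
    )
    return bytes(payload.tobytes()), digests


def encode(
    seq_or_seqs: Union[FilteredSequence, Sequence[FilteredSequence]],
    cfg: Optional[CompetitionConfig] = None,
) -> tuple[bytes, RunResult]:
    """Encode record(s) into a container; also returns the engine RunResult.

    The competition pass determines the per-block winning depths, then a
    second pass over fresh tables range-codes depth indices and symbols.
    """
    blob, result, _ = encode_with_digests(seq_or_seqs, cfg)
    return blob, result


def encode_with_digests(
    seq_or_seqs: Union[FilteredSequence, Sequence[FilteredSequence]],
    cfg: Optional[CompetitionConfig] = None,
):
    """Like :func:`encode` but also returns per-block model-state digests
    (one array per record) — the encoder half of the state-equality hook."""
    cfg = cfg or CompetitionConfig()
    if isinstance(seq_or_seqs, FilteredSequence):
        seqs = [seq_or_seqs]
    else:
        seqs = list(seq_or_seqs)
    if not cfg.reset_per_record and len(seqs) > 1:
        raise NotImplementedError("encoding with cross-record count sharing")
    result = run_records(seqs, cfg)
    container = BitstreamContainer(config=cfg, records=[])
    sym_crcs = []
    for seq, rec in zip(seqs, result.records):
        chosen = np.array([blk.chosen for blk in rec.blocks], dtype=np.int64)
        payload, digests = _encode_one(cfg, seq, chosen)
        container.records.append(
            EncodedRecord(
                record_id=seq.record_id,
                n_symbols=len(seq),
                payload=payload,
                block_digests=digests,
            )
        )
        sym_crcs.append(zlib.crc32(np.ascontiguousarray(seq.codes, dtype=np.int8).tobytes()))
    blob = bytearray(container.to_bytes())
    _patch_sym_crcs(blob, sym_crcs)
    return bytes(blob), result, [rec.block_digests for rec in container.records]


def _patch_sym_crcs(blob: bytearray, sym_crcs: list[int]) -> None:
    """Fill the sym_crc fields (walk the container once)."""
    rd = _Reader(bytes(blob))
    rd.take(4)
    rd.unpack("<H")
    (cfg_len,) = rd.unpack("<I")
    rd.take(cfg_len)
    (nrec,) = rd.unpack("<I")
    for i in range(nrec):
        (id_len,) = rd.unpack("<H")
        rd.take(id_len)
        rd.unpack("<Q")
        (pay_len,) = rd.unpack("<Q")
        rd.take(pay_len)
        rd.unpack("<I")
        struct.pack_into("<I", blob, rd.pos, sym_crcs[i])
        rd.unpack("<I")


def decode(data: bytes) -> tuple[CompetitionConfig, list[tuple[str, np.ndarray]]]:
    """Decode a container back to per-record 2-bit code arrays.

    Corruption (bad magic, truncation, CRC mismatch of payload or of the
    decoded symbols) raises :class:`CodecError` rather than returning
    garbage.
    """
    decoded, _ = decode_with_digests(data)
    return decoded


def decode_with_digests(data: bytes):
    from dnafcm.competition import _kernel_args

    rd = _Reader(data)
    if rd.take(4) != MAGIC:
        raise CodecError("bad magic; not a dnafcm container")
    (version,) = rd.unpack("<H")
    if version != VERSION:
        raise CodecError(f"unsupported container version {version}")
    (cfg_len,) = rd.unpack("<I")
    try:
        cfg = CompetitionConfig.from_dict(json.loads(rd.take(cfg_len).decode()))
    except (ValueError, KeyError, TypeError) as exc:
        raise CodecError(f"bad embedded config: {exc}") from exc
    (nrec,) = rd.unpack("<I")
    records: list[tuple[str, np.ndarray]] = []
    digests = []
    for _ in range(nrec):
        (id_len,) = rd.unpack("<H")
        rid = rd.take(id_len).decode()
        (nsym,) = rd.unpack("<Q")
        (pay_len,) = rd.unpack("<Q")
        payload = rd.take(pay_len)
        (pay_crc,) = rd.unpack("<I")
        (sym_crc,) = rd.unpack("<I")
        if zlib.crc32(payload) != pay_crc:
            raise CodecError(f"record {rid!r}: payload checksum mismatch")
        alphas = [cfg.alpha_for(d) for d in cfg.depths]
        b = _kernel_args(cfg, cfg.depths, alphas)
        codes, _, dig = _kernels.decode_payload(
            np.frombuffer(payload, dtype=np.uint8),
            np.int64(nsym),
            b["ks"],
            b["a_num"],
            b["a_den"],
            b["backend"],
            b["dense"],
            b["hmaps"],
            b["hrows"],
            b["hlens"],
            cfg.use_ir,
            cfg.block_size,
            np.int64(cfg.side_alpha.numerator),
            np.int64(cfg.side_alpha.denominator),
            b["side_counts"],
            np.int64(0),
        )
        if zlib.crc32(np.ascontiguousarray(codes).tobytes()) != sym_crc:
            raise CodecError(f"record {rid!r}: decoded symbols fail checksum")
        records.append((rid, codes))
        digests.append(dig)
    return (cfg, records), digests


def encode_to_file(
    path: Union[str, Path],
    seqs: Sequence[FilteredSequence],
    cfg: Optional[CompetitionConfig] = None,
) -> RunResult:
    """Encode to a file; partial output is removed on failure."""
    path = Path(path)
    try:
        blob, result = encode(seqs, cfg)
        with open(path, "wb") as fh:
            fh.write(blob)
    except BaseException:
        path.unlink(missing_ok=True)
        raise
    return result


def decode_from_file(path: Union[str, Path]):
    with open(path, "rb") as fh:
        return decode(fh.read())


def ideal_bits(seq: FilteredSequence, cfg: Optional[CompetitionConfig] = None) -> float:
    """Dry run: total ideal code length (symbol + side) without a bitstream."""
    res = run_multi(seq, cfg or CompetitionConfig())
    return res.symbol_bits + res.side_bits
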