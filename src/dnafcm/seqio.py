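"""FASTA I/O and 2-bit symbol coding.

Bases are mapped to integer codes A=0, C=1, G=2, T=3 so that the
Watson-Crick complement of code ``c`` is ``3 - c``.  Non-ACGT symbols
(N, IUPAC ambiguity codes, gaps) are dropped before modeling; their
1-based coordinates are preserved so profiles can be mapped back onto
the original sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

ALPHABET = "ACGT"

#: code -> complementary code (A<->T, C<->G)
COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)

# byte -> 2-bit code lookup, -1 for every non-ACGT byte; lowercase folds up
_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

_CHAR_ARR = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)


class FastaFormatError(ValueError):
    """Raised for empty or malformed FASTA input."""


@dataclass
class FilteredSequence:
    """A cleaned 2-bit coded sequence plus its original coordinates.

    ``positions[i]`` is the 1-based coordinate in the raw record of the
    base stored in ``codes[i]``; non-ACGT characters leave gaps in the
    coordinate list but are otherwise forgotten.
    """

    record_id: str
    codes: np.ndarray  # int8, values in {0,1,2,3}
    positions: np.ndarray  # int64, 1-based, strictly increasing
    original_length: int

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.codes.shape != self.positions.shape:
            raise ValueError("codes and positions must have equal length")
        if len(self.positions) and (
            self.positions[0] < 1
            or self.positions[-1] > self.original_length
            or np.any(np.diff(self.positions) <= 0)
        ):
            raise ValueError("positions must be strictly increasing within the record")

    def __len__(self) -> int:
        return len(self.codes)

    def to_string(self) -> str:
        """The retained bases as an ACGT string (coordinates dropped)."""
        return codes_to_string(self.codes)


def codes_to_string(codes: np.ndarray) -> str:
    codes = np.asarray(codes, dtype=np.int64)
    return _CHAR_ARR[codes].tobytes().decode("ascii")


def string_to_codes(seq: str) -> np.ndarray:
    """Strict ACGT-only mapping (raises on anything else)."""
    arr = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(arr < 0):
        raise ValueError("sequence contains non-ACGT characters")
    return arr.astype(np.int8)


def reverse_complement(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT[np.asarray(codes, dtype=np.int8)][::-1]


def read_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Read a (possibly multi-record) FASTA file.

    Returns ``(record_id, sequence_text)`` pairs in file order, with
    wrapped sequence lines concatenated and case preserved.  The record
    id is the header token up to the first whitespace.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    with open(path) as handle:
        first = handle.read(1)
        if first == "":
            raise FastaFormatError(f"{path}: empty file")
        if first != ">":
            raise FastaFormatError(f"{path}: does not start with a '>' header")
        handle.seek(0)
        try:
            for title, seq in SimpleFastaParser(handle):
                records.append((title.split()[0] if title else "", seq))
        except ValueError as exc:  # pragma: no cover - biopython message passthrough
            raise FastaFormatError(f"{path}: {exc}") from exc
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def filter_sequence(raw: str, record_id: str = "") -> FilteredSequence:
    """Map a raw sequence to 2-bit codes, dropping non-ACGT symbols.

    Lowercase (soft-masked) bases are folded to uppercase; everything
    that is not A/C/G/T after folding is removed while recording the
    surviving bases' original 1-based coordinates.
    """
    data = np.frombuffer(raw.encode("ascii", errors="replace"), dtype=np.uint8)
    mapped = _CODE_LUT[data]
    keep = mapped >= 0
    positions = np.nonzero(keep)[0].astype(np.int64) + 1
    return FilteredSequence(
        record_id=record_id,
        codes=mapped[keep],
        positions=positions,
        original_length=len(raw),
    )


def read_filtered(path: Union[str, Path]) -> list[FilteredSequence]:
    """``read_fasta`` + ``filter_sequence`` for every record."""
    return [filter_sequence(seq, rid) for rid, seq in read_fasta(path)]


def write_fasta(
    path: Union[str, Path],
    records: Iterable[tuple[str, str]],
    width: int = 70,
) -> None:
    with open(path, "w") as out:
        for rid, seq in records:
            out.write(f">{rid}\n")
            for i in range(0, max(len(seq), 1), width):
                chunk = seq[i : i + width]
                out.write(chunk + "\n")
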