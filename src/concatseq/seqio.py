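"""FASTQ input/output and elementary sequence operations.

Reads are held as :class:`PhredRead` objects: an identifier, a DNA string
over the IUPAC alphabet, and a numpy array of integer Phred scores (one per
base).  Only the Sanger/Illumina-1.8 encoding (Phred+33) is supported;
Phred+64 input is rejected rather than auto-detected, because a silent
misdetection would corrupt every downstream expected-error computation.

Files ending in ``.gz`` are read and written gzip-compressed transparently.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
MAX_PHRED = 93  # '~' in Phred+33

IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

#: base sets covered by each IUPAC nucleotide code
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


class FastqFormatError(ValueError):
    """Malformed FASTQ record (length mismatch, bad quality encoding, ...)."""


class PairingError(ValueError):
    """R1/R2 files disagree in record count or template identifiers."""


@dataclass(eq=False)
class PhredRead:
    """One sequencing read: identifier, bases and per-base Phred scores."""

    id: str
    bases: str
    quals: np.ndarray  # integer Phred scores, same length as bases

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != self.quals.size:
            raise FastqFormatError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{self.quals.size} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhredRead):
            return NotImplemented
        return (self.id == other.id and self.bases == other.bases
                and np.array_equal(self.quals, other.quals))

    @property
    def template_id(self) -> str:
        """Identifier with mate annotations stripped (trailing /1, /2, or a
        space-delimited comment field)."""
        token = self.id.split(None, 1)[0] if self.id else ""
        if token.endswith(("/1", "/2")):
            token = token[:-2]
        return token


@dataclass
class ReadPair:
    """A forward (R1) / reverse (R2) read pair from one template."""

    r1: PhredRead
    r2: PhredRead

    def __post_init__(self) -> None:
        if self.r1.template_id != self.r2.template_id:
            raise PairingError(
                f"mate identifiers differ: {self.r1.id!r} vs {self.r2.id!r}"
            )


def _open_text(path: str | Path, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def decode_quals(qual_string: str) -> np.ndarray:
    """Decode a Phred+33 quality string to integer scores."""
    arr = np.frombuffer(qual_string.encode("ascii"), dtype=np.uint8)
    if arr.size and (arr.min() < PHRED_OFFSET or arr.max() > PHRED_OFFSET + MAX_PHRED):
        raise FastqFormatError(
            "quality character outside '!'..'~' (is this Phred+64 input?)"
        )
    return (arr.astype(np.int16) - PHRED_OFFSET)


def encode_quals(quals: np.ndarray) -> str:
    arr = np.asarray(quals, dtype=np.int16)
    if arr.size and (arr.min() < 0 or arr.max() > MAX_PHRED):
        raise FastqFormatError("Phred score outside [0, 93]")
    return (arr + PHRED_OFFSET).astype(np.uint8).tobytes().decode("ascii")


def read_fastq(path: str | Path) -> Iterator[PhredRead]:
    """Stream :class:`PhredRead` records from a (possibly gzipped) FASTQ file."""
    with _open_text(path, "r") as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                yield PhredRead(id=title, bases=seq.upper(), quals=decode_quals(qual))
        except ValueError as exc:  # malformed record from the parser
            raise FastqFormatError(str(exc)) from exc


def read_fastq_pairs(path_r1: str | Path, path_r2: str | Path) -> Iterator[ReadPair]:
    """Stream read pairs from two parallel FASTQ files.

    Records are paired positionally; identifiers must refer to the same
    template after stripping mate annotations.  A record-count mismatch
    between the two files raises :class:`PairingError`.
    """
    it1, it2 = read_fastq(path_r1), read_fastq(path_r2)
    sentinel = object()
    n = 0
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            short = path_r2 if r2 is sentinel else path_r1
            raise PairingError(
                f"record count mismatch after {n} pairs: {short} ended first"
            )
        n += 1
        yield ReadPair(r1, r2)  # type: ignore[arg-type]


def write_fastq(reads: Iterable[PhredRead], path: str | Path,
                min_length: int = 1) -> int:
    """Write reads as 4-line Phred+33 FASTQ; returns the record count.

    Reads shorter than ``min_length`` (by default, zero-length reads left
    over from trimming) are dropped rather than written.
    """
    n = 0
    with _open_text(path, "w") as handle:
        for read in reads:
            if len(read) < min_length:
                continue
            handle.write(f"@{read.id}\n{read.bases}\n+\n{encode_quals(read.quals)}\n")
            n += 1
    return n


def reverse_complement(read: PhredRead) -> PhredRead:
    """Reverse-complement bases (IUPAC-aware) and reverse the quality scores."""
    invalid = set(read.bases.upper()) - IUPAC_ALPHABET
    if invalid:
        raise FastqFormatError(
            f"read {read.id!r}: non-IUPAC characters {sorted(invalid)}"
        )
    return PhredRead(
        id=read.id,
        bases=read.bases.translate(_COMPLEMENT)[::-1],
        quals=read.quals[::-1].copy(),
    )


def revcomp_seq(seq: str) -> str:
    """Reverse-complement a bare DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]
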