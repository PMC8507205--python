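"""Primer removal and the read-trimming regimes used ahead of joining.

Three 3' trimming regimes are supported:

* **none** - reads pass through untouched (primer removal only);
* **length** - every read of a library is cut at one fixed position,
  derived from the library's per-position median quality: the first
  position where the median Phred score drops below 20 (the retained
  length *includes* that first below-threshold base);
* **quality** - each read is cut individually at its 3' end using the
  partial-sum algorithm popularised by BWA and cutadapt: scanning from
  the 3' end, accumulate ``threshold - q`` and cut where the running sum
  is maximal and positive.

Primer removal is IUPAC-aware and tolerates mismatches and indels up to a
fraction of the primer length (default 0.10), counting both equally.
When both a 3' trim and primer removal are requested, the 3' trim is
applied first and primers are then removed from the 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import edlib
import numpy as np

from .seqio import IUPAC_SETS, MAX_PHRED, PhredRead, ReadPair

#: character pairs edlib should treat as equal (degenerate code vs. base)
IUPAC_EQUALITIES: list[tuple[str, str]] = [
    (code, base)
    for code, bases in IUPAC_SETS.items()
    for base in bases
    if code != base
]


@dataclass
class QualityProfile:
    """Per-position median Phred score of a read library.

    Positions are 0-based; ``median_q[p]`` is the median over all reads
    long enough to cover position ``p`` and ``n_reads_at_position[p]`` is
    how many reads that was.  Reads of unequal length are allowed, so the
    coverage count is non-increasing with position.
    """

    median_q: np.ndarray
    n_reads_at_position: np.ndarray

    @property
    def n_positions(self) -> int:
        return self.median_q.size


@dataclass
class TrimSpec:
    """Fixed per-mate retained lengths for length trimming (0 = keep all)."""

    r1_length: int = 0
    r2_length: int = 0

    def __post_init__(self) -> None:
        if self.r1_length < 0 or self.r2_length < 0:
            raise ValueError("trim lengths must be >= 0 (0 means keep all)")


class PrimerTrimResult(NamedTuple):
    pair: ReadPair
    r1_matched: bool
    r2_matched: bool


def _remove_primer(read: PhredRead, primer: str,
                   max_error_rate: float) -> tuple[PhredRead, bool]:
    if len(read) == 0:
        return read, False
    max_errors = int(max_error_rate * len(primer))
    result = edlib.align(primer, read.bases, mode="HW", task="locations",
                         k=max_errors, additionalEqualities=IUPAC_EQUALITIES)
    if result["editDistance"] < 0:
        return read, False
    # leftmost occurrence (removal proceeds from the 5' end); among
    # equally good alignments there, prefer the span closest to the
    # primer length (the no-indel interpretation), then the longer one
    locations = result["locations"]
    start = min(loc[0] for loc in locations)
    end = min((loc[1] for loc in locations if loc[0] == start),
              key=lambda e: (abs((e - start + 1) - len(primer)), -e)) + 1
    return PhredRead(read.id, read.bases[end:], read.quals[end:].copy()), True


def remove_primers(pair: ReadPair, fwd_primer: str, rev_primer: str,
                   max_error_rate: float = 0.10) -> PrimerTrimResult:
    """Remove the forward primer from R1 and the reverse primer from R2.

    The best occurrence of the primer (IUPAC-aware, at most
    ``max_error_rate * len(primer)`` mismatches plus indels) is located and
    the prefix through the match is removed from bases and qualities.  A
    read without a match is returned unchanged, with its flag unset.
    Reads emptied by removal stay in the stream as zero-length and are
    dropped by the minimum-length-1 rule at write/filter time.
    """
    if not fwd_primer or not rev_primer:
        raise ValueError("primer sequences must be non-empty")
    if not 0 <= max_error_rate < 0.5:
        raise ValueError("max_error_rate must be in [0, 0.5)")
    r1, hit1 = _remove_primer(pair.r1, fwd_primer.upper(), max_error_rate)
    r2, hit2 = _remove_primer(pair.r2, rev_primer.upper(), max_error_rate)
    return PrimerTrimResult(ReadPair(r1, r2), hit1, hit2)


def quality_profile(reads: Iterable[PhredRead]) -> QualityProfile:
    """Per-position median Phred score over a read stream.

    Even-count medians use the mean of the two middle values.  Raises
    ``ValueError`` on an empty stream.
    """
    hist: np.ndarray | None = None  # (position, phred) count matrix
    for read in reads:
        n = len(read)
        if hist is None or n > hist.shape[0]:
            grown = np.zeros((n, MAX_PHRED + 1), dtype=np.int64)
            if hist is not None:
                grown[: hist.shape[0]] = hist
            hist = grown
        if n:
            np.add.at(hist, (np.arange(n), read.quals), 1)
    if hist is None or hist.shape[0] == 0:
        raise ValueError("quality_profile requires at least one non-empty read")

    counts = hist.sum(axis=1)
    medians = np.empty(hist.shape[0], dtype=np.float64)
    for p in range(hist.shape[0]):
        n = counts[p]
        cum = np.cumsum(hist[p])
        lo = int(np.searchsorted(cum, (n - 1) // 2 + 1))
        hi = int(np.searchsorted(cum, n // 2 + 1))
        medians[p] = (lo + hi) / 2.0
    return QualityProfile(median_q=medians, n_reads_at_position=counts)


def length_trim_position(profile: QualityProfile, q_threshold: float = 20) -> int:
    """Retained length under the median-quality rule.

    Moving 5' to 3', the first position where the median Phred score falls
    below ``q_threshold`` is returned as a 1-based retained length (that
    first below-threshold base is included).  Returns 0 - meaning "keep
    all bases" - when the median never drops below the threshold.
    """
    below = np.nonzero(profile.median_q < q_threshold)[0]
    return int(below[0]) + 1 if below.size else 0


def trim_to_length(read: PhredRead, length: int) -> PhredRead:
    """Keep the first ``length`` bases (0 keeps the whole read)."""
    if length < 0:
        raise ValueError("trim length must be >= 0")
    if length == 0 or length >= len(read):
        return read
    return PhredRead(read.id, read.bases[:length], read.quals[:length].copy())


def quality_trim_3prime(read: PhredRead, q_threshold: int = 20) -> PhredRead:
    """3' quality trim by the partial-sum (BWA/cutadapt) algorithm.

    Scanning from the 3' end, the running sum of ``q_threshold - q`` is
    accumulated; the read is cut at the position where that sum is maximal
    and positive.  Among equally good cut points the longest retained
    prefix wins.  The result may be empty (later removed by the
    minimum-length rule).
    """
    if q_threshold < 0:
        raise ValueError("q_threshold must be >= 0")
    n = len(read)
    if n == 0:
        return read
    # vectorised suffix partial sums: s[i] = sum_{j>=i} (threshold - q_j)
    deltas = q_threshold - read.quals.astype(np.int64)
    suffix = np.cumsum(deltas[::-1])[::-1]
    best = suffix.max()
    if best <= 0:
        return read
    cut = int(np.nonzero(suffix == best)[0][-1])  # rightmost max: trim least
    return PhredRead(read.id, read.bases[:cut], read.quals[:cut].copy())


def truncate_at_quality(read: PhredRead, trunc_q: int = 2) -> PhredRead:
    """Truncate immediately before the first base with quality <= ``trunc_q``."""
    if trunc_q < 0:
        raise ValueError("trunc_q must be >= 0")
    low = np.nonzero(read.quals <= trunc_q)[0]
    if not low.size:
        return read
    cut = int(low[0])
    return PhredRead(read.id, read.bases[:cut], read.quals[:cut].copy())
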