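"""Paired-read preparation: overlap merging, concatenation, and both.

The four preparations of a read pair are:

* **merge** (``Mp``): assemble R1 with the reverse-complemented R2 via
  their overlapping 3' ends, requiring a minimum overlap (default 20 bp)
  and a minimum overlap identity (default 0.9); unmergeable pairs fail.
* **merge + concatenate** (``Bp``): merged output, with every pair that
  failed to merge appended as a concatenated read instead - no pair is
  lost.
* **concatenate all** (``Cs``): every pair is joined as
  ``R1 + revcomp(R2)`` with no overlap detection at all; if the reads do
  overlap, the overlap bases appear twice in the output.
* single-end pass-through (``R1``/``R2``), handled at the pipeline level.

Overlap detection is ungapped: all offsets aligning the 3' end of R1 with
the 5' end of the reverse-complemented R2 (including full containment)
are scored by ``matches - mismatches``, ties resolved toward the longest
overlap so error-free pairs always reconstruct the true amplicon.  In the
merged overlap the base with the higher quality wins; consensus quality
is ``min(q1 + q2, 93)`` at agreements and ``|q1 - q2|`` at disagreements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Optional

import numpy as np

from .seqio import MAX_PHRED, PhredRead, ReadPair, reverse_complement


@dataclass
class MergeParams:
    min_overlap: int = 20
    min_overlap_identity: float = 0.9
    max_assembled_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0 < self.min_overlap_identity <= 1:
            raise ValueError("min_overlap_identity must be in (0, 1]")


@dataclass(eq=False)
class JoinedRead(PhredRead):
    """A merged or concatenated sequence with provenance."""

    provenance: str = "merged"  # merged | concatenated | single_end
    overlap_length: int = 0


class OverlapHit(NamedTuple):
    offset: int      # start of r2rc within r1 coordinates
    length: int      # overlap length
    matches: int
    mismatches: int

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0


class MergeFailure(NamedTuple):
    pair: ReadPair
    reason: str  # no_overlap | low_identity | too_long


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan_offsets(a1: np.ndarray, a2: np.ndarray,
                  min_overlap: int) -> Optional[tuple[int, int, int, int]]:
    """Best ungapped offset by score = matches - mismatches.

    Offsets are tried in order of decreasing overlap; a candidate is kept
    only if it strictly beats the incumbent, so ties resolve to the
    longest overlap.  Scanning stops early once no remaining overlap could
    beat the incumbent score (score <= overlap length).
    """
    len1, len2 = a1.size, a2.size
    best: Optional[tuple[int, int, int, int]] = None  # score, ov, offset, matches
    for p in range(0, len1 - min_overlap + 1):
        ov = min(len1 - p, len2)
        if ov < min_overlap:
            break
        if best is not None and best[0] >= ov:
            break
        m = int((a1[p:p + ov] == a2[:ov]).sum())
        score = 2 * m - ov
        if best is None or score > best[0]:
            best = (score, ov, p, m)
    return best


def find_best_overlap(r1: PhredRead, r2rc: PhredRead,
                      params: MergeParams) -> Optional[OverlapHit]:
    """Best ungapped overlap of R1 with the reverse-complemented R2.

    Returns ``None`` when no offset reaches ``min_overlap`` or when the
    best-scoring offset's identity falls below ``min_overlap_identity``
    (failure is a value, not an exception).
    """
    best = _scan_offsets(_as_bytes(r1.bases), _as_bytes(r2rc.bases),
                         params.min_overlap)
    if best is None:
        return None
    _, ov, p, m = best
    hit = OverlapHit(offset=p, length=ov, matches=m, mismatches=ov - m)
    if hit.identity < params.min_overlap_identity:
        return None
    return hit


def merge_pair(pair: ReadPair,
               params: MergeParams | None = None) -> JoinedRead | MergeFailure:
    """Assemble a pair via its overlap, or return a :class:`MergeFailure`."""
    params = params or MergeParams()
    r1 = pair.r1
    r2rc = reverse_complement(pair.r2)
    best = _scan_offsets(_as_bytes(r1.bases), _as_bytes(r2rc.bases),
                         params.min_overlap)
    if best is None:
        return MergeFailure(pair, "no_overlap")
    _, ov, p, m = best
    if (m / ov) < params.min_overlap_identity:
        return MergeFailure(pair, "low_identity")

    a1, a2 = _as_bytes(r1.bases), _as_bytes(r2rc.bases)
    q1 = r1.quals[p:p + ov].astype(np.int64)
    q2 = r2rc.quals[:ov].astype(np.int64)
    b1, b2 = a1[p:p + ov], a2[:ov]
    agree = b1 == b2
    cons_b = np.where(agree | (q1 >= q2), b1, b2)  # higher quality wins; r1 on tie
    cons_q = np.where(agree, np.minimum(q1 + q2, MAX_PHRED), np.abs(q1 - q2))

    if p + a2.size >= a1.size:  # r2rc extends past (or to) the end of r1
        tail_b, tail_q = r2rc.bases[ov:], r2rc.quals[ov:]
    else:  # r2rc fully contained within r1
        tail_b, tail_q = r1.bases[p + ov:], r1.quals[p + ov:]

    bases = r1.bases[:p] + cons_b.tobytes().decode("ascii") + tail_b
    quals = np.concatenate([r1.quals[:p], cons_q, tail_q]).astype(np.int16)
    if params.max_assembled_length is not None and len(bases) > params.max_assembled_length:
        return MergeFailure(pair, "too_long")
    return JoinedRead(id=r1.id, bases=bases, quals=quals,
                      provenance="merged", overlap_length=ov)


def concatenate_pair(pair: ReadPair) -> JoinedRead:
    """Join ``R1 + revcomp(R2)`` directly: no overlap detection, no loss.

    If the reads overlap, the overlap bases are duplicated in the output;
    if they do not, the output simply misses the unsequenced middle.
    """
    r2rc = reverse_complement(pair.r2)
    return JoinedRead(
        id=pair.r1.id,
        bases=pair.r1.bases + r2rc.bases,
        quals=np.concatenate([pair.r1.quals, r2rc.quals]).astype(np.int16),
        provenance="concatenated",
        overlap_length=0,
    )


def merge_and_concatenate(pairs: Iterable[ReadPair],
                          params: MergeParams | None = None) -> Iterator[JoinedRead]:
    """The ``Bp`` preparation: merge where possible, concatenate the rest.

    Every input pair yields exactly one output read; provenance on each
    :class:`JoinedRead` says which route it took.
    """
    params = params or MergeParams()
    for pair in pairs:
        result = merge_pair(pair, params)
        if isinstance(result, MergeFailure):
            yield concatenate_pair(pair)
        else:
            yield result


def concatenate_all(pairs: Iterable[ReadPair]) -> Iterator[JoinedRead]:
    """The ``Cs`` preparation: concatenate every pair unconditionally."""
    for pair in pairs:
        yield concatenate_pair(pair)
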