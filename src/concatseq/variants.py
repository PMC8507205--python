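"""Read filtering, exact-sequence dereplication, and abundance thresholding.

Quality filtering follows the parameter set conventional for amplicon
denoisers: truncate each read at the first base with quality <= truncQ,
then discard reads shorter than a minimum length, reads with more than
maxN ambiguous bases, and reads whose expected error count
``EE = sum(10^(-Q/10))`` exceeds maxEE.

Dereplication collapses reads into exact sequence variants - this
package's stand-in for denoised amplicon sequence variants (ASVs).
Variant identifiers are MD5 hashes of the sequence, so they are stable
across runs and link back to the sequence itself.  Abundance filtering
removes variants whose proportional abundance (against the pre-filter
total) is strictly below a threshold.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seqio import PhredRead


@dataclass
class FilterParams:
    max_n: int = 0
    trunc_q: int = 2
    max_ee: float = 2.0
    min_length: int = 1

    def __post_init__(self) -> None:
        if min(self.max_n, self.trunc_q, self.min_length) < 0 or self.max_ee < 0:
            raise ValueError("filter parameters must be non-negative")


@dataclass
class FilterReport:
    """Per-rule discard tallies for one filtering run."""

    n_input: int = 0
    n_output: int = 0
    n_too_short: int = 0
    n_too_many_n: int = 0
    n_too_many_ee: int = 0

    @property
    def n_discarded(self) -> int:
        return self.n_too_short + self.n_too_many_n + self.n_too_many_ee


def expected_errors(read: PhredRead) -> float:
    """Expected number of base-call errors, ``sum(10^(-Q/10))``."""
    if len(read) == 0:
        return 0.0
    return float(np.sum(10.0 ** (-read.quals.astype(np.float64) / 10.0)))


def filter_reads(reads: Iterable[PhredRead],
                 params: FilterParams | None = None
                 ) -> tuple[list[PhredRead], FilterReport]:
    """Truncate at ``trunc_q`` then apply length / maxN / maxEE filters.

    Rules are applied in that order and each discarded read is tallied
    under the first rule it failed, so the report reconciles exactly with
    the input count.
    """
    from .trimming import truncate_at_quality  # local import: no cycle at load

    params = params or FilterParams()
    report = FilterReport()
    kept: list[PhredRead] = []
    for read in reads:
        report.n_input += 1
        read = truncate_at_quality(read, params.trunc_q)
        if len(read) < params.min_length:
            report.n_too_short += 1
            continue
        if read.bases.count("N") > params.max_n:
            report.n_too_many_n += 1
            continue
        if expected_errors(read) > params.max_ee:
            report.n_too_many_ee += 1
            continue
        kept.append(read)
    report.n_output = len(kept)
    return kept, report


def variant_id(sequence: str) -> str:
    """Stable identifier for a variant: the MD5 hex digest of its sequence."""
    return hashlib.md5(sequence.encode("ascii")).hexdigest()


@dataclass
class VariantTable:
    """Exact sequence variants with per-sample counts.

    Variants are ordered by descending total count, then lexicographically
    by sequence, so serialisation is deterministic.
    """

    _counts: dict[str, Counter] = field(default_factory=dict)  # seq -> sample -> n
    samples: list[str] = field(default_factory=list)

    def add(self, sequence: str, sample_id: str, count: int = 1) -> None:
        if sample_id not in self.samples:
            self.samples.append(sample_id)
        self._counts.setdefault(sequence, Counter())[sample_id] += count

    @property
    def sequences(self) -> list[str]:
        return sorted(self._counts,
                      key=lambda s: (-sum(self._counts[s].values()), s))

    @property
    def ids(self) -> list[str]:
        return [variant_id(s) for s in self.sequences]

    @property
    def n_variants(self) -> int:
        return len(self._counts)

    @property
    def total_count(self) -> int:
        return sum(sum(c.values()) for c in self._counts.values())

    def count(self, sequence: str) -> int:
        return sum(self._counts.get(sequence, Counter()).values())

    def proportions(self) -> dict[str, float]:
        total = self.total_count
        return {s: self.count(s) / total for s in self.sequences} if total else {}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seq in self.sequences:
            row: dict[str, object] = {"variant_id": variant_id(seq), "sequence": seq}
            for sample in self.samples:
                row[sample] = self._counts[seq].get(sample, 0)
            rows.append(row)
        columns = ["variant_id", "sequence", *self.samples]
        return pd.DataFrame(rows, columns=columns)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariantTable":
        frame = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "sequence": str})
        table = cls()
        sample_cols = [c for c in frame.columns if c not in ("variant_id", "sequence")]
        for _, row in frame.iterrows():
            for sample in sample_cols:
                n = int(row[sample])
                if n:
                    table.add(str(row["sequence"]), sample, n)
        return table

    def to_fasta(self, path: str | Path) -> None:
        """Variant sequences with ``;size=N`` abundance annotations."""
        with open(path, "w") as handle:
            for seq in self.sequences:
                handle.write(f">{variant_id(seq)};size={self.count(seq)}\n{seq}\n")


def dereplicate(reads: Iterable[PhredRead], sample_id: str = "sample") -> VariantTable:
    """Collapse a read stream into exact sequence variants for one sample.

    Identical sequences with different quality strings collapse into a
    single variant; the sum of variant counts equals the read count.
    """
    table = VariantTable()
    counter: Counter = Counter(read.bases for read in reads)
    for seq, n in counter.items():
        table.add(seq, sample_id, n)
    if sample_id not in table.samples:
        table.samples.append(sample_id)
    return table


def abundance_filter(table: VariantTable, threshold: float) -> VariantTable:
    """Drop variants whose proportional abundance is strictly below ``threshold``.

    The proportion is computed against the table's total count *before*
    filtering, so the operation is order-independent and monotone in the
    threshold; variants sitting exactly on the threshold survive.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be a fraction in [0, 1]")
    out = VariantTable(samples=list(table.samples))
    total = table.total_count
    if total == 0:
        return out
    for seq, per_sample in table._counts.items():
        if sum(per_sample.values()) / total >= threshold:
            for sample, n in per_sample.items():
                out.add(seq, sample, n)
    return out
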