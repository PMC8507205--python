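"""Named pipeline configurations and end-to-end orchestration.

A pipeline code combines a trimming regime with a paired-read
preparation:

* trim modes: ``N`` (none), ``L`` (length trim at the library's
  median-Q20 position), ``Q`` (per-read 3' quality trim at Q20);
* join modes: ``Mp`` (merge, drop unmergeable pairs), ``Bp`` (merge plus
  concatenate the unmergeable pairs), ``Cs`` (concatenate everything),
  ``R1``/``R2`` (single-end pass-through; quality trimming is not
  combined with single-end modes).

Codes ending in ``Md`` (denoiser-internal merging) are recognised but
rejected: that merging happens inside an external denoiser and
reimplementing it here would misattribute its behaviour to this package.

Stage order: 3' trimming (when requested) precedes 5' primer removal;
joining follows; then quality filtering (truncQ / maxN / maxEE) and
exact-sequence dereplication.  Every stage reports read counts so runs
reconcile input to output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import joining, trimming, variants
from .evaluation import (Lineage, MockComposition, threshold_sweep)
from .joining import JoinedRead, MergeParams
from .seqio import PhredRead, ReadPair
from .simulate import SimTruth, toy_classify
from .trimming import TrimSpec
from .variants import FilterParams, FilterReport, VariantTable

TRIM_MODES = ("N", "L", "Q")
JOIN_MODES = ("Mp", "Bp", "Cs", "R1", "R2")
_DENOISER_MERGED = ("NMd", "LMd", "QMd", "QdMd")


class UnsupportedPipelineError(ValueError):
    """A recognised pipeline code this package deliberately does not run."""


@dataclass(frozen=True)
class PipelineCode:
    trim_mode: str
    join_mode: str

    def __post_init__(self) -> None:
        if self.trim_mode not in TRIM_MODES:
            raise ValueError(f"unknown trim mode {self.trim_mode!r}")
        if self.join_mode not in JOIN_MODES:
            raise ValueError(f"unknown join mode {self.join_mode!r}")
        if self.trim_mode == "Q" and self.join_mode in ("R1", "R2"):
            raise ValueError(
                "quality trimming is not combined with single-end modes"
            )

    @classmethod
    def parse(cls, code: str) -> "PipelineCode":
        code = code.strip()
        if code in _DENOISER_MERGED:
            raise UnsupportedPipelineError(
                f"pipeline {code!r} merges read pairs inside the external "
                "denoiser and is out of scope here; use Mp, Bp or Cs instead"
            )
        for join in JOIN_MODES:
            if code.endswith(join) and code[: -len(join)] in TRIM_MODES:
                return cls(trim_mode=code[: -len(join)], join_mode=join)
        raise ValueError(f"unrecognised pipeline code {code!r}")

    def __str__(self) -> str:
        return f"{self.trim_mode}{self.join_mode}"


@dataclass
class PipelineConfig:
    """Flat parameter set for a run; defaults are the conventional values."""

    fwd_primer: Optional[str] = None
    rev_primer: Optional[str] = None
    primer_max_error_rate: float = 0.10
    trim_q: int = 20
    trim_spec: Optional[TrimSpec] = None  # explicit length override for L mode
    merge: MergeParams = field(default_factory=MergeParams)
    filter: FilterParams = field(default_factory=FilterParams)
    sample_id: str = "sample"


@dataclass
class StageReport:
    """Read accounting for one pipeline run."""

    pipeline: str = ""
    input_pairs: int = 0
    r1_trim_length: int = 0   # 0 = untrimmed
    r2_trim_length: int = 0
    primer_matched_r1: int = 0
    primer_matched_r2: int = 0
    joined: int = 0
    merged: int = 0
    concatenated: int = 0
    discarded_unmerged: int = 0
    filter: FilterReport = field(default_factory=FilterReport)
    n_variants: int = 0

    def as_dict(self) -> dict[str, object]:
        d = {k: v for k, v in self.__dict__.items() if k != "filter"}
        d.update({f"filter_{k}": v for k, v in self.filter.__dict__.items()})
        return d


@dataclass
class PipelineResult:
    table: VariantTable
    report: StageReport


def _derive_trim_spec(pairs: Sequence[ReadPair], config: PipelineConfig) -> TrimSpec:
    if config.trim_spec is not None:
        return config.trim_spec
    profile_r1 = trimming.quality_profile(p.r1 for p in pairs)
    profile_r2 = trimming.quality_profile(p.r2 for p in pairs)
    return TrimSpec(
        r1_length=trimming.length_trim_position(profile_r1, config.trim_q),
        r2_length=trimming.length_trim_position(profile_r2, config.trim_q),
    )


def run_pipeline(code: PipelineCode | str, pairs: Iterable[ReadPair],
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run one named pipeline over an in-memory read-pair stream.

    Returns the dereplicated variant table and a fully populated stage
    report.  Deterministic for fixed inputs.
    """
    if isinstance(code, str):
        code = PipelineCode.parse(code)
    config = config or PipelineConfig()
    pairs = list(pairs)
    report = StageReport(pipeline=str(code), input_pairs=len(pairs))

    # 3' trimming first (L / Q), then primer removal from the 5' end
    if code.trim_mode == "L":
        spec = _derive_trim_spec(pairs, config)
        report.r1_trim_length = spec.r1_length
        report.r2_trim_length = spec.r2_length
        pairs = [ReadPair(trimming.trim_to_length(p.r1, spec.r1_length),
                          trimming.trim_to_length(p.r2, spec.r2_length))
                 for p in pairs]
    elif code.trim_mode == "Q":
        pairs = [ReadPair(trimming.quality_trim_3prime(p.r1, config.trim_q),
                          trimming.quality_trim_3prime(p.r2, config.trim_q))
                 for p in pairs]

    if config.fwd_primer and config.rev_primer:
        trimmed = []
        for pair in pairs:
            result = trimming.remove_primers(pair, config.fwd_primer,
                                             config.rev_primer,
                                             config.primer_max_error_rate)
            report.primer_matched_r1 += result.r1_matched
            report.primer_matched_r2 += result.r2_matched
            trimmed.append(result.pair)
        pairs = trimmed

    joined: list[PhredRead]
    if code.join_mode == "Mp":
        joined = []
        for pair in pairs:
            result = joining.merge_pair(pair, config.merge)
            if isinstance(result, joining.MergeFailure):
                report.discarded_unmerged += 1
            else:
                joined.append(result)
        report.merged = len(joined)
    elif code.join_mode == "Bp":
        joined = list(joining.merge_and_concatenate(pairs, config.merge))
        report.merged = sum(1 for r in joined
                            if getattr(r, "provenance", "merged") == "merged")
        report.concatenated = len(joined) - report.merged
    elif code.join_mode == "Cs":
        joined = list(joining.concatenate_all(pairs))
        report.concatenated = len(joined)
    elif code.join_mode == "R1":
        joined = [p.r1 for p in pairs]
    else:  # R2
        joined = [p.r2 for p in pairs]
    report.joined = len(joined)

    filtered, report.filter = variants.filter_reads(joined, config.filter)
    table = variants.dereplicate(filtered, config.sample_id)
    report.n_variants = table.n_variants
    return PipelineResult(table=table, report=report)


@dataclass
class BenchmarkInput:
    """One mock dataset: read pairs, truth composition, and a classifier
    source (either simulator truth for the toy classifier or an explicit
    variant-id -> lineage map)."""

    name: str
    pairs: list[ReadPair]
    mock: MockComposition
    truth: Optional[SimTruth] = None
    assignments: Optional[Mapping[str, Lineage]] = None

    def classify(self, table: VariantTable) -> Mapping[str, Lineage]:
        if self.assignments is not None:
            return self.assignments
        if self.truth is None:
            raise ValueError(f"dataset {self.name!r} has no classifier source")
        return toy_classify(table, self.truth)


def compare_pipelines(codes: Sequence[PipelineCode | str],
                      inputs: Sequence[BenchmarkInput],
                      thresholds: Sequence[float] = (0.0, 0.0001),
                      config: PipelineConfig | None = None) -> pd.DataFrame:
    """Run several pipelines over several mocks and tabulate the metrics.

    Returns a long-format table (pipeline, mock, threshold, TP, FP, FN,
    precision, recall, F-measure) plus one ``mock == "mean"`` row per
    pipeline/threshold averaging across the mocks.
    """
    if not codes:
        raise ValueError("at least one pipeline code is required")
    rows = []
    for code in codes:
        code = PipelineCode.parse(code) if isinstance(code, str) else code
        for dataset in inputs:
            result = run_pipeline(code, dataset.pairs, config)
            assignments = dataset.classify(result.table)
            sweep = threshold_sweep(result.table, assignments, dataset.mock,
                                    thresholds=list(thresholds))
            for threshold, ev in sweep.items():
                rows.append({
                    "pipeline": str(code), "mock": dataset.name,
                    "threshold": threshold, "tp": ev.tp, "fp": ev.fp,
                    "fn": ev.fn, "precision": ev.precision,
                    "recall": ev.recall, "f_measure": ev.f_measure,
                })
    frame = pd.DataFrame(rows)
    means = (frame.groupby(["pipeline", "threshold"], as_index=False)
             [["tp", "fp", "fn", "precision", "recall", "f_measure"]].mean())
    means.insert(1, "mock", "mean")
    return pd.concat([frame, means], ignore_index=True)
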