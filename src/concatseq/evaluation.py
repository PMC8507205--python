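"""Genus-level benchmarking of a pipeline against a mock community.

The evaluation mirrors how mock-community benchmarks are scored in the
amplicon literature: the variants a pipeline reports are mapped to genus
names, nomenclature is standardised so that database dialects and
synonymous names do not masquerade as errors, and the detected genus set
is compared to the known composition:

* TP - a detected genus present (possibly under a synonym) in the mock;
* FP - a detected genus absent from the mock (misclassification or
  contamination);
* FN - a mock genus the pipeline failed to report.

``precision = TP/(TP+FP)``, ``recall = TP/(TP+FN)``, and the F-measure is
their harmonic mean.  Community structure is summarised by Shannon
diversity (natural log) and Pielou's evenness ``J = H/ln(S)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon_entropy

from .variants import VariantTable, abundance_filter

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_GG_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
_SILVA_PREFIXES = tuple(f"D_{i}__" for i in range(7))

#: tokens whose presence (as a whole word, case-insensitive) marks a genus
#: name as too ambiguous to score; duplicates in common curation lists are
#: collapsed here.
DEFAULT_AMBIGUOUS_TOKENS = (
    "UCG", "NK", "group", "of", "soil", "clade", "env", "genus",
    "candidatus", "species", "subsp", "subgroup", "subsec", "marine",
    "lineage", "metagenome", "mitochondria", "R1", "chloroplast",
    "Incertae", "NA",
)

UNKNOWN = "unknown"


@dataclass
class Lineage:
    """An ordered taxonomic lineage; missing ranks are empty strings."""

    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def __getitem__(self, rank: str) -> str:
        return getattr(self, "class_" if rank == "class" else rank)


@dataclass
class MockComposition:
    """The evaluation truth: expected genera, proportions, synonyms."""

    expected_genera: frozenset[str]
    expected_proportions: dict[str, float] | None = None
    synonym_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.expected_genera = frozenset(self.expected_genera)
        if not self.expected_genera:
            raise ValueError("a mock community must contain at least one genus")
        if self.expected_proportions is not None:
            total = sum(self.expected_proportions.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"expected proportions sum to {total}, not 1")
        lowered = {g.casefold() for g in self.expected_genera}
        for alias, canonical in self.synonym_map.items():
            if canonical.casefold() not in lowered:
                raise ValueError(
                    f"synonym target {canonical!r} is not an expected genus"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MockComposition":
        """Read a ``genus<TAB>proportion<TAB>synonyms`` table.

        The proportion column may be empty; synonyms are comma-separated
        aliases for the genus on the same row.
        """
        frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        genera, proportions, synonyms = [], {}, {}
        for _, row in frame.iterrows():
            genus = row["genus"].strip()
            genera.append(genus)
            if row.get("proportion", ""):
                proportions[genus] = float(row["proportion"])
            for alias in str(row.get("synonyms", "")).split(","):
                alias = alias.strip()
                if alias:
                    synonyms[alias] = genus
        return cls(expected_genera=frozenset(genera),
                   expected_proportions=proportions or None,
                   synonym_map=synonyms)

    def to_tsv(self, path: str | Path) -> None:
        aliases: dict[str, list[str]] = {g: [] for g in self.expected_genera}
        for alias, canonical in self.synonym_map.items():
            aliases[canonical].append(alias)
        rows = [
            {
                "genus": g,
                "proportion": (self.expected_proportions or {}).get(g, ""),
                "synonyms": ",".join(sorted(aliases[g])),
            }
            for g in sorted(self.expected_genera)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    tp_genera: tuple[str, ...]
    fp_genera: tuple[str, ...]
    fn_genera: tuple[str, ...]
    precision: float
    recall: float
    f_measure: float


def parse_lineage(text: str, dialect: str = "greengenes") -> Lineage:
    """Parse a semicolon-delimited lineage string.

    ``greengenes`` strips ``k__``/``p__``/... rank prefixes, ``silva``
    strips ``D_0__``/... prefixes, and ``plain`` takes fields positionally
    (kingdom first).  Whitespace is trimmed; missing ranks stay empty.
    """
    if dialect == "greengenes":
        prefixes: Sequence[str] | None = _GG_PREFIXES
    elif dialect == "silva":
        prefixes = _SILVA_PREFIXES
    elif dialect == "plain":
        prefixes = None
    else:
        raise ValueError(f"unknown lineage dialect {dialect!r}")

    fields = [f.strip() for f in text.split(";")]
    values = {}
    for i, rank in enumerate(RANKS):
        if i >= len(fields):
            break
        value = fields[i]
        if prefixes is not None and value.startswith(prefixes[i]):
            value = value[len(prefixes[i]):]
        values[rank] = value.strip()
    return Lineage(**{("class_" if r == "class" else r): v
                      for r, v in values.items()})


def _word_match(token: str, name: str) -> bool:
    return re.search(rf"\b{re.escape(token)}\b", name, flags=re.IGNORECASE) is not None


def standardize_genus(lineage: Lineage, mock: MockComposition,
                      ambiguous_tokens: Iterable[str] = DEFAULT_AMBIGUOUS_TOKENS
                      ) -> str:
    """Map a lineage to a scoreable genus name, or ``"unknown"``.

    A genus is unresolvable when it is empty, repeats the family-level
    name, contains digits (uncultured-strain numbering), or contains any
    ambiguous token as a whole word.  Otherwise the synonym map is applied
    and the (possibly renamed) genus returned.
    """
    genus = lineage.genus.strip()
    if not genus:
        return UNKNOWN
    if lineage.family.strip() and genus.casefold() == lineage.family.strip().casefold():
        return UNKNOWN
    if any(ch.isdigit() for ch in genus):
        return UNKNOWN
    if any(_word_match(tok, genus) for tok in ambiguous_tokens):
        return UNKNOWN
    synonyms = {alias.casefold(): canonical
                for alias, canonical in mock.synonym_map.items()}
    return synonyms.get(genus.casefold(), genus)


def kingdom_filter(assignments: Iterable[tuple[str, Lineage]],
                   kingdom: str = "Bacteria"
                   ) -> tuple[list[tuple[str, Lineage]], int]:
    """Keep assignments whose kingdom matches (case-insensitive).

    Returns the retained list and the number of assignments removed.
    """
    kept, removed = [], 0
    for key, lineage in assignments:
        if lineage.kingdom.strip().casefold() == kingdom.casefold():
            kept.append((key, lineage))
        else:
            removed += 1
    return kept, removed


def detected_genera(table: VariantTable, assignments: Mapping[str, Lineage],
                    mock: MockComposition, threshold: float = 0.0,
                    kingdom: str = "Bacteria") -> frozenset[str]:
    """The set of genera a pipeline reports at an abundance threshold.

    Variants are abundance-filtered, restricted to the target kingdom,
    and standardised; ``"unknown"`` never enters the detected set, and
    multiplicity is ignored (presence/absence scoring).  Variants missing
    from ``assignments`` count as unknown.
    """
    surviving = abundance_filter(table, threshold)
    pairs = [(vid, assignments.get(vid, Lineage())) for vid in surviving.ids]
    kept, _ = kingdom_filter(pairs, kingdom=kingdom)
    genera = {standardize_genus(lineage, mock) for _, lineage in kept}
    genera.discard(UNKNOWN)
    return frozenset(genera)


def confusion_counts(detected: Iterable[str], mock: MockComposition
                     ) -> tuple[int, int, int, tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
    """TP/FP/FN counts and genus lists (case-insensitive comparison)."""
    if not mock.expected_genera:
        raise ValueError("expected genus set is empty")
    expected = {g.casefold(): g for g in mock.expected_genera}
    seen = {g.casefold(): g for g in detected}
    tp = tuple(sorted(expected[k] for k in seen.keys() & expected.keys()))
    fp = tuple(sorted(seen[k] for k in seen.keys() - expected.keys()))
    fn = tuple(sorted(expected[k] for k in expected.keys() - seen.keys()))
    return len(tp), len(fp), len(fn), tp, fp, fn


def prf_metrics(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F-measure from confusion counts.

    Precision is defined as 0 when nothing was detected, and the
    F-measure as 0 when precision + recall is 0.  ``tp + fn`` must be
    positive (there must be expected genera to recall).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0:
        raise ValueError("tp + fn must be >= 1 (no expected genera?)")
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn)
    f_measure = (2 * precision * recall / (precision + recall)
                 if (precision + recall) else 0.0)
    return precision, recall, f_measure


def evaluate_detected(detected: Iterable[str], mock: MockComposition) -> EvalResult:
    tp, fp, fn, tp_g, fp_g, fn_g = confusion_counts(detected, mock)
    precision, recall, f_measure = prf_metrics(tp, fp, fn)
    return EvalResult(tp=tp, fp=fp, fn=fn, tp_genera=tp_g, fp_genera=fp_g,
                      fn_genera=fn_g, precision=precision, recall=recall,
                      f_measure=f_measure)


def threshold_sweep(table: VariantTable, assignments: Mapping[str, Lineage],
                    mock: MockComposition,
                    thresholds: Sequence[float] = (0.0, 0.0001, 0.0005,
                                                   0.001, 0.005, 0.01),
                    kingdom: str = "Bacteria") -> dict[float, EvalResult]:
    """Evaluate at each abundance threshold (ascending).

    Because the surviving variant sets are nested across thresholds, TP
    and FP are non-increasing and FN non-decreasing with the threshold -
    the mechanism by which abundance filtering trades recall for
    precision.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    results = {}
    for threshold in thresholds:
        detected = detected_genera(table, assignments, mock, threshold, kingdom)
        results[threshold] = evaluate_detected(detected, mock)
    return results


def sweep_frame(results: Mapping[float, EvalResult]) -> pd.DataFrame:
    """Long-format table of a threshold sweep."""
    rows = [
        {"threshold": t, "tp": r.tp, "fp": r.fp, "fn": r.fn,
         "precision": r.precision, "recall": r.recall, "f_measure": r.f_measure}
        for t, r in results.items()
    ]
    return pd.DataFrame(rows)


def diversity_stats(profile: Mapping[str, float]) -> tuple[float, float, int]:
    """Shannon diversity H (natural log), Pielou's evenness J, and richness.

    ``profile`` maps genus to relative abundance; abundances must be
    positive and sum to 1 (within 1e-6).  For a single-genus community
    H = 0 and J is reported as 1 by convention.
    """
    p = np.asarray([v for v in profile.values() if v > 0], dtype=np.float64)
    if p.size == 0 or np.any(np.asarray(list(profile.values())) < 0):
        raise ValueError("abundances must be positive")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"abundances sum to {p.sum():.8f}, not 1")
    richness = int(p.size)
    shannon_h = float(_shannon_entropy(p))  # natural log
    pielou_j = 1.0 if richness == 1 else shannon_h / np.log(richness)
    return shannon_h, pielou_j, richness


def read_taxonomy_tsv(path: str | Path, dialect: str = "greengenes"
                      ) -> dict[str, Lineage]:
    """Read a ``variant_id<TAB>lineage[<TAB>confidence]`` assignment table."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    id_col, lineage_col = frame.columns[0], frame.columns[1]
    return {row[id_col]: parse_lineage(row[lineage_col], dialect)
            for _, row in frame.iterrows()}


def write_taxonomy_tsv(assignments: Mapping[str, Lineage], path: str | Path) -> None:
    rows = []
    for vid, lineage in assignments.items():
        ranks = [lineage[r] for r in RANKS]
        rows.append({"variant_id": vid, "lineage": ";".join(ranks), "confidence": ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
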