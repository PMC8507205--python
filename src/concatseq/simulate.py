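"""Synthetic mock communities and paired-end amplicon reads.

The simulator emulates the structure of MiSeq 16S rRNA amplicon
libraries sequenced from mock communities of known composition:

* one reference amplicon per genus - a random core flanked by the
  configured primer sites, with pairwise identity kept below 80% by
  rejection sampling so a k-mer classifier can separate the genera;
* balanced (uniform) or unbalanced (geometric ``skew^rank``) genus
  compositions, with optional trace-level contaminant genera;
* R1 reads from the template 5' end and R2 reads from the reverse
  complement, so pairs overlap if and only if the template is shorter
  than twice the read length;
* position-dependent quality decay ``Q(p) = q_start - (q_start - q_end) *
  (p / read_length)^decay_shape`` with R2 lowered by a flat penalty, and
  substitution errors drawn per base at rate ``10^(-Q/10)``.

Genus counts are allocated deterministically from the composition by
largest-remainder rounding (a mock community *is* a fixed composition;
sampling noise would only blur the truth the evaluation compares
against), and read order is then shuffled.  Everything is driven by one
seeded generator, so a configuration reproduces its library exactly.

A toy classifier (exact/substring match backed by k-mer cosine
similarity, scored on both halves of concatenated variants and on both
strands) stands in for database-backed taxonomy so that the whole
pipeline is testable end to end without reference downloads.
"""

from __future__ import annotations

import itertools
import string
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .evaluation import Lineage, MockComposition
from .seqio import IUPAC_SETS, PhredRead, ReadPair, revcomp_seq
from .variants import VariantTable

#: 515F / 806R, the standard V4 primer pair
DEFAULT_FWD_PRIMER = "GTGYCAGCMGCCGCGGTAA"
DEFAULT_REV_PRIMER = "GGACTACNVGGGTWTCTAAT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one simulated mock-community library."""

    n_genera: int = 10
    amplicon_length: int | tuple[int, int] = 253  # core length between primers
    read_length: int = 250
    n_pairs: int = 5000
    composition: str = "balanced"  # balanced | unbalanced
    skew: float = 0.5              # geometric ratio for unbalanced mocks
    q_start: int = 38
    q_end: int = 23
    decay_shape: float = 3.0
    r2_penalty: int = 4
    n_contaminants: int = 0
    contaminant_abundance: float = 0.00004  # per contaminant genus
    substitution_errors: bool = True
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not (self.q_start >= self.q_end >= 2):
            raise ValueError("quality model requires q_start >= q_end >= 2")
        if self.composition not in ("balanced", "unbalanced"):
            raise ValueError("composition must be 'balanced' or 'unbalanced'")
        if not 0 < self.skew <= 1:
            raise ValueError("skew must be in (0, 1]")


@dataclass
class SimTruth:
    """References, composition and contaminant labels behind a simulation."""

    references: dict[str, str]          # genus -> template (with primer sites)
    composition: dict[str, float]       # genus -> expected fraction
    contaminants: frozenset[str]
    seed: int

    @property
    def genera(self) -> list[str]:
        return list(self.references)

    def to_mock_composition(self) -> MockComposition:
        """The evaluation truth: non-contaminant genera, renormalised."""
        main = {g: f for g, f in self.composition.items()
                if g not in self.contaminants}
        total = sum(main.values())
        return MockComposition(
            expected_genera=frozenset(main),
            expected_proportions={g: f / total for g, f in main.items()},
        )

    def write_reference_fasta(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write(f"# synthetic reference, seed={self.seed}\n")
            for genus, template in self.references.items():
                tag = " contaminant" if genus in self.contaminants else ""
                handle.write(f">{genus} genus={genus}{tag}\n{template}\n")


@dataclass
class SimulatedReads:
    """A simulated library plus its per-read truth."""

    pairs: list[ReadPair]
    read_genus: dict[str, str]            # template id -> source genus
    realized_composition: dict[str, float]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"read_id": rid, "genus": genus}
             for rid, genus in self.read_genus.items()]
        )


def _genus_names(n: int, prefix: str = "Genus") -> list[str]:
    """Digit-free synthetic genus names: GenusA, GenusB, ... GenusAA, ..."""
    names: list[str] = []
    if n <= 0:
        return names
    for size in itertools.count(1):
        for letters in itertools.product(string.ascii_uppercase, repeat=size):
            names.append(prefix + "".join(letters))
            if len(names) == n:
                return names
    return names


def _instantiate_primer(primer: str, rng: np.random.Generator) -> str:
    """Replace degenerate IUPAC codes by a concrete random base."""
    return "".join(
        base if base in "ACGT" else str(rng.choice(list(IUPAC_SETS[base])))
        for base in primer.upper()
    )


def _identity(a: str, b: str) -> float:
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def _composition_fractions(config: SimConfig, genera: Sequence[str],
                           contaminants: Sequence[str]) -> dict[str, float]:
    n = len(genera)
    if config.composition == "balanced":
        main = np.full(n, 1.0 / n)
    else:
        main = config.skew ** np.arange(n)
        main /= main.sum()
    cont_mass = config.contaminant_abundance * len(contaminants)
    if cont_mass >= 0.5:
        raise ValueError("contaminant abundance is too high to be a trace")
    fractions = {g: float(f * (1 - cont_mass)) for g, f in zip(genera, main)}
    fractions.update({c: config.contaminant_abundance for c in contaminants})
    return fractions


def make_reference(config: SimConfig,
                   rng: Optional[np.random.Generator] = None,
                   max_attempts: int = 1000) -> SimTruth:
    """Generate one labelled reference amplicon per genus.

    Each template is ``fwd_primer + random core + revcomp(rev_primer)``
    with degenerate primer positions instantiated per genus.  Cores are
    rejection-sampled until every pairwise identity (global alignment)
    is below 80%.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genera = _genus_names(config.n_genera)
    contaminants = _genus_names(config.n_contaminants, prefix="Contam")
    references: dict[str, str] = {}
    for genus in genera + contaminants:
        if isinstance(config.amplicon_length, int):
            core_len = config.amplicon_length
        else:
            lo, hi = config.amplicon_length
            core_len = int(rng.integers(lo, hi + 1))
        for _ in range(max_attempts):
            core = _BASES[rng.integers(0, 4, size=core_len)].tobytes().decode()
            if all(_identity(core, t) < 0.8 for t in references.values()):
                break
        else:
            raise RuntimeError(
                "could not generate sufficiently distinct amplicons; "
                "try fewer genera or longer amplicons"
            )
        template = (_instantiate_primer(config.fwd_primer, rng) + core
                    + revcomp_seq(_instantiate_primer(config.rev_primer, rng)))
        references[genus] = template
    composition = _composition_fractions(config, genera, contaminants)
    return SimTruth(references=references, composition=composition,
                    contaminants=frozenset(contaminants), seed=config.seed)


def _allocate_counts(composition: Mapping[str, float],
                     contaminants: frozenset[str], n_pairs: int) -> dict[str, int]:
    """Largest-remainder allocation; contaminants get at least one read."""
    counts = {c: max(1, round(composition[c] * n_pairs)) for c in contaminants}
    n_main = n_pairs - sum(counts.values())
    main = {g: f for g, f in composition.items() if g not in contaminants}
    total = sum(main.values())
    raw = {g: f / total * n_main for g, f in main.items()}
    floors = {g: int(v) for g, v in raw.items()}
    leftover = n_main - sum(floors.values())
    by_remainder = sorted(main, key=lambda g: (floors[g] - raw[g], g))
    for g in by_remainder[:leftover]:
        floors[g] += 1
    counts.update(floors)
    return counts


def quality_model(config: SimConfig, mate: int, length: int) -> np.ndarray:
    """Per-position integer Phred scores for one mate (1 or 2)."""
    p = np.arange(length, dtype=np.float64)
    q = (config.q_start
         - (config.q_start - config.q_end) * (p / config.read_length) ** config.decay_shape)
    if mate == 2:
        q = q - config.r2_penalty
    return np.clip(np.rint(q), 2, 93).astype(np.int16)


def _mutate(template_bytes: np.ndarray, quals: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    p_err = 10.0 ** (-quals.astype(np.float64) / 10.0)
    hits = np.nonzero(rng.random(template_bytes.size) < p_err)[0]
    if not hits.size:
        return template_bytes
    out = template_bytes.copy()
    # substitute with a uniform choice among the three other bases
    idx = np.searchsorted(_BASES, out[hits])
    shift = rng.integers(1, 4, size=hits.size)
    out[hits] = _BASES[(idx + shift) % 4]
    return out


def simulate_pairs(truth: SimTruth, config: SimConfig,
                   rng: Optional[np.random.Generator] = None) -> SimulatedReads:
    """Simulate a paired-end library from a reference set.

    R1 is the first ``read_length`` bases of the template and R2 the
    first ``read_length`` bases of its reverse complement (both truncated
    if the template is shorter).  Substitution errors are applied per
    base at rate ``10^(-Q/10)`` unless ``substitution_errors`` is off.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    counts = _allocate_counts(truth.composition, truth.contaminants, config.n_pairs)
    order = np.repeat(list(counts.keys()), list(counts.values()))
    rng.shuffle(order)

    # per-genus template slices and shared quality arrays, encoded once
    slices: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for genus, template in truth.references.items():
        n = min(config.read_length, len(template))
        r1 = np.frombuffer(template[:n].encode(), dtype=np.uint8)
        r2 = np.frombuffer(revcomp_seq(template)[:n].encode(), dtype=np.uint8)
        q1 = quality_model(config, 1, n)
        q2 = quality_model(config, 2, n)
        slices[genus] = (r1, r2, q1, q2)

    pairs: list[ReadPair] = []
    read_genus: dict[str, str] = {}
    for i, genus in enumerate(order):
        rid = f"sim{i:07d}"
        r1b, r2b, q1, q2 = slices[genus]
        if config.substitution_errors:
            r1b = _mutate(r1b, q1, rng)
            r2b = _mutate(r2b, q2, rng)
        pairs.append(ReadPair(
            PhredRead(f"{rid}/1", r1b.tobytes().decode(), q1),
            PhredRead(f"{rid}/2", r2b.tobytes().decode(), q2),
        ))
        read_genus[rid] = str(genus)

    realized = {g: c / config.n_pairs for g, c in counts.items()}
    return SimulatedReads(pairs=pairs, read_genus=read_genus,
                          realized_composition=realized)


def simulate_mock(config: SimConfig) -> tuple[SimTruth, SimulatedReads]:
    """Convenience wrapper: reference set plus library from one generator."""
    rng = np.random.default_rng(config.seed)
    truth = make_reference(config, rng=rng)
    reads = simulate_pairs(truth, config, rng=rng)
    return truth, reads


# ---------------------------------------------------------------------------
# toy classifier


def _kmer_counts(seq: str, k: int) -> Counter:
    return Counter(seq[i:i + k] for i in range(len(seq) - k + 1))


def _cosine(a: Counter, b: Counter) -> float:
    if not a or not b:
        return 0.0
    dot = sum(n * b[kmer] for kmer, n in a.items() if kmer in b)
    norm = np.sqrt(sum(n * n for n in a.values()) * sum(n * n for n in b.values()))
    return float(dot / norm) if norm else 0.0


def toy_classify(table: VariantTable, truth: SimTruth, k: int = 8,
                 min_similarity: float = 0.7) -> dict[str, Lineage]:
    """Assign each variant a genus from the simulated reference set.

    A variant that occurs verbatim inside a reference (either strand)
    takes that genus.  Otherwise the reference with the highest k-mer
    cosine similarity wins, where each variant is scored both as a whole
    and as the mean of its two halves - the latter rescues concatenated
    variants, whose halves each match the reference even though the
    junction (duplicated or missing bases) does not.  Variants below
    ``min_similarity`` are left without a genus (kingdom only), which
    downstream standardisation reports as unknown.
    """
    if not truth.references:
        raise ValueError("reference set is empty")
    ref_vecs = {g: _kmer_counts(t, k) for g, t in truth.references.items()}
    assignments: dict[str, Lineage] = {}
    for vid, seq in zip(table.ids, table.sequences):
        genus = ""
        for g, template in truth.references.items():
            if seq in template or revcomp_seq(seq) in template:
                genus = g
                break
        if not genus:
            best_genus, best_sim = "", 0.0
            for strand in (seq, revcomp_seq(seq)):
                whole = _kmer_counts(strand, k)
                half = len(strand) // 2
                h1 = _kmer_counts(strand[:half], k)
                h2 = _kmer_counts(strand[half:], k)
                for g, vec in ref_vecs.items():
                    sim = max(_cosine(whole, vec),
                              0.5 * (_cosine(h1, vec) + _cosine(h2, vec)))
                    if sim > best_sim:
                        best_genus, best_sim = g, sim
            if best_sim >= min_similarity:
                genus = best_genus
        assignments[vid] = Lineage(kingdom="Bacteria", genus=genus)
    return assignments
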