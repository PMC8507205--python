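"""Lineage parsing, nomenclature standardization, scoring, and diversity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from concatseq.evaluation import (Lineage, MockComposition, confusion_counts,
                                  detected_genera, diversity_stats,
                                  evaluate_detected, kingdom_filter,
                                  parse_lineage, prf_metrics,
                                  standardize_genus, threshold_sweep,
                                  UNKNOWN)
from concatseq.variants import VariantTable, variant_id

MOCK = MockComposition(
    expected_genera=frozenset({"Bacillus", "Escherichia", "Lactobacillus"}),
    synonym_map={"Escherichia-Shigella": "Escherichia"},
)


class TestParseLineage:
    def test_greengenes_prefixes_stripped(self):
        lineage = parse_lineage(
            "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; "
            "f__Bacillaceae; g__Bacillus", "greengenes")
        assert lineage.kingdom == "Bacteria"
        assert lineage.genus == "Bacillus"
        assert lineage.species == ""

    def test_silva_prefixes_stripped(self):
        lineage = parse_lineage(
            "D_0__Bacteria;D_1__Proteobacteria;D_2__Gamma;D_3__Entero;"
            "D_4__Enterobacteriaceae;D_5__Escherichia", "silva")
        assert lineage.kingdom == "Bacteria"
        assert lineage.genus == "Escherichia"

    def test_empty_rank_preserved(self):
        lineage = parse_lineage("k__Bacteria; p__; c__Bacilli", "greengenes")
        assert lineage.phylum == "" and lineage.class_ == "Bacilli"

    def test_plain_dialect_positional(self):
        lineage = parse_lineage("Bacteria;;;;Bacillaceae;Bacillus", "plain")
        assert lineage.family == "Bacillaceae" and lineage.genus == "Bacillus"

    def test_unknown_dialect(self):
        with pytest.raises(ValueError):
            parse_lineage("k__Bacteria", "rdp")


class TestStandardizeGenus:
    def test_digits_mark_unknown(self):
        lineage = Lineage(genus="Clostridium sensu stricto 1")
        assert standardize_genus(lineage, MOCK) == UNKNOWN

    def test_family_equal_to_genus_marks_unknown(self):
        lineage = Lineage(family="Lachnospiraceae", genus="Lachnospiraceae")
        assert standardize_genus(lineage, MOCK) == UNKNOWN

    def test_synonym_renamed_to_canonical(self):
        lineage = Lineage(genus="Escherichia-Shigella")
        assert standardize_genus(lineage, MOCK) == "Escherichia"

    def test_empty_genus_unknown(self):
        assert standardize_genus(Lineage(genus="  "), MOCK) == UNKNOWN

    @pytest.mark.parametrize("genus", [
        "Eubacterium coprostanoligenes group",
        "Candidatus Arthromitus",
        "uncultured soil bacterium",
        "Incertae Sedis",
        "gut metagenome",
    ])
    def test_ambiguous_tokens_word_matched(self, genus):
        assert standardize_genus(Lineage(genus=genus), MOCK) == UNKNOWN

    def test_token_matching_requires_word_boundary(self):
        # 'NA' and 'of' appear only inside words here: the genus survives
        assert standardize_genus(Lineage(genus="Anaerofustis"), MOCK) == "Anaerofustis"

    def test_idempotent_at_genus_level(self):
        for genus in ("Bacillus", "Escherichia-Shigella", "Strain 12",
                      "Lachnospiraceae UCG", "Anaerofustis"):
            once = standardize_genus(Lineage(genus=genus), MOCK)
            twice = standardize_genus(Lineage(genus=once), MOCK)
            assert twice == once


class TestKingdomFilter:
    def test_case_insensitive_match(self):
        pairs = [("a", Lineage(kingdom="bacteria")),
                 ("b", Lineage(kingdom="Archaea")),
                 ("c", Lineage(kingdom=""))]
        kept, removed = kingdom_filter(pairs)
        assert [key for key, _ in kept] == ["a"]
        assert removed == 2


class TestConfusionAndMetrics:
    def test_perfect_detection(self):
        tp, fp, fn, *_ = confusion_counts(MOCK.expected_genera, MOCK)
        assert (tp, fp, fn) == (3, 0, 0)

    def test_extra_genus_is_fp(self):
        detected = set(MOCK.expected_genera) | {"Salmonella"}
        tp, fp, fn, _, fp_list, _ = confusion_counts(detected, MOCK)
        assert (tp, fp, fn) == (3, 1, 0)
        assert fp_list == ("Salmonella",)

    def test_nothing_detected(self):
        tp, fp, fn, *_ = confusion_counts(set(), MOCK)
        assert (tp, fp, fn) == (0, 0, 3)

    def test_case_insensitive_comparison(self):
        tp, fp, fn, *_ = confusion_counts({"bacillus"}, MOCK)
        assert (tp, fp) == (1, 0)

    def test_precision_zero_when_nothing_detected(self):
        precision, recall, f = prf_metrics(0, 0, 5)
        assert (precision, recall, f) == (0.0, 0.0, 0.0)

    def test_no_expected_genera_rejected(self):
        with pytest.raises(ValueError):
            prf_metrics(0, 3, 0)

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_matches_brute_force_recomputation(self, tp, fp, fn):
        """Recompute the metrics from explicit genus lists."""
        if tp + fn == 0:
            return
        expected = {f"E{i}" for i in range(tp + fn)}
        detected = {f"E{i}" for i in range(tp)} | {f"X{i}" for i in range(fp)}
        mock = MockComposition(expected_genera=frozenset(expected))
        result = evaluate_detected(detected, mock)
        assert (result.tp, result.fp, result.fn) == (tp, fp, fn)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn)
        f = (2 * precision * recall / (precision + recall)
             if precision + recall else 0.0)
        assert result.precision == pytest.approx(precision)
        assert result.f_measure == pytest.approx(f)
        assert 0 <= result.f_measure <= (result.precision + result.recall) / 2 + 1e-12


def sweep_fixture():
    """Three expected genera plus one contaminant at 0.004% abundance."""
    table = VariantTable()
    sequences = {"Bacillus": "AAAAAAAA", "Escherichia": "CCCCCCCC",
                 "Lactobacillus": "GGGGGGGG", "Sphingomonas": "TTTTTTTT"}
    table.add(sequences["Bacillus"], "s", 49998)
    table.add(sequences["Escherichia"], "s", 30000)
    table.add(sequences["Lactobacillus"], "s", 20000)
    table.add(sequences["Sphingomonas"], "s", 2)  # 2/100000 = 0.002%
    assignments = {variant_id(seq): Lineage(kingdom="Bacteria", genus=genus)
                   for genus, seq in sequences.items()}
    return table, assignments


class TestThresholdSweep:
    def test_contaminant_removed_by_threshold(self):
        table, assignments = sweep_fixture()
        results = threshold_sweep(table, assignments, MOCK,
                                  thresholds=[0.0, 0.0001])
        assert results[0.0].fp == 1 and results[0.0].tp == 3
        assert results[0.0001].fp == 0 and results[0.0001].tp == 3

    def test_monotone_counts(self):
        table, assignments = sweep_fixture()
        thresholds = [0.0, 0.0001, 0.0005, 0.001, 0.005, 0.01]
        results = threshold_sweep(table, assignments, MOCK, thresholds)
        ordered = [results[t] for t in thresholds]
        for a, b in zip(ordered, ordered[1:]):
            assert b.tp <= a.tp and b.fp <= a.fp and b.fn >= a.fn

    def test_zero_threshold_equals_unfiltered(self):
        table, assignments = sweep_fixture()
        detected = detected_genera(table, assignments, MOCK, 0.0)
        result = threshold_sweep(table, assignments, MOCK, [0.0])[0.0]
        assert set(result.tp_genera) | set(result.fp_genera) == set(detected)

    def test_unsorted_thresholds_rejected(self):
        table, assignments = sweep_fixture()
        with pytest.raises(ValueError):
            threshold_sweep(table, assignments, MOCK, [0.01, 0.0])


class TestDetectedGenera:
    def test_set_semantics_and_unknown_excluded(self):
        table = VariantTable()
        table.add("AAAA", "s", 5)
        table.add("CCCC", "s", 5)
        table.add("GGGG", "s", 5)
        assignments = {
            variant_id("AAAA"): Lineage(kingdom="Bacteria", genus="Bacillus"),
            variant_id("CCCC"): Lineage(kingdom="Bacteria", genus="Bacillus"),
            variant_id("GGGG"): Lineage(kingdom="Bacteria", genus=""),
        }
        assert detected_genera(table, assignments, MOCK) == {"Bacillus"}

    def test_non_bacterial_kingdom_dropped(self):
        table = VariantTable()
        table.add("AAAA", "s", 5)
        assignments = {variant_id("AAAA"): Lineage(kingdom="Archaea",
                                                   genus="Methanobrevibacter")}
        assert detected_genera(table, assignments, MOCK) == frozenset()

    def test_missing_assignment_counts_as_unknown(self):
        table = VariantTable()
        table.add("AAAA", "s", 5)
        assert detected_genera(table, {}, MOCK) == frozenset()


class TestDiversityStats:
    def test_uniform_profile_is_maximally_even(self):
        profile = {f"G{i}": 1 / 17 for i in range(17)}
        h, j, richness = diversity_stats(profile)
        assert h == pytest.approx(np.log(17))
        assert j == pytest.approx(1.0)
        assert richness == 17

    def test_single_genus(self):
        h, j, richness = diversity_stats({"G": 1.0})
        assert (h, j, richness) == (0.0, 1.0, 1)

    def test_two_even_genera(self):
        h, j, _ = diversity_stats({"A": 0.5, "B": 0.5})
        assert h == pytest.approx(np.log(2)) and j == pytest.approx(1.0)

    def test_skewed_profile_less_even(self):
        _, j_even, _ = diversity_stats({"A": 0.5, "B": 0.5})
        _, j_skew, _ = diversity_stats({"A": 0.9, "B": 0.1})
        assert j_skew < j_even

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            diversity_stats({"A": 0.5, "B": 0.4})

    def test_relabeling_invariance(self):
        p = {"A": 0.2, "B": 0.3, "C": 0.5}
        q = {"X": 0.5, "Y": 0.2, "Z": 0.3}
        assert diversity_stats(p)[0] == pytest.approx(diversity_stats(q)[0])


def test_mock_composition_validation():
    with pytest.raises(ValueError):
        MockComposition(expected_genera=frozenset())
    with pytest.raises(ValueError):
        MockComposition(expected_genera=frozenset({"A"}),
                        expected_proportions={"A": 0.9})
    with pytest.raises(ValueError):
        MockComposition(expected_genera=frozenset({"A"}),
                        synonym_map={"B-alias": "B"})


def test_mock_composition_tsv_roundtrip(tmp_path):
    mock = MockComposition(
        expected_genera=frozenset({"Bacillus", "Escherichia"}),
        expected_proportions={"Bacillus": 0.6, "Escherichia": 0.4},
        synonym_map={"Escherichia-Shigella": "Escherichia"},
    )
    path = tmp_path / "mock.tsv"
    mock.to_tsv(path)
    back = MockComposition.from_tsv(path)
    assert back.expected_genera == mock.expected_genera
    assert back.synonym_map == mock.synonym_map
    assert back.expected_proportions == pytest.approx(mock.expected_proportions)
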