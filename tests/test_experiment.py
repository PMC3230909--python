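import csv
import io
import itertools
import json
import math
import random

import pytest

from srmdigest import (
    DigestParams,
    Experiment,
    PhosphoSiteSet,
    combine,
    export_datasheet,
    export_matrix_csv,
    load_rules,
    run_experiment,
    select_enzymes,
)
from srmdigest.experiment import CoverageMatrix
from srmdigest.rules import EnzymeRule, RuleRegistry


def make_registry(*rules):
    reg = RuleRegistry()
    for r in rules:
        reg.add(r)
    return reg


def make_matrix(cover_map, n_cols):
    """Matrix from {row_label: set of column indexes}."""
    columns = [("exp", i + 1) for i in range(n_cols)]
    rows = sorted(cover_map)
    cells = {
        (row, col): ("PEPTIDE" if i + 1 in cover_map[row] else None)
        for row in rows
        for i, col in enumerate(columns)
    }
    return CoverageMatrix(rows, columns, cells)


def exhaustive_min_cover(cover_map, coverable):
    """Smallest row subset covering every coverable column."""
    rows = sorted(cover_map)
    for k in range(len(rows) + 1):
        for combo in itertools.combinations(rows, k):
            if set().union(*(cover_map[r] for r in combo), set()) >= coverable:
                return k
    raise AssertionError("unreachable")


class TestRunExperiment:
    def _experiment(self, **kw):
        defaults = dict(
            name="toy",
            protein_id="P1",
            sequence="AGSTNKQRSTW",
            target_sites=PhosphoSiteSet({3: "S"}),
            params=DigestParams(len_min=1, len_max=30,
                                excluded_residues=frozenset()),
        )
        defaults.update(kw)
        return Experiment(**defaults)

    def test_single_mode_one_result_per_enzyme(self, registry):
        exp = self._experiment()
        results = run_experiment(exp, registry)
        assert len(results) == len(registry)
        assert [r.enzymes for r in results] == [(n,) for n in registry.names()]

    def test_pairwise_mode_runs_unordered_pairs(self):
        reg = make_registry(
            EnzymeRule("A", "K", 1),
            EnzymeRule("B", "R", 1),
            EnzymeRule("C", "N", 1),
        )
        exp = self._experiment(params=DigestParams(
            len_min=1, len_max=30, excluded_residues=frozenset(), pairwise=True
        ))
        results = run_experiment(exp, reg)
        assert sorted(r.enzymes for r in results) == [
            ("A", "B"), ("A", "C"), ("B", "C")
        ]

    def test_qualifying_enzyme_covers_planted_site(self):
        # K6 splits AGSTNK|QRSTW; the first fragment spans site 3.
        reg = make_registry(EnzymeRule("lysc-like", "K", 1))
        exp = self._experiment(params=DigestParams(
            len_min=1, len_max=30, excluded_residues=frozenset(),
            phospho_aware=False,
        ))
        (res,) = run_experiment(exp, reg)
        assert res.qualified
        assert res.coverage.covering[3].sequence == "AGSTNK"

    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_experiment(self._experiment(), RuleRegistry())


class TestCombine:
    def _pairs(self):
        reg = make_registry(EnzymeRule("E1", "K", 1), EnzymeRule("E2", "W", 1))
        p = DigestParams(len_min=1, len_max=50, excluded_residues=frozenset(),
                         phospho_aware=False)
        exp1 = Experiment("exp1", "P1", "AGSTNKQRSTW",
                          PhosphoSiteSet({3: "S", 9: "S"}), p)
        exp2 = Experiment("exp2", "P2", "KAGSTN", PhosphoSiteSet({4: "S"}), p)
        return [
            (exp1, run_experiment(exp1, reg)),
            (exp2, run_experiment(exp2, reg)),
        ]

    def test_column_count_is_additive(self):
        matrix = combine(self._pairs())
        assert matrix.columns == [("exp1", 3), ("exp1", 9), ("exp2", 4)]

    def test_rows_are_union_of_labels(self):
        matrix = combine(self._pairs())
        assert matrix.rows == ["E1", "E2"]

    def test_covered_cell_exposes_peptide_sequence(self):
        matrix = combine(self._pairs())
        assert matrix.peptide_at("E1", ("exp1", 3)) == "AGSTNK"

    def test_invariant_to_experiment_order(self):
        fwd = combine(self._pairs())
        rev = combine(list(reversed(self._pairs())))
        assert set(fwd.columns) == set(rev.columns)
        assert fwd.rows == rev.rows
        for col in fwd.columns:
            for row in fwd.rows:
                assert fwd.peptide_at(row, col) == rev.peptide_at(row, col)

    def test_duplicate_experiment_names_rejected(self):
        pairs = self._pairs()
        clash = [(pairs[0][0], pairs[0][1]), (pairs[0][0], pairs[0][1])]
        with pytest.raises(ValueError, match="duplicate experiment"):
            combine(clash)


class TestSelectEnzymes:
    def test_overlapping_cover_example(self):
        matrix = make_matrix({"A": {1, 2}, "B": {2, 3}, "C": {3}}, 3)
        selected, residual = select_enzymes(matrix)
        assert set(selected) == {"A", "B"}
        assert residual == []

    def test_single_dominating_row(self):
        matrix = make_matrix({"A": {1, 2, 3}, "B": {1}}, 3)
        selected, residual = select_enzymes(matrix)
        assert selected == ["A"] and residual == []

    def test_uncoverable_column_reported_as_residual(self):
        matrix = make_matrix({"A": {1}}, 2)
        selected, residual = select_enzymes(matrix)
        assert selected == ["A"]
        assert residual == [("exp", 2)]

    def test_tie_broken_lexicographically(self):
        matrix = make_matrix({"B": {1}, "A": {2}}, 2)
        selected, _ = select_enzymes(matrix)
        assert selected == ["A", "B"]

    def test_greedy_against_exhaustive_oracle(self):
        """Randomised matrices up to 10x10: greedy coverage is complete
        and its size within the (1 + ln n) guarantee of optimal."""
        rng = random.Random(2024)
        for _ in range(60):
            n_rows = rng.randint(1, 10)
            n_cols = rng.randint(1, 10)
            cover_map = {
                f"R{i:02d}": {
                    c + 1 for c in range(n_cols) if rng.random() < 0.35
                }
                for i in range(n_rows)
            }
            matrix = make_matrix(cover_map, n_cols)
            selected, residual = select_enzymes(matrix)
            coverable = set().union(*cover_map.values(), set())
            greedy_cover = set().union(
                *(cover_map[r] for r in selected), set()
            )
            assert greedy_cover == coverable
            assert {c[1] for c in residual} == (
                set(range(1, n_cols + 1)) - coverable
            )
            if coverable:
                opt = exhaustive_min_cover(cover_map, coverable)
                bound = opt * (1 + math.log(n_cols))
                assert len(selected) <= bound


class TestExports:
    def test_csv_cells_match_matrix_bijectively(self):
        rng = random.Random(7)
        cover_map = {
            f"R{i}": {c + 1 for c in range(6) if rng.random() < 0.5}
            for i in range(4)
        }
        matrix = make_matrix(cover_map, 6)
        parsed = list(csv.reader(io.StringIO(export_matrix_csv(matrix))))
        header, *rows = parsed
        assert header[1:] == [matrix.column_label(c) for c in matrix.columns]
        assert [r[0] for r in rows] == matrix.rows
        for row in rows:
            for cell, col in zip(row[1:], matrix.columns):
                assert (cell == "Y") == matrix.is_covered(row[0], col)

    def test_csv_row_subset_drops_other_rows(self):
        matrix = make_matrix({"A": {1}, "B": {1}, "C": set()}, 1)
        parsed = list(
            csv.reader(io.StringIO(export_matrix_csv(matrix, ["B"])))
        )
        assert [r[0] for r in parsed[1:]] == ["B"]

    def test_minimal_matrix_csv(self):
        matrix = make_matrix({"OnlyEnzyme": {1}}, 1)
        text = export_matrix_csv(matrix)
        lines = text.strip().split("\n")
        assert len(lines) == 2
        assert '"Y"' in lines[1]

    def test_datasheet_fields_and_round_trip(self):
        reg = make_registry(EnzymeRule("E1", "K", 1))
        params = DigestParams()
        exp = Experiment(
            "AKT-like - S9", "P1",
            "AGSTNKQRSTWAGSTNKQRSTW",
            PhosphoSiteSet({9: "S"}), params,
            search_term="akt", matched_protein="AKT-like kinase",
        )
        results = run_experiment(exp, reg)
        sheet = export_datasheet(exp, results)
        for key in (
            "experimentName", "searchTerm", "matchedProtein",
            "fragmentFilterCriterion", "peptideLengthCriterion",
            "targetSequenceHighlighted", "qualifyingEnzymes",
        ):
            assert key in sheet
        assert sheet["experimentName"] == exp.name
        assert sheet["searchTerm"] == "akt"
        assert sheet["peptideLengthCriterion"] == {
            "peptideLenMin": 5, "peptideLenMax": 30,
        }
        assert sheet["fragmentFilterCriterion"]["exclusionChars"] == ["C", "M"]
        assert " [S] " in sheet["targetSequenceHighlighted"]
        # JSON round-trip preserves every value
        assert json.loads(json.dumps(sheet)) == sheet

    def test_datasheet_with_no_qualifying_enzymes_is_valid(self):
        reg = make_registry(EnzymeRule("never", "W", 1))
        params = DigestParams(require_all_sites=True)
        exp = Experiment(
            "empty", "P1", "AGSTNAGSTNAGSTN",
            PhosphoSiteSet({3: "S"}), params,
        )
        results = run_experiment(exp, reg)
        # single uncut peptide of length 15 passes filters and covers the
        # site, so force failure with an impossible length window instead
        params2 = DigestParams(len_min=1, len_max=2,
                               excluded_residues=frozenset(),
                               require_all_sites=True)
        exp2 = Experiment("empty2", "P1", "AGSTNAGSTNAGSTN",
                          PhosphoSiteSet({3: "S"}), params2)
        results2 = run_experiment(exp2, reg)
        sheet = export_datasheet(exp2, results2)
        assert sheet["qualifyingEnzymes"] == []
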