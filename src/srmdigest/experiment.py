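"""Batch experiments, coverage matrices, and enzyme-panel selection.

An *experiment* pairs a protein sequence with target sites and digest
parameters.  Running an experiment digests the protein once per enzyme
(or per unordered enzyme pair in pairwise mode), filters the peptides,
and records which target sites each digest covers.  Results from many
experiments combine into a single enzymes-by-sites coverage matrix —
the view an assay designer scans to pick a minimal enzyme panel that
covers every monitored site across every protein.

"Most appropriate combination of enzymes" is formalised as
minimum-cardinality set cover, solved greedily (largest remaining
coverage first, ties broken by label) with deterministic output.
Columns no enzyme can cover are reported as residual, never dropped.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

from .digest import Peptide, PhosphoSiteSet, digest
from .filters import DigestParams, SiteCoverage, apply_filters, enzyme_qualifies, site_coverage
from .props import PeptideProperties, RtCoefficients, compute_properties, highlight
from .rules import EnzymeRule, RuleRegistry

__all__ = [
    "Experiment",
    "DigestResult",
    "CoverageMatrix",
    "run_experiment",
    "combine",
    "select_enzymes",
    "export_matrix_csv",
    "export_datasheet",
    "PAIR_SEPARATOR",
]

#: Row-label separator for two-enzyme digests.
PAIR_SEPARATOR = " + "


@dataclass(frozen=True)
class Experiment:
    """A named digest task: protein, target sites, and parameters."""

    name: str
    protein_id: str
    sequence: str
    target_sites: PhosphoSiteSet
    params: DigestParams = field(default_factory=DigestParams)
    search_term: str = ""
    matched_protein: str = ""

    def __post_init__(self) -> None:
        # Re-validating the sites against this sequence catches mismatched
        # coordinates before any digest runs.
        PhosphoSiteSet(
            {p: self.target_sites.residue(p) for p in self.target_sites},
            sequence=self.sequence,
        )


@dataclass
class DigestResult:
    """Outcome of one enzyme (or pair) applied to one experiment."""

    enzymes: tuple[str, ...]
    peptides: list[tuple[Peptide, PeptideProperties]]
    coverage: SiteCoverage
    qualified: bool
    n_raw: int = 0  # peptide count before filtering, for run logs

    @property
    def label(self) -> str:
        return PAIR_SEPARATOR.join(self.enzymes)


def run_experiment(
    exp: Experiment,
    registry: RuleRegistry,
    rt_coeffs: RtCoefficients | None = None,
    include_singles_with_pairs: bool = False,
) -> list[DigestResult]:
    """Digest an experiment's protein with every enzyme (or enzyme pair).

    In pairwise mode each unordered pair is a simultaneous double
    digest; ``include_singles_with_pairs`` additionally runs each enzyme
    alone.  Each result carries filtered peptides with their property
    blocks, the per-site coverage, and the qualification verdict.
    """
    if len(registry) == 0:
        raise ValueError("empty enzyme registry")
    rule_sets: list[tuple[EnzymeRule, ...]]
    if exp.params.pairwise:
        rule_sets = [tuple(pair) for pair in combinations(registry, 2)]
        if include_singles_with_pairs:
            rule_sets = [(r,) for r in registry] + rule_sets
    else:
        rule_sets = [(r,) for r in registry]

    results = []
    for rules in rule_sets:
        peptides = digest(
            exp.sequence,
            list(rules),
            phospho=exp.target_sites,
            phospho_aware=exp.params.phospho_aware,
            parent_id=exp.protein_id,
        )
        kept = apply_filters(peptides, exp.params)
        coverage = site_coverage(kept, exp.target_sites)
        results.append(
            DigestResult(
                enzymes=tuple(r.name for r in rules),
                peptides=[
                    (p, compute_properties(p, exp.target_sites, rt_coeffs))
                    for p in kept
                ],
                coverage=coverage,
                qualified=enzyme_qualifies(coverage, exp.params),
                n_raw=len(peptides),
            )
        )
    return results


@dataclass
class CoverageMatrix:
    """Enzymes x (experiment, site) coverage grid.

    Rows are enzyme (or enzyme-pair) labels; columns are
    ``(experiment_name, site_position)`` pairs ordered by experiment
    then site.  Each covered cell records the covering peptide's
    sequence so the designer can inspect the actual SRM candidate.
    """

    rows: list[str]
    columns: list[tuple[str, int]]
    cells: dict[tuple[str, tuple[str, int]], str | None]
    column_proteins: dict[tuple[str, int], str] = field(default_factory=dict)

    def peptide_at(self, row: str, column: tuple[str, int]) -> str | None:
        return self.cells.get((row, column))

    def is_covered(self, row: str, column: tuple[str, int]) -> bool:
        return self.cells.get((row, column)) is not None

    def covered_columns(self, row: str) -> set[tuple[str, int]]:
        return {c for c in self.columns if self.is_covered(row, c)}

    def column_label(self, column: tuple[str, int]) -> str:
        name = self.column_proteins.get(column, column[0])
        return f"{name}:{column[1]}"


def combine(
    experiment_results: Sequence[tuple[Experiment, Sequence[DigestResult]]],
) -> CoverageMatrix:
    """Merge per-experiment digest results into one coverage matrix.

    Row set = union of enzyme labels across experiments (sorted for a
    stable report); enzyme/experiment combinations absent from the input
    are uncovered.  Invariant to experiment input order up to column
    ordering.
    """
    if not experiment_results:
        raise ValueError("combine requires at least one experiment")
    names = [exp.name for exp, _ in experiment_results]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate experiment names: {dupes}")

    columns: list[tuple[str, int]] = []
    column_proteins: dict[tuple[str, int], str] = {}
    for exp, _ in experiment_results:
        for site in sorted(exp.target_sites):
            col = (exp.name, site)
            columns.append(col)
            column_proteins[col] = exp.protein_id or exp.name

    rows = sorted(
        {res.label for _, results in experiment_results for res in results}
    )
    cells: dict[tuple[str, tuple[str, int]], str | None] = {
        (row, col): None for row in rows for col in columns
    }
    for exp, results in experiment_results:
        for res in results:
            for site in res.coverage.sites:
                pep = res.coverage.covering[site]
                if pep is not None:
                    cells[(res.label, (exp.name, site))] = pep.sequence
    return CoverageMatrix(rows, columns, cells, column_proteins)


def select_enzymes(
    matrix: CoverageMatrix,
) -> tuple[list[str], list[tuple[str, int]]]:
    """Greedy set cover over the matrix rows.

    Repeatedly picks the row covering the most still-uncovered columns
    (lexicographically smallest label on ties) until no row adds
    coverage.  Returns the selected labels in pick order plus the
    residual columns no selected row covers.
    """
    uncovered = set(matrix.columns)
    selected: list[str] = []
    remaining = list(matrix.rows)
    while uncovered and remaining:
        gains = {
            row: len(matrix.covered_columns(row) & uncovered)
            for row in remaining
        }
        best_gain = max(gains.values())
        if best_gain == 0:
            break
        best = min(row for row, g in gains.items() if g == best_gain)
        selected.append(best)
        remaining.remove(best)
        uncovered -= matrix.covered_columns(best)
    residual = [c for c in matrix.columns if c in uncovered]
    return selected, residual


def export_matrix_csv(
    matrix: CoverageMatrix, selected_rows: Sequence[str] | None = None
) -> str:
    """Spreadsheet-ready Y/N matrix grouped by enzyme.

    The header lists ``protein:site`` column labels; each subsequent row
    is one enzyme with "Y" for covered cells and "N" otherwise.  Passing
    ``selected_rows`` restricts the report to those enzymes.
    """
    rows = matrix.rows if selected_rows is None else [
        r for r in sorted(selected_rows) if r in set(matrix.rows)
    ]
    buf = io.StringIO()
    writer = csv.writer(buf, quoting=csv.QUOTE_ALL, lineterminator="\n")
    writer.writerow(["Enzyme", *(matrix.column_label(c) for c in matrix.columns)])
    for row in sorted(rows):
        writer.writerow(
            [row]
            + ["Y" if matrix.is_covered(row, c) else "N" for c in matrix.columns]
        )
    return buf.getvalue()


def _props_dict(pep: Peptide, props: PeptideProperties) -> dict:
    return {
        "indexStart": pep.start,
        "indexEnd": pep.end,
        "sequence": pep.sequence,
        "sequenceHighlighted": props.highlighted,
        "length": props.length,
        "charge": props.charge,
        "massPhospho": round(props.mass_phospho, 5),
        "massNonPhospho": round(props.mass_nonphospho, 5),
        "mzPhospho": round(props.mz_phospho, 5),
        "mzNonPhospho": round(props.mz_nonphospho, 5),
        "percentageHydrophobic": props.pct_hydrophobic,
        "retentionTime": round(props.retention_time, 2),
    }


def export_datasheet(
    exp: Experiment, results: Sequence[DigestResult]
) -> dict:
    """Structured per-experiment report (JSON-serialisable).

    Carries the experiment metadata — name, search term, matched
    protein, the residue-exclusion and length criteria, the target
    sequence with modified residues highlighted — plus the qualifying
    enzymes and the full property block of every passing peptide.
    """
    qualifying = [res for res in results if res.qualified]
    return {
        "experimentName": exp.name,
        "searchTerm": exp.search_term,
        "matchedProtein": exp.matched_protein or exp.protein_id,
        "fragmentFilterCriterion": {
            "exclusionChars": sorted(exp.params.excluded_residues),
        },
        "peptideLengthCriterion": {
            "peptideLenMin": exp.params.len_min,
            "peptideLenMax": exp.params.len_max,
        },
        "targetSequenceHighlighted": highlight(
            exp.sequence, 1, exp.target_sites
        ),
        "qualifyingEnzymes": [res.label for res in qualifying],
        "digests": [
            {
                "enzymes": list(res.enzymes),
                "qualified": res.qualified,
                "coveredSites": res.coverage.covered_sites,
                "peptides": [
                    _props_dict(pep, props) for pep, props in res.peptides
                ],
            }
            for res in results
        ],
    }
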