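"""Peptide filtering and target-site coverage.

Digest output is screened with two per-peptide predicates — a length
window and a problematic-residue exclusion list (default: no M or C,
which complicate synthesis and oxidise unpredictably) — and the
surviving peptides are intersected with the experiment's target sites
to decide whether an enzyme qualifies for the assay.

An enzyme covers a site when some passing peptide spans it.  With
``require_all_sites`` the enzyme must cover every target site to be
listed; otherwise covering any site is enough (partial panels are often
useful when sites are far apart).  A stricter single-peptide reading —
all sites inside one peptide — is available via
``sites_in_single_peptide`` for experiments with clustered sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .digest import Peptide, PhosphoSiteSet

__all__ = [
    "DigestParams",
    "SiteCoverage",
    "apply_filters",
    "site_coverage",
    "enzyme_qualifies",
    "sites_in_single_peptide",
]

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DigestParams:
    """The per-experiment digest parameter set.

    Defaults correspond to a typical phospho-SRM design: peptide length
    5-30, exclude M and C, suppress cleavage next to modified residues,
    single-enzyme digests, and allow partially covering enzymes.
    """

    len_min: int = 5
    len_max: int = 30
    excluded_residues: frozenset[str] = frozenset("MC")
    phospho_aware: bool = True
    pairwise: bool = False
    require_all_sites: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.len_min <= self.len_max:
            raise ValueError(
                f"invalid length window [{self.len_min}, {self.len_max}]"
            )
        excl = frozenset(r.upper() for r in self.excluded_residues)
        bad = excl - AMINO_ALPHABET
        if bad:
            raise ValueError(f"excluded residues not amino acids: {sorted(bad)}")
        object.__setattr__(self, "excluded_residues", excl)


@dataclass
class SiteCoverage:
    """Per-site verdicts: the first passing peptide spanning each site."""

    covering: dict[int, Peptide | None] = field(default_factory=dict)

    @property
    def sites(self) -> list[int]:
        return sorted(self.covering)

    def is_covered(self, site: int) -> bool:
        return self.covering.get(site) is not None

    @property
    def covered_sites(self) -> list[int]:
        return sorted(s for s, p in self.covering.items() if p is not None)

    @property
    def all_covered(self) -> bool:
        return all(p is not None for p in self.covering.values())

    @property
    def any_covered(self) -> bool:
        return any(p is not None for p in self.covering.values())


def apply_filters(peptides: list[Peptide], params: DigestParams) -> list[Peptide]:
    """Keep peptides inside the length window and free of excluded residues.

    Both predicates are per-peptide, so the filter is idempotent and
    order-independent; input order is preserved.
    """
    kept = []
    for pep in peptides:
        if not params.len_min <= len(pep) <= params.len_max:
            continue
        if any(r in params.excluded_residues for r in pep.sequence):
            continue
        kept.append(pep)
    return kept


def site_coverage(
    peptides: list[Peptide], sites: PhosphoSiteSet
) -> SiteCoverage:
    """Which target sites are spanned by a (filtered) peptide.

    Bounds are inclusive: a site equal to a peptide's start or end
    position counts as covered.  The first covering peptide in sequence
    order is recorded.
    """
    coverage = SiteCoverage()
    for s in sites:
        coverage.covering[s] = next(
            (pep for pep in peptides if pep.covers(s)), None
        )
    return coverage


def enzyme_qualifies(coverage: SiteCoverage, params: DigestParams) -> bool:
    """Whether an enzyme's digest should be listed for this experiment.

    Vacuously true when the experiment has no target sites.
    """
    if not coverage.covering:
        return True
    if params.require_all_sites:
        return coverage.all_covered
    return coverage.any_covered


def sites_in_single_peptide(
    peptides: list[Peptide], sites: PhosphoSiteSet
) -> Peptide | None:
    """Strict mode: the first peptide containing *every* target site.

    Returns None when no single peptide spans all sites (or when there
    are no sites at all, making the question ill-posed).
    """
    positions = sorted(sites)
    if not positions:
        return None
    return next(
        (
            pep
            for pep in peptides
            if all(pep.covers(s) for s in positions)
        ),
        None,
    )
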