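"""Cleavage-site finding and peptide generation.

Coordinates are 1-based throughout.  A *cleavage bond* ``b`` denotes the
peptide bond between residue ``b`` and residue ``b+1``; valid bonds lie
in ``1 <= b <= L-1`` for a sequence of length ``L``.  A pattern match
starting at residue ``p`` contributes the bond ``b = p + distance - 1``,
so distance 0 cuts before the matched motif and distance 1 cuts after
its first residue.  Offsets that land on a terminus (``b == 0`` or
``b == L``) are no-ops.

Phosphorylation can shield neighbouring bonds from proteolysis: in
phospho-aware mode every bond flanking a modified residue is removed
from the cleavage set, so the site stays inside one (longer) peptide —
the in-silico analogue of a missed cleavage at a modified residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .rules import VALID_AMINO_ACIDS, EnzymeRule

__all__ = [
    "Peptide",
    "PhosphoSiteSet",
    "find_cleavage_sites",
    "suppress_phospho_adjacent",
    "peptides_from_bonds",
    "digest",
]


@dataclass(frozen=True)
class Peptide:
    """A digest fragment located in its parent protein.

    ``start`` and ``end`` are 1-based inclusive positions in the parent
    sequence, so ``end - start + 1 == len(sequence)``.
    """

    sequence: str
    start: int
    end: int
    parent_id: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"peptide coordinates [{self.start}, {self.end}] do not "
                f"match sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def covers(self, position: int) -> bool:
        """Whether a 1-based parent position falls inside this peptide."""
        return self.start <= position <= self.end


class PhosphoSiteSet:
    """Modified residue positions (1-based) with their residue letters.

    Construct from a mapping ``{position: residue}`` or an iterable of
    positions (residue letters then unchecked).  When a parent sequence
    is supplied, each annotated letter is validated against it.
    """

    def __init__(
        self,
        sites: Mapping[int, str] | Iterable[int] = (),
        sequence: str | None = None,
    ) -> None:
        if isinstance(sites, Mapping):
            self._sites = {int(p): r.upper() for p, r in sites.items()}
        else:
            self._sites = {int(p): "" for p in sites}
        for pos, res in self._sites.items():
            if pos < 1:
                raise ValueError(f"phospho position {pos} is not positive")
            if sequence is not None:
                if pos > len(sequence):
                    raise ValueError(
                        f"phospho position {pos} beyond sequence length "
                        f"{len(sequence)}"
                    )
                if res and sequence[pos - 1] != res:
                    raise ValueError(
                        f"phospho site {res}{pos} does not match sequence "
                        f"residue {sequence[pos - 1]!r} at that position"
                    )

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(self._sites)

    def residue(self, position: int) -> str:
        return self._sites[position]

    def in_range(self, start: int, end: int) -> list[int]:
        """Sorted positions falling within [start, end] inclusive."""
        return sorted(p for p in self._sites if start <= p <= end)

    def __len__(self) -> int:
        return len(self._sites)

    def __contains__(self, position: int) -> bool:
        return position in self._sites

    def __iter__(self):
        return iter(sorted(self._sites))

    def __repr__(self) -> str:
        inner = ", ".join(f"{self._sites[p]}{p}" for p in sorted(self._sites))
        return f"PhosphoSiteSet({{{inner}}})"


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty protein sequence")
    bad = set(sequence) - VALID_AMINO_ACIDS
    if bad:
        raise ValueError(
            f"sequence contains non-amino-acid characters: {sorted(bad)}"
        )


def find_cleavage_sites(sequence: str, rule: EnzymeRule) -> frozenset[int]:
    """All cleavage bonds a rule produces on a sequence.

    Every start position is probed independently, so overlapping motif
    occurrences (e.g. consecutive lysines under a ``K`` rule) each
    contribute their own cut.  Bonds falling on a terminus are dropped.
    """
    _check_sequence(sequence)
    regex = rule.compiled()
    L = len(sequence)
    bonds = set()
    for p0 in range(L):  # p0 is the 0-based start; 1-based p = p0 + 1
        if regex.match(sequence, p0) is not None:
            b = p0 + rule.distance_to_cleavage  # == p + distance - 1
            if 1 <= b <= L - 1:
                bonds.add(b)
    return frozenset(bonds)


def suppress_phospho_adjacent(
    bonds: Iterable[int], phospho: PhosphoSiteSet
) -> frozenset[int]:
    """Drop every bond flanking a modified residue.

    A phosphorylated residue at position ``s`` shields the bonds
    ``s - 1`` (N-terminal side) and ``s`` (C-terminal side).  Idempotent
    and antitone: the result is always a subset of the input.
    """
    shielded = set()
    for s in phospho.positions:
        shielded.add(s - 1)
        shielded.add(s)
    return frozenset(b for b in bonds if b not in shielded)


def peptides_from_bonds(
    sequence: str, bonds: Iterable[int], parent_id: str = ""
) -> list[Peptide]:
    """Partition a sequence at the given bonds into ordered peptides.

    The fragments tile the parent: their concatenation in order equals
    the input sequence, and the count is ``len(bonds) + 1``.
    """
    _check_sequence(sequence)
    L = len(sequence)
    cuts = sorted(set(bonds))
    if cuts and not (1 <= cuts[0] and cuts[-1] <= L - 1):
        raise ValueError(f"bond out of range 1..{L - 1}: {cuts}")
    edges = [0, *cuts, L]
    return [
        Peptide(sequence[a:b], a + 1, b, parent_id)
        for a, b in zip(edges, edges[1:])
    ]


def digest(
    sequence: str,
    rules: EnzymeRule | Sequence[EnzymeRule],
    phospho: PhosphoSiteSet | None = None,
    phospho_aware: bool = False,
    parent_id: str = "",
) -> list[Peptide]:
    """Digest a sequence with one enzyme or a simultaneous pair.

    A two-enzyme digest is modelled as the union of the two single
    digests' cleavage bonds (a simultaneous double digest, no ordering).
    With ``phospho_aware`` set, bonds adjacent to modified residues are
    suppressed before peptides are formed.
    """
    if isinstance(rules, EnzymeRule):
        rules = [rules]
    if not 1 <= len(rules) <= 2:
        raise ValueError(f"digest requires one or two enzymes, got {len(rules)}")
    if len(rules) == 2 and rules[0].name == rules[1].name:
        raise ValueError(f"duplicate enzyme in pair: {rules[0].name!r}")
    bonds: set[int] = set()
    for rule in rules:
        bonds |= find_cleavage_sites(sequence, rule)
    if phospho_aware and phospho is not None:
        bonds = set(suppress_phospho_adjacent(bonds, phospho))
    return peptides_from_bonds(sequence, bonds, parent_id)
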