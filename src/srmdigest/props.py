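"""Physicochemical properties of digest peptides.

For every candidate peptide the reporting layer needs the detail block
used in transition design: monoisotopic masses of the phosphorylated and
unmodified forms, m/z at a predicted charge, the percentage of
hydrophobic residues, a predicted retention time, and a display string
with the modified residues bracketed.

Masses are monoisotopic.  A phosphoryl group adds the HPO3 increment
(79.96633 Da) per modified residue; m/z is ``(M + z * m_proton) / z``.
The charge heuristic counts protonation sites (N-terminus plus K/R/H
side chains) and is deliberately replaceable — it names the convention,
not chemistry ground truth.  Retention time uses an additive per-residue
coefficient model; the bundled coefficient table is a generic C18/pH-2
calibration and should be refit for a specific gradient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .digest import Peptide, PhosphoSiteSet

__all__ = [
    "PeptideProperties",
    "RtCoefficients",
    "WATER_MONO",
    "PHOSPHO_MONO",
    "PROTON_MASS",
    "RESIDUE_MASSES",
    "HYDROPHOBIC_RESIDUES",
    "monoisotopic_mass",
    "predict_charge",
    "mz",
    "hydrophobic_percent",
    "retention_time",
    "highlight",
    "compute_properties",
    "load_rt_coefficients",
]


def _load_mass_table() -> dict:
    path = resources.files("srmdigest").joinpath("data", "residue_masses.json")
    return json.loads(path.read_text())


_MASS_DATA = _load_mass_table()
RESIDUE_MASSES: dict[str, float] = dict(_MASS_DATA["residues"])
WATER_MONO: float = _MASS_DATA["water"]
PHOSPHO_MONO: float = _MASS_DATA["phospho"]
PROTON_MASS: float = _MASS_DATA["proton"]

#: Residues counted as hydrophobic for the percentage report.
HYDROPHOBIC_RESIDUES = frozenset("AVLIMFW")

#: Residues that can carry a phosphoryl group.
PHOSPHORYLATABLE = frozenset("STY")

#: Basic residues assumed protonated alongside the N-terminus.
BASIC_RESIDUES = frozenset("KRH")


@dataclass(frozen=True)
class RtCoefficients:
    """Additive retention model: intercept + sum of residue coefficients."""

    intercept: float
    coefficients: dict[str, float]

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.coefficients)
        if missing:
            raise ValueError(
                f"retention coefficients missing for residues {sorted(missing)}"
            )


def load_rt_coefficients(path: str | Path | None = None) -> RtCoefficients:
    """Load a retention coefficient table (bundled default when omitted)."""
    if path is None:
        src = resources.files("srmdigest").joinpath("data", "rt_coefficients.json")
        payload = json.loads(src.read_text())
    else:
        payload = json.loads(Path(path).read_text())
    return RtCoefficients(
        intercept=float(payload["intercept"]),
        coefficients={k: float(v) for k, v in payload["coefficients"].items()},
    )


_DEFAULT_RT = load_rt_coefficients()


def _check_peptide(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty peptide sequence")
    bad = set(sequence) - set(RESIDUE_MASSES)
    if bad:
        raise ValueError(f"unknown residue letters: {sorted(bad)}")


def monoisotopic_mass(sequence: str, n_phospho: int = 0) -> float:
    """Monoisotopic peptide mass in Da with ``n_phospho`` HPO3 groups."""
    _check_peptide(sequence)
    if n_phospho < 0:
        raise ValueError("n_phospho must be non-negative")
    n_sites = sum(sequence.count(r) for r in PHOSPHORYLATABLE)
    if n_phospho > n_sites:
        raise ValueError(
            f"{n_phospho} phospho groups exceed the {n_sites} "
            f"phosphorylatable (S/T/Y) residues in {sequence!r}"
        )
    residue_sum = sum(RESIDUE_MASSES[r] for r in sequence)
    return residue_sum + WATER_MONO + n_phospho * PHOSPHO_MONO


def predict_charge(sequence: str) -> int:
    """Predicted positive charge: N-terminus plus one per K/R/H."""
    _check_peptide(sequence)
    return 1 + sum(1 for r in sequence if r in BASIC_RESIDUES)


def mz(mass: float, charge: int) -> float:
    """Mass-to-charge ratio ``(M + z * m_proton) / z`` for charge z >= 1."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * PROTON_MASS) / charge


def hydrophobic_percent(sequence: str) -> float:
    """Percentage of A/V/L/I/M/F/W residues, to one decimal place."""
    _check_peptide(sequence)
    count = sum(1 for r in sequence if r in HYDROPHOBIC_RESIDUES)
    return round(100.0 * count / len(sequence), 1)


def retention_time(sequence: str, coeffs: RtCoefficients | None = None) -> float:
    """Predicted retention time in minutes under the additive model.

    Modification-blind: phosphorylation does not change the prediction.
    """
    _check_peptide(sequence)
    coeffs = _DEFAULT_RT if coeffs is None else coeffs
    return coeffs.intercept + sum(coeffs.coefficients[r] for r in sequence)


def highlight(
    sequence: str, peptide_start: int, phospho: PhosphoSiteSet
) -> str:
    """Render a peptide with modified residues bracketed: ``MK [T] F``.

    ``peptide_start`` is the peptide's 1-based position in the parent;
    phospho positions are in parent coordinates.  Adjacent modified
    residues share a single separating space.
    """
    _check_peptide(sequence)
    local = {
        p - peptide_start for p in phospho.in_range(
            peptide_start, peptide_start + len(sequence) - 1
        )
    }
    for i in local:
        annotated = phospho.residue(i + peptide_start)
        if annotated and sequence[i] != annotated:
            raise ValueError(
                f"phospho residue {annotated!r} at parent position "
                f"{i + peptide_start} does not match peptide residue "
                f"{sequence[i]!r}"
            )
    parts = [
        f" [{res}] " if i in local else res for i, res in enumerate(sequence)
    ]
    text = "".join(parts)
    while "  " in text:
        text = text.replace("  ", " ")
    return text.strip()


@dataclass(frozen=True)
class PeptideProperties:
    """The per-peptide detail block reported for assay design."""

    length: int
    mass_nonphospho: float
    mass_phospho: float
    mz_nonphospho: float
    mz_phospho: float
    charge: int
    pct_hydrophobic: float
    retention_time: float
    highlighted: str
    n_phospho: int


def compute_properties(
    peptide: Peptide,
    phospho: PhosphoSiteSet,
    rt_coeffs: RtCoefficients | None = None,
) -> PeptideProperties:
    """Assemble the full property block for one located peptide."""
    seq = peptide.sequence
    n_mod = len(phospho.in_range(peptide.start, peptide.end))
    m0 = monoisotopic_mass(seq, 0)
    mp = m0 + n_mod * PHOSPHO_MONO
    z = predict_charge(seq)
    return PeptideProperties(
        length=len(seq),
        mass_nonphospho=m0,
        mass_phospho=mp,
        mz_nonphospho=mz(m0, z),
        mz_phospho=mz(mp, z),
        charge=z,
        pct_hydrophobic=hydrophobic_percent(seq),
        retention_time=retention_time(seq, rt_coeffs),
        highlighted=highlight(seq, peptide.start, phospho),
        n_phospho=n_mod,
    )
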