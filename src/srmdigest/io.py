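"""File formats: FASTA input, sites tables, XML digest reports, run configs.

The XML report dialect nests ``DigestResults`` → ``digest`` →
``enzyme`` / ``peptide`` elements, each peptide carrying
``indexEnd``, ``sequenceHighlighted``, ``molecularWeight``,
``percentageSolubility``, ``retentionTime``, ``sequence`` and
``indexStart`` children, with the parent sequence as a trailing
element.  Masses are written to five decimals, percentages to one, and
retention times to two; ``parse_digest_xml`` round-trips the writer's
output to equal values at those precisions.

Phosphorylation-site annotations arrive as a local tab-separated table
(protein_id, position, residue, modification) standing in for a live
modification-database lookup.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence
from xml.etree import ElementTree as ET

from Bio import SeqIO

from .digest import PhosphoSiteSet
from .experiment import DigestResult
from .filters import AMINO_ALPHABET, DigestParams

__all__ = [
    "SiteRecord",
    "SitesTable",
    "RunConfig",
    "read_fasta",
    "read_sites_table",
    "write_digest_xml",
    "parse_digest_xml",
    "params_to_config",
    "params_from_config",
    "load_run_config",
]


def read_fasta(path: str | Path, strict: bool = True) -> dict[str, str]:
    """Read FASTA records into an ordered ``{record_id: sequence}`` map.

    Sequences are uppercased.  Under ``strict`` any letter outside the
    standard 20-residue alphabet (U, B, Z, X, ...) is an error naming
    the record and position; otherwise offending records are dropped.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path.name}: duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = next(
            ((i, ch) for i, ch in enumerate(seq, 1) if ch not in AMINO_ALPHABET),
            None,
        )
        if bad is not None:
            if strict:
                raise ValueError(
                    f"{path.name}: record {rec.id!r} has illegal residue "
                    f"{bad[1]!r} at position {bad[0]}"
                )
            continue
        records[rec.id] = seq
    if not records:
        raise ValueError(f"{path.name}: no usable FASTA records")
    return records


@dataclass(frozen=True)
class SiteRecord:
    protein_id: str
    position: int
    residue: str
    modification: str = "phospho"


@dataclass
class SitesTable:
    """Validated per-protein modification-site annotations."""

    records: list[SiteRecord] = field(default_factory=list)

    def for_protein(
        self, protein_id: str, sequence: str | None = None
    ) -> PhosphoSiteSet:
        sites = {
            r.position: r.residue
            for r in self.records
            if r.protein_id == protein_id
        }
        return PhosphoSiteSet(sites, sequence=sequence)

    def proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.protein_id, None)
        return list(seen)


_SITE_COLUMNS = ["protein_id", "position", "residue", "modification"]


def read_sites_table(
    path: str | Path, sequences: Mapping[str, str] | None = None
) -> SitesTable:
    """Read a tab-separated sites table and validate it.

    Requires the header ``protein_id  position  residue  modification``.
    Positions must be positive integers; duplicate (protein, position)
    rows are rejected; when ``sequences`` is given, each residue letter
    is cross-checked against the referenced sequence.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or [
            f.strip() for f in reader.fieldnames
        ] != _SITE_COLUMNS:
            raise ValueError(
                f"{path.name}: expected header {_SITE_COLUMNS}, "
                f"got {reader.fieldnames}"
            )
        seen: set[tuple[str, int]] = set()
        records = []
        for lineno, row in enumerate(reader, 2):
            pid = row["protein_id"].strip()
            try:
                pos = int(row["position"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path.name}:{lineno}: non-numeric position "
                    f"{row['position']!r}"
                ) from None
            if pos < 1:
                raise ValueError(f"{path.name}:{lineno}: position {pos} < 1")
            residue = row["residue"].strip().upper()
            if residue not in AMINO_ALPHABET:
                raise ValueError(
                    f"{path.name}:{lineno}: invalid residue {residue!r}"
                )
            key = (pid, pos)
            if key in seen:
                raise ValueError(
                    f"{path.name}:{lineno}: duplicate site ({pid}, {pos})"
                )
            seen.add(key)
            if sequences is not None and pid in sequences:
                seq = sequences[pid]
                if pos > len(seq):
                    raise ValueError(
                        f"{path.name}:{lineno}: position {pos} beyond "
                        f"{pid} length {len(seq)}"
                    )
                if seq[pos - 1] != residue:
                    raise ValueError(
                        f"{path.name}:{lineno}: residue {residue} at "
                        f"{pid}:{pos} does not match sequence residue "
                        f"{seq[pos - 1]}"
                    )
            records.append(
                SiteRecord(pid, pos, residue, row["modification"].strip())
            )
    return SitesTable(records)


def write_digest_xml(results: Sequence[DigestResult], sequence: str) -> str:
    """Serialise digest results to the XML report dialect."""
    root = ET.Element("DigestResults")
    for res in results:
        dig = ET.SubElement(root, "digest")
        for name in res.enzymes:
            ET.SubElement(dig, "enzyme").text = name
        for pep, props in res.peptides:
            p = ET.SubElement(dig, "peptide")
            ET.SubElement(p, "indexEnd").text = str(pep.end)
            ET.SubElement(p, "sequenceHighlighted").text = props.highlighted
            ET.SubElement(p, "molecularWeight").text = f"{props.mass_phospho:.5f}"
            ET.SubElement(p, "percentageSolubility").text = (
                f"{props.pct_hydrophobic:.1f}"
            )
            ET.SubElement(p, "retentionTime").text = f"{props.retention_time:.2f}"
            ET.SubElement(p, "sequence").text = pep.sequence
            ET.SubElement(p, "indexStart").text = str(pep.start)
    ET.SubElement(root, "sequence").text = sequence
    ET.indent(root)
    return ET.tostring(root, encoding="unicode") + "\n"


def parse_digest_xml(text: str) -> dict:
    """Parse a digest report back into plain values (round-trip check)."""
    root = ET.fromstring(text)
    if root.tag != "DigestResults":
        raise ValueError(f"unexpected root element <{root.tag}>")
    digests = []
    for dig in root.findall("digest"):
        peptides = []
        for p in dig.findall("peptide"):
            peptides.append(
                {
                    "indexStart": int(p.findtext("indexStart")),
                    "indexEnd": int(p.findtext("indexEnd")),
                    "sequence": p.findtext("sequence") or "",
                    "sequenceHighlighted": p.findtext("sequenceHighlighted")
                    or "",
                    "molecularWeight": float(p.findtext("molecularWeight")),
                    "percentageSolubility": float(
                        p.findtext("percentageSolubility")
                    ),
                    "retentionTime": float(p.findtext("retentionTime")),
                }
            )
        digests.append(
            {
                "enzymes": [e.text for e in dig.findall("enzyme")],
                "peptides": peptides,
            }
        )
    return {"digests": digests, "sequence": root.findtext("sequence") or ""}


# Mapping between DigestParams fields and the external parameter names
# used in run configs.
_PARAM_NAMES = {
    "len_min": "peptideLenMin",
    "len_max": "peptideLenMax",
    "phospho_aware": "ignoreCleavAtPhosSite",
    "pairwise": "usePairWiseEnzymeDigest",
    "require_all_sites": "peptideMustHaveAllResidues",
}


def params_to_config(params: DigestParams) -> dict:
    out = {ext: getattr(params, attr) for attr, ext in _PARAM_NAMES.items()}
    out["exclusionChars"] = sorted(params.excluded_residues)
    return out


def params_from_config(payload: Mapping) -> DigestParams:
    kwargs = {
        attr: payload[ext]
        for attr, ext in _PARAM_NAMES.items()
        if ext in payload
    }
    if "exclusionChars" in payload:
        kwargs["excluded_residues"] = frozenset(payload["exclusionChars"])
    return DigestParams(**kwargs)


@dataclass
class RunConfig:
    """A batch run: input paths, experiments, parameters, enzyme subset."""

    fasta: Path
    sites: Path
    experiments: list[dict]
    params: DigestParams = field(default_factory=DigestParams)
    enzymes: list[str] | None = None

    @property
    def experiment_names(self) -> list[str]:
        return [e["name"] for e in self.experiments]


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run config.

    Schema: ``fasta`` and ``sites`` paths (relative to the config file),
    an ``experiments`` list of ``{name, record, sites?}`` entries
    (``sites`` omitted or "all" uses every annotated site for the
    record, otherwise a list of positions), optional ``params`` under
    the external parameter names, and an optional ``enzymes`` subset.
    """
    path = Path(path)
    payload = json.loads(path.read_text())
    for key in ("fasta", "sites", "experiments"):
        if key not in payload:
            raise ValueError(f"{path.name}: missing required key {key!r}")
    experiments = payload["experiments"]
    if not isinstance(experiments, list) or not experiments:
        raise ValueError(f"{path.name}: experiments must be a non-empty list")
    for i, entry in enumerate(experiments):
        if "name" not in entry or "record" not in entry:
            raise ValueError(
                f"{path.name}: experiment #{i + 1} needs 'name' and 'record'"
            )
    return RunConfig(
        fasta=(path.parent / payload["fasta"]).resolve(),
        sites=(path.parent / payload["sites"]).resolve(),
        experiments=experiments,
        params=params_from_config(payload.get("params", {})),
        enzymes=payload.get("enzymes"),
    )
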