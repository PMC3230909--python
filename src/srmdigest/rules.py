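"""Enzyme cleavage-rule registry.

A cleavage rule is a regular-expression recognition pattern over the
20-letter amino-acid alphabet plus an integer *distance to cleavage
point*: the offset from the start of a pattern match to the peptide bond
that is cut.  For the pattern ``WKP`` a distance of 0 places the cut
before the W, a distance of 1 between W and K, and so on.  Storing the
specificity as data (XML or JSON, one pattern per enzyme) keeps the
pattern set editable without touching the matching engine.

The bundled registry transcribes the published PeptideCutter
specificities for 34 proteases and chemical cleavage reagents; rules
with exceptions (e.g. trypsin's suppressed cleavage before proline) are
encoded with lookaround constructs inside the single pattern.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator
from xml.etree import ElementTree as ET

__all__ = [
    "EnzymeRule",
    "RuleRegistry",
    "RuleError",
    "validate_rule",
    "load_rules",
    "write_rules",
    "default_rule_path",
]

VALID_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class RuleError(ValueError):
    """Raised for malformed rule files or invalid rule definitions."""


def _pattern_max_width(pattern: str) -> int | None:
    """Maximum number of residues a match of ``pattern`` can consume.

    Lookarounds are zero-width and do not count.  Returns None when the
    width cannot be determined (the bound check is then skipped).
    """
    try:
        parsed = re._parser.parse(pattern)  # type: ignore[attr-defined]
        _, hi = parsed.getwidth()
    except Exception:
        return None
    if hi >= re._constants.MAXREPEAT:  # type: ignore[attr-defined]
        return None
    return hi


@dataclass(frozen=True)
class EnzymeRule:
    """A named cleavage specificity: pattern plus cleavage offset."""

    name: str
    pattern: str
    distance_to_cleavage: int
    description: str = ""

    def compiled(self) -> re.Pattern[str]:
        return re.compile(self.pattern)


def validate_rule(rule: EnzymeRule) -> list[str]:
    """Check a rule against its invariants.

    Returns an empty list when the rule is valid, otherwise a list of
    human-readable violation messages (a verdict, never an exception).
    """
    violations: list[str] = []
    if not rule.name:
        violations.append("empty enzyme name")
    try:
        re.compile(rule.pattern)
    except re.error as exc:
        violations.append(f"pattern does not compile: {exc}")
        return violations
    if rule.distance_to_cleavage < 0:
        violations.append(
            f"distance_to_cleavage is negative ({rule.distance_to_cleavage})"
        )
    else:
        max_width = _pattern_max_width(rule.pattern)
        if max_width is not None and rule.distance_to_cleavage > max_width:
            violations.append(
                f"distance_to_cleavage {rule.distance_to_cleavage} exceeds "
                f"the maximum match length {max_width} of pattern "
                f"{rule.pattern!r}"
            )
    return violations


@dataclass
class RuleRegistry:
    """Ordered, name-unique collection of enzyme rules.

    Iteration order is load order, so every downstream report is
    deterministic for a given rule file.
    """

    _rules: dict[str, EnzymeRule] = field(default_factory=dict)

    def add(self, rule: EnzymeRule) -> None:
        if rule.name in self._rules:
            raise RuleError(f"duplicate enzyme name: {rule.name!r}")
        violations = validate_rule(rule)
        if violations:
            raise RuleError(f"invalid rule {rule.name!r}: " + "; ".join(violations))
        self._rules[rule.name] = rule

    def __iter__(self) -> Iterator[EnzymeRule]:
        return iter(self._rules.values())

    def __len__(self) -> int:
        return len(self._rules)

    def __contains__(self, name: str) -> bool:
        return name in self._rules

    def __getitem__(self, name: str) -> EnzymeRule:
        try:
            return self._rules[name]
        except KeyError:
            raise KeyError(f"unknown enzyme: {name!r}") from None

    def names(self) -> list[str]:
        return list(self._rules)

    def subset(self, names: list[str]) -> "RuleRegistry":
        sub = RuleRegistry()
        for name in names:
            sub.add(self[name])
        return sub

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RuleRegistry):
            return NotImplemented
        return list(self) == list(other)


def default_rule_path() -> Path:
    """Path to the bundled 34-enzyme rule file."""
    return Path(str(resources.files("srmdigest").joinpath("data", "enzymes.xml")))


def _rules_from_xml(text: str, source: str) -> list[EnzymeRule]:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise RuleError(f"{source}: not well-formed XML: {exc}") from exc
    if root.tag != "Enzymes":
        raise RuleError(f"{source}: expected root element <Enzymes>, got <{root.tag}>")
    rules = []
    for i, elem in enumerate(root.findall("Enzyme")):
        name = (elem.findtext("Name") or "").strip()
        pattern = (elem.findtext("Pattern") or "").strip()
        distance = (elem.findtext("DistanceToCleavagePoint") or "").strip()
        description = (elem.findtext("Description") or "").strip()
        if not name:
            raise RuleError(f"{source}: Enzyme entry #{i + 1} has no Name")
        if not pattern:
            raise RuleError(f"{source}: enzyme {name!r} has no Pattern")
        try:
            dist = int(distance)
        except ValueError:
            raise RuleError(
                f"{source}: enzyme {name!r} has non-integer "
                f"DistanceToCleavagePoint {distance!r}"
            ) from None
        rules.append(EnzymeRule(name, pattern, dist, description))
    return rules


def _rules_from_json(text: str, source: str) -> list[EnzymeRule]:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise RuleError(f"{source}: not valid JSON: {exc}") from exc
    entries = payload.get("Enzymes") if isinstance(payload, dict) else payload
    if not isinstance(entries, list):
        raise RuleError(f"{source}: expected a list of enzyme entries")
    rules = []
    for i, entry in enumerate(entries):
        if not isinstance(entry, dict):
            raise RuleError(f"{source}: entry #{i + 1} is not an object")
        missing = {"Name", "Pattern", "DistanceToCleavagePoint"} - entry.keys()
        if missing:
            raise RuleError(
                f"{source}: entry #{i + 1} missing fields {sorted(missing)}"
            )
        rules.append(
            EnzymeRule(
                str(entry["Name"]),
                str(entry["Pattern"]),
                int(entry["DistanceToCleavagePoint"]),
                str(entry.get("Description", "")),
            )
        )
    return rules


def load_rules(path: str | Path | None = None) -> RuleRegistry:
    """Load a rule registry from an XML or JSON rule file.

    With no argument the bundled 34-enzyme default file is loaded.
    Raises :class:`RuleError` naming the offending entry on any schema
    violation, duplicate name, or invalid pattern.
    """
    path = default_rule_path() if path is None else Path(path)
    if not path.exists():
        raise FileNotFoundError(f"rule file not found: {path}")
    text = path.read_text()
    source = path.name
    if text.lstrip().startswith("<"):
        rules = _rules_from_xml(text, source)
    else:
        rules = _rules_from_json(text, source)
    registry = RuleRegistry()
    for rule in rules:
        registry.add(rule)
    return registry


def write_rules(registry: RuleRegistry, path: str | Path) -> None:
    """Serialize a registry to the rule-file format chosen by extension.

    ``.json`` writes the JSON mirror; anything else writes the XML
    dialect.  ``load_rules(write_rules(reg, p))`` round-trips exactly.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "Enzymes": [
                {
                    "Name": r.name,
                    "Pattern": r.pattern,
                    "DistanceToCleavagePoint": r.distance_to_cleavage,
                    "Description": r.description,
                }
                for r in registry
            ]
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    root = ET.Element("Enzymes")
    for r in registry:
        elem = ET.SubElement(root, "Enzyme")
        ET.SubElement(elem, "Name").text = r.name
        ET.SubElement(elem, "Pattern").text = r.pattern
        ET.SubElement(elem, "DistanceToCleavagePoint").text = str(
            r.distance_to_cleavage
        )
        ET.SubElement(elem, "Description").text = r.description
    ET.indent(root)
    path.write_text(ET.tostring(root, encoding="unicode") + "\n")
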