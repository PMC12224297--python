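"""Rule-based assignment of regulator proteins to named subclasses.

Each rule tests a protein's *domain set* (unordered, duplicates collapsed).
A rule matches when at least one of its ``required_any`` domain sets is fully
present, none of its ``forbidden`` domains occur, and — for ``exact`` rules —
the protein carries no domains beyond the matched required set ("solely" those
domains, duplicates allowed). Rules are evaluated in priority order (lower
first, most specific first) and the first match wins; proteins matching no
rule are labelled ``unclassified``.

The shipped default ruleset encodes the SARP family split — small SARPs
(exactly Trans_reg_C + BTAD), medium SARPs (plus NB-ARC), large SARPs (plus a
TPR_10/TPR_12 tetratricopeptide repeat) and SARP-LAL hybrids (AAA_16/AAA_22
ATPase instead of TPRs) — together with LuxR-type, TetR-type and several
single-domain subclasses. Non-SARP definitions are marked editable in the
rules file: they are reasonable domain-level stand-ins, intended to be
replaced by a user's own curation for real-genome work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .domain_hits import RegulatorProtein

__all__ = [
    "SubclassRule",
    "Classification",
    "UNCLASSIFIED",
    "load_ruleset",
    "default_ruleset_path",
    "classify",
    "classify_all",
]

UNCLASSIFIED = "unclassified"

_RULE_FIELDS = {"name", "family", "required_any", "forbidden", "exact", "priority", "editable"}


@dataclass(frozen=True)
class SubclassRule:
    name: str
    family: str
    required_any: tuple[frozenset[str], ...]
    forbidden: frozenset[str] = frozenset()
    exact: bool = False
    priority: int = 0

    def __post_init__(self) -> None:
        if not self.required_any:
            raise ValueError(f"rule {self.name!r}: required_any must be non-empty")
        if any(not s for s in self.required_any):
            raise ValueError(f"rule {self.name!r}: empty required set")

    def matches(self, domain_set: frozenset[str]) -> bool:
        if self.forbidden & domain_set:
            return False
        for req in self.required_any:
            if req <= domain_set:
                if self.exact and domain_set != req:
                    continue
                return True
        return False


@dataclass(frozen=True)
class Classification:
    protein_id: str
    gene_id: str
    subclass: str
    family: str
    matched_rule: str | None = None


def default_ruleset_path() -> Path:
    return Path(__file__).parent / "data" / "subclass_rules.yaml"


def load_ruleset(path: str | Path | None = None) -> list[SubclassRule]:
    """Load and validate a subclass ruleset from YAML (default: shipped file).

    Raises on unknown fields, duplicate rule names and duplicate priorities.
    An empty file yields an empty ruleset (everything unclassified).
    """
    path = default_ruleset_path() if path is None else path
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return []
    raw_rules = doc.get("rules", []) if isinstance(doc, dict) else doc
    rules: list[SubclassRule] = []
    for raw in raw_rules:
        unknown = set(raw) - _RULE_FIELDS
        if unknown:
            raise ValueError(f"rule {raw.get('name')!r}: unknown fields {sorted(unknown)}")
        rules.append(
            SubclassRule(
                name=raw["name"],
                family=raw.get("family", raw["name"]),
                required_any=tuple(frozenset(s) for s in raw["required_any"]),
                forbidden=frozenset(raw.get("forbidden", [])),
                exact=bool(raw.get("exact", False)),
                priority=int(raw["priority"]),
            )
        )
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        raise ValueError("duplicate rule names in ruleset")
    prios = [r.priority for r in rules]
    if len(set(prios)) != len(prios):
        raise ValueError("duplicate priorities in ruleset")
    return sorted(rules, key=lambda r: r.priority)


def classify(protein: RegulatorProtein, rules: Sequence[SubclassRule]) -> Classification:
    """First matching rule by priority wins; no match -> ``unclassified``."""
    for rule in sorted(rules, key=lambda r: r.priority):
        if rule.matches(protein.domain_set):
            return Classification(
                protein_id=protein.protein_id,
                gene_id=protein.gene_id,
                subclass=rule.name,
                family=rule.family,
                matched_rule=rule.name,
            )
    return Classification(
        protein_id=protein.protein_id,
        gene_id=protein.gene_id,
        subclass=UNCLASSIFIED,
        family=UNCLASSIFIED,
        matched_rule=None,
    )


def classify_all(
    proteins: Iterable[RegulatorProtein], rules: Sequence[SubclassRule]
) -> list[Classification]:
    ordered = sorted(rules, key=lambda r: r.priority)
    return [classify(p, ordered) for p in proteins]


def write_classifications(classifications: Iterable[Classification], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tgene_id\tsubclass\tfamily\n")
        for c in classifications:
            fh.write(f"{c.protein_id}\t{c.gene_id}\t{c.subclass}\t{c.family}\n")
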