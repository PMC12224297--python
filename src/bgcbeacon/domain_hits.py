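"""Domain-hit tables and per-protein domain architectures.

Regulatory proteins are recognised by profile-HMM hits against a keyword-selected
subset of Pfam families. Hits arrive in the per-domain tabular ("domtblout")
layout produced by hmmsearch-style tools; each hit is scored relative to the
family's curated gathering (GA) threshold, giving a dimensionless *normalized
bitscore* (hit bitscore / GA). Overlapping hits on the same protein are resolved
greedily in favour of the highest normalized bitscore, and the surviving,
coordinate-ordered hits define the protein's domain architecture.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PfamMeta",
    "DomainHit",
    "RegulatorProtein",
    "load_pfam_meta",
    "write_pfam_meta",
    "load_keywords",
    "default_keywords_path",
    "parse_domtblout",
    "select_regulatory_pfams",
    "resolve_overlaps",
    "build_architecture",
    "collect_regulators",
]


@dataclass(frozen=True)
class PfamMeta:
    """Metadata for one Pfam family: accession, name, description and GA cutoff."""

    accession: str
    name: str
    description: str
    ga_threshold: float

    def __post_init__(self) -> None:
        if self.ga_threshold <= 0:
            raise ValueError(
                f"GA threshold for {self.accession} must be > 0, got {self.ga_threshold}"
            )


@dataclass(frozen=True)
class DomainHit:
    """One Pfam match on one protein.

    Coordinates are envelope coordinates, 1-based inclusive on the amino-acid
    sequence. ``normalized_bitscore`` is bitscore / GA threshold; hits at
    exactly the GA cutoff (normalized 1.0) are retained.
    """

    protein_id: str
    pfam_accession: str
    pfam_name: str
    start_aa: int
    end_aa: int
    bitscore: float
    normalized_bitscore: float

    def __post_init__(self) -> None:
        if self.start_aa > self.end_aa:
            raise ValueError(
                f"{self.protein_id}/{self.pfam_name}: start_aa {self.start_aa} "
                f"> end_aa {self.end_aa}"
            )

    def overlaps(self, other: "DomainHit") -> bool:
        """True if the two hits share at least one amino-acid position."""
        return self.start_aa <= other.end_aa and other.start_aa <= self.end_aa


@dataclass(frozen=True)
class RegulatorProtein:
    """A protein with its overlap-resolved, coordinate-ordered domain architecture."""

    protein_id: str
    gene_id: str
    architecture: tuple[str, ...]
    domain_set: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        object.__setattr__(self, "domain_set", frozenset(self.architecture))


# ---------------------------------------------------------------------------
# Pfam metadata and keyword files


def load_pfam_meta(path: str | Path) -> dict[str, PfamMeta]:
    """Read a Pfam metadata TSV (accession, name, ga, description) keyed by accession."""
    metas: dict[str, PfamMeta] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed metadata row at line {lineno}")
            acc, name, ga, desc = parts[0], parts[1], parts[2], parts[3]
            if acc in metas:
                raise ValueError(f"{path}: duplicate accession {acc} at line {lineno}")
            metas[acc] = PfamMeta(acc, name, desc, float(ga))
    return metas


def write_pfam_meta(metas: Iterable[PfamMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#accession\tname\tga\tdescription\n")
        for m in metas:
            fh.write(f"{m.accession}\t{m.name}\t{m.ga_threshold}\t{m.description}\n")


def default_keywords_path() -> Path:
    """Path of the shipped regulation-keyword list.

    The shipped list carries only the commonly cited example keywords and is
    explicitly incomplete; users mining real genomes should supply their own
    curated keyword file.
    """
    return Path(__file__).parent / "data" / "regulatory_keywords.txt"


def load_keywords(path: str | Path | None = None) -> list[str]:
    path = default_keywords_path() if path is None else path
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


# ---------------------------------------------------------------------------
# domtblout parsing

# column indices in the 23-column per-domain table
_COL_TARGET = 0
_COL_QNAME = 3
_COL_QACC = 4
_COL_DOMSCORE = 13
_COL_ENV_FROM = 19
_COL_ENV_TO = 20
_N_COLS = 23


def parse_domtblout(path: str | Path, pfam_meta: Mapping[str, PfamMeta]) -> list[DomainHit]:
    """Parse a per-domain tabular hits file into :class:`DomainHit` records.

    Envelope coordinates are used as hit start/end. The normalized bitscore is
    computed against the GA threshold looked up in ``pfam_meta``; an accession
    absent from the table is an error (versioned accessions like PF00486.28
    are matched on the unversioned accession).
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split(None, _N_COLS - 1)
            if len(parts) < _N_COLS - 1:
                raise ValueError(f"{path}: malformed row at line {lineno}")
            acc = parts[_COL_QACC].split(".")[0]
            if acc not in pfam_meta:
                raise ValueError(
                    f"{path}: unknown Pfam accession {parts[_COL_QACC]!r} at line {lineno}"
                )
            meta = pfam_meta[acc]
            try:
                score = float(parts[_COL_DOMSCORE])
                start = int(parts[_COL_ENV_FROM])
                end = int(parts[_COL_ENV_TO])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            hits.append(
                DomainHit(
                    protein_id=parts[_COL_TARGET],
                    pfam_accession=acc,
                    pfam_name=parts[_COL_QNAME],
                    start_aa=start,
                    end_aa=end,
                    bitscore=score,
                    normalized_bitscore=score / meta.ga_threshold,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# keyword selection

_DASHES = re.compile(r"[‐‑‒–—―]")
_WS = re.compile(r"\s+")


def _normalize_text(text: str) -> str:
    # en/em dashes become hyphens and runs of whitespace collapse, so that
    # "helix–turn–helix (HTH)" matches "Helix-turn-helix domain" descriptions
    return _WS.sub(" ", _DASHES.sub("-", text)).strip().lower()


def select_regulatory_pfams(
    pfam_meta: Iterable[PfamMeta], keywords: Sequence[str]
) -> set[str]:
    """Accessions whose description matches any keyword (case-insensitive substring).

    Matching normalizes typography first (dashes, whitespace). A keyword with a
    parenthesised abbreviation, e.g. ``helix-turn-helix (HTH)``, also matches on
    either the long form or the abbreviation alone.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    probes: list[str] = []
    for kw in keywords:
        norm = _normalize_text(kw)
        probes.append(norm)
        m = re.fullmatch(r"(.+?)\s*\(([^)]+)\)", norm)
        if m:
            probes.append(m.group(1).strip())
            probes.append(m.group(2).strip())
    selected: set[str] = set()
    for meta in pfam_meta:
        desc = _normalize_text(meta.description)
        if any(p in desc for p in probes):
            selected.add(meta.accession)
    return selected


# ---------------------------------------------------------------------------
# overlap resolution and architectures


def _priority(hit: DomainHit) -> tuple[float, int, str]:
    return (-hit.normalized_bitscore, hit.start_aa, hit.pfam_accession)


def resolve_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Greedy non-overlapping hit selection for a single protein.

    Candidates are visited in order of normalized bitscore (descending), ties
    broken by lower start coordinate then accession; a hit is accepted iff it
    shares no amino-acid position with an already-accepted hit. The result is
    returned sorted by start coordinate and is idempotent under re-resolution.
    """
    if len({h.protein_id for h in hits}) > 1:
        raise ValueError("resolve_overlaps expects hits from a single protein")
    accepted: list[DomainHit] = []
    for hit in sorted(hits, key=_priority):
        if not any(hit.overlaps(a) for a in accepted):
            accepted.append(hit)
    accepted.sort(key=lambda h: (h.start_aa, h.end_aa, h.pfam_accession))
    return accepted


def build_architecture(
    protein_id: str, gene_id: str, hits: Sequence[DomainHit]
) -> RegulatorProtein | None:
    """Assemble the ordered domain architecture from overlap-resolved hits.

    Duplicate domain names are preserved in the architecture but collapse in
    the domain set. Returns ``None`` for an empty hit list (the protein carries
    no recognised domain and is not emitted as a regulator).
    """
    if not hits:
        return None
    ordered = sorted(hits, key=lambda h: (h.start_aa, h.end_aa, h.pfam_accession))
    return RegulatorProtein(
        protein_id=protein_id,
        gene_id=gene_id,
        architecture=tuple(h.pfam_name for h in ordered),
    )


def collect_regulators(
    hits: Iterable[DomainHit],
    regulatory_accessions: set[str],
    protein_to_gene: Mapping[str, str],
) -> list[RegulatorProtein]:
    """Build regulator proteins from a mixed hit table.

    A protein qualifies as a putative regulator when at least one of its hits
    falls in ``regulatory_accessions``; its architecture is then built from
    *all* of its overlap-resolved hits, mirroring the two-pass search strategy
    (regulatory profiles to find the proteins, the full Pfam library to
    describe them).
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    regulators: list[RegulatorProtein] = []
    for pid in sorted(by_protein):
        phits = by_protein[pid]
        if not any(h.pfam_accession in regulatory_accessions for h in phits):
            continue
        resolved = resolve_overlaps(phits)
        prot = build_architecture(pid, protein_to_gene.get(pid, pid), resolved)
        if prot is not None:
            regulators.append(prot)
    return regulators
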