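"""Beacon-based discovery of candidate BGC regions.

Regulator genes of a high in-BGC-ratio subclass that lie *outside* predicted
BGC regions — at least one approximate BGC length (20 kb by default) away from
every region boundary — serve as beacons. Around each beacon a fixed-size
window (20 kb, centred on the gene midpoint) is extracted, its
biosynthesis-associated Pfam content is counted to prioritise windows likely
to encode secondary rather than primary metabolism, and windows are grouped by
content similarity (Jaccard on domain sets blended with a shared-adjacency
index over the windows' ordered domain strings, single-linkage components at a
cutoff). A simple exact direct-repeat scanner searches promoter sequence for
SARP-type binding sites (e.g. TTGCAGT-N10-TTGCAGT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .bgc_association import BgcRegion, _interval_gap

__all__ = [
    "CandidateRegion",
    "RepeatHit",
    "find_beacon_genes",
    "extract_window",
    "count_biosynthetic_domains",
    "region_similarity",
    "cluster_regions",
    "find_direct_repeats",
    "load_biosynthetic_pfams",
    "default_biosynthetic_pfams_path",
]


@dataclass
class CandidateRegion:
    """A beacon-centred genomic window with its gene and domain content."""

    beacon_gene_id: str
    subclass: str
    contig: str
    start: int
    end: int
    gene_ids: tuple[str, ...] = ()
    domain_string: tuple[str, ...] = ()  # window domains in genomic order
    biosyn_count: int = 0
    cluster_id: str | None = None
    truncated: bool = False

    @property
    def domain_set(self) -> frozenset[str]:
        return frozenset(self.domain_string)


@dataclass(frozen=True)
class RepeatHit:
    """An exact (or near-exact) spaced direct repeat in forward coordinates."""

    unit: str
    first_start: int
    second_start: int
    spacer: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.second_start != self.first_start + len(self.unit) + self.spacer:
            raise ValueError("second_start inconsistent with unit length and spacer")


# ---------------------------------------------------------------------------
# beacons and windows


def find_beacon_genes(
    classifications: pd.DataFrame,
    flags: pd.DataFrame,
    regions: Sequence[BgcRegion],
    target_subclasses: set[str] | str,
    min_distance_nt: int = 20_000,
) -> pd.DataFrame:
    """Out-of-BGC genes of the target subclass(es) far from every region.

    A gene qualifies when it is flagged out-of-BGC and the interval gap to
    every region on its contig is at least ``min_distance_nt`` (inclusive);
    contigs carrying no region qualify trivially. Returns the qualifying rows
    of ``flags`` joined with their subclass, in genomic order.
    """
    if isinstance(target_subclasses, str):
        target_subclasses = {target_subclasses}
    by_contig: dict[str, list[BgcRegion]] = {}
    for r in regions:
        by_contig.setdefault(r.contig, []).append(r)
    sub = classifications.set_index("gene_id")["subclass"]
    rows = []
    for row in flags.itertuples(index=False):
        if row.gene_id not in sub.index or sub.loc[row.gene_id] not in target_subclasses:
            continue
        if bool(row.in_bgc):
            continue
        gaps = [
            _interval_gap(int(row.start), int(row.end), r.start, r.end)
            for r in by_contig.get(row.contig, [])
        ]
        if not gaps or min(gaps) >= min_distance_nt:
            d = row._asdict()
            d["subclass"] = sub.loc[row.gene_id]
            rows.append(d)
    out = pd.DataFrame(
        rows, columns=list(flags.columns) + ["subclass"]
    )
    return out.sort_values(["contig", "start"], ignore_index=True)


def extract_window(
    beacon: Mapping,
    genes: pd.DataFrame,
    hits_by_gene: Mapping[str, Sequence] | None = None,
    window_nt: int = 20_000,
    contig_length: int | None = None,
) -> CandidateRegion:
    """Fixed-size window centred on the beacon gene's midpoint.

    The window is clipped to contig bounds (flagged ``truncated``); genes
    intersecting the window by at least 1 nt are included in genomic order.
    ``hits_by_gene`` optionally maps gene_id -> overlap-resolved DomainHit
    sequence used to build the window's ordered domain string.
    """
    mid = (int(beacon["start"]) + int(beacon["end"])) // 2
    start = mid - window_nt // 2
    end = start + window_nt
    truncated = False
    if start < 0:
        start, truncated = 0, True
    if contig_length is not None and end > contig_length:
        end, truncated = contig_length, True
    contig = beacon["contig"]
    in_window = genes[
        (genes["contig"] == contig) & (genes["start"] < end) & (genes["end"] > start)
    ].sort_values("start")
    domain_string: list[str] = []
    if hits_by_gene is not None:
        for g in in_window.itertuples(index=False):
            for h in sorted(
                hits_by_gene.get(g.gene_id, ()), key=lambda h: (h.start_aa, h.end_aa)
            ):
                domain_string.append(h.pfam_name)
    return CandidateRegion(
        beacon_gene_id=beacon["gene_id"],
        subclass=beacon.get("subclass", ""),
        contig=contig,
        start=start,
        end=end,
        gene_ids=tuple(in_window["gene_id"]),
        domain_string=tuple(domain_string),
        truncated=truncated,
    )


def default_biosynthetic_pfams_path() -> Path:
    return Path(__file__).parent / "data" / "biosynthetic_pfams.txt"


def load_biosynthetic_pfams(path: str | Path | None = None) -> set[str]:
    path = default_biosynthetic_pfams_path() if path is None else path
    with open(path) as fh:
        return {ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")}


def count_biosynthetic_domains(region: CandidateRegion, biosyn_pfams: set[str]) -> int:
    """Count (with multiplicity) window domain hits in the biosynthesis set."""
    if not biosyn_pfams:
        raise ValueError("biosynthesis-associated Pfam set is empty; configuration missing")
    region.biosyn_count = sum(1 for d in region.domain_string if d in biosyn_pfams)
    return region.biosyn_count


# ---------------------------------------------------------------------------
# similarity and clustering


def _adjacency_pairs(domain_string: Sequence[str]) -> frozenset[tuple[str, str]]:
    return frozenset(zip(domain_string, domain_string[1:]))


def region_similarity(
    a: CandidateRegion,
    b: CandidateRegion,
    w_jaccard: float = 0.5,
    w_adjacency: float = 0.5,
) -> float:
    """Blend of domain-set Jaccard and shared-adjacency index, in [0, 1].

    The adjacency index is the Jaccard of the two windows' sets of adjacent
    ordered domain pairs; when neither window has an adjacent pair the index
    is 1 (no order information to disagree on). Windows with no domain content
    have similarity 0 with everything. Symmetric by construction.
    """
    sa, sb = a.domain_set, b.domain_set
    if not sa or not sb:
        return 0.0
    jac = len(sa & sb) / len(sa | sb)
    pa, pb = _adjacency_pairs(a.domain_string), _adjacency_pairs(b.domain_string)
    if not pa and not pb:
        adj = 1.0
    else:
        adj = len(pa & pb) / len(pa | pb)
    return w_jaccard * jac + w_adjacency * adj


def cluster_regions(
    regions: Sequence[CandidateRegion], cutoff: float = 0.3
) -> tuple[dict[str, str], int, int]:
    """Single-linkage grouping of candidate windows at a similarity cutoff.

    Builds a graph with an edge wherever pairwise similarity >= cutoff and
    takes connected components. Labels are written back onto the regions
    (cluster label = smallest beacon gene id in the component). Returns
    (labels by beacon gene id, number of multi-member clusters, number of
    singletons).
    """
    g = nx.Graph()
    g.add_nodes_from(r.beacon_gene_id for r in regions)
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            if region_similarity(regions[i], regions[j]) >= cutoff:
                g.add_edge(regions[i].beacon_gene_id, regions[j].beacon_gene_id)
    labels: dict[str, str] = {}
    n_clusters = n_singletons = 0
    for comp in nx.connected_components(g):
        label = min(comp)
        if len(comp) == 1:
            n_singletons += 1
        else:
            n_clusters += 1
        for node in comp:
            labels[node] = label
    for r in regions:
        r.cluster_id = labels.get(r.beacon_gene_id)
    return labels, n_clusters, n_singletons


# ---------------------------------------------------------------------------
# direct-repeat scanning

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _mismatches(a: str, b: str, budget: int) -> int | None:
    n = 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":  # N never matches
            return None
        if x != y:
            n += 1
            if n > budget:
                return None
    return n


def find_direct_repeats(
    seq: str,
    unit_len: int = 7,
    spacer_min: int = 0,
    spacer_max: int = 20,
    max_mismatch: int = 0,
) -> list[RepeatHit]:
    """All spaced direct repeats unit-N(s)-unit with spacer_min <= s <= spacer_max.

    Scans every position pair on both strands; reverse-strand hits are reported
    in forward coordinates with strand '-'. ``N`` matches nothing. Degenerate
    low-complexity sequence (e.g. homopolymers) yields a hit at every offset by
    definition. Units shorter than 4 nt are rejected as uninformative.
    """
    if unit_len < 4:
        raise ValueError(f"unit_len must be >= 4, got {unit_len}")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    hits: list[RepeatHit] = []
    hits.extend(_scan_forward(seq, unit_len, spacer_min, spacer_max, max_mismatch, "+"))
    seen = {(h.first_start, h.spacer) for h in hits}
    rc = _revcomp(seq)
    L = len(seq)
    for h in _scan_forward(rc, unit_len, spacer_min, spacer_max, max_mismatch, "-"):
        # map the repeat back to forward coordinates: the minus-strand second
        # copy becomes the forward-coordinate first copy. A direct repeat is
        # strand-symmetric, so a minus hit occupying the same placement as a
        # plus hit is the same repeat and is reported once (plus strand).
        first = L - h.second_start - unit_len
        if (first, h.spacer) in seen:
            continue
        hits.append(
            RepeatHit(
                unit=h.unit,
                first_start=first,
                second_start=first + unit_len + h.spacer,
                spacer=h.spacer,
                strand="-",
            )
        )
    hits.sort(key=lambda h: (h.first_start, h.spacer, h.strand))
    return hits


def _scan_forward(
    seq: str, unit_len: int, spacer_min: int, spacer_max: int, max_mismatch: int, strand: str
) -> list[RepeatHit]:
    hits = []
    n = len(seq)
    for i in range(n - 2 * unit_len - spacer_min + 1):
        a = seq[i : i + unit_len]
        if "N" in a:
            continue
        for s in range(spacer_min, spacer_max + 1):
            j = i + unit_len + s
            if j + unit_len > n:
                break
            b = seq[j : j + unit_len]
            if _mismatches(a, b, max_mismatch) is not None:
                hits.append(RepeatHit(unit=a, first_start=i, second_start=j, spacer=s, strand=strand))
    return hits


def write_candidates_tsv(regions: Iterable[CandidateRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "beacon_gene_id\tsubclass\tcontig\tstart\tend\tn_genes\t"
            "biosyn_count\tcluster_id\ttruncated\n"
        )
        for r in regions:
            fh.write(
                f"{r.beacon_gene_id}\t{r.subclass}\t{r.contig}\t{r.start}\t{r.end}\t"
                f"{len(r.gene_ids)}\t{r.biosyn_count}\t{r.cluster_id or ''}\t"
                f"{int(r.truncated)}\n"
            )


def write_repeats_bed(hits: Iterable[RepeatHit], contig: str, path: str | Path) -> None:
    """BED-like TSV: contig, start, end (of the full repeat), unit, spacer, strand."""
    with open(path, "w") as fh:
        for h in hits:
            end = h.second_start + len(h.unit)
            fh.write(f"{contig}\t{h.first_start}\t{end}\t{h.unit}\t{h.spacer}\t{h.strand}\n")
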