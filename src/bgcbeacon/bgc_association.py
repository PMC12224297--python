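"""Association statistics between regulator subclasses and BGC regions.

A gene counts as *in-BGC* when its interval is fully contained in a predicted
region interval (regions extend beyond their core genes by design, so full
containment is the conservative membership rule). Per subclass we report:

* the in/out ratio ``n_in / (n_in + n_out)``, reported as a percentage
  rounded half-up to one decimal;
* the distribution of BGC classes via the *nearest core gene* of the
  containing region (interval gap distance, 0 when overlapping);
* the distribution of known product activities, restricted to regions whose
  best known-cluster match reaches ``min_similarity_pct`` (default 50) and to
  subclass-activity pairs observed at least ``min_count`` times (default 10);
* upper-quartile selection of the subclasses most associated with BGCs
  (linear-interpolation 75th percentile over subclass in-ratios).

All genomic intervals are 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoreGene",
    "BgcRegion",
    "AssociationRecord",
    "assign_in_bgc",
    "flag_genes",
    "in_bgc_ratio",
    "nearest_core_class",
    "functional_association",
    "select_upper_quartile",
    "load_regions_json",
    "write_regions_json",
    "round_pct",
]


@dataclass(frozen=True)
class CoreGene:
    gene_id: str
    bgc_class: str
    start: int
    end: int


@dataclass(frozen=True)
class BgcRegion:
    """A predicted BGC region with product classes and best known-cluster match."""

    region_id: str
    contig: str
    start: int
    end: int
    classes: tuple[str, ...]
    core_genes: tuple[CoreGene, ...] = ()
    known_cluster_id: str | None = None
    known_similarity_pct: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.region_id}: empty interval [{self.start},{self.end})")
        for cg in self.core_genes:
            if cg.start < self.start or cg.end > self.end:
                raise ValueError(
                    f"{self.region_id}: core gene {cg.gene_id} outside region bounds"
                )

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass
class AssociationRecord:
    subclass: str
    n_in: int = 0
    n_out: int = 0
    class_distribution: dict[str, int] = field(default_factory=dict)
    function_distribution: dict[str, int] = field(default_factory=dict)
    unknown_function_fraction: float = float("nan")

    @property
    def total(self) -> int:
        return self.n_in + self.n_out

    @property
    def in_ratio(self) -> float:
        return self.n_in / self.total if self.total else float("nan")

    @property
    def in_ratio_pct(self) -> float:
        """Percentage, rounded half-up to one decimal for reports."""
        return round_pct(self.in_ratio)


def round_pct(ratio: float) -> float:
    """100·ratio rounded half-up to one decimal (presentation rounding)."""
    return float(Decimal(str(ratio * 100)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# membership


def assign_in_bgc(
    contig: str,
    start: int,
    end: int,
    regions: Sequence[BgcRegion],
    known_contigs: set[str] | None = None,
) -> tuple[bool, str | None]:
    """Full-containment membership test of a gene against regions on its contig.

    ``regions`` may span several contigs; only same-contig regions are tested.
    If ``known_contigs`` is given, a gene on a contig outside it is an error.
    """
    if known_contigs is not None and contig not in known_contigs:
        raise ValueError(f"gene on unknown contig {contig!r}")
    for region in regions:
        if region.contig == contig and region.contains(start, end):
            return True, region.region_id
    return False, None


def flag_genes(genes: pd.DataFrame, regions: Sequence[BgcRegion]) -> pd.DataFrame:
    """Compute in-BGC flags for a gene table (columns: gene_id, contig, start, end).

    Returns a copy with boolean ``in_bgc`` and nullable ``region_id`` columns.
    """
    by_contig: dict[str, list[BgcRegion]] = {}
    for r in regions:
        by_contig.setdefault(r.contig, []).append(r)
    known = set(genes["contig"].unique()) | set(by_contig)
    flags, region_ids = [], []
    for row in genes.itertuples(index=False):
        flag, rid = assign_in_bgc(
            row.contig, int(row.start), int(row.end), by_contig.get(row.contig, []), known
        )
        flags.append(flag)
        region_ids.append(rid)
    out = genes.copy()
    out["in_bgc"] = flags
    out["region_id"] = region_ids
    return out


# ---------------------------------------------------------------------------
# per-subclass statistics


def in_bgc_ratio(
    classifications: pd.DataFrame,
    flags: pd.DataFrame,
    regions: Sequence[BgcRegion] = (),
    include_unclassified: bool = False,
    per_domain_weights: Mapping[str, int] | None = None,
) -> dict[str, AssociationRecord]:
    """Per-subclass in/out counts, ratios and nearest-core-gene class distributions.

    ``classifications`` needs columns (gene_id, subclass); ``flags`` needs
    (gene_id, contig, start, end, in_bgc, region_id) as produced by
    :func:`flag_genes`. Every classified gene must carry a flag.
    ``per_domain_weights`` optionally weights each gene by its number of
    domain hits instead of counting genes once (off by default).
    """
    flag_map = flags.set_index("gene_id")
    region_map = {r.region_id: r for r in regions}
    records: dict[str, AssociationRecord] = {}
    for row in classifications.itertuples(index=False):
        if row.subclass == "unclassified" and not include_unclassified:
            continue
        if row.gene_id not in flag_map.index:
            raise ValueError(f"classified gene {row.gene_id!r} has no in/out flag")
        g = flag_map.loc[row.gene_id]
        rec = records.setdefault(row.subclass, AssociationRecord(subclass=row.subclass))
        w = int(per_domain_weights.get(row.gene_id, 1)) if per_domain_weights else 1
        if bool(g["in_bgc"]):
            rec.n_in += w
            region = region_map.get(g["region_id"])
            if region is not None:
                cls, _ = nearest_core_class(int(g["start"]), int(g["end"]), region)
                rec.class_distribution[cls] = rec.class_distribution.get(cls, 0) + w
        else:
            rec.n_out += w
    return records


def _interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in nt between two half-open intervals; 0 when they overlap or touch."""
    return max(0, a_start - b_end, b_start - a_end)


def nearest_core_class(
    gene_start: int, gene_end: int, region: BgcRegion
) -> tuple[str, bool]:
    """Class of the region's core gene nearest to the gene (min interval gap).

    Ties break toward the core gene with the smaller start. Regions without
    core genes fall back to the region's first listed class; the returned flag
    is True when the fallback was used.
    """
    if not region.core_genes:
        return (region.classes[0] if region.classes else "unknown"), True
    best = min(
        region.core_genes,
        key=lambda cg: (_interval_gap(gene_start, gene_end, cg.start, cg.end), cg.start),
    )
    return best.bgc_class, False


def functional_association(
    records: Mapping[str, AssociationRecord],
    classifications: pd.DataFrame,
    flags: pd.DataFrame,
    regions: Sequence[BgcRegion],
    activity_table: Mapping[str, Sequence[str]],
    min_similarity_pct: float = 50.0,
    min_count: int = 10,
) -> dict[str, AssociationRecord]:
    """Fill per-subclass product-activity distributions under the two filters.

    A gene contributes to (subclass, activity) counts only when its containing
    region's best known-cluster similarity is at least ``min_similarity_pct``
    and the known cluster has activity annotations; pairs observed fewer than
    ``min_count`` times are dropped. In-BGC genes failing the similarity or
    annotation filter count toward the subclass's unknown-function fraction.
    Thresholds are inclusive. Records are updated in place and returned.
    """
    region_map = {r.region_id: r for r in regions}
    flag_map = flags.set_index("gene_id")
    raw: dict[tuple[str, str], int] = {}
    unknown: dict[str, int] = {}
    for row in classifications.itertuples(index=False):
        if row.subclass not in records:
            continue
        g = flag_map.loc[row.gene_id]
        if not bool(g["in_bgc"]):
            continue
        region = region_map.get(g["region_id"])
        sim = region.known_similarity_pct if region else None
        activities: Sequence[str] = ()
        if (
            region is not None
            and region.known_cluster_id is not None
            and sim is not None
            and sim >= min_similarity_pct
        ):
            activities = activity_table.get(region.known_cluster_id, ())
        if activities:
            for act in activities:
                raw[(row.subclass, act)] = raw.get((row.subclass, act), 0) + 1
        else:
            unknown[row.subclass] = unknown.get(row.subclass, 0) + 1
    for rec in records.values():
        rec.function_distribution = {
            act: c
            for (sub, act), c in sorted(raw.items())
            if sub == rec.subclass and c >= min_count
        }
        rec.unknown_function_fraction = (
            unknown.get(rec.subclass, 0) / rec.n_in if rec.n_in else float("nan")
        )
    return dict(records)


def select_upper_quartile(
    records: Mapping[str, AssociationRecord] | Iterable[AssociationRecord],
    min_total: int = 20,
) -> list[str]:
    """Subclasses whose in-ratio reaches the 75th percentile of all subclass ratios.

    Subclasses with fewer than ``min_total`` genes are excluded before the
    percentile (linear interpolation) is computed. Requires at least four
    eligible subclasses; otherwise the quartile is meaningless and an error
    advises manual selection.
    """
    recs = list(records.values()) if isinstance(records, Mapping) else list(records)
    eligible = [r for r in recs if r.total >= min_total and r.total > 0]
    if len(eligible) < 4:
        raise ValueError(
            f"only {len(eligible)} subclasses with >= {min_total} genes; "
            "too few for a quartile rule — select subclasses manually"
        )
    ratios = np.array([r.in_ratio for r in eligible])
    q75 = float(np.percentile(ratios, 75, method="linear"))
    return sorted(r.subclass for r in eligible if r.in_ratio >= q75)


# ---------------------------------------------------------------------------
# region I/O (JSON schema shared with the synthetic generator)


def write_regions_json(regions: Sequence[BgcRegion], path: str | Path) -> None:
    payload = [
        {
            "region_id": r.region_id,
            "contig": r.contig,
            "start": r.start,
            "end": r.end,
            "classes": list(r.classes),
            "core_genes": [
                {"id": cg.gene_id, "class": cg.bgc_class, "start": cg.start, "end": cg.end}
                for cg in r.core_genes
            ],
            "known_cluster": (
                None
                if r.known_cluster_id is None
                else {"id": r.known_cluster_id, "similarity_pct": r.known_similarity_pct}
            ),
        }
        for r in regions
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_regions_json(path: str | Path) -> list[BgcRegion]:
    with open(path) as fh:
        payload = json.load(fh)
    regions = []
    for rec in payload:
        kc = rec.get("known_cluster")
        regions.append(
            BgcRegion(
                region_id=rec["region_id"],
                contig=rec["contig"],
                start=int(rec["start"]),
                end=int(rec["end"]),
                classes=tuple(rec.get("classes", [])),
                core_genes=tuple(
                    CoreGene(cg["id"], cg["class"], int(cg["start"]), int(cg["end"]))
                    for cg in rec.get("core_genes", [])
                ),
                known_cluster_id=None if kc is None else kc["id"],
                known_similarity_pct=None if kc is None else float(kc["similarity_pct"]),
            )
        )
    return regions


def write_association_tsv(records: Mapping[str, AssociationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "subclass\tn_in\tn_out\tin_ratio_pct\tclass_distribution\t"
            "function_distribution\tunknown_function_fraction\n"
        )
        for name in sorted(records):
            r = records[name]
            cls = ",".join(f"{k}:{v}" for k, v in sorted(r.class_distribution.items()))
            fun = ",".join(f"{k}:{v}" for k, v in sorted(r.function_distribution.items()))
            fh.write(
                f"{r.subclass}\t{r.n_in}\t{r.n_out}\t{r.in_ratio_pct}\t{cls}\t{fun}\t"
                f"{r.unknown_function_fraction:.4f}\n"
            )
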