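"""Synthetic genome-scale fixtures with known ground truth.

The generator emulates the statistical structure of the real inputs to the
pipeline — per-genome gene annotation tables, per-protein Pfam domain hits,
predicted BGC region files and promoter sequences — without any sequence-level
realism (no codon usage, no protein sequences; domain hits are drawn directly
from per-family architecture grammars).

Each simulated genome is one contig. BGC regions are placed disjoint and
non-adjacent; a gene labelled with family *f* is fully contained in a region
with probability ``family_p_in[f]``, and unlabeled background genes with
probability ``background_p_in`` (default 0.146, the genomic background
fraction of coding regions inside predicted regions). Each region carries a
product class drawn from ``bgc_class_weights``, 1–3 core biosynthetic genes,
and optionally a best known-cluster match with a similarity percentage drawn
from ``mibig_similarity_law``. Domain hits follow the gene's family grammar
plus decoy hits that overlap a true hit with strictly lower normalized
bitscore, exercising overlap resolution deterministically.

Optionally the generator plants *hidden BGC windows*: an out-of-BGC small-SARP
gene at least 25 kb from every predicted region, surrounded by neighbours rich
in biosynthesis-associated domains — the ground truth for beacon-recall tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bgc_association import BgcRegion, CoreGene, write_regions_json, load_regions_json
from .domain_hits import DomainHit, PfamMeta, write_pfam_meta, load_pfam_meta

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "PromoterTruth",
    "DEFAULT_FAMILY_GRAMMARS",
    "generate_genomes",
    "generate_promoter",
    "write_fixture",
    "load_fixture",
    "write_domtblout",
]

# ---------------------------------------------------------------------------
# domain vocabulary

# family name -> list of architectures (ordered domain tuples) to sample from
DEFAULT_FAMILY_GRAMMARS: dict[str, list[tuple[str, ...]]] = {
    "smallSARP": [("BTAD", "Trans_reg_C"), ("Trans_reg_C", "BTAD")],
    "mediumSARP": [("BTAD", "Trans_reg_C", "NB-ARC")],
    "largeSARP": [
        ("BTAD", "Trans_reg_C", "NB-ARC", "TPR_12"),
        ("BTAD", "Trans_reg_C", "NB-ARC", "TPR_10"),
    ],
    "SARP_LAL": [("BTAD", "Trans_reg_C", "NB-ARC", "AAA_16")],
    "LuxR_AAA16": [("AAA_16", "GerE")],
    "PAS_LuxR_small": [("PAS", "GerE")],
    "PAS_LuxR_large": [("PAS", "PAS_4", "GerE")],
    "TetR_C_33": [("TetR_C_33",)],
    "XRE": [("HTH_3",)],
    "NrdR": [("ATP-cone",)],
    "LexA": [("LexA_DNA_bind", "Peptidase_S24")],
    "ScbR": [("TetR_N", "GBL_bind")],
}

# descriptions decide which accessions the keyword filter selects as regulatory
_REGULATORY_DESCRIPTIONS = {
    "Trans_reg_C": "Transcriptional regulatory protein, C terminal; DNA binding effector domain",
    "BTAD": "Bacterial transcriptional activator domain",
    "GerE": "Bacterial regulatory proteins, luxR family; helix-turn-helix DNA binding",
    "TetR_N": "Bacterial regulatory proteins, tetR family; helix-turn-helix repressor",
    "TetR_C_33": "TetR family transcriptional repressor, C-terminal ligand binding domain",
    "HTH_3": "Helix-turn-helix domain of resolvase-like XRE regulators",
    "ATP-cone": "ATP-cone domain of the NrdR transcriptional repressor",
    "LexA_DNA_bind": "LexA repressor, DNA binding domain",
}

_ACCESSORY_DESCRIPTIONS = {
    "NB-ARC": "NB-ARC nucleotide-binding adaptor domain",
    "TPR_10": "Tetratricopeptide repeat",
    "TPR_12": "Tetratricopeptide repeat",
    "AAA_16": "AAA ATPase domain",
    "AAA_22": "AAA ATPase domain",
    "PAS": "PAS sensor domain",
    "PAS_4": "PAS fold sensor domain",
    "GBL_bind": "Gamma-butyrolactone receptor, ligand binding domain",
    "Peptidase_S24": "Peptidase S24, LexA autocleavage domain",
}

BIOSYN_DOMAINS: tuple[str, ...] = (
    "Condensation",
    "AMP-binding",
    "PKS_KS",
    "PKS_AT",
    "Thioesterase",
    "Methyltransf_11",
    "p450",
    "Aminotran_1_2",
    "Epimerase",
    "Radical_SAM",
)

_BIOSYN_DESCRIPTIONS = {
    "Condensation": "Condensation domain of nonribosomal peptide synthetases",
    "AMP-binding": "AMP-dependent synthetase and ligase",
    "PKS_KS": "Beta-ketoacyl synthase domain of polyketide synthases",
    "PKS_AT": "Acyl transferase domain of polyketide synthases",
    "Thioesterase": "Thioesterase domain",
    "Methyltransf_11": "Methyltransferase domain",
    "p450": "Cytochrome P450 oxidoreductase",
    "Aminotran_1_2": "Aminotransferase class I and II",
    "Epimerase": "NAD dependent epimerase/dehydratase family",
    "Radical_SAM": "Radical SAM superfamily enzyme",
}

_DECOY_DOMAINS = ("DUF4145", "DUF3152", "SnoaL_like")
_BACKGROUND_DOMAINS = ("ABC_tran", "MFS_1", "Acetyltransf_1")
_MISC_DESCRIPTIONS = {
    "DUF4145": "Domain of unknown function",
    "DUF3152": "Domain of unknown function",
    "SnoaL_like": "SnoaL-like polyketide cyclase domain",
    "ABC_tran": "ABC transporter nucleotide binding domain",
    "MFS_1": "Major facilitator superfamily transporter",
    "Acetyltransf_1": "GNAT family acetyltransferase",
}

_KNOWN_CLUSTER_POOL = 40  # distinct known-cluster ids KC0000..KC0039

_ACTIVITY_CYCLE = (
    ("antibacterial",),
    ("antifungal",),
    ("cytotoxic",),
    ("antibacterial", "antifungal"),
    ("siderophore",),
)


def activity_table() -> dict[str, tuple[str, ...]]:
    """Deterministic product-activity annotations for the known-cluster pool.

    Every seventh cluster id is left unannotated, emulating known clusters
    without recorded bioactivity.
    """
    table: dict[str, tuple[str, ...]] = {}
    for i in range(_KNOWN_CLUSTER_POOL):
        if i % 7 == 0:
            continue
        table[f"KC{i:04d}"] = _ACTIVITY_CYCLE[i % len(_ACTIVITY_CYCLE)]
    return table


def build_pfam_registry() -> dict[str, PfamMeta]:
    """Deterministic Pfam metadata covering every domain the generator emits.

    Accessions are synthetic (PF9xxxx) and GA thresholds vary per family so
    that normalized bitscores are non-trivial.
    """
    names: list[str] = sorted(
        set(_REGULATORY_DESCRIPTIONS)
        | set(_ACCESSORY_DESCRIPTIONS)
        | set(_BIOSYN_DESCRIPTIONS)
        | set(_MISC_DESCRIPTIONS)
    )
    registry: dict[str, PfamMeta] = {}
    for i, name in enumerate(names):
        desc = (
            _REGULATORY_DESCRIPTIONS.get(name)
            or _ACCESSORY_DESCRIPTIONS.get(name)
            or _BIOSYN_DESCRIPTIONS.get(name)
            or _MISC_DESCRIPTIONS[name]
        )
        acc = f"PF9{i:04d}"
        registry[acc] = PfamMeta(acc, name, desc, ga_threshold=20.0 + 1.5 * i)
    return registry


def _name_to_meta(registry: Mapping[str, PfamMeta]) -> dict[str, PfamMeta]:
    return {m.name: m for m in registry.values()}


# ---------------------------------------------------------------------------
# configuration and truth


def _uniform_similarity(rng: np.random.Generator) -> float:
    return float(rng.uniform(0.0, 100.0))


@dataclass
class SimConfig:
    """Study conditions for one simulated genome collection.

    ``genes_per_genome`` counts unlabeled background genes; labelled regulator
    genes are added on top via ``family_counts``. Probabilities are per-gene
    Bernoulli placement probabilities of full containment in a BGC region.
    """

    n_genomes: int = 5
    genes_per_genome: int = 100
    contig_length: int = 500_000
    n_bgc_per_genome: int = 5
    bgc_length: int = 20_000
    family_grammars: dict[str, list[tuple[str, ...]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_FAMILY_GRAMMARS.items()}
    )
    family_counts: dict[str, int] = field(default_factory=dict)
    family_p_in: dict[str, float] = field(default_factory=dict)
    background_p_in: float = 0.146
    bgc_class_weights: dict[str, float] = field(
        default_factory=lambda: {
            "NRPS": 0.25,
            "T1PKS": 0.20,
            "PKS": 0.15,
            "RiPP": 0.15,
            "terpene": 0.15,
            "other": 0.10,
        }
    )
    mibig_similarity_law: Callable[[np.random.Generator], float] = _uniform_similarity
    p_known_cluster: float = 0.7
    n_hidden_per_genome: int = 0
    hidden_margin_nt: int = 25_000
    decoy_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        probs = list(self.family_p_in.values()) + [self.background_p_in, self.p_known_cluster]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        needed = self.n_bgc_per_genome * self.bgc_length + max(0, self.n_bgc_per_genome - 1)
        if needed > self.contig_length:
            raise ValueError(
                f"cannot place {self.n_bgc_per_genome} disjoint regions of "
                f"{self.bgc_length} nt on a {self.contig_length} nt contig"
            )
        for fam in self.family_p_in:
            if not self.family_grammars.get(fam):
                raise ValueError(f"family {fam!r} has no architecture grammar")
        for fam in self.family_counts:
            if not self.family_grammars.get(fam):
                raise ValueError(f"family {fam!r} has no architecture grammar")
        if any(w < 0 for w in self.bgc_class_weights.values()):
            raise ValueError("class weights must be non-negative")


@dataclass(frozen=True)
class HiddenWindow:
    contig: str
    start: int
    end: int
    beacon_gene_id: str


@dataclass
class SimTruth:
    """Ground truth: per-gene family label and in/out flag, plus planted windows.

    ``genes`` has columns (gene_id, family, in_bgc, region_id, hidden); the
    flags are recomputable from the emitted coordinates by the interval test.
    """

    genes: pd.DataFrame
    hidden_windows: list[HiddenWindow] = field(default_factory=list)


@dataclass
class SimResult:
    genes: pd.DataFrame  # gene_id, protein_id, contig, start, end, strand
    hits: list[DomainHit]
    regions: list[BgcRegion]
    pfam_meta: dict[str, PfamMeta]
    truth: SimTruth
    config: SimConfig | None = None


@dataclass(frozen=True)
class PromoterTruth:
    unit: str
    spacer: int
    first_start: int
    second_start: int


# ---------------------------------------------------------------------------
# generation


def _place_disjoint_regions(
    rng: np.random.Generator, n: int, length: int, contig_length: int
) -> list[tuple[int, int]]:
    """Disjoint, non-adjacent (>=1 nt gap) intervals of fixed length."""
    if n == 0:
        return []
    min_gap = 1
    free = contig_length - n * length - (n - 1) * min_gap
    gaps = rng.multinomial(free, [1.0 / (n + 1)] * (n + 1))
    starts = []
    pos = 0
    for i in range(n):
        pos += int(gaps[i]) + (min_gap if i > 0 else 0)
        starts.append(pos)
        pos += length
    return [(s, s + length) for s in starts]


def _complement_gaps(
    intervals: Sequence[tuple[int, int]], contig_length: int
) -> list[tuple[int, int]]:
    gaps = []
    pos = 0
    for s, e in sorted(intervals):
        if s > pos:
            gaps.append((pos, s))
        pos = max(pos, e)
    if pos < contig_length:
        gaps.append((pos, contig_length))
    return gaps


def _place_in_gaps(
    rng: np.random.Generator, gaps: Sequence[tuple[int, int]], gene_len: int
) -> tuple[int, int]:
    slots = [(s, e) for s, e in gaps if e - s >= gene_len]
    if not slots:
        raise ValueError("no inter-region gap large enough to place an out-of-BGC gene")
    weights = np.array([e - s - gene_len + 1 for s, e in slots], dtype=float)
    idx = int(rng.choice(len(slots), p=weights / weights.sum()))
    s, e = slots[idx]
    start = int(rng.integers(s, e - gene_len + 1))
    return start, start + gene_len


def _grammar_hits(
    rng: np.random.Generator,
    protein_id: str,
    architecture: Sequence[str],
    name_meta: Mapping[str, PfamMeta],
) -> list[DomainHit]:
    hits = []
    pos = int(rng.integers(1, 30))
    for dom in architecture:
        meta = name_meta[dom]
        length = int(rng.integers(50, 120))
        score = meta.ga_threshold * float(rng.uniform(1.2, 3.0))
        hits.append(
            DomainHit(
                protein_id=protein_id,
                pfam_accession=meta.accession,
                pfam_name=meta.name,
                start_aa=pos,
                end_aa=pos + length - 1,
                bitscore=score,
                normalized_bitscore=score / meta.ga_threshold,
            )
        )
        pos += length + int(rng.integers(5, 25))
    return hits


def _decoy_hit(
    rng: np.random.Generator, target: DomainHit, name_meta: Mapping[str, PfamMeta]
) -> DomainHit:
    # overlaps its target by construction and scores strictly below it, so
    # greedy overlap resolution always removes it
    meta = name_meta[_DECOY_DOMAINS[int(rng.integers(len(_DECOY_DOMAINS)))]]
    start = int(rng.integers(target.start_aa, target.end_aa + 1))
    length = int(rng.integers(40, 100))
    norm = target.normalized_bitscore * float(rng.uniform(0.3, 0.9))
    score = norm * meta.ga_threshold
    return DomainHit(
        protein_id=target.protein_id,
        pfam_accession=meta.accession,
        pfam_name=meta.name,
        start_aa=start,
        end_aa=start + length - 1,
        bitscore=score,
        normalized_bitscore=score / meta.ga_threshold,
    )


def generate_genomes(config: SimConfig) -> SimResult:
    """Generate the full fixture: gene tables, domain hits, regions, truth.

    Deterministic given ``config.seed``. All intervals are 0-based half-open;
    a gene flagged in-BGC is fully contained in its region by construction.
    """
    config.validate()
    registry = build_pfam_registry()
    name_meta = _name_to_meta(registry)
    class_names = sorted(config.bgc_class_weights)
    weights = np.array([config.bgc_class_weights[c] for c in class_names], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("bgc_class_weights must have positive total mass")
    weights = weights / weights.sum()

    gene_rows: list[dict] = []
    truth_rows: list[dict] = []
    hits: list[DomainHit] = []
    regions: list[BgcRegion] = []
    hidden_windows: list[HiddenWindow] = []

    for g in range(config.n_genomes):
        rng = np.random.default_rng([config.seed, g])
        contig = f"ctg{g:03d}"
        gene_counter = 0

        def new_gene(start: int, end: int, family: str | None, in_bgc: bool,
                     region_id: str | None, hidden: bool = False) -> str:
            nonlocal gene_counter
            gid = f"{contig}_g{gene_counter:05d}"
            gene_counter += 1
            gene_rows.append(
                {
                    "gene_id": gid,
                    "protein_id": f"{gid}_p",
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
            truth_rows.append(
                {
                    "gene_id": gid,
                    "family": family if family is not None else "",
                    "in_bgc": in_bgc,
                    "region_id": region_id if region_id is not None else "",
                    "hidden": hidden,
                }
            )
            return gid

        # --- BGC regions with core genes
        intervals = _place_disjoint_regions(
            rng, config.n_bgc_per_genome, config.bgc_length, config.contig_length
        )
        contig_regions: list[BgcRegion] = []
        for ri, (rs, re_) in enumerate(intervals):
            region_id = f"{contig}_r{ri:03d}"
            main_class = class_names[int(rng.choice(len(class_names), p=weights))]
            n_core = int(rng.integers(1, 4))
            cores: list[CoreGene] = []
            pos = rs + int(rng.integers(200, 1500))
            for ci in range(n_core):
                clen = int(rng.integers(2000, 6000))
                if pos + clen > re_ - 200:
                    break
                cls = main_class if ci == 0 else class_names[
                    int(rng.choice(len(class_names), p=weights))
                ]
                cgid = new_gene(pos, pos + clen, "_core", True, region_id)
                cores.append(CoreGene(cgid, cls, pos, pos + clen))
                # core genes carry biosynthetic domain hits
                arch = tuple(
                    BIOSYN_DOMAINS[int(k)]
                    for k in rng.choice(len(BIOSYN_DOMAINS), size=int(rng.integers(1, 4)))
                )
                hits.extend(_grammar_hits(rng, f"{cgid}_p", arch, name_meta))
                pos += clen + int(rng.integers(200, 800))
            known_id = None
            known_sim = None
            if rng.random() < config.p_known_cluster:
                known_id = f"KC{int(rng.integers(_KNOWN_CLUSTER_POOL)):04d}"
                known_sim = float(config.mibig_similarity_law(rng))
            classes = [main_class] + sorted(
                {c.bgc_class for c in cores if c.bgc_class != main_class}
            )
            contig_regions.append(
                BgcRegion(
                    region_id=region_id,
                    contig=contig,
                    start=rs,
                    end=re_,
                    classes=tuple(classes),
                    core_genes=tuple(cores),
                    known_cluster_id=known_id,
                    known_similarity_pct=known_sim,
                )
            )
        regions.extend(contig_regions)
        gaps = _complement_gaps(intervals, config.contig_length)

        # --- hidden planted windows (out-of-BGC, far from every region)
        if config.n_hidden_per_genome:
            centers = _hidden_centers(
                intervals,
                config.contig_length,
                config.n_hidden_per_genome,
                config.hidden_margin_nt,
            )
            for c in centers:
                blen = int(rng.integers(700, 1100))
                bstart = c - blen // 2
                bgid = new_gene(bstart, bstart + blen, "smallSARP", False, None, hidden=True)
                grammar = config.family_grammars["smallSARP"]
                arch = grammar[int(rng.integers(len(grammar)))]
                hits.extend(_grammar_hits(rng, f"{bgid}_p", arch, name_meta))
                hidden_windows.append(
                    HiddenWindow(contig, c - 10_000, c + 10_000, bgid)
                )
                # biosynthesis-rich neighbours on both sides of the beacon
                for off in (-8000, -5000, -2500, 2000, 4500, 7000):
                    nlen = int(rng.integers(1200, 2200))
                    ns = c + off
                    ngid = new_gene(ns, ns + nlen, "_hidden_biosyn", False, None, hidden=True)
                    arch = tuple(
                        BIOSYN_DOMAINS[int(k)]
                        for k in rng.choice(
                            len(BIOSYN_DOMAINS), size=int(rng.integers(2, 5))
                        )
                    )
                    hits.extend(_grammar_hits(rng, f"{ngid}_p", arch, name_meta))

        # --- labelled regulator family genes
        for fam in sorted(config.family_counts):
            count = config.family_counts[fam]
            p_in = config.family_p_in.get(fam, config.background_p_in)
            grammar = config.family_grammars[fam]
            for _ in range(count):
                glen = int(rng.integers(600, 1800))
                place_in = bool(rng.random() < p_in)
                if place_in:
                    if not intervals:
                        raise ValueError(
                            f"family {fam!r} requires in-BGC placement but "
                            "n_bgc_per_genome is 0"
                        )
                    rs, re_ = intervals[int(rng.integers(len(intervals)))]
                    glen = min(glen, re_ - rs)
                    start = int(rng.integers(rs, re_ - glen + 1))
                    rid = contig_regions[intervals.index((rs, re_))].region_id
                    gid = new_gene(start, start + glen, fam, True, rid)
                else:
                    start, end = _place_in_gaps(rng, gaps, glen)
                    gid = new_gene(start, end, fam, False, None)
                arch = grammar[int(rng.integers(len(grammar)))]
                fam_hits = _grammar_hits(rng, f"{gid}_p", arch, name_meta)
                hits.extend(fam_hits)
                if rng.random() < config.decoy_rate:
                    target = fam_hits[int(rng.integers(len(fam_hits)))]
                    hits.append(_decoy_hit(rng, target, name_meta))

        # --- unlabeled background genes
        for _ in range(config.genes_per_genome):
            glen = int(rng.integers(600, 1800))
            place_in = bool(rng.random() < config.background_p_in) and bool(intervals)
            if place_in:
                rs, re_ = intervals[int(rng.integers(len(intervals)))]
                glen = min(glen, re_ - rs)
                start = int(rng.integers(rs, re_ - glen + 1))
                rid = contig_regions[intervals.index((rs, re_))].region_id
                gid = new_gene(start, start + glen, None, True, rid)
            else:
                start, end = _place_in_gaps(rng, gaps, glen)
                gid = new_gene(start, end, None, False, None)
            if rng.random() < 0.5:
                dom = _BACKGROUND_DOMAINS[int(rng.integers(len(_BACKGROUND_DOMAINS)))]
                hits.extend(_grammar_hits(rng, f"{gid}_p", (dom,), name_meta))

    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "protein_id", "contig", "start", "end", "strand"]
    )
    truth = SimTruth(
        genes=pd.DataFrame(
            truth_rows, columns=["gene_id", "family", "in_bgc", "region_id", "hidden"]
        ),
        hidden_windows=hidden_windows,
    )
    return SimResult(
        genes=genes, hits=hits, regions=regions, pfam_meta=registry, truth=truth,
        config=config,
    )


def _hidden_centers(
    intervals: Sequence[tuple[int, int]],
    contig_length: int,
    n_hidden: int,
    margin: int,
) -> list[int]:
    """Deterministic window centers at >= margin from every region interval."""
    half = 10_000
    blocked = [(max(0, s - margin), min(contig_length, e + margin)) for s, e in intervals]
    allowed = _complement_gaps(blocked, contig_length)
    centers: list[int] = []
    spacing = 2 * half + 1000
    for s, e in allowed:
        lo, hi = max(s + half, half), min(e - half, contig_length - half)
        c = lo
        while c <= hi and len(centers) < n_hidden:
            centers.append(int(c))
            c += spacing
        if len(centers) >= n_hidden:
            break
    if len(centers) < n_hidden:
        raise ValueError(
            f"cannot place {n_hidden} hidden windows at margin {margin} nt; "
            "contig too crowded"
        )
    return centers


# ---------------------------------------------------------------------------
# promoters


def generate_promoter(
    unit: str,
    spacer: int,
    flank: int,
    seed: int = 0,
    spacer_seq: str | None = None,
) -> tuple[str, PromoterTruth]:
    """A promoter containing exactly one planted spaced direct repeat.

    Returns ``flank`` random nucleotides, the unit, ``spacer`` random
    nucleotides (or the supplied ``spacer_seq``), the unit again, and another
    ``flank`` random nucleotides. Random parts are rejection-sampled so the
    returned sequence contains no additional exact copy of the unit (nor of
    its reverse complement, which would plant a minus-strand repeat).
    """
    unit = unit.upper()
    if not unit or set(unit) - set("ACGT"):
        raise ValueError("unit must be a non-empty string over A,C,G,T")
    if spacer < 0:
        raise ValueError("spacer must be >= 0")
    if spacer_seq is not None and len(spacer_seq) != spacer:
        raise ValueError("spacer_seq length must equal spacer")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))

    def draw(n: int) -> str:
        return "".join(rng.choice(alphabet, size=n)) if n else ""

    rc = unit.translate(str.maketrans("ACGT", "TGCA"))[::-1]

    def count(hay: str, needle: str) -> int:
        return sum(
            1 for i in range(len(hay) - len(needle) + 1) if hay[i : i + len(needle)] == needle
        )

    for _ in range(10_000):
        sp = spacer_seq if spacer_seq is not None else draw(spacer)
        core = unit + sp + unit
        seq = draw(flank) + core + draw(flank)
        # the planted core may contain extra overlapping copies for
        # self-periodic units (e.g. unit "AA", core "AAAA"); the random parts
        # must add no copies beyond that unavoidable baseline
        if count(seq, unit) == count(core, unit) and (
            rc == unit or count(seq, rc) == count(core, rc)
        ):
            return seq, PromoterTruth(
                unit=unit,
                spacer=spacer,
                first_start=flank,
                second_start=flank + len(unit) + spacer,
            )
    raise RuntimeError("rejection sampling failed to produce a clean promoter")


# ---------------------------------------------------------------------------
# fixture I/O (plain-text formats only)

_DOMTBL_HEADER = (
    "#target_name t_acc tlen query_name q_acc qlen full_evalue full_score "
    "full_bias dom_n dom_of c_evalue i_evalue dom_score dom_bias hmm_from "
    "hmm_to ali_from ali_to env_from env_to acc description\n"
)


def write_domtblout(hits: Sequence[DomainHit], path: str | Path) -> None:
    """Write hits in the 23-column per-domain tabular layout.

    Scores are written at full precision so a parse round-trips exactly.
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    with open(path, "w") as fh:
        fh.write(_DOMTBL_HEADER)
        for pid in sorted(by_protein):
            phits = sorted(by_protein[pid], key=lambda h: (h.start_aa, h.end_aa))
            tlen = max(h.end_aa for h in phits) + 20
            for k, h in enumerate(phits, 1):
                qlen = h.end_aa - h.start_aa + 1
                fh.write(
                    f"{h.protein_id} - {tlen} {h.pfam_name} {h.pfam_accession} {qlen} "
                    f"1e-20 {format(h.bitscore, '.17g')} 0.0 {k} {len(phits)} "
                    f"1e-20 1e-20 {format(h.bitscore, '.17g')} 0.0 "
                    f"1 {qlen} {h.start_aa} {h.end_aa} {h.start_aa} {h.end_aa} "
                    f"0.95 simulated domain hit\n"
                )


def write_gff(genes: pd.DataFrame, path: str | Path) -> None:
    """GFF3 gene table (type CDS, 1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.sort_values(["contig", "start"]).itertuples(index=False):
            attrs = f"ID={row.gene_id};protein_id={row.protein_id}"
            fh.write(
                f"{row.contig}\tbgcbeacon_sim\tCDS\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t0\t{attrs}\n"
            )


def load_gff(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            rows.append(
                {
                    "gene_id": attrs["ID"],
                    "protein_id": attrs.get("protein_id", attrs["ID"]),
                    "contig": parts[0],
                    "start": int(parts[3]) - 1,
                    "end": int(parts[4]),
                    "strand": parts[6],
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "protein_id", "contig", "start", "end", "strand"]
    )


def write_fixture(result: SimResult, outdir: str | Path) -> Path:
    """Write a full fixture directory: per-genome GFF3, domtblout and region JSON,
    plus Pfam metadata, a combined region TSV and the ground-truth tables."""
    outdir = Path(outdir)
    for sub in ("genes", "domtblout", "regions"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    contigs = sorted(result.genes["contig"].unique()) if len(result.genes) else []
    hits_by_contig: dict[str, list[DomainHit]] = {c: [] for c in contigs}
    gene_contig = dict(zip(result.genes["gene_id"], result.genes["contig"]))
    for h in result.hits:
        contig = gene_contig.get(h.protein_id[:-2], None)  # protein_id = gene_id + "_p"
        if contig is None:
            contig = h.protein_id.split("_g")[0]
        hits_by_contig.setdefault(contig, []).append(h)
    for contig in contigs:
        write_gff(
            result.genes[result.genes["contig"] == contig], outdir / "genes" / f"{contig}.gff3"
        )
        write_domtblout(hits_by_contig.get(contig, []), outdir / "domtblout" / f"{contig}.domtbl")
        write_regions_json(
            [r for r in result.regions if r.contig == contig],
            outdir / "regions" / f"{contig}.json",
        )
    write_pfam_meta(result.pfam_meta.values(), outdir / "pfam_meta.tsv")
    with open(outdir / "regions.tsv", "w") as fh:
        fh.write("region_id\tcontig\tstart\tend\tclasses\tknown_cluster_id\tknown_similarity_pct\n")
        for r in result.regions:
            fh.write(
                f"{r.region_id}\t{r.contig}\t{r.start}\t{r.end}\t{','.join(r.classes)}\t"
                f"{r.known_cluster_id or ''}\t"
                f"{'' if r.known_similarity_pct is None else format(r.known_similarity_pct, '.17g')}\n"
            )
    with open(outdir / "activities.tsv", "w") as fh:
        fh.write("cluster_id\tactivity\n")
        for cid, acts in sorted(activity_table().items()):
            for act in acts:
                fh.write(f"{cid}\t{act}\n")
    result.truth.genes.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "hidden_windows.tsv", "w") as fh:
        fh.write("contig\tstart\tend\tbeacon_gene_id\n")
        for w in result.truth.hidden_windows:
            fh.write(f"{w.contig}\t{w.start}\t{w.end}\t{w.beacon_gene_id}\n")
    if result.config is not None:
        with open(outdir / "config.json", "w") as fh:
            cfg = {
                k: v
                for k, v in vars(result.config).items()
                if not callable(v)
            }
            cfg["family_grammars"] = {
                k: [list(a) for a in v] for k, v in cfg["family_grammars"].items()
            }
            json.dump(cfg, fh, indent=1, default=str)
    return outdir


def load_fixture(indir: str | Path) -> SimResult:
    """Load a fixture directory written by :func:`write_fixture`."""
    from .domain_hits import parse_domtblout

    indir = Path(indir)
    registry = load_pfam_meta(indir / "pfam_meta.tsv")
    gene_frames = [load_gff(p) for p in sorted((indir / "genes").glob("*.gff3"))]
    genes = (
        pd.concat(gene_frames, ignore_index=True)
        if gene_frames
        else pd.DataFrame(columns=["gene_id", "protein_id", "contig", "start", "end", "strand"])
    )
    hits: list[DomainHit] = []
    for p in sorted((indir / "domtblout").glob("*.domtbl")):
        hits.extend(parse_domtblout(p, registry))
    regions: list[BgcRegion] = []
    for p in sorted((indir / "regions").glob("*.json")):
        regions.extend(load_regions_json(p))
    truth = None
    truth_path = indir / "truth.tsv"
    if truth_path.exists():
        tg = pd.read_csv(
            truth_path, sep="\t", keep_default_na=False,
            dtype={"family": str, "region_id": str},
        )
        for col in ("in_bgc", "hidden"):  # serialized as True/False strings
            tg[col] = tg[col].map({"True": True, "False": False, True: True, False: False})
        windows = []
        hw_path = indir / "hidden_windows.tsv"
        if hw_path.exists():
            hw = pd.read_csv(hw_path, sep="\t")
            windows = [
                HiddenWindow(r.contig, int(r.start), int(r.end), r.beacon_gene_id)
                for r in hw.itertuples(index=False)
            ]
        truth = SimTruth(genes=tg, hidden_windows=windows)
    return SimResult(
        genes=genes,
        hits=hits,
        regions=regions,
        pfam_meta=registry,
        truth=truth if truth is not None else SimTruth(genes=pd.DataFrame()),
    )
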