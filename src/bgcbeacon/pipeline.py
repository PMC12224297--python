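"""End-to-end orchestration of the regulator-mining stages.

``run_pipeline`` executes, on a fixture directory, the chain

    domain hits -> co-occurrence network -> subclass classification
    -> BGC association -> beacon discovery

writing per-stage TSV/JSON/GraphML outputs plus a deterministic run manifest
(config hash, input checksums, per-stage record counts, collected warnings).
The pipeline composes the stage functions verbatim and adds no computation of
its own, so stage-wise manual runs reproduce its outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings as _warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import bgc_association as assoc
from . import beacon_discovery as beacon
from . import cooccurrence_network as coocnet
from . import domain_hits as dh
from . import regulator_classification as rc
from . import synthetic_data as sim

__all__ = ["RunConfig", "run_pipeline", "simulate", "load_activity_table"]


@dataclass
class RunConfig:
    """All stage parameters with their standard defaults.

    Defaults mirror the canonical analysis settings: co-occurrence edges need
    at least 100 supporting proteins, MCL inflation 6, known-cluster
    similarity at least 50%, associations observed at least 10 times, 20 kb
    beacon distance and 20 kb candidate windows.
    """

    input_dir: str | Path = "."
    output_dir: str | Path = "run_output"
    min_cooccurrence: int = 100
    inflation: float = 6.0
    min_similarity_pct: float = 50.0
    min_function_count: int = 10
    min_subclass_total: int = 20
    min_distance_nt: int = 20_000
    window_nt: int = 20_000
    similarity_cutoff: float = 0.3
    target_subclasses: tuple[str, ...] = ("SARP_small",)
    keywords_path: str | Path | None = None
    ruleset_path: str | Path | None = None
    biosyn_path: str | Path | None = None
    activity_path: str | Path | None = None
    seed: int = 0

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_activity_table(path: str | Path) -> dict[str, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t")
    table: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        table.setdefault(row.cluster_id, []).append(row.activity)
    return {k: tuple(v) for k, v in table.items()}


def simulate(config: sim.SimConfig, outdir: str | Path) -> Path:
    """Generate a synthetic fixture directory (front-end to the generator)."""
    result = sim.generate_genomes(config)
    return sim.write_fixture(result, outdir)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages on ``config.input_dir``; returns the manifest dict."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    collected: list[str] = []

    with _warnings.catch_warnings(record=True) as wrec:
        _warnings.simplefilter("always")

        fixture = sim.load_fixture(indir)
        genes, hits, regions = fixture.genes, fixture.hits, fixture.regions

        # stage 1: regulatory selection and architectures
        keywords = dh.load_keywords(config.keywords_path)
        reg_accs = dh.select_regulatory_pfams(fixture.pfam_meta.values(), keywords)
        protein_to_gene = dict(zip(genes["protein_id"], genes["gene_id"]))
        regulators = dh.collect_regulators(hits, reg_accs, protein_to_gene)
        _write_architectures(regulators, outdir / "architectures.tsv")

        # stage 2: co-occurrence network + MCL
        net = coocnet.build_network(regulators, min_count=config.min_cooccurrence)
        mcl = None
        if net.nodes:
            mcl = coocnet.mcl_cluster(net, coocnet.MclParams(inflation=config.inflation))
            if not mcl.converged:
                collected.append("mcl: did not converge")
        coocnet.export_network(net, mcl, outdir / "network")

        # stage 3: subclass classification
        rules = rc.load_ruleset(config.ruleset_path)
        classifications = rc.classify_all(regulators, rules)
        rc.write_classifications(classifications, outdir / "classifications.tsv")
        cls_df = pd.DataFrame(
            [
                {"protein_id": c.protein_id, "gene_id": c.gene_id, "subclass": c.subclass}
                for c in classifications
            ],
            columns=["protein_id", "gene_id", "subclass"],
        )

        # stage 4: BGC association
        flags = assoc.flag_genes(genes, regions) if len(genes) else genes.assign(
            in_bgc=pd.Series(dtype=bool), region_id=pd.Series(dtype=object)
        )
        records = assoc.in_bgc_ratio(cls_df, flags, regions) if len(cls_df) else {}
        activity_path = config.activity_path
        if activity_path is None and (indir / "activities.tsv").exists():
            activity_path = indir / "activities.tsv"
        if records and activity_path is not None:
            assoc.functional_association(
                records,
                cls_df,
                flags,
                regions,
                load_activity_table(activity_path),
                min_similarity_pct=config.min_similarity_pct,
                min_count=config.min_function_count,
            )
        assoc.write_association_tsv(records, outdir / "associations.tsv")
        try:
            selected = assoc.select_upper_quartile(records, min_total=config.min_subclass_total)
        except ValueError as exc:
            selected = []
            collected.append(f"upper-quartile selection skipped: {exc}")
        (outdir / "selected_subclasses.txt").write_text("\n".join(selected) + "\n")

        # stage 5: beacon discovery
        candidates: list[beacon.CandidateRegion] = []
        n_clusters = n_singletons = 0
        if len(cls_df):
            beacons = beacon.find_beacon_genes(
                cls_df, flags, regions, set(config.target_subclasses),
                min_distance_nt=config.min_distance_nt,
            )
            hits_by_gene = _resolved_hits_by_gene(hits, protein_to_gene)
            contig_length = None
            cfg_json = indir / "config.json"
            if cfg_json.exists():
                contig_length = json.loads(cfg_json.read_text()).get("contig_length")
            for _, b in beacons.iterrows():
                cand = beacon.extract_window(
                    b, genes, hits_by_gene, window_nt=config.window_nt,
                    contig_length=contig_length,
                )
                if cand.truncated:
                    collected.append(f"window truncated at contig edge: {cand.beacon_gene_id}")
                beacon.count_biosynthetic_domains(
                    cand, beacon.load_biosynthetic_pfams(config.biosyn_path)
                )
                candidates.append(cand)
            _, n_clusters, n_singletons = beacon.cluster_regions(
                candidates, cutoff=config.similarity_cutoff
            )
            beacon.write_candidates_tsv(candidates, outdir / "candidates.tsv")

        collected.extend(str(w.message) for w in wrec)

    manifest = {
        "config_hash": config.config_hash(),
        "input_checksums": {
            str(p.relative_to(indir)): _checksum(p)
            for p in sorted(indir.rglob("*"))
            if p.is_file()
        },
        "counts": {
            "genes": int(len(genes)),
            "domain_hits": int(len(hits)),
            "regions": int(len(regions)),
            "regulators": len(regulators),
            "network_nodes": len(net.nodes),
            "network_edges": len(net.edges),
            "mcl_clusters": len(mcl.clusters) if mcl else 0,
            "classified": int((cls_df["subclass"] != rc.UNCLASSIFIED).sum())
            if len(cls_df)
            else 0,
            "association_records": len(records),
            "selected_subclasses": len(selected),
            "beacons": len(candidates),
            "candidate_clusters": n_clusters,
            "candidate_singletons": n_singletons,
        },
        "warnings": collected,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _write_architectures(regulators: Sequence[dh.RegulatorProtein], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tgene_id\tarchitecture\n")
        for r in regulators:
            fh.write(f"{r.protein_id}\t{r.gene_id}\t{','.join(r.architecture)}\n")


def _resolved_hits_by_gene(
    hits: Sequence[dh.DomainHit], protein_to_gene: Mapping[str, str]
) -> dict[str, list[dh.DomainHit]]:
    by_protein: dict[str, list[dh.DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    out: dict[str, list[dh.DomainHit]] = {}
    for pid, phits in by_protein.items():
        gid = protein_to_gene.get(pid, pid)
        out[gid] = dh.resolve_overlaps(phits)
    return out
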