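"""In/out-BGC membership, ratios, nearest-core classes, filters, quartile rule."""

import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgcbeacon.bgc_association import (
    AssociationRecord,
    BgcRegion,
    CoreGene,
    assign_in_bgc,
    flag_genes,
    functional_association,
    in_bgc_ratio,
    load_regions_json,
    nearest_core_class,
    round_pct,
    select_upper_quartile,
    write_regions_json,
)


def _region(rid="r0", contig="c", start=0, end=20_000, cores=(), sim=None, kc=None, classes=("NRPS",)):
    return BgcRegion(
        region_id=rid, contig=contig, start=start, end=end, classes=classes,
        core_genes=cores, known_cluster_id=kc, known_similarity_pct=sim,
    )


# ---------------------------------------------------------------------------
# membership


def test_contained_gene_is_in():
    flag, rid = assign_in_bgc("c", 100, 400, [_region()])
    assert flag and rid == "r0"


def test_straddling_gene_is_out():
    flag, rid = assign_in_bgc("c", 19_990, 20_010, [_region()])
    assert not flag and rid is None


def test_unknown_contig_is_error():
    with pytest.raises(ValueError, match="unknown contig"):
        assign_in_bgc("nope", 0, 10, [_region()], known_contigs={"c"})


def test_flags_equal_brute_force_all_pairs():
    rng = random.Random(9)
    regions = []
    for i in range(20):
        contig = f"c{rng.randint(0, 2)}"
        s = rng.randint(0, 80_000)
        regions.append(_region(rid=f"r{i}", contig=contig, start=s, end=s + rng.randint(500, 15_000)))
    genes = pd.DataFrame(
        [
            {
                "gene_id": f"g{i}",
                "contig": f"c{rng.randint(0, 2)}",
                "start": (s := rng.randint(0, 95_000)),
                "end": s + rng.randint(100, 6_000),
            }
            for i in range(500)
        ]
    )
    flags = flag_genes(genes, regions)
    for row in flags.itertuples(index=False):
        expected = any(
            r.contig == row.contig and r.start <= row.start and row.end <= r.end
            for r in regions
        )
        assert bool(row.in_bgc) == expected


# ---------------------------------------------------------------------------
# ratios


def test_worked_ratio_864_in_189_out():
    cls = pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(1053)], "subclass": "SARP_small"}
    )
    flags = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(1053)],
            "contig": "c",
            "start": 0,
            "end": 10,
            "in_bgc": [i < 864 for i in range(1053)],
            "region_id": None,
        }
    )
    (rec,) = in_bgc_ratio(cls, flags).values()
    assert (rec.n_in, rec.n_out) == (864, 189)
    assert rec.in_ratio_pct == 82.1
    assert round_pct(rec.n_out / rec.total) == 17.9


def test_zero_in_ratio():
    rec = AssociationRecord("x", n_in=0, n_out=10)
    assert rec.in_ratio_pct == 0.0


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 5000), st.integers(0, 5000))
def test_ratio_equals_independent_arithmetic(n_in, n_out):
    if n_in + n_out == 0:
        return
    rec = AssociationRecord("x", n_in=n_in, n_out=n_out)
    assert rec.in_ratio == pytest.approx(n_in / (n_in + n_out))


def test_class_distribution_sums_to_n_in(small_cohort):
    from bgcbeacon.domain_hits import collect_regulators, load_keywords, select_regulatory_pfams
    from bgcbeacon.regulator_classification import classify_all, load_ruleset

    accs = select_regulatory_pfams(small_cohort.pfam_meta.values(), load_keywords())
    p2g = dict(zip(small_cohort.genes["protein_id"], small_cohort.genes["gene_id"]))
    regs = collect_regulators(small_cohort.hits, accs, p2g)
    cls = pd.DataFrame(
        [
            {"gene_id": c.gene_id, "subclass": c.subclass}
            for c in classify_all(regs, load_ruleset())
        ]
    )
    flags = flag_genes(small_cohort.genes, small_cohort.regions)
    records = in_bgc_ratio(cls, flags, small_cohort.regions)
    assert records
    for rec in records.values():
        assert sum(rec.class_distribution.values()) == rec.n_in
        assert rec.n_in + rec.n_out == rec.total


# ---------------------------------------------------------------------------
# nearest core gene


def test_nearest_core_by_gap():
    region = _region(
        cores=(
            CoreGene("c1", "NRPS", 1000, 4000),
            CoreGene("c2", "T1PKS", 8000, 12_000),
        )
    )
    cls, fallback = nearest_core_class(5000, 5600, region)
    assert cls == "NRPS" and not fallback  # gap 1000 < 2400


def test_overlapping_core_wins_with_gap_zero():
    region = _region(cores=(CoreGene("c1", "RiPP", 1000, 4000),))
    cls, _ = nearest_core_class(2000, 2500, region)
    assert cls == "RiPP"


def test_region_without_cores_falls_back_to_first_class():
    cls, fallback = nearest_core_class(100, 200, _region(classes=("terpene", "other")))
    assert cls == "terpene" and fallback


def test_nearest_core_matches_brute_force():
    rng = random.Random(2)
    for _ in range(100):
        cores = []
        for i in range(rng.randint(1, 5)):
            s = rng.randint(0, 18_000)
            cores.append(CoreGene(f"c{i}", f"cls{i}", s, min(20_000, s + rng.randint(100, 3000))))
        region = _region(cores=tuple(cores))
        gs = rng.randint(0, 19_000)
        ge = min(20_000, gs + rng.randint(50, 900))

        def gap(cg):
            return max(0, cg.start - ge, gs - cg.end)

        best = min(cores, key=lambda cg: (gap(cg), cg.start))
        assert nearest_core_class(gs, ge, region)[0] == best.bgc_class


# ---------------------------------------------------------------------------
# functional association


def _cohort(sims, counts):
    """Build (records, cls, flags, regions) with one subclass per similarity bin."""
    regions, rows, frows = [], [], []
    gid = 0
    for i, (sim, n) in enumerate(zip(sims, counts)):
        rid = f"r{i}"
        regions.append(_region(rid=rid, contig="c", start=i * 30_000, end=i * 30_000 + 20_000,
                               sim=sim, kc=f"K{i}"))
        for _ in range(n):
            rows.append({"gene_id": f"g{gid}", "subclass": "S"})
            frows.append({"gene_id": f"g{gid}", "contig": "c", "start": i * 30_000 + 10,
                          "end": i * 30_000 + 20, "in_bgc": True, "region_id": rid})
            gid += 1
    cls = pd.DataFrame(rows)
    flags = pd.DataFrame(frows)
    records = in_bgc_ratio(cls, flags, regions)
    return records, cls, flags, regions


def test_similarity_just_below_threshold_counts_as_unknown():
    records, cls, flags, regions = _cohort([49.9], [12])
    functional_association(records, cls, flags, regions, {"K0": ("antibacterial",)})
    rec = records["S"]
    assert rec.function_distribution == {}
    assert rec.unknown_function_fraction == pytest.approx(1.0)


def test_min_count_boundary_nine_dropped_ten_kept():
    for n, expect in [(9, {}), (10, {"antibacterial": 10})]:
        records, cls, flags, regions = _cohort([80.0], [n])
        functional_association(records, cls, flags, regions, {"K0": ("antibacterial",)})
        assert records["S"].function_distribution == expect


def test_function_distribution_equals_direct_tally():
    rng = random.Random(7)
    sims = [rng.uniform(0, 100) for _ in range(6)]
    counts = [rng.randint(1, 30) for _ in range(6)]
    acts = {f"K{i}": (rng.choice(["antibacterial", "antifungal", "cytotoxic"]),)
            for i in range(6) if rng.random() < 0.8}
    records, cls, flags, regions = _cohort(sims, counts)
    functional_association(records, cls, flags, regions, acts)
    # independent tally under the two filters
    expected: dict[str, int] = {}
    unknown = 0
    for i in range(6):
        eligible = sims[i] >= 50.0 and f"K{i}" in acts
        if eligible:
            act = acts[f"K{i}"][0]
            expected[act] = expected.get(act, 0) + counts[i]
        else:
            unknown += counts[i]
    expected = {k: v for k, v in expected.items() if v >= 10}
    rec = records["S"]
    assert rec.function_distribution == expected
    assert rec.unknown_function_fraction == pytest.approx(unknown / sum(counts))


@settings(max_examples=30, derandomize=True)
@given(
    st.lists(st.tuples(st.floats(0, 100), st.integers(1, 25)), min_size=1, max_size=6),
    st.floats(0, 100),
    st.integers(1, 15),
)
def test_filters_monotone(bins, min_sim, min_count):
    """Raising either filter threshold never increases any function count."""
    sims = [b[0] for b in bins]
    counts = [b[1] for b in bins]
    acts = {f"K{i}": ("antibacterial",) for i in range(len(bins))}

    def run(ms, mc):
        records, cls, flags, regions = _cohort(sims, counts)
        functional_association(records, cls, flags, regions, acts,
                               min_similarity_pct=ms, min_count=mc)
        return records["S"].function_distribution

    base = run(min_sim, min_count)
    for tighter in (run(min_sim + 5, min_count), run(min_sim, min_count + 3)):
        for act, c in tighter.items():
            assert act in base and c <= base[act]


# ---------------------------------------------------------------------------
# upper quartile


def _rec(name, ratio, total=100):
    n_in = round(ratio * total)
    return AssociationRecord(name, n_in=n_in, n_out=total - n_in)


def test_quartile_selects_top_subclass():
    records = {n: _rec(n, r) for n, r in zip("abcd", [0.1, 0.2, 0.3, 0.9])}
    assert select_upper_quartile(records) == ["d"]


def test_quartile_degenerate_all_equal():
    records = {n: _rec(n, 0.5) for n in "abcde"}
    assert select_upper_quartile(records) == list("abcde")


def test_quartile_excludes_small_subclasses_before_percentile():
    records = {n: _rec(n, r) for n, r in zip("abcd", [0.1, 0.2, 0.3, 0.4])}
    records["tiny"] = _rec("tiny", 1.0, total=5)  # below min_total, ignored
    assert select_upper_quartile(records, min_total=20) == ["d"]


def test_quartile_too_few_subclasses_errors():
    records = {n: _rec(n, 0.5) for n in "abc"}
    with pytest.raises(ValueError, match="manual"):
        select_upper_quartile(records)


def test_quartile_matches_numpy_percentile():
    rng = random.Random(5)
    ratios = [rng.random() for _ in range(16)]
    records = {f"s{i}": _rec(f"s{i}", r) for i, r in enumerate(ratios)}
    got = select_upper_quartile(records)
    q75 = float(np.percentile([records[f"s{i}"].in_ratio for i in range(16)], 75))
    expected = sorted(f"s{i}" for i in range(16) if records[f"s{i}"].in_ratio >= q75)
    assert got == expected


# ---------------------------------------------------------------------------
# region JSON round trip


def test_regions_json_round_trip(tmp_path):
    regions = [
        _region(rid="rA", sim=63.2, kc="BGC0001", cores=(CoreGene("x", "NRPS", 10, 500),)),
        _region(rid="rB", contig="c2", start=5, end=50),
    ]
    p = tmp_path / "regions.json"
    write_regions_json(regions, p)
    assert load_regions_json(p) == regions
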