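"""Beacon selection, window extraction, similarity clustering, repeat scanning."""

import itertools
import random

import networkx as nx
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgcbeacon.bgc_association import BgcRegion, flag_genes
from bgcbeacon.beacon_discovery import (
    CandidateRegion,
    cluster_regions,
    count_biosynthetic_domains,
    extract_window,
    find_beacon_genes,
    find_direct_repeats,
    region_similarity,
)


def _region(rid, start, end, contig="c"):
    return BgcRegion(region_id=rid, contig=contig, start=start, end=end, classes=("NRPS",))


def _cls(gene_ids, subclass="SARP_small"):
    return pd.DataFrame({"gene_id": gene_ids, "subclass": subclass})


def _flags(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "contig", "start", "end", "in_bgc", "region_id"]
    )


# ---------------------------------------------------------------------------
# beacons


def test_beacon_boundary_gap_inclusive():
    flags = _flags([
        ("gA", "c", 29_000, 30_000, False, None),  # gap to region = 20_001
        ("gB", "c", 29_001, 30_001, False, None),  # gap exactly 20_000
        ("gC", "c", 29_002, 30_002, False, None),  # gap 19_999 -> excluded
    ])
    regions = [_region("r0", 50_001, 70_001)]
    got = find_beacon_genes(_cls(["gA", "gB", "gC"]), flags, regions, "SARP_small")
    assert list(got["gene_id"]) == ["gA", "gB"]


def test_in_bgc_gene_never_a_beacon():
    flags = _flags([("gA", "c", 100, 900, True, "r0")])
    regions = [_region("r0", 0, 20_000)]
    got = find_beacon_genes(_cls(["gA"]), flags, regions, "SARP_small")
    assert got.empty


def test_contig_without_regions_qualifies_trivially():
    flags = _flags([("gA", "lonely", 10, 500, False, None)])
    got = find_beacon_genes(_cls(["gA"]), flags, [_region("r0", 0, 100, contig="other")], "SARP_small")
    assert list(got["gene_id"]) == ["gA"]


def test_beacons_match_brute_force_min_gap():
    rng = random.Random(3)
    regions = [
        _region(f"r{i}", s := rng.randrange(0, 400_000), s + 20_000) for i in range(6)
    ]
    rows = []
    for i in range(200):
        s = rng.randrange(0, 450_000)
        e = s + rng.randrange(300, 2000)
        in_bgc = any(r.start <= s and e <= r.end for r in regions)
        rid = next((r.region_id for r in regions if r.start <= s and e <= r.end), None)
        rows.append((f"g{i}", "c", s, e, in_bgc, rid))
    flags = _flags(rows)
    got = set(find_beacon_genes(_cls([r[0] for r in rows]), flags, regions, "SARP_small")["gene_id"])
    expected = set()
    for gid, _, s, e, in_bgc, _ in rows:
        if in_bgc:
            continue
        gaps = [max(0, r.start - e, s - r.end) for r in regions]
        if min(gaps) >= 20_000:
            expected.add(gid)
    assert got == expected


# ---------------------------------------------------------------------------
# windows


def test_window_centered_on_midpoint():
    genes = pd.DataFrame(
        [{"gene_id": "b", "contig": "c", "start": 49_500, "end": 50_500}]
    )
    cand = extract_window(
        {"gene_id": "b", "contig": "c", "start": 49_500, "end": 50_500}, genes
    )
    assert (cand.start, cand.end) == (40_000, 60_000)
    assert not cand.truncated
    assert cand.gene_ids == ("b",)


def test_window_clipped_at_contig_start():
    genes = pd.DataFrame([{"gene_id": "b", "contig": "c", "start": 1000, "end": 2000}])
    cand = extract_window({"gene_id": "b", "contig": "c", "start": 1000, "end": 2000}, genes)
    assert cand.start == 0 and cand.truncated


def test_window_gene_inclusion_matches_brute_force():
    rng = random.Random(8)
    genes = pd.DataFrame(
        [
            {
                "gene_id": f"g{i}",
                "contig": "c",
                "start": (s := rng.randrange(0, 100_000)),
                "end": s + rng.randrange(200, 3000),
            }
            for i in range(300)
        ]
    )
    beacon = {"gene_id": "g0", "contig": "c",
              "start": int(genes.loc[0, "start"]), "end": int(genes.loc[0, "end"])}
    cand = extract_window(beacon, genes)
    expected = {
        r.gene_id
        for r in genes.itertuples(index=False)
        if r.start < cand.end and r.end > cand.start
    }
    assert set(cand.gene_ids) == expected


# ---------------------------------------------------------------------------
# biosynthetic counting


def test_biosyn_count_direct_tally():
    cand = CandidateRegion("b", "S", "c", 0, 20_000,
                           domain_string=("Condensation", "Condensation", "Methyltransf_11", "MFS_1"))
    assert count_biosynthetic_domains(cand, {"Condensation", "Methyltransf_11"}) == 3
    assert cand.biosyn_count == 3


def test_biosyn_count_zero_and_empty_set_error():
    cand = CandidateRegion("b", "S", "c", 0, 20_000, domain_string=("MFS_1",))
    assert count_biosynthetic_domains(cand, {"Condensation"}) == 0
    with pytest.raises(ValueError, match="empty"):
        count_biosynthetic_domains(cand, set())


# ---------------------------------------------------------------------------
# similarity and clustering


def _cand(name, domains):
    return CandidateRegion(name, "S", "c", 0, 20_000, domain_string=tuple(domains))


def test_similarity_identity_and_disjoint():
    a = _cand("a", "ABC")
    assert region_similarity(a, a) == pytest.approx(1.0)
    assert region_similarity(a, _cand("b", "XYZ")) == 0.0
    assert region_similarity(a, _cand("e", "")) == 0.0


def test_similarity_hand_computed_example():
    a, b = _cand("a", "ABC"), _cand("b", "BCD")
    expected = 0.5 * (2 / 4) + 0.5 * (1 / 3)
    assert region_similarity(a, b) == pytest.approx(expected)
    assert region_similarity(b, a) == pytest.approx(expected)  # symmetric


def test_cluster_no_pairs_all_singletons():
    cands = [_cand("a", "ABC"), _cand("b", "XYZ"), _cand("c", "MNO")]
    labels, n_clusters, n_singletons = cluster_regions(cands, cutoff=0.3)
    assert (n_clusters, n_singletons) == (0, 3)
    assert all(c.cluster_id == c.beacon_gene_id for c in cands)


def test_cluster_chain_transitivity():
    a = _cand("a", "ABCD")
    b = _cand("b", "BCDE")
    c = _cand("c", "CDEF")
    # a~b and b~c similar, a~c less so; single linkage joins all three
    assert region_similarity(a, c) < region_similarity(a, b)
    labels, n_clusters, n_singletons = cluster_regions([a, b, c], cutoff=0.4)
    assert (n_clusters, n_singletons) == (1, 0)
    assert len(set(labels.values())) == 1


def test_clustering_matches_brute_force_components():
    rng = random.Random(6)
    pool = list("ABCDEFGH")
    cands = [
        _cand(f"g{i}", rng.sample(pool, rng.randint(2, 5))) for i in range(15)
    ]
    cutoff = 0.35
    labels, n_clusters, n_singletons = cluster_regions(cands, cutoff=cutoff)
    g = nx.Graph()
    g.add_nodes_from(c.beacon_gene_id for c in cands)
    for x, y in itertools.combinations(cands, 2):
        if region_similarity(x, y) >= cutoff:
            g.add_edge(x.beacon_gene_id, y.beacon_gene_id)
    comps = sorted((frozenset(c) for c in nx.connected_components(g)), key=min)
    got = {}
    for node, lab in labels.items():
        got.setdefault(lab, set()).add(node)
    assert sorted(map(frozenset, got.values()), key=min) == comps
    assert n_clusters + n_singletons == len(comps)


@settings(max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_raising_cutoff_never_merges_components(seed):
    rng = random.Random(seed)
    pool = list("ABCDEF")
    cands = [_cand(f"g{i}", rng.sample(pool, rng.randint(1, 4))) for i in range(8)]
    counts = []
    for cutoff in (0.2, 0.4, 0.6, 0.8):
        _, nc, ns = cluster_regions(cands, cutoff=cutoff)
        counts.append(nc + ns)
    assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# direct repeats


def test_planted_heptamer_repeat_found():
    seq = "TTGCAGT" + "ACGTACGTAC" + "TTGCAGT"
    hits = find_direct_repeats(seq, unit_len=7, spacer_min=10, spacer_max=10)
    assert len(hits) == 1
    h = hits[0]
    assert (h.unit, h.spacer, h.first_start, h.second_start) == ("TTGCAGT", 10, 0, 17)


def test_poly_a_hits_every_offset():
    seq = "A" * 30
    hits = find_direct_repeats(seq, unit_len=7, spacer_min=0, spacer_max=0)
    plus = [h for h in hits if h.strand == "+"]
    assert [h.first_start for h in plus] == list(range(30 - 14 + 1))


def test_unit_len_below_four_rejected():
    with pytest.raises(ValueError, match="unit_len"):
        find_direct_repeats("ACGTACGT", unit_len=3)


def test_n_never_matches():
    seq = "TTGCAGT" + "AAAA" + "TTGCANT"
    assert find_direct_repeats(seq, unit_len=7, spacer_min=4, spacer_max=4) == []


def test_mismatch_budget():
    seq = "TTGCAGT" + "AAAA" + "TTGCAAT"
    assert find_direct_repeats(seq, unit_len=7, spacer_min=4, spacer_max=4) == []
    hits = find_direct_repeats(seq, unit_len=7, spacer_min=4, spacer_max=4, max_mismatch=1)
    assert [h.first_start for h in hits] == [0]


def test_scan_matches_brute_force_double_loop():
    rng = random.Random(12)
    seq = "".join(rng.choice("ACGT") for _ in range(2000))
    unit_len, smin, smax = 7, 0, 20
    got = {(h.first_start, h.spacer) for h in find_direct_repeats(seq, unit_len, smin, smax)}
    expected = set()
    for i in range(len(seq)):
        for s in range(smin, smax + 1):
            j = i + unit_len + s
            if j + unit_len > len(seq):
                break
            if seq[i : i + unit_len] == seq[j : j + unit_len]:
                expected.add((i, s))
    # exact repeats are strand-symmetric, so the forward brute force is complete
    assert got == expected
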