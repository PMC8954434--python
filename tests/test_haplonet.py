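"""Haplotype collapsing, the median-augmented minimum-spanning network and
the chloroplast long-distance-dispersal detector."""

import itertools

import networkx as nx
import numpy as np
import pytest

from dispersalscreen.diffstats import FstMatrix
from dispersalscreen.genio import Alignment
from dispersalscreen.haplonet import (
    HaploNetError,
    build_network,
    collapse_haplotypes,
    detect_signal4,
    export_edge_list,
    hamming,
)
from dispersalscreen.signals import DETECTED, NOT_ASSESSABLE, NOT_DETECTED


def _aln(seqs, ids=None):
    ids = ids or [f"h{i}" for i in range(len(seqs))]
    return Alignment(ids=ids, sequences=seqs)


# ---------------------------------------------------------------------------
# Collapsing
# ---------------------------------------------------------------------------


def test_identical_sequences_one_haplotype():
    hs = collapse_haplotypes(_aln(["ACGT"] * 4))
    assert hs.n_haplotypes == 1
    assert hs.counts == [4]
    assert sum(hs.counts) == 4


def test_two_haplotypes_with_counts():
    hs = collapse_haplotypes(_aln(["AAT", "AAT", "ACT"]))
    assert hs.n_haplotypes == 2
    assert sorted(hs.counts) == [1, 2]


def test_ambiguous_sample_merges_into_most_frequent():
    """A sequence with an N compatible with two haplotypes joins the more
    frequent one (documented tie-break)."""
    seqs = ["AAA"] * 5 + ["ATA"] * 2 + ["ANA"]
    hs = collapse_haplotypes(_aln(seqs))
    assert hs.n_haplotypes == 2
    big = max(range(2), key=lambda h: hs.counts[h])
    assert hs.sample_to_hap["h7"] == big
    assert hs.counts[big] == 6


def test_complete_columns_policy():
    hs = collapse_haplotypes(_aln(["ANT", "AAT", "ACT"]), missing_policy="complete_columns")
    # column 1 dropped -> all three identical over remaining columns
    assert hs.n_haplotypes == 1
    with pytest.raises(HaploNetError, match="every alignment column"):
        collapse_haplotypes(_aln(["N", "A"]), missing_policy="complete_columns")


def test_hamming_ignores_missing_positions():
    assert hamming("ACGT", "ACGA") == 1
    assert hamming("ACNT", "ACGA") == 1
    assert hamming("AC-T", "ACGT") == 0


def test_counts_conserved(iso6_cp):
    hs = collapse_haplotypes(iso6_cp.cp_alignment)
    assert sum(hs.counts) == len(iso6_cp.cp_alignment.ids)
    assert set(hs.sample_to_hap) == set(iso6_cp.cp_alignment.ids)
    # distinct haplotypes differ at >= 1 used column
    for a, b in itertools.combinations(range(hs.n_haplotypes), 2):
        assert hamming(hs.sequences[a], hs.sequences[b]) >= 1


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


def test_single_haplotype_network():
    hs = collapse_haplotypes(_aln(["ACGT", "ACGT"]))
    net = build_network(hs)
    assert net.graph.number_of_nodes() == 1
    assert net.graph.number_of_edges() == 0


def test_chain_topology_no_median():
    """A-B 1 mutation, B-C 1 mutation, A-C 2: plain chain, no median node."""
    hs = collapse_haplotypes(_aln(["AAA", "ACA", "ACC"]))
    net = build_network(hs)
    assert net.graph.number_of_nodes() == 3
    edges = {frozenset((u, v)): d for u, v, d in export_edge_list(net)}
    assert all(m == 1 for m in edges.values())
    assert net.total_length() == 2


def test_star_median_inferred():
    """Four sequences each one mutation from an unsampled centre (pairwise
    distance 2) gain a single degree-4 median node."""
    seqs = ["TAAAA", "ATAAA", "AATAA", "AAATA"]  # centre AAAAA unobserved
    hs = collapse_haplotypes(_aln(seqs))
    net = build_network(hs)
    medians = [n for n, d in net.graph.nodes(data=True) if not d["sampled"]]
    assert len(medians) == 1
    m = medians[0]
    assert net.graph.degree(m) == 4
    # haplotypes are represented over the variable columns only
    assert net.graph.nodes[m]["sequence"] == "A" * len(hs.sequences[0])
    assert all(net.graph.edges[m, u]["mutations"] == 1 for u in net.graph.neighbors(m))


def test_edge_weights_equal_pairwise_differences(hd3_cp):
    hs = collapse_haplotypes(hd3_cp.cp_alignment)
    net = build_network(hs)
    for u, v, d in net.graph.edges(data=True):
        su, sv = net.graph.nodes[u]["sequence"], net.graph.nodes[v]["sequence"]
        assert d["mutations"] == hamming(su, sv)
    assert nx.is_connected(net.graph)


def _exhaustive_min_length(seqs):
    """Brute-force oracle: minimum spanning length over the sampled
    haplotypes plus any subset (size <= 2) of candidate median sequences
    from the closure of triplet majority consensus."""
    from dispersalscreen.haplonet import _mst_length, _pairwise_dist, _to_array, _missing_mask

    def mst_len(ss):
        arr = _to_array(list(ss))
        return _mst_length(_pairwise_dist(arr, _missing_mask(arr)))

    def medians(pool):
        out = set()
        for a, b, c in itertools.combinations(pool, 3):
            m = "".join(
                x if (x == y or x == z) else (y if y == z else x)
                for x, y, z in zip(a, b, c)
            )
            out.add(m)
        return out - set(pool)

    cands = medians(seqs)
    cands |= medians(list(seqs) + sorted(cands))
    best = mst_len(seqs)
    for r in (1, 2):
        for extra in itertools.combinations(sorted(cands), r):
            best = min(best, mst_len(list(seqs) + list(extra)))
    return best


def _tree_like_seqs(rng, n, L=16):
    """Sequences generated by successive mutation of existing ones, as a
    genealogy produces them (the regime haplotype networks are built for)."""
    seqs = [list("A" * L)]
    while len(seqs) < n:
        child = seqs[rng.integers(len(seqs))][:]
        for _ in range(rng.integers(1, 3)):
            pos = int(rng.integers(L))
            child[pos] = rng.choice([c for c in "ACGT" if c != child[pos]])
        seqs.append(child)
    return ["".join(s) for s in seqs]


def _achieved_length(net):
    from dispersalscreen.haplonet import _missing_mask, _mst_length, _pairwise_dist, _to_array

    arr = _to_array([d["sequence"] for _, d in net.graph.nodes(data=True)])
    return _mst_length(_pairwise_dist(arr, _missing_mask(arr)))


@pytest.mark.parametrize("seed", range(6))
def test_network_length_matches_exhaustive_search(seed):
    """On small genealogy-like instances the greedy median augmentation
    reaches the same minimum spanning length as exhaustive search over
    candidate median sets."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 7))
    seqs = _tree_like_seqs(rng, n)
    hs = collapse_haplotypes(_aln(seqs, ids=[f"s{i}" for i in range(n)]))
    net = build_network(hs)
    assert _achieved_length(net) == _exhaustive_min_length(hs.sequences)


@pytest.mark.parametrize("seed", range(3))
def test_medians_never_lengthen_network(seed):
    """Even on adversarial (non-tree-like) random sequences, the augmented
    spanning length never exceeds the plain MST over sampled haplotypes."""
    from dispersalscreen.haplonet import _missing_mask, _mst_length, _pairwise_dist, _to_array

    rng = np.random.default_rng(seed)
    seqs = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(int(rng.integers(4, 7)))]
    hs = collapse_haplotypes(_aln(seqs, ids=[f"s{i}" for i in range(len(seqs))]))
    net = build_network(hs)
    plain_arr = _to_array(hs.sequences)
    plain = _mst_length(_pairwise_dist(plain_arr, _missing_mask(plain_arr)))
    assert _achieved_length(net) <= plain


# ---------------------------------------------------------------------------
# Signal 4
# ---------------------------------------------------------------------------


def _fst(codes, value):
    k = len(codes)
    m = np.full((k, k), float(value))
    np.fill_diagonal(m, np.nan)
    return FstMatrix(list(codes), m, np.ones((k, k), dtype=int), {c: 2 for c in codes}, [])


COORDS = {"A": (-30.0, 152.0), "B": (-27.0, 152.0), "C": (-24.0, 152.0)}


def test_signal4_shared_haplotype_between_differentiated_sites():
    """A haplotype shared by two distant sites with high nuclear Fst, all
    other haplotypes site-private, triggers the LDD pattern."""
    seqs = ["AAAAA", "AAAAA", "CCCCC", "CCCCC", "GGGGG", "AAAAA"]
    ids = ["a1", "a2", "b1", "b2", "c1", "c2"]
    sites = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
    hs = collapse_haplotypes(_aln(seqs, ids))
    net = build_network(hs)
    res = detect_signal4(net, hs, sites, COORDS, _fst("ABC", 0.3))
    assert res.status == DETECTED and "LDD" in res.evidence["patterns"]
    ev = res.evidence["ldd_events"]
    assert any(set(e["sites"]) == {"A", "C"} for e in ev)


def test_signal4_private_divergent_haplotypes_not_flagged():
    """Site-private haplotypes many mutations apart (long-term isolation)."""
    seqs = ["AAAAAAAAAA", "AAAAAAAAAA", "CCCCCAAAAA", "CCCCCAAAAA", "GGGGGGGGAA", "GGGGGGGGAA"]
    ids = ["a1", "a2", "b1", "b2", "c1", "c2"]
    sites = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
    hs = collapse_haplotypes(_aln(seqs, ids))
    net = build_network(hs)
    res = detect_signal4(net, hs, sites, COORDS, _fst("ABC", 0.4))
    assert res.status == NOT_DETECTED


def test_signal4_widespread_haplotype():
    """One haplotype in 90% of samples at every site: rapid-expansion flag."""
    seqs = ["AAAA"] * 9 + ["TTTT"]
    ids = [f"s{i}" for i in range(10)]
    sites = {f"s{i}": "ABC"[i % 3] for i in range(10)}
    hs = collapse_haplotypes(_aln(seqs, ids))
    net = build_network(hs)
    res = detect_signal4(net, hs, sites, COORDS, _fst("ABC", 0.05))
    assert res.status == DETECTED
    assert res.evidence["patterns"] == ["widespread"]


def test_signal4_region_fallback_without_fst():
    seqs = ["AAAA", "AAAA", "TTTT"]
    ids = ["a1", "c1", "c2"]
    sites = {"a1": "A", "c1": "C", "c2": "C"}
    res_regions = detect_signal4(
        build_network(collapse_haplotypes(_aln(seqs, ids))),
        collapse_haplotypes(_aln(seqs, ids)),
        sites, COORDS, None, regions={"A": "south", "C": "north"},
    )
    assert res_regions.status == DETECTED
    res_none = detect_signal4(
        build_network(collapse_haplotypes(_aln(seqs, ids))),
        collapse_haplotypes(_aln(seqs, ids)),
        sites, COORDS, None,
    )
    assert res_none.status == NOT_DETECTED


def test_signal4_not_assessable_without_data():
    from dispersalscreen.haplonet import HaplotypeSet

    empty = HaplotypeSet(sequences=[], counts=[], sample_to_hap={}, used_columns=np.array([], dtype=int))
    res = detect_signal4(None, empty, {}, {}, None)
    assert res.status == NOT_ASSESSABLE


def test_signal4_scenario_contrast(iso6_cp, hd3_cp):
    """The ancient-pulse scenario shows chloroplast LDD evidence; matched
    isolation data from the same seed does not."""
    from dispersalscreen import pairwise_fst

    out = {}
    for name, ds in (("iso", iso6_cp), ("hd3", hd3_cp)):
        hs = collapse_haplotypes(ds.cp_alignment)
        net = build_network(hs)
        meta = ds.sample_metadata
        fst = pairwise_fst(ds.genotype_matrix, ds.site_assignment)
        coords = {r.site_code: (r.latitude, r.longitude)
                  for r in meta.drop_duplicates("site_code").itertuples()}
        res = detect_signal4(net, hs, dict(zip(meta.sample_id, meta.site_code)), coords, fst)
        out[name] = "LDD" in res.evidence["patterns"]
    assert out["hd3"] and not out["iso"]
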