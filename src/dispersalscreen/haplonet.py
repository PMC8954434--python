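"""Chloroplast haplotype networks and the detector for dispersal signal 4
(haplotype long-distance dispersal, or a single widespread haplotype).

The chloroplast is haploid, non-recombining and uniparentally inherited in
most angiosperms, so its haplotypes trace seed movement specifically.
Distinct alignment sequences are collapsed into haplotypes, connected into
a minimum-spanning network (the union of all minimum spanning trees over
pairwise Hamming distances) and augmented, median-joining style, with
inferred unsampled node sequences.  At epsilon = 0 a median node is added
only when it strictly shortens the total spanning length.

Haplotype sequences are represented over the *used* alignment columns:
constant columns carry no distance information and are dropped up front,
which keeps all pairwise comparisons proportional to the number of
variable positions rather than the alignment length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.sparse import csr_matrix

from .diffstats import FstMatrix, haversine_km
from .genio import AMBIGUOUS, Alignment
from .signals import DETECTED, NOT_ASSESSABLE, NOT_DETECTED, SignalResult


class HaploNetError(ValueError):
    pass


_AMBIG_CODES = np.frombuffer("".join(sorted(AMBIGUOUS)).encode(), dtype=np.uint8)


def _to_array(seqs: list[str]) -> np.ndarray:
    if not seqs:
        return np.zeros((0, 0), dtype=np.uint8)
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


def _missing_mask(arr: np.ndarray) -> np.ndarray:
    return np.isin(arr, _AMBIG_CODES)


def _is_missing(ch: str) -> bool:
    return ch in AMBIGUOUS


def hamming(a: str, b: str) -> int:
    """Pairwise-complete Hamming distance: positions missing (gap or
    ambiguity code) in either sequence are ignored."""
    return sum(1 for x, y in zip(a, b) if x != y and not _is_missing(x) and not _is_missing(y))


def _pairwise_dist(arr: np.ndarray, miss: np.ndarray) -> np.ndarray:
    """Dense pairwise-complete Hamming distance matrix for byte rows."""
    n = arr.shape[0]
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        diff = arr[i][None, :] != arr
        ok = ~(miss[i][None, :] | miss)
        d[i] = (diff & ok).sum(axis=1)
    return d


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeSet:
    """Distinct haplotypes with counts and the sample -> haplotype map.

    ``sequences[i]`` is the representative sequence of haplotype i over the
    used (variable) columns; ``counts[i]`` its number of samples.  Per-site
    counts are available through :meth:`site_counts`.
    """

    sequences: list[str]
    counts: list[int]
    sample_to_hap: dict[str, int]
    used_columns: np.ndarray  # 0-based indices into the original alignment

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    def site_counts(self, site_assignment: Mapping[str, str]) -> dict[int, dict[str, int]]:
        """Haplotype index -> {site -> sample count}."""
        out: dict[int, dict[str, int]] = {i: {} for i in range(self.n_haplotypes)}
        for sid, h in self.sample_to_hap.items():
            site = site_assignment[sid]
            out[h][site] = out[h].get(site, 0) + 1
        return out


def collapse_haplotypes(aln: Alignment, missing_policy: str = "pairwise_complete") -> HaplotypeSet:
    """Collapse aligned sequences into distinct haplotypes.

    Under ``"complete_columns"`` every column containing a gap or ambiguity
    code is dropped first (an error if that is every column).  Under
    ``"pairwise_complete"`` such columns are kept; a sequence with missing
    positions merges into an existing haplotype whenever it is compatible
    at all its non-missing positions (ties break to the most frequent
    haplotype, then lexicographically by sequence).  Fully resolved
    sequences are grouped first so ambiguous ones merge into established
    haplotypes deterministically.  Columns constant across all sequences
    are dropped in both policies: they cannot separate haplotypes.
    """
    if missing_policy not in ("pairwise_complete", "complete_columns"):
        raise HaploNetError(f"unknown missing_policy {missing_policy!r}")
    arr = _to_array(aln.sequences)
    miss = _missing_mask(arr)
    n, n_cols = arr.shape
    keep = np.ones(n_cols, dtype=bool)
    if missing_policy == "complete_columns":
        keep = ~miss.any(axis=0)
        if n_cols and not keep.any():
            raise HaploNetError("complete_columns policy dropped every alignment column")
    # drop constant columns (over non-missing entries)
    lo = np.where(miss, 255, arr).min(axis=0)
    hi = np.where(miss, 0, arr).max(axis=0)
    keep &= hi > lo
    used = np.flatnonzero(keep)
    arr, miss = arr[:, used], miss[:, used]

    order = sorted(range(n), key=lambda i: (bool(miss[i].any()), i))
    hap_rows: list[np.ndarray] = []
    hap_miss: list[np.ndarray] = []
    counts: list[int] = []
    sample_to_hap: dict[str, int] = {}
    for i in order:
        row, m = arr[i], miss[i]
        compatible = [
            h
            for h in range(len(hap_rows))
            if not ((row != hap_rows[h]) & ~m & ~hap_miss[h]).any()
        ]
        if compatible:
            h = min(compatible, key=lambda h: (-counts[h], hap_rows[h].tobytes()))
            counts[h] += 1
        else:
            hap_rows.append(row)
            hap_miss.append(m)
            counts.append(1)
            h = len(hap_rows) - 1
        sample_to_hap[aln.ids[i]] = h
    return HaplotypeSet(
        sequences=[r.tobytes().decode() for r in hap_rows],
        counts=counts,
        sample_to_hap=sample_to_hap,
        used_columns=used,
    )


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


@dataclass
class HaploNetwork:
    """Mutation-weighted haplotype network.

    ``graph`` is an undirected networkx graph whose nodes are haplotype
    indices with attributes ``sequence``, ``count`` and ``sampled`` (False
    for inferred median nodes); each edge carries ``mutations``, the
    Hamming distance between its endpoint sequences.
    """

    graph: nx.Graph
    epsilon: int

    def total_length(self) -> int:
        return sum(d["mutations"] for _, _, d in self.graph.edges(data=True))


def _msn_edges(d: np.ndarray) -> list[tuple[int, int, int]]:
    """Minimum-spanning-network edges from a distance matrix.

    Kruskal with grouped weights: all edges of a given distance that join
    components still separate at the start of that distance class enter the
    network (the union of all minimum spanning trees).
    """
    n = d.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    iu = list(zip(*np.triu_indices(n, k=1)))
    edges = []
    for w in sorted({int(d[i, j]) for i, j in iu}):
        klass = [(i, j) for i, j in iu if d[i, j] == w]
        comp = {i: find(i) for i in range(n)}  # frozen at class start
        added = [(i, j) for i, j in klass if comp[i] != comp[j]]
        for i, j in added:
            edges.append((int(i), int(j), w))
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return edges


def _mst_length(d: np.ndarray) -> int:
    if d.shape[0] < 2:
        return 0
    # +1 offset keeps genuine zero-distance edges visible to the sparse MST
    return int(minimum_spanning_tree(csr_matrix(d + 1)).sum()) - (d.shape[0] - 1)


def _median_row(rows: np.ndarray, misses: np.ndarray, order: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positionwise majority of three byte rows; three-way ties take the
    character of the first parent in ``order`` (heaviest, then
    lexicographically first).  A position missing in a parent abstains."""
    L = rows.shape[1]
    out = np.zeros(L, dtype=np.uint8)
    out_miss = np.zeros(L, dtype=bool)
    for p in range(L):
        votes: dict[int, int] = {}
        for t in range(3):
            if not misses[t, p]:
                votes[int(rows[t, p])] = votes.get(int(rows[t, p]), 0) + 1
        if not votes:
            out_miss[p] = True
            continue
        best = max(votes.values())
        if best >= 2:
            out[p] = next(v for v, c in votes.items() if c == best)
        else:
            for t in order:
                if not misses[t, p]:
                    out[p] = rows[t, p]
                    break
    return out, out_miss


def build_network(hs: HaplotypeSet, epsilon: int = 0, max_medians: int = 32) -> HaploNetwork:
    """Build the mutation-weighted haplotype network.

    The base structure is the minimum-spanning network over pairwise
    Hamming distances.  Median (inferred, unsampled) node sequences are
    then added greedily, median-joining style: candidate medians are the
    positionwise consensus of node triplets that are mutually close in the
    current network (at least two of the three pairs joined by an edge),
    and at each round the median giving the largest strict reduction in
    total spanning length is kept (ties break to the lexicographically
    smallest sequence).  With ``epsilon = 0`` this admits only medians that
    strictly shorten the network, so the final spanning length never
    exceeds the plain minimum-spanning-tree length over the sampled
    haplotypes.  Deterministic under fixed input ordering.
    """
    if hs.n_haplotypes < 1:
        raise HaploNetError("need at least one haplotype")
    if epsilon != 0:
        raise HaploNetError("only epsilon = 0 is supported")
    arr = _to_array(hs.sequences)
    miss = _missing_mask(arr)
    weights = list(hs.counts)
    sampled = [True] * len(hs.sequences)
    d = _pairwise_dist(arr, miss)
    current_len = _mst_length(d)

    while (len(weights) - hs.n_haplotypes) < max_medians and arr.shape[0] >= 3:
        edges = {(min(i, j), max(i, j)) for i, j, _ in _msn_edges(d)}
        best = None  # (new_len, seq_bytes, row, row_miss, dist_vector)
        seen: set[bytes] = set()
        for i, j, k in itertools.combinations(range(arr.shape[0]), 3):
            n_linked = sum(1 for a, b in ((i, j), (i, k), (j, k)) if (a, b) in edges)
            if n_linked < 2:
                continue
            trio = np.array([i, j, k])
            order = sorted(range(3), key=lambda t: (-weights[trio[t]], arr[trio[t]].tobytes()))
            row, row_miss = _median_row(arr[trio], miss[trio], np.array(order))
            key = row.tobytes()
            if key in seen:
                continue
            seen.add(key)
            if any((row == arr[t]).all() for t in range(arr.shape[0])):
                continue
            diff = (row[None, :] != arr) & ~row_miss[None, :] & ~miss
            dv = diff.sum(axis=1)
            nd = np.zeros((d.shape[0] + 1, d.shape[0] + 1), dtype=int)
            nd[:-1, :-1] = d
            nd[-1, :-1] = dv
            nd[:-1, -1] = dv
            new_len = _mst_length(nd)
            if new_len < current_len and (best is None or (new_len, key) < (best[0], best[1])):
                best = (new_len, key, row, row_miss, dv)
        if best is None:
            break
        current_len = best[0]
        arr = np.vstack([arr, best[2]])
        miss = np.vstack([miss, best[3]])
        nd = np.zeros((d.shape[0] + 1, d.shape[0] + 1), dtype=int)
        nd[:-1, :-1] = d
        nd[-1, :-1] = best[4]
        nd[:-1, -1] = best[4]
        d = nd
        weights.append(0)
        sampled.append(False)

    g = nx.Graph()
    for idx in range(arr.shape[0]):
        g.add_node(idx, sequence=arr[idx].tobytes().decode(), count=weights[idx], sampled=sampled[idx])
    for i, j, w in _msn_edges(d):
        g.add_edge(i, j, mutations=w)
    # prune inferred nodes that ended up as leaves (they cannot shorten paths)
    changed = True
    while changed:
        changed = False
        for node in list(g.nodes):
            if not g.nodes[node]["sampled"] and g.degree(node) <= 1:
                g.remove_node(node)
                changed = True
    return HaploNetwork(graph=g, epsilon=epsilon)


def export_edge_list(net: HaploNetwork) -> list[tuple[int, int, int]]:
    return [(u, v, d["mutations"]) for u, v, d in net.graph.edges(data=True)]


# ---------------------------------------------------------------------------
# Signal 4: haplotype long-distance dispersal
# ---------------------------------------------------------------------------


def detect_signal4(
    net: HaploNetwork,
    hs: HaplotypeSet,
    site_assignment: Mapping[str, str],
    site_coords: Mapping[str, tuple[float, float]],
    nuclear_fst: FstMatrix | None,
    max_mut: int = 2,
    min_fst: float = 0.15,
    min_km: float | None = None,
    widespread_fraction: float = 0.80,
    regions: Mapping[str, str] | None = None,
) -> SignalResult:
    """Flag haplotype sharing consistent with long-distance seed dispersal.

    Two patterns trigger the signal.  ``"LDD"``: a haplotype (or a pair of
    haplotypes within ``max_mut`` mutations) occurs at two sites at least
    ``min_km`` apart whose nuclear Fst is at least ``min_fst`` (or, with no
    nuclear estimate for the pair, which lie in different declared
    regions).  ``"widespread"``: a single haplotype carries at least
    ``widespread_fraction`` of all samples and occurs at every sampled
    site (recent rapid range expansion).  ``min_km`` defaults to the
    species' median between-site distance, making "disjunct" scale-free
    across species with very different ranges.
    """
    if hs.n_haplotypes == 0 or not hs.sample_to_hap:
        return SignalResult(NOT_ASSESSABLE, {"reason": "no chloroplast data"})
    site_counts = hs.site_counts(site_assignment)
    all_sites = sorted({s for c in site_counts.values() for s in c})
    missing_coords = [s for s in all_sites if s not in site_coords]
    if missing_coords:
        raise HaploNetError(f"site coordinates missing for {missing_coords}")
    if len(all_sites) < 2:
        return SignalResult(NOT_ASSESSABLE, {"reason": "haplotypes from a single site"})

    dists = {
        (a, b): haversine_km(*site_coords[a], *site_coords[b])
        for a, b in itertools.combinations(all_sites, 2)
    }
    if min_km is None:
        min_km = float(np.median(list(dists.values())))

    def fst_for(a: str, b: str) -> float | None:
        if nuclear_fst is None:
            return None
        try:
            v = nuclear_fst.pair(a, b)
        except ValueError:
            return None
        return None if np.isnan(v) else v

    ldd_events = []
    for h1, h2 in itertools.combinations_with_replacement(range(hs.n_haplotypes), 2):
        d_h = 0 if h1 == h2 else hamming(hs.sequences[h1], hs.sequences[h2])
        if d_h > max_mut:
            continue
        seen_pairs: set[frozenset] = set()
        for a in site_counts[h1]:
            for b in site_counts[h2]:
                if a == b or frozenset((a, b)) in seen_pairs:
                    continue
                seen_pairs.add(frozenset((a, b)))
                key = (a, b) if (a, b) in dists else (b, a)
                km = dists[key]
                if km < min_km:
                    continue
                fst = fst_for(a, b)
                if fst is not None and fst >= min_fst:
                    reason = f"nuclear Fst {fst:.3f} >= {min_fst}"
                elif fst is None and regions is not None and regions.get(a) != regions.get(b):
                    reason = "different declared regions (no nuclear Fst)"
                else:
                    continue
                ldd_events.append(
                    {"haplotypes": sorted({h1, h2}), "sites": sorted({a, b}),
                     "mutations": d_h, "distance_km": km, "nuclear_fst": fst, "basis": reason}
                )

    total = sum(hs.counts)
    widespread = []
    for h in range(hs.n_haplotypes):
        frac = hs.counts[h] / total
        if frac >= widespread_fraction and set(site_counts[h]) == set(all_sites):
            widespread.append({"haplotype": h, "fraction": frac})

    patterns = [p for p, hit in (("LDD", ldd_events), ("widespread", widespread)) if hit]
    status = DETECTED if patterns else NOT_DETECTED
    return SignalResult(
        status,
        {"patterns": patterns, "ldd_events": ldd_events, "widespread": widespread,
         "min_km": min_km, "max_mut": max_mut, "min_fst": min_fst},
    )
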