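"""Pairwise Fst, distance-binned differentiation and the Mantel test of
isolation by distance (IBD); detector for dispersal signal 1 (low Fst with
no IBD, the footprint of recent rapid spread).

The differentiation estimator is the multilocus Weir–Hill ratio-of-averages
theta computed from allele frequencies.  For a pair of populations and one
locus, with n_i sampled allele copies and alternate-allele frequency p_i in
population i (r = 2 populations):

    MSP = sum_i n_i (p_i - p_bar)^2 / (r - 1)          between-population MS
    MSG = sum_i n_i p_i (1 - p_i) / (sum_i n_i - r)    within-population MS
    n_c = (sum_i n_i - sum_i n_i^2 / sum_i n_i) / (r - 1)

    theta = sum_loci (MSP - MSG) / sum_loci (MSP + (n_c - 1) MSG)

i.e. per-locus variance components are summed across loci in the numerator
and denominator separately (a ratio of averages, not an average of ratios).
Loci monomorphic across the pair contribute zero to both sums; missing
calls reduce the per-locus allele counts.  Negative estimates are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix
from .signals import DETECTED, NOT_ASSESSABLE, NOT_DETECTED, SignalResult

#: IUGG mean Earth radius, km (haversine great-circle distances).
EARTH_RADIUS_KM = 6371.0088


class DiffStatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pairwise Fst
# ---------------------------------------------------------------------------


@dataclass
class FstMatrix:
    """Symmetric site-by-site multilocus Fst estimates.

    Self-pairs are NaN.  Estimator noise can make values slightly negative;
    they are deliberately not truncated.  ``n_loci_used[i, j]`` counts loci
    with data in both sites; ``n_samples`` maps site code to sample count.
    """

    site_codes: list[str]
    values: np.ndarray
    n_loci_used: np.ndarray
    n_samples: dict[str, int]
    undefined_pairs: list[tuple[str, str]]

    def pair(self, a: str, b: str) -> float:
        i, j = self.site_codes.index(a), self.site_codes.index(b)
        return float(self.values[i, j])

    def offdiag(self) -> np.ndarray:
        """Upper-triangle values in site order."""
        iu = np.triu_indices(len(self.site_codes), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_codes, columns=self.site_codes)


def _site_allele_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus allele-copy count and alternate-allele count for one site."""
    present = calls != MISSING
    n = 2 * present.sum(axis=0)
    alt = np.where(present, calls, 0).sum(axis=0)
    return n.astype(float), alt.astype(float)


def weir_hill_theta(n1, alt1, n2, alt2) -> tuple[float, int]:
    """Multilocus Weir–Hill theta for one site pair.

    Parameters are per-locus allele-copy counts and alternate-allele counts
    for the two sites.  Returns ``(theta, n_loci_used)``; theta is NaN when
    no locus is informative.
    """
    n1, alt1, n2, alt2 = (np.asarray(x, dtype=float) for x in (n1, alt1, n2, alt2))
    usable = (n1 >= 2) & (n2 >= 2)
    n1, alt1, n2, alt2 = n1[usable], alt1[usable], n2[usable], alt2[usable]
    n_loci_used = int(usable.sum())
    if n_loci_used == 0:
        return float("nan"), 0
    p1, p2 = alt1 / n1, alt2 / n2
    ntot = n1 + n2
    pbar = (alt1 + alt2) / ntot
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r - 1 = 1
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
    nc = ntot - (n1**2 + n2**2) / ntot
    num = (msp - msg).sum()
    den = (msp + (nc - 1) * msg).sum()
    if den == 0:
        return float("nan"), n_loci_used
    return float(num / den), n_loci_used


def pairwise_fst(gm: GenotypeMatrix, site_assignment: Mapping[str, str]) -> FstMatrix:
    """Weir–Hill pairwise Fst between every pair of sample sites.

    ``site_assignment`` maps sample id to site code.  Requires at least two
    sites with at least two genotyped samples each.  A pair for which one
    site has fewer than two allele copies at every locus is left undefined
    (NaN) and flagged in ``undefined_pairs``.
    """
    sites: dict[str, list[int]] = {}
    for i, sid in enumerate(gm.sample_ids):
        if sid not in site_assignment:
            raise DiffStatsError(f"sample {sid!r} has no site assignment")
        sites.setdefault(site_assignment[sid], []).append(i)
    site_codes = list(sites)
    if sum(1 for idx in sites.values() if len(idx) >= 2) < 2:
        raise DiffStatsError("need >= 2 sites with >= 2 genotyped samples each")
    stats = {s: _site_allele_stats(gm.calls[idx]) for s, idx in sites.items()}
    k = len(site_codes)
    values = np.full((k, k), np.nan)
    nlu = np.zeros((k, k), dtype=int)
    undefined = []
    for i in range(k):
        for j in range(i + 1, k):
            (n1, a1), (n2, a2) = stats[site_codes[i]], stats[site_codes[j]]
            theta, used = weir_hill_theta(n1, a1, n2, a2)
            values[i, j] = values[j, i] = theta
            nlu[i, j] = nlu[j, i] = used
            if math.isnan(theta):
                undefined.append((site_codes[i], site_codes[j]))
    return FstMatrix(
        site_codes=site_codes,
        values=values,
        n_loci_used=nlu,
        n_samples={s: len(idx) for s, idx in sites.items()},
        undefined_pairs=undefined,
    )


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km between two points in decimal degrees."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def geographic_distances(meta: pd.DataFrame, by_site: bool = True) -> tuple[list[str], np.ndarray]:
    """Site-by-site great-circle distance matrix (km) from sample metadata.

    Site coordinates are the centroid (mean latitude/longitude) of the
    site's samples.  Returns ``(site_codes, distances)``.
    """
    required = {"site_code", "latitude", "longitude"}
    if not required <= set(meta.columns):
        raise DiffStatsError(f"metadata lacks columns {sorted(required - set(meta.columns))}")
    if meta[["latitude", "longitude"]].isna().any().any():
        bad = meta.loc[meta[["latitude", "longitude"]].isna().any(axis=1), "site_code"].unique()
        raise DiffStatsError(f"missing coordinates for sites {sorted(bad)}")
    cent = meta.groupby("site_code", sort=False)[["latitude", "longitude"]].mean()
    codes = cent.index.tolist()
    k = len(codes)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = haversine_km(
                cent.iloc[i, 0], cent.iloc[i, 1], cent.iloc[j, 0], cent.iloc[j, 1]
            )
    return codes, d


def align_distances(fst: FstMatrix, codes: list[str], dists: np.ndarray) -> np.ndarray:
    """Reorder a distance matrix to the site ordering of an FstMatrix."""
    try:
        order = [codes.index(s) for s in fst.site_codes]
    except ValueError as e:
        raise DiffStatsError(f"distance matrix lacks a site present in the Fst matrix: {e}") from None
    return dists[np.ix_(order, order)]


# ---------------------------------------------------------------------------
# Distance-binned Fst
# ---------------------------------------------------------------------------


@dataclass
class BinnedFst:
    """Mean pairwise Fst in half-open 50-km distance bins (lower, upper].

    ``pooled_mean``/``pooled_count`` aggregate the sparse long-distance
    bins (301–700 km) for display.  ``n_excluded`` counts pairs beyond the
    maximum distance.
    """

    bin_edges: np.ndarray
    means: np.ndarray
    counts: np.ndarray
    pooled_lower: float
    pooled_mean: float
    pooled_count: int
    n_excluded: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lower_km": self.bin_edges[:-1],
                "bin_upper_km": self.bin_edges[1:],
                "mean_fst": self.means,
                "n_pairs": self.counts,
            }
        )


def bin_fst_by_distance(
    fst: FstMatrix,
    dists: np.ndarray,
    bin_width: float = 50.0,
    max_km: float = 700.0,
    pooled_from_km: float = 300.0,
) -> BinnedFst:
    """Average pairwise Fst in 50-km distance intervals from 0 to 700 km.

    Bins are half-open (lower, upper], so a pair at exactly 50 km falls in
    the first bin.  Pairs beyond ``max_km`` are excluded and counted.
    """
    if dists.shape != fst.values.shape:
        raise DiffStatsError("distance matrix shape mismatch")
    iu = np.triu_indices(len(fst.site_codes), k=1)
    f, d = fst.values[iu], dists[iu]
    ok = ~np.isnan(f)
    f, d = f[ok], d[ok]
    edges = np.arange(0.0, max_km + bin_width, bin_width)
    n_bins = len(edges) - 1
    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    # half-open (lower, upper]
    idx = np.ceil(d / bin_width).astype(int) - 1
    idx[d <= 0] = 0
    inside = (d > 0) & (d <= max_km)
    for b in range(n_bins):
        sel = inside & (idx == b)
        counts[b] = sel.sum()
        if counts[b]:
            means[b] = f[sel].mean()
    pooled_sel = inside & (d > pooled_from_km)
    return BinnedFst(
        bin_edges=edges,
        means=means,
        counts=counts,
        pooled_lower=pooled_from_km,
        pooled_mean=float(f[pooled_sel].mean()) if pooled_sel.any() else float("nan"),
        pooled_count=int(pooled_sel.sum()),
        n_excluded=int((d > max_km).sum()),
    )


# ---------------------------------------------------------------------------
# Mantel test of isolation by distance
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    """Pearson Mantel correlation of linearised Fst against log distance."""

    r: float
    p: float
    n_permutations: int
    n_sites: int


def mantel_ibd(
    fst: FstMatrix,
    dists: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    cap_fst: bool = False,
    cap_value: float = 0.999,
) -> MantelResult:
    """Permutation Mantel test for positive isolation by distance.

    Genetic distances are linearised, Fst / (1 - Fst); geographic distances
    are natural-log transformed.  The Pearson correlation r is computed on
    the off-diagonal upper-triangle entries, and the one-sided p-value is
    (#{permuted r >= observed} + 1) / (n_perm + 1) under joint row/column
    permutation of the geographic matrix.  Values of Fst >= ``cap_value``
    make the linearisation blow up; they raise unless ``cap_fst`` is on,
    in which case they are capped at ``cap_value``.
    """
    k = len(fst.site_codes)
    if k < 3:
        raise DiffStatsError("Mantel test needs >= 3 sites")
    if dists.shape != fst.values.shape:
        raise DiffStatsError("distance matrix shape mismatch")
    iu = np.triu_indices(k, k=1)
    if (dists[iu] <= 0).any():
        raise DiffStatsError("all between-site distances must be > 0")
    f = fst.values.copy()
    if np.isnan(f[iu]).any():
        raise DiffStatsError("Fst matrix contains undefined pairs")
    if (f[iu] >= cap_value).any():
        if not cap_fst:
            raise DiffStatsError(
                f"Fst >= {cap_value} makes Fst/(1-Fst) undefined; "
                "enable cap_fst to cap before linearisation"
            )
        f = np.minimum(f, cap_value)
    g = f / (1.0 - f)
    logd = np.log(dists, out=np.zeros_like(dists), where=dists > 0)  # diagonal unused

    def _r(perm: np.ndarray) -> float:
        x = logd[np.ix_(perm, perm)][iu]
        y = g[iu]
        xs, ys = x - x.mean(), y - y.mean()
        denom = math.sqrt((xs**2).sum() * (ys**2).sum())
        return float((xs * ys).sum() / denom) if denom > 0 else 0.0

    ident = np.arange(k)
    r_obs = _r(ident)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        if _r(rng.permutation(k)) >= r_obs:
            n_ge += 1
    p = (n_ge + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_permutations=n_perm, n_sites=k)


# ---------------------------------------------------------------------------
# Signal 1: low Fst with no isolation by distance
# ---------------------------------------------------------------------------


def detect_signal1(
    fst: FstMatrix,
    mantel: MantelResult | None,
    low_fst_threshold: float = 0.05,
    r_threshold: float = 0.30,
    p_threshold: float = 0.05,
) -> SignalResult:
    """Flag the footprint of recent, rapid range-wide dispersal.

    Detected iff the median pairwise Fst is below ``low_fst_threshold`` AND
    the Mantel test shows no appreciable IBD (r below ``r_threshold`` or p
    above ``p_threshold``; overall pattern is weighed, not significance
    alone).  With fewer than three sites the Mantel test cannot run and the
    signal is *not assessable*.
    """
    vals = fst.offdiag()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0 or mantel is None:
        return SignalResult(NOT_ASSESSABLE, {"reason": "no defined Fst pairs" if vals.size == 0 else "Mantel test unavailable (<3 sites)"})
    median_fst = float(np.median(vals))
    no_ibd = (mantel.r < r_threshold) or (mantel.p > p_threshold)
    status = DETECTED if (median_fst < low_fst_threshold and no_ibd) else NOT_DETECTED
    return SignalResult(
        status,
        {
            "median_fst": median_fst,
            "mantel_r": mantel.r,
            "mantel_p": mantel.p,
            "low_fst_threshold": low_fst_threshold,
            "r_threshold": r_threshold,
        },
    )
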