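"""Ancestry inference: sparse-NMF admixture with masked cross-entropy model
selection, genotype PCA, and the detectors for dispersal signal 2
(between-site admixture) and signal 3 (within-site outlier genotypes).

The admixture model is STRUCTURE-like.  Genotypes are one-hot encoded into
three classes per locus (0, 1 or 2 copies of the alternate allele) giving a
matrix X of shape (n_samples, 3 * n_loci).  It is factorised as X ~ Q G
where the rows of Q (n_samples x K ancestry coefficients) live on the
probability simplex and, for every ancestral population k and locus l, the
three genotype-class frequencies of G sum to one.  The fit minimises

    || W o (X - Q G) ||_F^2  +  alpha ||Q||_F^2

by alternating projected-gradient steps on Q and G with backtracking line
search, where W masks missing genotypes and a random held-out fraction of
observed entries.  Backtracking only ever accepts a step that lowers the
objective, so the objective is non-increasing across updates.  Model choice
uses the masked cross-entropy: the mean negative log predicted probability
of the held-out genotype classes, lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix
from .signals import DETECTED, NOT_ASSESSABLE, NOT_DETECTED, SignalResult


class StructureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Simplex projections
# ---------------------------------------------------------------------------


def _project_rows_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = v.shape
    u = np.sort(v, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1  # last true index
    theta = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(v - theta[:, None], 0.0)


# ---------------------------------------------------------------------------
# Admixture fit
# ---------------------------------------------------------------------------


@dataclass
class AdmixtureFit:
    """Result of one sparse-NMF admixture run.

    ``Q`` is (n_samples, K); ``G`` is (K, n_loci, 3) with each (k, locus)
    triplet a genotype-class distribution.  ``cross_entropy`` is the masked
    held-out prediction criterion (lower is better).
    """

    K: int
    Q: np.ndarray
    G: np.ndarray
    cross_entropy: float
    replicate_seed: int
    converged: bool
    n_iterations: int
    objective: float
    objective_history: np.ndarray
    sample_ids: list[str]

    def dominant_component(self) -> np.ndarray:
        return self.Q.argmax(axis=1)

    def dominant_coefficient(self) -> np.ndarray:
        return self.Q.max(axis=1)

    def q_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Q, columns=[f"Q{k+1}" for k in range(self.K)])
        df.insert(0, "sample_id", self.sample_ids)
        return df


def _one_hot(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(X, observed) with X (n, L, 3) one-hot and observed (n, L) bool."""
    calls = gm.calls
    observed = calls != MISSING
    x = np.zeros((*calls.shape, 3))
    for c in range(3):
        x[..., c] = calls == c
    return x, observed


def fit_admixture(
    gm: GenotypeMatrix,
    K: int,
    alpha: float = 10.0,
    seed: int | None = None,
    mask_fraction: float = 0.05,
    max_iter: int = 200,
    tol: float = 1e-5,
    mask_seed: int | None = None,
) -> AdmixtureFit:
    """Fit the K-ancestral-population admixture model to a genotype matrix.

    A random ``mask_fraction`` of the non-missing genotype entries is held
    out before fitting (seeded by ``mask_seed``, defaulting to ``seed``, so
    callers comparing K values can share one mask stream) and the masked
    cross-entropy is evaluated on them.  Missing genotypes contribute to
    neither the fit nor the criterion.  Non-convergence within ``max_iter``
    returns ``converged=False`` rather than raising.
    """
    if K < 1:
        raise StructureError("K must be >= 1")
    n, L = gm.n_samples, gm.n_loci
    if K > n:
        raise StructureError(f"K={K} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    mask_rng = np.random.default_rng(seed if mask_seed is None else mask_seed)

    x3, observed = _one_hot(gm)
    heldout = np.zeros_like(observed)
    if mask_fraction > 0:
        obs_idx = np.argwhere(observed)
        n_hold = int(round(mask_fraction * len(obs_idx)))
        if n_hold:
            pick = mask_rng.choice(len(obs_idx), size=n_hold, replace=False)
            heldout[tuple(obs_idx[pick].T)] = True
    w = (observed & ~heldout).astype(float)  # (n, L)

    X = x3.reshape(n, 3 * L)
    W = np.repeat(w, 3, axis=1).reshape(n, 3 * L)

    Q = _project_rows_simplex(rng.random((n, K)))
    G = rng.random((K, L, 3))
    G /= G.sum(axis=2, keepdims=True)
    Gf = G.reshape(K, 3 * L)

    def objective(Qm, Gm) -> float:
        r = W * (X - Qm @ Gm)
        return float((r * r).sum() + alpha * (Qm * Qm).sum())

    obj = objective(Q, Gf)
    history = [obj]
    eta_q = eta_g = 1e-2
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # Q step (projected gradient with backtracking)
        R = W * (Q @ Gf - X)
        grad_q = 2.0 * (R @ Gf.T) + 2.0 * alpha * Q
        while eta_q > 1e-14:
            Q_new = _project_rows_simplex(Q - eta_q * grad_q)
            obj_new = objective(Q_new, Gf)
            if obj_new <= obj:
                break
            eta_q *= 0.5
        else:
            Q_new, obj_new = Q, obj
        Q, obj = Q_new, obj_new
        eta_q *= 1.2

        # G step
        R = W * (Q @ Gf - X)
        grad_g = 2.0 * (Q.T @ R)
        obj_before_g = obj
        while eta_g > 1e-14:
            G_new = (Gf - eta_g * grad_g).reshape(K * L, 3)
            G_new = _project_rows_simplex(G_new).reshape(K, 3 * L)
            obj_new = objective(Q, G_new)
            if obj_new <= obj:
                break
            eta_g *= 0.5
        else:
            G_new, obj_new = Gf, obj
        Gf, prev_obj, obj = G_new, obj_before_g, obj_new
        eta_g *= 1.2
        history.append(obj)

        if prev_obj - obj <= tol * max(prev_obj, 1.0) and it > 1:
            converged = True
            break

    G = Gf.reshape(K, L, 3)
    ce = masked_cross_entropy(Q, G, x3, heldout)
    return AdmixtureFit(
        K=K, Q=Q, G=G, cross_entropy=ce,
        replicate_seed=-1 if seed is None else int(seed),
        converged=converged, n_iterations=it, objective=obj,
        objective_history=np.array(history), sample_ids=list(gm.sample_ids),
    )


def masked_cross_entropy(Q: np.ndarray, G: np.ndarray, x3: np.ndarray, heldout: np.ndarray) -> float:
    """Mean negative log predicted probability of held-out genotype classes.

    Predicted class probabilities at (sample, locus) are the Q-weighted
    mixture of the ancestral genotype-class frequencies, renormalised over
    the three classes and floored at 1e-12.
    """
    if not heldout.any():
        return float("nan")
    p = np.einsum("nk,klc->nlc", Q, G)
    p = np.clip(p, 1e-12, None)
    p /= p.sum(axis=2, keepdims=True)
    i, j = np.nonzero(heldout)
    cls = x3[i, j].argmax(axis=1)
    return float(-np.log(p[i, j, cls]).mean())


# ---------------------------------------------------------------------------
# Model selection and replicate alignment
# ---------------------------------------------------------------------------


@dataclass
class KSelection:
    best_k: int
    table: pd.DataFrame  # columns K, mean_cross_entropy, sd, n_replicates
    best_fits: dict[int, AdmixtureFit]  # lowest-cross-entropy fit per K


def select_k(
    gm: GenotypeMatrix,
    k_values: Iterable[int] = range(1, 11),
    n_replicates: int = 10,
    seed: int | None = None,
    **fit_kwargs,
) -> KSelection:
    """Choose the number of ancestral populations by masked cross-entropy.

    Runs ``n_replicates`` seeded fits per K.  The held-out mask stream is
    shared across K (one mask per replicate index), so every K is scored on
    the same held-out entries.  K* minimises the mean cross-entropy; ties
    break to the smallest K.  The per-K table is returned so callers can
    apply plateau heuristics instead.
    """
    k_values = sorted(set(int(k) for k in k_values))
    if not k_values or n_replicates < 1:
        raise StructureError("need at least one K value and one replicate")
    ss = np.random.SeedSequence(seed)
    fit_seeds = [int(s % (2**31 - 1)) for s in ss.generate_state(n_replicates * len(k_values))]
    mask_seeds = [int(s % (2**31 - 1)) for s in np.random.SeedSequence((seed if seed is not None else 0) + 1).generate_state(n_replicates)]
    rows = []
    best_fits: dict[int, AdmixtureFit] = {}
    ces: dict[int, list[float]] = {k: [] for k in k_values}
    idx = 0
    for k in k_values:
        for r in range(n_replicates):
            fit = fit_admixture(gm, K=k, seed=fit_seeds[idx], mask_seed=mask_seeds[r], **fit_kwargs)
            idx += 1
            ces[k].append(fit.cross_entropy)
            if k not in best_fits or fit.cross_entropy < best_fits[k].cross_entropy:
                best_fits[k] = fit
    for k in k_values:
        arr = np.array(ces[k])
        rows.append((k, arr.mean(), arr.std(ddof=1) if len(arr) > 1 else 0.0, len(arr)))
    table = pd.DataFrame(rows, columns=["K", "mean_cross_entropy", "sd", "n_replicates"])
    best_k = int(table.loc[table["mean_cross_entropy"].idxmin(), "K"])  # idxmin -> first = smallest K on ties
    return KSelection(best_k=best_k, table=table, best_fits=best_fits)


def align_q(q_ref: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Greedily permute the columns of ``q`` to best match ``q_ref``.

    Label switching makes replicate Q matrices comparable only up to column
    permutation; columns are matched one at a time by highest Pearson
    correlation against the reference.
    """
    if q.shape != q_ref.shape:
        raise StructureError("Q shapes differ")
    k = q.shape[1]
    corr = np.corrcoef(q_ref.T, q.T)[:k, k:]
    corr = np.nan_to_num(corr, nan=-2.0)
    perm = [-1] * k
    used_ref, used = set(), set()
    for _ in range(k):
        best = None
        for i in range(k):
            if i in used_ref:
                continue
            for j in range(k):
                if j in used:
                    continue
                if best is None or corr[i, j] > corr[best[0], best[1]]:
                    best = (i, j)
        used_ref.add(best[0])
        used.add(best[1])
        perm[best[0]] = best[1]
    return q[:, perm]


def mean_aligned_q(fits: Sequence[AdmixtureFit]) -> np.ndarray:
    """Replicate-mean ancestry coefficients after label alignment.

    The reference is the lowest-cross-entropy replicate.
    """
    if not fits:
        raise StructureError("no fits")
    ref = min(fits, key=lambda f: f.cross_entropy)
    acc = np.zeros_like(ref.Q)
    for f in fits:
        acc += align_q(ref.Q, f.Q)
    return acc / len(fits)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: np.ndarray  # (n_samples, n_axes)
    explained_variance_fractions: np.ndarray
    sample_ids: list[str]


def pca_genotypes(gm: GenotypeMatrix, n_axes: int = 3, scale: bool = True) -> PcaResult:
    """Principal components of the genotype matrix.

    Missing calls are mean-imputed per locus; loci are centred and, when
    ``scale`` is on, divided by the binomial standard deviation
    sqrt(p(1-p)) of their allele frequency.  Scores come from the singular
    value decomposition; each axis's sign is fixed so that the
    largest-magnitude loading is positive.
    """
    if gm.n_samples < 2 or gm.n_loci < 2:
        raise StructureError("PCA needs >= 2 samples and >= 2 loci")
    calls = gm.calls.astype(float)
    obs = gm.calls != MISSING
    if not obs.any():
        raise StructureError("all calls missing")
    with np.errstate(invalid="ignore"):
        means = np.where(obs, calls, np.nan)
        mu = np.nanmean(means, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    xm = np.where(obs, calls, mu[None, :]) - mu[None, :]
    if scale:
        p = mu / 2.0
        sd = np.sqrt(np.clip(p * (1 - p), 1e-12, None))
        xm = xm / sd[None, :]
    if not np.any(xm):
        raise StructureError("zero-variance genotype matrix")
    u, s, vt = np.linalg.svd(xm, full_matrices=False)
    n_axes = min(n_axes, len(s))
    # sign convention: largest-magnitude loading positive per axis
    for a in range(n_axes):
        j = np.argmax(np.abs(vt[a]))
        if vt[a, j] < 0:
            vt[a] *= -1
            u[:, a] *= -1
    scores = u[:, :n_axes] * s[:n_axes]
    var = s**2
    evf = var[:n_axes] / var.sum()
    return PcaResult(scores=scores, explained_variance_fractions=evf, sample_ids=list(gm.sample_ids))


# ---------------------------------------------------------------------------
# Signal 2: admixture between sites
# ---------------------------------------------------------------------------


def detect_signal2(
    fit: AdmixtureFit,
    site_assignment: Mapping[str, str],
    dominance_threshold: float = 0.75,
    site_majority: float = 0.5,
) -> SignalResult:
    """Flag sites whose genotypes look admixed between two source pools.

    A site is flagged iff more than ``site_majority`` of its samples have
    dominant ancestry at or below ``dominance_threshold`` AND the site's
    two largest mean ancestry components each dominate at least one other
    site — distinguishing between-site admixture (secondary contact) from
    mere within-site noise.  Requires K >= 2; with a single inferred
    ancestral population the signal is not assessable.
    """
    if fit.K < 2:
        return SignalResult(NOT_ASSESSABLE, {"reason": f"K={fit.K} < 2"})
    sites: dict[str, list[int]] = {}
    for i, sid in enumerate(fit.sample_ids):
        sites.setdefault(site_assignment[sid], []).append(i)
    modal: dict[str, int] = {}
    mean_q: dict[str, np.ndarray] = {}
    small_sites = [s for s, idx in sites.items() if len(idx) < 2]
    for s, idx in sites.items():
        mean_q[s] = fit.Q[idx].mean(axis=0)
        modal[s] = int(mean_q[s].argmax())
    flagged = []
    details = {}
    dom = fit.dominant_coefficient()
    for s, idx in sites.items():
        if len(idx) < 2:
            continue
        frac_admixed = float(np.mean(dom[idx] <= dominance_threshold))
        top2 = np.argsort(mean_q[s])[::-1][:2]
        sourced = all(
            any(modal[o] == int(c) for o in sites if o != s and len(sites[o]) >= 2) for c in top2
        )
        details[s] = {"fraction_admixed": frac_admixed, "top_components": [int(c) for c in top2],
                      "components_sourced_elsewhere": sourced}
        if frac_admixed > site_majority and sourced:
            flagged.append(s)
    status = DETECTED if flagged else NOT_DETECTED
    return SignalResult(status, {"flagged_sites": flagged, "sites": details,
                                 "excluded_small_sites": small_sites, "K": fit.K})


# ---------------------------------------------------------------------------
# Signal 3: within-site outlier genotypes
# ---------------------------------------------------------------------------


def detect_signal3(
    fit: AdmixtureFit,
    pca: PcaResult,
    site_assignment: Mapping[str, str],
    foreign_dominance: float = 0.60,
    n_axes: int = 3,
) -> SignalResult:
    """Flag samples whose genotype belongs with another site.

    A sample is flagged iff (a) its dominant ancestry component differs
    from its site's modal component with coefficient at least
    ``foreign_dominance``, and (b) the nearest site centroid in PCA score
    space (first ``n_axes`` axes, Euclidean) is not its own site.  Both the
    ancestry and the ordination must agree before a sample is called an
    outlier.  Requires K >= 2.
    """
    if fit.K < 2:
        return SignalResult(NOT_ASSESSABLE, {"reason": f"K={fit.K} < 2"})
    if fit.sample_ids != pca.sample_ids:
        raise StructureError("admixture and PCA sample orderings differ")
    sites: dict[str, list[int]] = {}
    for i, sid in enumerate(fit.sample_ids):
        sites.setdefault(site_assignment[sid], []).append(i)
    modal = {s: int(fit.Q[idx].mean(axis=0).argmax()) for s, idx in sites.items()}
    axes = min(n_axes, pca.scores.shape[1])
    centroids = {s: pca.scores[idx, :axes].mean(axis=0) for s, idx in sites.items()}
    dom_comp = fit.dominant_component()
    dom_coef = fit.dominant_coefficient()
    outliers = []
    evidence = {}
    for i, sid in enumerate(fit.sample_ids):
        s = site_assignment[sid]
        foreign = dom_comp[i] != modal[s] and dom_coef[i] >= foreign_dominance
        d = {o: float(np.linalg.norm(pca.scores[i, :axes] - c)) for o, c in centroids.items()}
        nearest = min(d, key=d.get)
        pca_foreign = nearest != s
        if foreign or pca_foreign:
            evidence[sid] = {"site": s, "dominant_component": int(dom_comp[i]),
                             "site_modal_component": modal[s],
                             "dominant_coefficient": float(dom_coef[i]),
                             "nearest_pca_site": nearest,
                             "ancestry_criterion": bool(foreign),
                             "pca_criterion": bool(pca_foreign)}
        if foreign and pca_foreign:
            outliers.append(sid)
    status = DETECTED if outliers else NOT_DETECTED
    return SignalResult(status, {"outlier_samples": outliers, "candidates": evidence, "K": fit.K})
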