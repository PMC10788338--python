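"""Class-count selection (AIC elbow) and endotype stability analysis.

The number of latent classes K is chosen by fitting a contiguous range of
K values and locating the elbow of the AIC curve: after normalizing both
axes to [0, 1], the selected K maximizes the perpendicular distance to
the chord joining the first and last curve points (the classic "knee"
construction; invariant to affine rescaling of either axis).

Stability: the LCA fit is repeated R times with independent restarts,
giving R*K item-response profiles. These are pooled and meta-clustered
with a diagonal-covariance Gaussian mixture (a latent profile analysis of
the profiles themselves), the mixture size G chosen by BIC. A stable
solution yields exactly K recurring meta-profiles, each receiving one
profile from every replicate; the stability score is the fraction of
replicates for which that holds. The representative model is the
replicate with the lowest AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.mixture import GaussianMixture

from .lca import LcaFit, em_fit

__all__ = ["AicCurve", "StabilityReport", "fit_k_range", "detect_elbow",
           "replicate_fits", "meta_cluster", "align_labels"]


@dataclass
class AicCurve:
    """AIC across a contiguous K range, with the elbow selection."""

    k_values: list[int]
    aic_values: list[float]
    selected_k: int | None = None
    method: str = "max-chord-distance"
    no_elbow: bool = False
    fits: dict[int, LcaFit] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {"k_values": self.k_values,
                "aic_values": [float(a) for a in self.aic_values],
                "selected_k": self.selected_k, "method": self.method,
                "no_elbow": self.no_elbow}


@dataclass
class StabilityReport:
    """Meta-clustering of pooled replicate class profiles."""

    n_replicates: int
    k: int
    profiles: np.ndarray = field(repr=False)          # (R*K, J)
    replicate_of: np.ndarray = field(repr=False)      # (R*K,) replicate index
    n_meta_clusters: int
    meta_assignment: np.ndarray = field(repr=False)   # (R*K,)
    meta_means: np.ndarray = field(repr=False)        # (G, J)
    meta_sds: np.ndarray = field(repr=False)          # (G, J)
    representative_index: int
    stability_score: float

    def to_dict(self) -> dict:
        return {"n_replicates": self.n_replicates, "k": self.k,
                "n_meta_clusters": self.n_meta_clusters,
                "meta_assignment": self.meta_assignment.tolist(),
                "meta_means": self.meta_means.tolist(),
                "meta_sds": self.meta_sds.tolist(),
                "representative_index": self.representative_index,
                "stability_score": float(self.stability_score)}


def fit_k_range(matrix, k_min: int = 1, k_max: int = 8,
                n_restarts: int = 20, tol: float = 1e-8,
                max_iter: int = 5000, seed: int | None = None,
                burn_iter: int | None = 40) -> AicCurve:
    """Best-of-restarts fit at each K in [k_min, k_max]; record AIC.

    Individual K failures are recorded as NaN without aborting the curve.
    The fitted models are cached on the returned curve for reuse. By
    default restarts use a 40-iteration burn-in with only the leading
    start refined to convergence (see :func:`endotypes.lca.em_fit`).
    """
    if not 1 <= k_min < k_max:
        raise ValueError("need 1 <= k_min < k_max")
    ks, aics, fits = [], [], {}
    seeds = np.random.SeedSequence(seed).spawn(k_max - k_min + 1)
    for idx, k in enumerate(range(k_min, k_max + 1)):
        ks.append(k)
        try:
            fit = em_fit(matrix, k, n_restarts=n_restarts, tol=tol,
                         max_iter=max_iter, burn_iter=burn_iter,
                         seed=int(seeds[idx].generate_state(1)[0] % 2**31))
            fits[k] = fit
            aics.append(fit.aic)
        except Exception as exc:  # noqa: BLE001 - record, keep the curve
            warnings.warn(f"fit_k_range: K={k} failed ({exc})")
            aics.append(float("nan"))
    curve = AicCurve(k_values=ks, aic_values=aics, fits=fits)
    detect_elbow(curve)
    return curve


def detect_elbow(curve: AicCurve) -> int:
    """Elbow K: maximum normalized distance to the first-last chord.

    Both axes are min-max normalized before computing perpendicular
    distances, making the selection invariant to affine rescaling of the
    AIC axis. Candidate K values are restricted to the decreasing segment
    of the curve (up to the global AIC minimum): an elbow marks where
    improvement flattens, so the rising overfit tail cannot contain it.
    Ties break to the smaller K. A curve whose minimum sits at the first
    point never improves on k_min and has no elbow: the smallest K is
    returned with ``no_elbow`` set.
    """
    ks = np.asarray(curve.k_values, dtype=float)
    aic = np.asarray(curve.aic_values, dtype=float)
    if len(ks) < 3:
        raise ValueError("elbow detection needs at least 3 curve points")
    if not np.isfinite(aic).all():
        raise ValueError("elbow detection requires finite AIC values")

    i_min = int(np.argmin(aic))
    if i_min == 0:
        warnings.warn("AIC never improves on the smallest K; no elbow")
        curve.selected_k = int(curve.k_values[0])
        curve.no_elbow = True
        return curve.selected_k

    x = (ks - ks[0]) / (ks[-1] - ks[0])
    span = aic.max() - aic.min()
    y = (aic - aic.min()) / span if span > 0 else np.zeros_like(aic)
    # distance from (x, y) to the chord through the end points
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    norm = np.hypot(x1 - x0, y1 - y0)
    d = np.abs((x1 - x0) * (y0 - y) - (x0 - x) * (y1 - y0)) / norm
    d[i_min + 1:] = 0.0  # rising tail excluded from candidacy
    if d.max() <= 1e-12:
        warnings.warn("AIC curve is a straight line; no elbow")
        curve.selected_k = int(curve.k_values[0])
        curve.no_elbow = True
        return curve.selected_k
    curve.selected_k = int(ks[int(np.argmax(d))])
    curve.no_elbow = False
    return curve.selected_k


def replicate_fits(matrix, k: int, r: int = 30, base_seed: int | None = None,
                   n_restarts: int = 3, tol: float = 1e-8,
                   max_iter: int = 5000) -> list[LcaFit]:
    """R independent LCA fits at the same K with distinct derived seeds.

    Each replicate is itself a best-of-``n_restarts`` fit so that
    replicate-to-replicate variation reflects the data rather than
    single-start EM local optima.
    """
    if r < 2:
        raise ValueError("need at least 2 replicates")
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(base_seed).spawn(r)]
    if len(set(seeds)) != r:  # astronomically unlikely; fail loudly
        raise RuntimeError("derived replicate seeds collide")
    return [em_fit(matrix, k, n_restarts=n_restarts, tol=tol,
                   max_iter=max_iter, seed=s) for s in seeds]


def align_labels(reference_rho: np.ndarray,
                 candidate_rho: np.ndarray) -> np.ndarray:
    """Permutation p minimizing total distance of candidate rows to
    reference rows: ``candidate_rho[p]`` best matches ``reference_rho``.

    Solves the optimal assignment on squared Euclidean row distances.
    """
    ref = np.asarray(reference_rho, dtype=float)
    cand = np.asarray(candidate_rho, dtype=float)
    if ref.shape != cand.shape:
        raise ValueError("profile matrices must share a shape")
    cost = ((ref[:, None, :] - cand[None, :, :]) ** 2).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    return cols[np.argsort(rows)]


def meta_cluster(fits: list[LcaFit], g_max: int = 10,
                 seed: int | None = None) -> StabilityReport:
    """Meta-cluster pooled replicate profiles with a diagonal GMM.

    The mixture size G is chosen by BIC over 1..g_max (capped at the
    number of distinct pooled profiles). The stability score is the
    fraction of replicates contributing exactly one profile to each of
    the K largest meta-clusters.
    """
    if len(fits) < 2:
        raise ValueError("meta-clustering requires at least 2 replicate fits")
    k = fits[0].k
    if any(f.k != k for f in fits):
        raise ValueError("replicate fits must share the same K")
    r = len(fits)
    profiles = np.vstack([f.rho for f in fits])
    replicate_of = np.repeat(np.arange(r), k)

    n_distinct = np.unique(np.round(profiles, 6), axis=0).shape[0]
    g_hi = min(g_max, n_distinct, profiles.shape[0])
    if g_hi < 1:
        raise ValueError("no distinct profiles to cluster; lower g_max")

    best_g, best_bic, best_gm = None, np.inf, None
    for g in range(1, g_hi + 1):
        gm = GaussianMixture(n_components=g, covariance_type="diag",
                             reg_covar=1e-6, n_init=3,
                             random_state=(seed if seed is not None else 0))
        gm.fit(profiles)
        bic = gm.bic(profiles)
        if bic < best_bic - 1e-9:
            best_g, best_bic, best_gm = g, bic, gm

    labels = best_gm.predict(profiles)
    means = best_gm.means_
    sds = np.sqrt(best_gm.covariances_)

    sizes = np.bincount(labels, minlength=best_g)
    top_k = set(np.argsort(sizes)[::-1][:k])
    stable = 0
    for rep in range(r):
        lab = labels[replicate_of == rep]
        counts = np.bincount(lab, minlength=best_g)
        if all(counts[g] == 1 for g in top_k):
            stable += 1
    score = stable / r

    aics = np.array([f.aic for f in fits])
    representative = int(np.argmin(aics))  # ties -> lowest index

    return StabilityReport(n_replicates=r, k=k, profiles=profiles,
                           replicate_of=replicate_of,
                           n_meta_clusters=int(best_g),
                           meta_assignment=labels, meta_means=means,
                           meta_sds=sds, representative_index=representative,
                           stability_score=score)
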