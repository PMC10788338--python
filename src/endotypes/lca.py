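"""Latent class analysis for binary comorbidity indicators.

Fits the standard binary latent class (Bernoulli mixture) model

    f(x_i) = sum_k pi_k  prod_j  rho_kj^{x_ij} (1 - rho_kj)^{1 - x_ij}

by expectation-maximization with random restarts. Each class k is an
"endotype": a patient subgroup with its own item-response probability
profile rho_k over the J comorbidity flags. Responsibilities tau_ik are
the posterior class-membership probabilities; modal assignment gives each
patient a discrete endotype label (0-based).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = ["LcaFit", "log_likelihood", "em_fit", "information_criteria",
           "assign_classes", "n_parameters"]

#: probability clamp keeping rho away from the {0,1} boundary
EPS = 1e-6


def n_parameters(k: int, j: int) -> int:
    """Free parameters of a K-class, J-item binary LCA: (K-1) + K*J."""
    return (k - 1) + k * j


@dataclass
class LcaFit:
    """One fitted binary latent class model.

    Attributes
    ----------
    k : int
        Number of latent classes.
    pi : ndarray, shape (K,)
        Mixing weights (sum to 1).
    rho : ndarray, shape (K, J)
        Item-response probabilities, clamped to [EPS, 1-EPS].
    tau : ndarray, shape (N, K)
        Posterior responsibilities (rows sum to 1).
    loglik : float
        Final observed-data log-likelihood.
    aic, bic : float
        Information criteria at ``n_params`` free parameters.
    n_params : int
    assignments : ndarray, shape (N,)
        Modal class per patient, 0-based; ties break to the lower index.
    n_iter : int
        EM iterations used by the selected restart.
    converged : bool
    seed : int or None
    restart_index : int
        Which restart attained the best final log-likelihood.
    loglik_trace : ndarray
        Per-iteration log-likelihood of the selected restart.
    """

    k: int
    pi: np.ndarray
    rho: np.ndarray
    tau: np.ndarray = field(repr=False)
    loglik: float
    aic: float
    bic: float
    n_params: int
    assignments: np.ndarray = field(repr=False)
    n_iter: int
    converged: bool
    seed: int | None
    restart_index: int
    loglik_trace: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        """JSON-serializable summary (responsibilities omitted)."""
        return {
            "k": self.k,
            "pi": self.pi.tolist(),
            "rho": self.rho.tolist(),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "n_params": self.n_params,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "seed": self.seed,
            "restart_index": self.restart_index,
        }


def _as_matrix(matrix) -> np.ndarray:
    x = np.asarray(matrix, dtype=float)
    if hasattr(matrix, "to_numpy"):
        x = matrix.to_numpy(dtype=float)
    if x.ndim != 2:
        raise ValueError("comorbidity matrix must be 2-D")
    if np.isnan(x).any():
        raise ValueError("comorbidity matrix contains missing values; "
                         "resolve them during cohort construction")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("comorbidity matrix entries must be binary")
    return x


def _log_components(x: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """N x K matrix of log p_k(x_i) for Bernoulli product components."""
    rho = np.clip(rho, EPS, 1 - EPS)
    return x @ np.log(rho).T + (1 - x) @ np.log1p(-rho).T


def log_likelihood(matrix, pi, rho) -> float:
    """Observed-data log-likelihood, computed stably in log space."""
    x = _as_matrix(matrix)
    pi = np.asarray(pi, dtype=float)
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    if not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("pi must sum to 1")
    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
    lw = _log_components(x, rho) + logpi
    row = logsumexp(lw, axis=1)
    if np.isneginf(row).any():
        warnings.warn("zero-density rows encountered; log-likelihood is -inf")
        return float("-inf")
    return float(row.sum())


def _e_step(x, pi, rho):
    with np.errstate(divide="ignore"):
        lw = _log_components(x, rho) + np.log(pi)
    norm = logsumexp(lw, axis=1)
    tau = np.exp(lw - norm[:, None])
    return tau, float(norm.sum())


def _m_step(x, tau):
    nk = tau.sum(axis=0)
    pi = nk / tau.shape[0]
    rho = (tau.T @ x) / nk[:, None]
    return pi, np.clip(rho, EPS, 1 - EPS)


def _run_em(x, pi, rho, max_iter, tol):
    """EM iterations from starting parameters.

    Returns (pi, rho, tau, loglik, trace, n_iter, converged, collapsed);
    `collapsed` is set when a class mass drops below 1e-8 * N.
    """
    n = x.shape[0]
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    tau = None
    for it in range(1, max_iter + 1):
        tau, ll = _e_step(x, pi, rho)
        trace.append(ll)
        if tau.sum(axis=0).min() < 1e-8 * n:
            return pi, rho, tau, ll, trace, it, False, True
        pi, rho = _m_step(x, tau)
        if abs(ll - prev) / (abs(ll) + 1.0) < tol:
            converged = True
            break
        prev = ll
    tau, ll = _e_step(x, pi, rho)  # sync tau/loglik with final (pi, rho)
    trace.append(ll)
    return pi, rho, tau, ll, trace, it, converged, False


def em_fit(matrix, k: int, n_restarts: int = 20, tol: float = 1e-8,
           max_iter: int = 5000, seed: int | None = None,
           burn_iter: int | None = None) -> LcaFit:
    """Fit a K-class binary LCA by EM, keeping the best of `n_restarts`.

    Each restart initializes responsibilities from a flat Dirichlet per
    patient followed by an M-step. Iteration stops when the relative
    log-likelihood change ``|dL| / (|L| + 1)`` drops below `tol` or after
    `max_iter` iterations. A restart whose smallest class mass collapses
    below ``1e-8 * N`` is re-drawn (logged). Deterministic for fixed seed.

    When `burn_iter` is given, every restart runs only `burn_iter`
    iterations; the restart leading at that point continues alone to
    convergence (short-run/long-run EM — much cheaper at many restarts,
    at the usual small risk of discarding a slow-starting basin).
    """
    x = _as_matrix(matrix)
    n, j = x.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of patients n={n}")

    root = np.random.SeedSequence(seed)
    children = root.spawn(n_restarts)
    limit = burn_iter if burn_iter is not None else max_iter

    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(children[r])
        result = None
        for _attempt in range(10):
            tau0 = rng.dirichlet(np.ones(k), size=n)
            pi0, rho0 = _m_step(x, tau0)
            out = _run_em(x, pi0, rho0, limit, tol)
            if not out[7]:  # not collapsed
                result = out
                break
            warnings.warn(f"em_fit: empty class in restart {r}, re-drawing")
        if result is None:
            continue
        pi, rho, tau, ll, trace, it, converged, _ = result
        if best is None or ll > best[0]:
            best = (ll, pi, rho, tau, it, converged, r, trace)

    if best is None:
        raise RuntimeError("all EM restarts collapsed to an empty class")

    ll, pi, rho, tau, it, converged, r, trace = best
    if burn_iter is not None and not converged:
        pi, rho, tau, ll, more, extra, converged, collapsed = _run_em(
            x, pi, rho, max_iter, tol)
        if collapsed:
            raise RuntimeError("EM collapsed while refining the best restart")
        trace = trace + more
        it += extra
    trace = np.array(trace)
    m = n_parameters(k, j)
    aic = -2 * ll + 2 * m
    bic = -2 * ll + m * np.log(n)
    return LcaFit(k=k, pi=pi, rho=rho, tau=tau, loglik=ll, aic=aic, bic=bic,
                  n_params=m, assignments=np.argmax(tau, axis=1),
                  n_iter=it, converged=converged, seed=seed,
                  restart_index=r, loglik_trace=trace)


def information_criteria(fit: LcaFit, n: int) -> tuple[float, float]:
    """(AIC, BIC) = (-2L + 2m, -2L + m log N) for a fitted model."""
    m = fit.n_params
    return (-2 * fit.loglik + 2 * m, -2 * fit.loglik + m * np.log(n))


def assign_classes(fit: LcaFit) -> np.ndarray:
    """Modal posterior class per patient (0-based; ties to lower index)."""
    return np.argmax(fit.tau, axis=1)
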