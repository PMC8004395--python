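"""Dirichlet multinomial mixture (DMM) modelling with Laplace model selection.

Count rows (items, or samples) are modelled as draws from a finite mixture of
Dirichlet-multinomial components.  The number of components K is chosen by
minimising a Laplace approximation to the negative log model evidence, so that
richer mixtures pay for their extra parameters.  The same model is used to
split food-composition categories into nutrient subcategories and to partition
metagenomes into CAZotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp, polygamma

__all__ = ["DMMFit", "fit_dmm", "simulate_dmm"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class DMMFit:
    """Fitted Dirichlet multinomial mixture.

    Attributes
    ----------
    k : int
        Selected number of components (minimum Laplace score).
    alphas : ndarray of shape (k, n_features)
        Dirichlet parameter vector of each component; strictly positive.
    weights : ndarray of shape (k,)
        Mixture weights, summing to one.
    laplace : dict[int, float]
        Laplace approximation of the negative log evidence per fitted K.
    log_likelihood : float
        Maximised log likelihood of the selected model.
    assignments : ndarray of shape (n_rows,)
        Hard component assignment (maximum posterior; ties broken toward the
        lowest component index).
    responsibilities : ndarray of shape (n_rows, k)
        Posterior component probabilities per row.
    """

    k: int
    alphas: np.ndarray
    weights: np.ndarray
    laplace: dict = field(default_factory=dict)
    log_likelihood: float = np.nan
    assignments: np.ndarray | None = None
    responsibilities: np.ndarray | None = None


def _dirmult_logpmf(counts, alpha):
    """Log Dirichlet-multinomial pmf (without the multinomial coefficient,
    which is constant across components and cancels in responsibilities)."""
    a0 = alpha.sum()
    n = counts.sum(axis=1)
    return (
        gammaln(a0)
        - gammaln(n + a0)
        + (gammaln(counts + alpha) - gammaln(alpha)).sum(axis=1)
    )


def _component_loglik_matrix(counts, alphas):
    return np.column_stack([_dirmult_logpmf(counts, a) for a in alphas])


def _update_alpha(counts, resp_k, alpha, n_iter=6, tol=1e-7):
    """Minka fixed-point update of one component's Dirichlet parameters,
    weighted by responsibilities.

    A handful of inner iterations per EM step is enough: the outer EM loop
    re-enters this update until the joint fit converges.
    """
    n = counts.sum(axis=1)
    for _ in range(n_iter):
        a0 = alpha.sum()
        num = resp_k @ (digamma(counts + alpha) - digamma(alpha))
        den = resp_k @ (digamma(n + a0) - digamma(a0))
        if den <= 0:
            break
        # upper cap: beyond ~1e4 the fit is effectively multinomial and the
        # likelihood only creeps logarithmically
        new = np.minimum(np.maximum(alpha * num / den, 1e-8), 1e4)
        done = np.max(np.abs(new - alpha)) < tol * np.max(alpha)
        alpha = new
        if done:
            break
    return alpha


_PRIOR_VAR = 25.0  # variance of the N(0, s^2) prior on log(alpha); wide
# enough that tight nutrient clusters (alpha ~ 1e3-1e4) are not unduly
# penalised, yet it still pins down the weakly identified concentration
# direction of each component


def _laplace_score(counts, alphas, weights, loglik):
    """Laplace approximation to the negative log model evidence.

    Uses the MAP form with a weak Gaussian prior on log(alpha): the
    Dirichlet-multinomial likelihood is nearly flat along each component's
    overall-concentration direction, so the bare observed information has a
    near-zero eigenvalue there and the prior curvature (1/s^2) keeps the
    approximation finite and honest.  Per component the Hessian w.r.t.
    log-alpha is diag(d) + c aa' (analytic), the mixture weights contribute
    the multinomial information determinant n^(K-1) prod(w).
    """
    k, j = alphas.shape
    n_rows = counts.shape[0]
    comp_ll = _component_loglik_matrix(counts, alphas)
    log_r = np.log(np.maximum(weights, 1e-300)) + comp_ll
    resp = np.exp(log_r - logsumexp(log_r, axis=1, keepdims=True))
    n = counts.sum(axis=1)

    tau = 1.0 / _PRIOR_VAR
    logdet = 0.0
    log_prior = 0.0
    for kk in range(k):
        a = alphas[kk]
        z = resp[:, kk]
        a0 = a.sum()
        # curvature of -E[log lik] w.r.t. alpha: diag(d) + c 11'
        c = -(z * (polygamma(1, a0) - polygamma(1, n + a0))).sum()
        d = -(polygamma(1, counts + a) - polygamma(1, a)).T @ z
        # chain rule to log-alpha coordinates (gradient vanishes at the MAP)
        h = np.diag(d * a * a + tau) + c * np.outer(a, a)
        ev = np.linalg.eigvalsh(h)
        logdet += np.sum(np.log(np.maximum(ev, tau / 10.0)))
        lam = np.log(a)
        log_prior += -0.5 * np.sum(lam * lam) * tau - 0.5 * j * np.log(
            2.0 * np.pi * _PRIOR_VAR
        )
    if k > 1:
        w = np.maximum(weights, 1e-12)
        logdet += (k - 1) * np.log(n_rows) + np.sum(np.log(w))
    n_par = k * j + (k - 1)
    return -loglik - log_prior + 0.5 * logdet - 0.5 * n_par * _LOG_2PI


def _fit_single_k(counts, k, rng, max_iter=80, tol=1e-5, n_restarts=3):
    n_rows, n_feat = counts.shape
    props = counts / counts.sum(axis=1, keepdims=True)
    best = None
    for _ in range(n_restarts if k > 1 else 1):
        # initialise responsibilities from a random hard split
        if k == 1:
            resp = np.ones((n_rows, 1))
        else:
            labels = rng.integers(0, k, size=n_rows)
            # ensure every component is seeded
            labels[rng.choice(n_rows, size=k, replace=False)] = np.arange(k)
            resp = np.zeros((n_rows, k))
            resp[np.arange(n_rows), labels] = 1.0
            resp = 0.9 * resp + 0.1 / k
        alphas = np.empty((k, n_feat))
        for kk in range(k):
            w = resp[:, kk]
            m = (props * w[:, None]).sum(axis=0) / w.sum()
            alphas[kk] = np.maximum(m, 1e-3) * 10.0
        weights = resp.mean(axis=0)
        prev_ll = -np.inf
        run_best = None
        for _ in range(max_iter):
            comp_ll = _component_loglik_matrix(counts, alphas)
            log_r = np.log(np.maximum(weights, 1e-300)) + comp_ll
            norm = logsumexp(log_r, axis=1, keepdims=True)
            ll = norm.sum()
            resp = np.exp(log_r - norm)
            if run_best is None or ll > run_best[0]:
                run_best = (ll, alphas.copy(), weights.copy(), resp.copy())
            # partial M-steps can make ll dip slightly; a dip or a tiny gain
            # both mean we are done
            if ll < prev_ll - 1e-9 or abs(ll - prev_ll) < max(tol * abs(ll) * 0.1, 1e-3):
                break
            prev_ll = ll
            weights = np.maximum(resp.mean(axis=0), 1e-10)
            weights /= weights.sum()
            for kk in range(k):
                alphas[kk] = _update_alpha(counts, resp[:, kk], alphas[kk])
        if best is None or run_best[0] > best[0]:
            best = run_best
    return best


def fit_dmm(count_table, k_range, seed=0, n_restarts=3):
    """Fit DMM models over ``k_range`` and select K by minimum Laplace score.

    Parameters
    ----------
    count_table : array-like of shape (n_rows, n_features)
        Non-negative integer counts; every row must have a positive total.
    k_range : iterable of int
        Candidate component numbers.  Values exceeding the number of rows are
        skipped with a warning.
    seed : int
        Seed for EM initialisation restarts.

    Returns
    -------
    DMMFit
    """
    counts = np.asarray(count_table, dtype=float)
    if counts.ndim != 2:
        raise ValueError("count_table must be two-dimensional")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1)
    zero_rows = np.flatnonzero(totals == 0)
    if zero_rows.size:
        raise ValueError(f"rows with all-zero counts: {zero_rows.tolist()}")
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or min(k_range) < 1:
        raise ValueError("k_range must contain positive integers")

    rng = np.random.default_rng(seed)
    n_rows = counts.shape[0]
    fits = {}
    scores = {}
    for k in k_range:
        if k > n_rows:
            warnings.warn(f"K={k} exceeds the number of rows ({n_rows}); skipped")
            continue
        ll, alphas, weights, resp = _fit_single_k(
            counts, k, rng, n_restarts=n_restarts
        )
        scores[k] = _laplace_score(counts, alphas, weights, ll)
        fits[k] = (ll, alphas, weights, resp)
    if not fits:
        raise ValueError("no feasible K in k_range")
    best_k = min(scores, key=lambda k: (scores[k], k))
    ll, alphas, weights, resp = fits[best_k]
    assignments = resp.argmax(axis=1)
    return DMMFit(
        k=best_k,
        alphas=alphas,
        weights=weights,
        laplace=scores,
        log_likelihood=ll,
        assignments=assignments,
        responsibilities=resp,
    )


def simulate_dmm(n_rows, alphas, weights, depth, seed=0):
    """Draw counts from a DMM with known parameters (testing utility).

    ``depth`` may be an int (common total per row) or an array of row totals.
    Returns (counts, component_labels).
    """
    alphas = np.asarray(alphas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    depth = np.broadcast_to(np.asarray(depth), (n_rows,))
    labels = rng.choice(len(weights), size=n_rows, p=weights / weights.sum())
    counts = np.empty((n_rows, alphas.shape[1]), dtype=int)
    for i, (lab, d) in enumerate(zip(labels, depth)):
        p = rng.dirichlet(alphas[lab])
        counts[i] = rng.multinomial(d, p)
    return counts, labels
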