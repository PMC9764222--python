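"""Independent brute-force oracles used to validate the statistical core.

Everything here is deliberately naive — exhaustive enumeration, textbook
rule-by-definition procedures, breadth-first flood fill, and numerical
integration — and shares no code path with the package implementation.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
from scipy import integrate, stats


def ranksum_p_enumeration(x, y) -> float:
    """Right-tailed rank-sum p by enumerating all group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    ranks = stats.rankdata(pooled)
    n_x = len(x)
    observed = ranks[:n_x].sum()
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_x):
        total += 1
        if ranks[list(idx)].sum() >= observed:
            count += 1
    return count / total


def signed_rank_p_enumeration(diffs, alternative="greater") -> float:
    """Signed-rank p by enumerating all 2^n sign assignments.

    Zero differences must already be removed.  The statistic is the sum
    of ranks of positive differences (W+).
    """
    d = np.asarray(diffs, dtype=float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    w_all = np.array([ranks[list(signs)].sum() if signs else 0.0
                      for r in range(n + 1)
                      for signs in itertools.combinations(range(n), r)])
    if alternative == "greater":
        return float(np.mean(w_all >= w_obs))
    if alternative == "less":
        return float(np.mean(w_all <= w_obs))
    p = 2 * min(np.mean(w_all >= w_obs), np.mean(w_all <= w_obs))
    return float(min(1.0, p))


def bh_reject_by_definition(p_values, alpha=0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rule, straight from its definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= alpha * k / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


def holm_adjust_by_definition(p_values, family_size=None) -> np.ndarray:
    """Holm step-down adjusted p-values, straight from the definition."""
    p = np.asarray(p_values, dtype=float)
    m = family_size if family_size is not None else p.size
    order = np.argsort(p)
    adjusted = np.empty_like(p)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, min(1.0, (m - i) * p[idx]))
        adjusted[idx] = running
    return adjusted


def flood_fill_clusters(mask: np.ndarray) -> list[set]:
    """Connected components under 26-connectivity via breadth-first search."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    offsets = [np.array(d) for d in itertools.product((-1, 0, 1), repeat=3)
               if d != (0, 0, 0)]
    comps = []
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        comp, queue = set(), deque([start])
        visited[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for off in offsets:
                w = tuple(np.array(v) + off)
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) \
                        and mask[w] and not visited[w]:
                    visited[w] = True
                    queue.append(w)
        comps.append(comp)
    return comps


def log_evidence_quadrature(y, X, g, a0, b0) -> float:
    """Log marginal likelihood by integrating the noise variance numerically.

    Conditional on sigma^2 the coefficients integrate out into a
    multivariate normal with covariance sigma^2 (I + g P_X); the
    remaining 1-D integral over the inverse-gamma prior is evaluated by
    adaptive quadrature on the log scale.
    """
    import math

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    cov_shape = np.eye(n) + g * (X @ np.linalg.inv(X.T @ X) @ X.T)

    def log_f(log_s2):
        # integrand over t = log sigma^2, including the Jacobian term
        s2 = np.exp(log_s2)
        log_norm = stats.multivariate_normal.logpdf(
            y, mean=np.zeros(n), cov=s2 * cov_shape)
        log_ig = (a0 * np.log(b0) - math.lgamma(a0)
                  - (a0 + 1) * log_s2 - b0 / s2)
        return log_norm + log_ig + log_s2

    t_mode = np.log((b0 + 0.5 * y @ y) / (a0 + n / 2 + 1))
    shift = log_f(t_mode)
    val, _ = integrate.quad(lambda t: np.exp(log_f(t) - shift),
                            t_mode - 25, t_mode + 25, limit=400)
    return float(np.log(val) + shift)


def dirichlet_posterior_grid(log_evidences, alpha0=1.0, n_grid=20001):
    """Exact 2-model RFX posterior mean of r by grid integration.

    The population frequency r of model 1 has prior Beta(alpha0, alpha0);
    each subject's model follows r, and the data enter through the
    subject-level evidences.  Returns E[r | data].
    """
    logE = np.asarray(log_evidences, dtype=float)
    r = np.linspace(1e-9, 1 - 1e-9, n_grid)
    log_prior = (alpha0 - 1) * (np.log(r) + np.log1p(-r))
    scaled = logE - logE.max(axis=1, keepdims=True)
    lik = np.exp(scaled)
    log_like = np.sum(
        np.log(r[None, :] * lik[:, 0:1] + (1 - r[None, :]) * lik[:, 1:2]),
        axis=0)
    log_post = log_prior + log_like
    w = np.exp(log_post - log_post.max())
    return float(np.trapezoid(w * r, r) / np.trapezoid(w, r))


def spearman_by_ranks(x, y) -> float:
    """Spearman's rho from the rank formula (Pearson on ranks)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
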