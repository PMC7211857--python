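"""Adaptive Gauss-Hermite quadrature for low-dimensional marginal likelihoods.

Serves as an independent numerical oracle for the Laplace approximation:
the same per-individual joint negative log-likelihood that the Laplace
method approximates around its mode is integrated here on a mode- and
curvature-centred Gauss-Hermite grid, which converges to the exact
marginal as the number of nodes grows (for the 1-3 random effects per
individual used in these growth models, a tensor grid is cheap).
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import logsumexp

__all__ = ["adaptive_gh_marginal_nll"]


def adaptive_gh_marginal_nll(f, mode, hess, nodes_per_dim: int) -> float:
    """Marginal negative log-likelihood ``-log \\int exp(-f(e)) de``.

    Parameters
    ----------
    f : callable mapping an (m, q) array of effect vectors to the (m,)
        joint negative log-likelihood values (must be vectorized).
    mode : (q,) minimizer of f (centre of the adapted grid).
    hess : (q, q) positive-definite Hessian of f at the mode (sets the
        grid scaling and orientation).
    nodes_per_dim : number of Gauss-Hermite nodes per dimension (>= 3).

    For q = 0 the integral is empty and ``f`` evaluated at the (empty)
    mode is returned, which makes the quadrature coincide with the
    Laplace value in the degenerate no-random-effects case.
    """
    mode = np.atleast_1d(np.asarray(mode, dtype=float))
    q = mode.size
    if q == 0:
        return float(f(np.zeros((1, 0)))[0])
    if nodes_per_dim < 3:
        raise ValueError("nodes_per_dim must be >= 3")
    hess = np.atleast_2d(np.asarray(hess, dtype=float))
    if hess.shape != (q, q):
        raise ValueError(f"hess must be ({q}, {q}), got {hess.shape}")
    L = np.linalg.cholesky(hess)  # raises on non-PD

    x1, w1 = hermgauss(nodes_per_dim)
    # tensor grid: nodes (n^q, q), log-weights summed across dimensions
    idx = np.array(list(itertools.product(range(nodes_per_dim), repeat=q)), dtype=int)
    grids = x1[idx]
    logw = np.sum(np.log(w1)[idx], axis=1)

    # substitution e = mode + sqrt(2) * L^{-T} x  =>  |J| = 2^{q/2} / det(L)
    A = np.linalg.solve(L.T, np.eye(q))
    points = mode[None, :] + np.sqrt(2.0) * grids @ A.T
    f0 = float(f(mode[None, :])[0])
    fvals = np.asarray(f(points), dtype=float)
    # integrand exp(x^2) * exp(-(f - f0)); shift by f0 for stability
    log_terms = logw + np.sum(grids**2, axis=1) - (fvals - f0)
    log_integral = (
        -f0 + 0.5 * q * np.log(2.0) - np.sum(np.log(np.diag(L))) + logsumexp(log_terms)
    )
    return float(-log_integral)
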