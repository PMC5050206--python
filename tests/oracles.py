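"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's profiled-likelihood machinery:
the mixed-model oracle maximizes the exact ML log-likelihood of
``u ~ N(X b, sigma_eps^2 I + sigma_line^2 Z Z^T)`` over a dense 2-D grid
of the two variance components (with zoom refinement), solving the fixed
effects by explicit GLS at every grid point.  The grid sweep evaluates
the Gaussian likelihood in the eigenbasis of ``Z Z^T`` (an exact
reformulation, asserted against a direct matrix-inverse evaluation on a
sample of grid points).
"""

from fractions import Fraction
from math import comb

import numpy as np


def _gls_logl_direct(u, X, V):
    """Reference evaluation with explicit inverse and determinant."""
    n = u.size
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    b = np.linalg.pinv(A) @ (X.T @ Vi @ u)
    r = u - X @ b
    sign, logdet = np.linalg.slogdet(V)
    assert sign > 0
    return -0.5 * (n * np.log(2 * np.pi) + logdet + r @ Vi @ r)


def _gls_logl_spectral_batch(ut, Xt, d, sl, se_grid):
    """Log-likelihoods for one sigma_line^2 and a vector of sigma_eps^2.

    V diagonalized: V = Q diag(se + sl*d) Q^T, evaluated in the rotated
    basis for all ``se`` at once; fixed effects by GLS (pinv) per point.
    """
    w = 1.0 / (se_grid[:, None] + sl * d[None, :])  # (S, n)
    A = np.einsum("sn,nk,nj->skj", w, Xt, Xt)
    c = (w * ut[None, :]) @ Xt
    b = np.einsum("skj,sj->sk", np.linalg.pinv(A), c)
    r = ut[None, :] - b @ Xt.T
    logdet = np.sum(np.log(se_grid[:, None] + sl * d[None, :]), axis=1)
    quad = np.sum(w * r * r, axis=1)
    return -0.5 * (ut.size * np.log(2 * np.pi) + logdet + quad)


def lmm_grid_logl(u, line_labels, X=None, n_rounds=8, self_check=True):
    """Max ML log-likelihood over a dense (sigma_line^2, sigma_eps^2) grid.

    The sigma_line^2 axis always includes the 0 boundary; zoom windows
    span +-4 steps of the previous grid (the likelihood can be very flat
    in the variance-ratio direction, so the coarse argmax may sit a few
    steps from the continuous optimum), and whenever the running optimum
    sits at the 0 boundary the full sigma_line^2 range is re-scanned.
    """
    u = np.asarray(u, dtype=float)
    labels = np.asarray(line_labels)
    lines, inv = np.unique(labels, return_inverse=True)
    Z = np.zeros((u.size, lines.size))
    Z[np.arange(u.size), inv] = 1.0
    ZZt = Z @ Z.T
    if X is None:
        X = np.ones((u.size, 1))
    else:
        X = np.asarray(X, dtype=float)
    d, Q = np.linalg.eigh(ZZt)
    ut, Xt = Q.T @ u, Q.T @ X

    var = max(np.var(u), 1e-12)
    lo_l0, hi_l0 = np.log10(var * 1e-8), np.log10(var * 50)
    lo_e0, hi_e0 = np.log10(var * 1e-8), np.log10(var * 50)
    lo_l, hi_l, lo_e, hi_e = lo_l0, hi_l0, lo_e0, hi_e0
    best = (-np.inf, 0.0, var)
    checked = False
    for _ in range(n_rounds):
        sigl = np.concatenate([[0.0], 10.0 ** np.linspace(lo_l, hi_l, 41)])
        sige = 10.0 ** np.linspace(lo_e, hi_e, 41)
        for sl in sigl:
            lls = _gls_logl_spectral_batch(ut, Xt, d, sl, sige)
            j = int(np.argmax(lls))
            if lls[j] > best[0]:
                best = (float(lls[j]), sl, float(sige[j]))
        _, sl, se = best
        if self_check and not checked:
            V = se * np.eye(u.size) + sl * ZZt
            assert abs(_gls_logl_direct(u, X, V) - best[0]) < 1e-8
            checked = True
        step_l = (hi_l - lo_l) / 40.0
        step_e = (hi_e - lo_e) / 40.0
        if sl > 0:
            lo_l, hi_l = np.log10(sl) - 4 * step_l, np.log10(sl) + 4 * step_l
        else:
            lo_l, hi_l = lo_l0, hi_l0  # boundary: keep scanning the full range
        lo_e, hi_e = np.log10(se) - 4 * step_e, np.log10(se) + 4 * step_e
    return best[0]


def hypergeom_tail_exact(N, K, n, k):
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational arithmetic."""
    total = comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, j) * comb(N - K, n - j), total)
    return float(acc)
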