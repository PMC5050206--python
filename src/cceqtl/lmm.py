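"""Maximum-likelihood linear mixed models for founder-dosage association.

Null model:     u_i = mu + beta_{m_i} + eps_i
Genetic model:  u_i = mu + sum_k alpha_k g_{k,m_i} + beta_{m_i} + eps_i

with a per-line random effect beta_m ~ N(0, sigma_line^2) and residual
eps_i ~ N(0, sigma_eps^2).  Both models are fitted by full maximum
likelihood (the likelihood-ratio statistic compares models that differ in
fixed effects, for which REML likelihoods are not comparable).

The likelihood is profiled: for a fixed variance ratio
``lambda = sigma_line^2 / sigma_eps^2`` the covariance is block-diagonal
per line, GLS reduces to a weighted regression of line means with weights
``n_m / (1 + lambda * n_m)``, and ``sigma_eps^2`` has a closed form; the
1-D profile over ``log10(lambda)`` is maximized by bounded search, with
the ``lambda = 0`` boundary checked explicitly.

Because the eight founder probabilities sum to 1 per line, the intercept
is confounded with the founder effects; the design uses the dosage columns
alone (their span contains the intercept), and the fitted coefficients are
reported under the sum-to-zero identification ``sum_k alpha_k = 0`` with
``mu`` absorbing the mean.  The log-likelihood — and hence the LR — is
invariant to this choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cceqtl.genome import N_FOUNDERS

_LOG10_LAMBDA_LO = -6.0
_LOG10_LAMBDA_HI = 6.0
_VAR_FLOOR_REL = 1e-8
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class LmmFit:
    """A fitted mixed model (null or genetic)."""

    log_likelihood: float
    mu_hat: float
    alpha_hat: np.ndarray | None  # (8,) sum-to-zero; None for the null model
    sigma_line2_hat: float
    sigma_eps2_hat: float
    converged: bool = True
    boundary: bool = False
    n_samples: int = 0
    sample_key: tuple = ()


@dataclass
class _LineStats:
    """Per-line sufficient statistics of a trait (permutation-invariant)."""

    line_ids: list
    ubar: np.ndarray  # (L,) per-line means
    nreps: np.ndarray  # (L,) replicate counts
    ssw: float  # total within-line sum of squares
    n: int
    var_u: float
    sample_key: tuple


def line_statistics(u, line_labels) -> _LineStats:
    """Collapse samples to per-line means and within-line scatter.

    These are sufficient for the profiled likelihood of both models, and
    do not change under permutation of line labels against genotypes.
    """
    u = np.asarray(u, dtype=float)
    labels = np.asarray(line_labels)
    if u.shape != labels.shape:
        raise ValueError("u and line_labels must have equal length")
    line_ids, inv = np.unique(labels, return_inverse=True)
    nreps = np.bincount(inv).astype(float)
    sums = np.bincount(inv, weights=u)
    ubar = sums / nreps
    ssw = float(np.sum((u - ubar[inv]) ** 2))
    return _LineStats(
        line_ids=list(line_ids),
        ubar=ubar,
        nreps=nreps,
        ssw=ssw,
        n=u.size,
        var_u=float(np.var(u)),
        sample_key=(u.size, tuple(line_ids), tuple(nreps.astype(int))),
    )


_LAMBDA_GRID = np.concatenate([[0.0], 10.0 ** np.linspace(_LOG10_LAMBDA_LO, _LOG10_LAMBDA_HI, 31)])


def _reduce_design(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full-column-rank reparameterization ``Xr = X @ V_r`` via SVD.

    The founder-probability design is rank-deficient whenever founders
    are indistinguishable on the grid (e.g. a monomorphic interval);
    dropping null singular directions keeps the GLS normal equations
    positive definite for every positive weight vector, without changing
    the column span (and hence the likelihood).
    """
    u_svd, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    r = int(np.sum(s > tol))
    vr = vt[:r].T
    return X @ vr, vr


def _eval_lambda_batch(stats: _LineStats, Xr: np.ndarray, lams: np.ndarray):
    """Profiled log-likelihood, GLS coefficients and sigma^2 per lambda.

    ``Xr`` is a full-column-rank line-level design (L x r).  For each
    variance ratio the GLS solve reduces to weighted least squares of the
    line means with weights ``n_m / (1 + lambda * n_m)``.
    """
    w = stats.nreps[None, :] / (1.0 + lams[:, None] * stats.nreps[None, :])  # (P, L)
    a_mats = np.einsum("pl,lk,lj->pkj", w, Xr, Xr)
    c_vecs = (w * stats.ubar[None, :]) @ Xr
    coefs = np.linalg.solve(a_mats, c_vecs[..., None])[..., 0]  # (P, r)
    resid = stats.ubar[None, :] - coefs @ Xr.T
    rss = stats.ssw + np.einsum("pl,pl->p", w, resid**2)
    sigma2 = rss / stats.n
    floor = _VAR_FLOOR_REL * max(stats.var_u, 1e-300)
    floored = sigma2 < floor
    sigma2 = np.maximum(sigma2, floor)
    logdet = np.sum(np.log1p(lams[:, None] * stats.nreps[None, :]), axis=1)
    logl = -0.5 * stats.n * (_LOG_2PI + np.log(sigma2) + rss / (sigma2 * stats.n)) - 0.5 * logdet
    return logl, coefs, sigma2, floored


def _fit_profiled(stats: _LineStats, X: np.ndarray | None, compute_alpha: bool = True) -> LmmFit:
    if X is None:
        Xr, vr = np.ones((len(stats.ubar), 1)), None
    else:
        Xr, vr = _reduce_design(X)
    balanced = bool(np.all(stats.nreps == stats.nreps[0]))
    closed_form = False
    if balanced and stats.nreps[0] == 1:
        # sigma_line and sigma_eps are confounded when every line has one
        # sample (the profile is flat in lambda); parameterize by total
        # variance with lambda pinned at 0.
        lams = np.array([0.0])
    elif balanced:
        # balanced replicates: every line gets the same GLS weight, so the
        # coefficients are the OLS line-mean fit for *every* lambda and the
        # profile over t = 1/(1 + lambda*m) has a closed-form maximizer
        # t* = L*ssw / ((n-L)*m*rss0)  (boundaries clipped).
        m = float(stats.nreps[0])
        n, L = stats.n, len(stats.ubar)
        coef0 = np.linalg.solve(Xr.T @ Xr, Xr.T @ stats.ubar)
        rss0 = float(np.sum((stats.ubar - Xr @ coef0) ** 2))
        t_min = 1.0 / (1.0 + 10.0**_LOG10_LAMBDA_HI * m)
        if rss0 <= 1e-30 * max(stats.var_u, 1e-300):
            lam_star = 0.0
        else:
            t_star = min(max(L * stats.ssw / ((n - L) * m * rss0), t_min), 1.0)
            lam_star = (1.0 / t_star - 1.0) / m
        lams = np.array([0.0, lam_star])
        closed_form = True
    else:
        lams = _LAMBDA_GRID
    logl, coefs, sigma2, floored = _eval_lambda_batch(stats, Xr, lams)
    best = int(np.argmax(logl))
    # local grid refinement on log10(lambda) around the best positive grid
    # point (lambda = 0 needs none, and the balanced closed form is exact)
    if not closed_form and lams.size > 1 and best > 0:
        span = (_LOG10_LAMBDA_HI - _LOG10_LAMBDA_LO) / 30.0
        center = np.log10(lams[best])
        for _ in range(2):
            grid = 10.0 ** np.linspace(center - span, center + span, 17)
            g_logl, g_coefs, g_sigma2, g_floored = _eval_lambda_batch(stats, Xr, grid)
            gb = int(np.argmax(g_logl))
            if g_logl[gb] >= logl[best]:
                lams, logl, coefs, sigma2, floored, best = grid, g_logl, g_coefs, g_sigma2, g_floored, gb
            center = np.log10(lams[best])
            span /= 8.0
    best_lam = float(lams[best])
    at_bound = best_lam == 0.0 or np.log10(max(best_lam, 1e-300)) >= _LOG10_LAMBDA_HI - 1e-3
    if X is None:
        mu, alpha = float(coefs[best][0]), None
    elif not compute_alpha:
        mu, alpha = np.nan, None
    else:
        # identification: the fitted line-level means determine (mu, alpha)
        # only up to directions confounded with the intercept (and, on
        # rank-deficient designs, founders indistinguishable on the grid);
        # report the minimum-norm sum-to-zero alpha reproducing the fit.
        ghat = Xr @ coefs[best]
        x_centered = X - X.mean(axis=0)
        alpha = np.linalg.lstsq(x_centered, ghat - ghat.mean(), rcond=None)[0]
        mu = float(ghat.mean() - X.mean(axis=0) @ alpha)
    return LmmFit(
        log_likelihood=float(logl[best]),
        mu_hat=mu,
        alpha_hat=alpha,
        sigma_line2_hat=float(best_lam * sigma2[best]),
        sigma_eps2_hat=float(sigma2[best]),
        converged=True,
        boundary=bool(at_bound or floored[best]),
        n_samples=stats.n,
        sample_key=stats.sample_key,
    )


def fit_lmm_null(u, line_labels) -> LmmFit:
    """Fit the null model ``u_i = mu + beta_{m_i} + eps_i`` by ML."""
    stats = line_statistics(u, line_labels)
    if len(stats.line_ids) < 2:
        raise ValueError("the mixed model requires at least 2 lines")
    return _fit_profiled(stats, None)


def fit_lmm_genetic(u, line_labels, dosage_row) -> LmmFit:
    """Fit the genetic model with founder-dosage fixed effects by ML.

    ``dosage_row`` maps each line to its 8 founder probabilities at one
    genome interval: either a mapping line_id -> (8,) vector or an array
    aligned with the sorted unique line labels.
    """
    stats = line_statistics(u, line_labels)
    if len(stats.line_ids) < 2:
        raise ValueError("the mixed model requires at least 2 lines")
    X = _design_for_lines(stats.line_ids, dosage_row)
    return _fit_profiled(stats, X)


def _design_for_lines(line_ids, dosage_row) -> np.ndarray:
    if isinstance(dosage_row, dict):
        missing = [l for l in line_ids if l not in dosage_row]
        if missing:
            raise ValueError(f"dosage row missing lines: {missing}")
        X = np.asarray([dosage_row[l] for l in line_ids], dtype=float)
    else:
        X = np.asarray(dosage_row, dtype=float)
        if X.shape[0] != len(line_ids):
            raise ValueError(
                f"dosage design has {X.shape[0]} rows for {len(line_ids)} lines"
            )
    if X.shape[1] != N_FOUNDERS:
        raise ValueError(f"dosage design must have {N_FOUNDERS} columns")
    return X


def lr_statistic(null_fit: LmmFit, genetic_fit: LmmFit) -> float:
    """Likelihood-ratio statistic ``2 * (logL_genetic - logL_null)``.

    Reported on the 2*delta-log-likelihood scale and clipped at zero (the
    models are nested, so a negative value can only be numerical noise).
    """
    if null_fit.sample_key != genetic_fit.sample_key:
        raise ValueError("fits compare different sample sets")
    return max(0.0, 2.0 * (genetic_fit.log_likelihood - null_fit.log_likelihood))


def scan_statistics(
    stats: _LineStats,
    designs: list[np.ndarray],
    null_fit: LmmFit | None = None,
    compute_alpha: bool = True,
) -> tuple[np.ndarray, list]:
    """LR per design against the shared null, reusing the null fit.

    Internal fast path used by the genome scan and the permutation null;
    equivalent to calling :func:`fit_lmm_genetic` per design.  With
    ``compute_alpha=False`` the per-design founder-effect recovery is
    skipped (the likelihood, and hence the LR, is unaffected).
    """
    if null_fit is None:
        null_fit = _fit_profiled(stats, None)
    lrs = np.empty(len(designs))
    fits = []
    for j, X in enumerate(designs):
        fit = _fit_profiled(stats, X, compute_alpha=compute_alpha)
        lrs[j] = max(0.0, 2.0 * (fit.log_likelihood - null_fit.log_likelihood))
        fits.append(fit)
    return lrs, fits
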