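"""Compositionally-aware genome-genome correlation (SparCC-style).

Read counts carry only relative information, so ordinary correlations on
fractions are distorted by the closure to a constant sum.  The estimator
used here works on log-ratio variances: with fractions x_i, the variation
matrix T_ij = var(log(x_i / x_j)) across samples is free of the closure
effect.  Assuming the underlying (basis) correlations are sparse,

    T_ij = w_i^2 + w_j^2 - 2 rho_ij w_i w_j  ~=  w_i^2 + w_j^2,

so the basis variances w_i^2 solve a linear system in the row sums of T,
and correlations follow as r_ij = (w_i^2 + w_j^2 - T_ij) / (2 w_i w_j),
clipped to [-1, 1].  Pairs whose estimated |r| exceeds an exclusion
threshold visibly violate sparsity and are removed from the system, which
is re-solved for a fixed number of rounds.  Fractions are drawn from a
Dirichlet posterior over the counts and the estimate averaged over a few
resamples.  Significance is assessed with bootstrap pseudo p-values: each
genome's counts are permuted across samples independently (destroying any
dependence while keeping marginals), correlations re-estimated, and
p(i,j) = (1 + #{|r_boot| >= |r_obs|}) / (n_bootstraps + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PhindexError

DEFAULT_ITERATIONS = 20
DEFAULT_EXCLUSION_THRESHOLD = 0.1
DEFAULT_RESAMPLES = 10

_MIN_BASIS_VAR = 1e-8


@dataclass
class CorrelationMatrix:
    correlations: pd.DataFrame
    pvalues: pd.DataFrame | None = None
    n_bootstraps: int = 0


def _variation_matrix(fracs: np.ndarray) -> np.ndarray:
    """T_ij = var(log(x_i / x_j)) over samples; fracs is samples x D."""
    logf = np.log(fracs)
    V = logf.var(axis=0, ddof=1)
    C = np.cov(logf, rowvar=False)
    return V[:, None] + V[None, :] - 2.0 * C


def _solve_basis(T: np.ndarray, included: np.ndarray) -> np.ndarray:
    """Basis variances under sparsity, using only non-excluded pairs.

    For each i: sum over included partners j of T_ij ~= k_i w_i + sum_j w_j,
    with k_i the number of included partners of i.
    """
    D = T.shape[0]
    M = included.astype(float)
    np.fill_diagonal(M, included.sum(axis=1))
    t = (T * included).sum(axis=1)
    try:
        w = np.linalg.solve(M, t)
    except np.linalg.LinAlgError:
        w = np.linalg.lstsq(M, t, rcond=None)[0]
    return np.clip(w, _MIN_BASIS_VAR, None)


def _correlations_from_basis(T: np.ndarray, w: np.ndarray) -> np.ndarray:
    sd = np.sqrt(w)
    r = (w[:, None] + w[None, :] - T) / (2.0 * np.outer(sd, sd))
    return np.clip(r, -1.0, 1.0)


def _estimate_once(
    fracs: np.ndarray, iterations: int, exclusion_threshold: float
) -> np.ndarray:
    T = _variation_matrix(fracs)
    D = T.shape[0]
    included = ~np.eye(D, dtype=bool)
    w = _solve_basis(T, included)
    r = _correlations_from_basis(T, w)
    for _ in range(iterations):
        cand = np.abs(r) * included
        np.fill_diagonal(cand, 0.0)
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        included[i, j] = included[j, i] = False
        # keep every component attached to at least 2 pairs so the system
        # stays well-posed
        if included.sum(axis=1).min() < 2:
            included[i, j] = included[j, i] = True
            break
        w = _solve_basis(T, included)
        r = _correlations_from_basis(T, w)
    np.fill_diagonal(r, 1.0)
    return r


def sparcc_estimate(
    counts: pd.DataFrame,
    iterations: int = DEFAULT_ITERATIONS,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | None = 0,
) -> CorrelationMatrix:
    """Estimate basis correlations from a genome x sample count matrix.

    Fractions are drawn from Dirichlet(counts + 1) per sample and the
    log-ratio-variance estimate averaged over ``n_resamples`` draws;
    strongly correlated pairs (|r| above ``exclusion_threshold``) are
    iteratively excluded from the basis-variance system, up to
    ``iterations`` rounds.  ``n_resamples=0`` skips the Dirichlet draw and
    uses the posterior-mean fractions (counts + 1) / total once, which
    makes the estimate fully deterministic and exactly invariant to sample
    order.
    """
    if counts.shape[0] < 3:
        raise PhindexError("the basis system needs at least 3 genomes")
    if counts.shape[1] < 4:
        raise PhindexError("need at least 4 samples to estimate variances")
    X = counts.to_numpy(dtype=float).T  # samples x D
    if n_resamples == 0:
        smoothed = X + 1.0
        fracs = smoothed / smoothed.sum(axis=1, keepdims=True)
        r = _estimate_once(fracs, iterations, exclusion_threshold)
    else:
        rng = np.random.default_rng(seed)
        acc = np.zeros((counts.shape[0], counts.shape[0]))
        for _ in range(n_resamples):
            fracs = np.stack([rng.dirichlet(row + 1.0) for row in X])
            acc += _estimate_once(fracs, iterations, exclusion_threshold)
        r = acc / n_resamples
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    corr = pd.DataFrame(r, index=counts.index, columns=counts.index)
    return CorrelationMatrix(corr)


def bootstrap_pseudo_p(
    counts: pd.DataFrame,
    observed: CorrelationMatrix,
    n_bootstraps: int = 1000,
    seed: int | None = 0,
    **estimate_kwargs,
) -> CorrelationMatrix:
    """Two-sided bootstrap pseudo p-values for an observed correlation matrix.

    Each bootstrap permutes every genome's counts across samples
    independently and re-estimates correlations; the add-one formula
    p = (1 + #{|r_boot| >= |r_obs|}) / (n_bootstraps + 1) keeps p-values
    strictly positive (minimum 1/(n_bootstraps + 1)).
    """
    if n_bootstraps < 1:
        raise PhindexError("n_bootstraps must be >= 1")
    rng = np.random.default_rng(seed)
    X = counts.to_numpy()
    r_obs = observed.correlations.to_numpy()
    exceed = np.zeros_like(r_obs)
    estimate_kwargs.setdefault("n_resamples", DEFAULT_RESAMPLES)
    for b in range(n_bootstraps):
        perm = np.stack([rng.permutation(row) for row in X])
        boot = pd.DataFrame(perm, index=counts.index, columns=counts.columns)
        r_b = sparcc_estimate(
            boot, seed=int(rng.integers(0, 2**31)), **estimate_kwargs
        ).correlations.to_numpy()
        exceed += np.abs(r_b) >= np.abs(r_obs) - 1e-12
    p = (1.0 + exceed) / (n_bootstraps + 1.0)
    np.fill_diagonal(p, 1.0)
    pvals = pd.DataFrame(p, index=counts.index, columns=counts.index)
    return CorrelationMatrix(observed.correlations, pvals, n_bootstraps)


def correlation_long_table(result: CorrelationMatrix) -> pd.DataFrame:
    """Long-format (g1, g2, r, p) table over unordered genome pairs."""
    ids = list(result.correlations.index)
    rows = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            rows.append(
                (
                    ids[a],
                    ids[b],
                    result.correlations.iat[a, b],
                    result.pvalues.iat[a, b] if result.pvalues is not None else np.nan,
                )
            )
    return pd.DataFrame(rows, columns=["g1", "g2", "r", "p"])
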