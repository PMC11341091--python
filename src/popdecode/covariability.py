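"""Factor-analysis decomposition of stimulus-independent covariance and
its summary metrics.

The spike-count covariance is modeled as Sigma = L L^T + Psi: a low-rank
shared component (neurons covary through R latent factors with loadings
L) plus diagonal private variance Psi. Fits are maximum likelihood (EM,
via scikit-learn); the shared dimensionality R is chosen by
cross-validated log-likelihood, since the in-sample likelihood never
decreases with R. Three scalar summaries describe the fitted model:
loading similarity, percent shared variance and dimensionality; axis
alignment is the absolute cosine similarity of two population vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import FactorAnalysis
from sklearn.model_selection import KFold

logger = logging.getLogger("popdecode")

_PSI_FLOOR = 1e-12


@dataclass
class FAFit:
    """Fitted factor model: Sigma = loadings @ loadings.T + diag(psi)."""

    loadings: np.ndarray  # neurons x R
    psi: np.ndarray       # private variances, length neurons
    mu: np.ndarray        # mean vector
    rank: int
    loglik: float         # mean per-sample training log-likelihood
    label: tuple | None = None

    def __post_init__(self) -> None:
        if np.any(self.psi <= 0):
            raise ValueError("private variances must be strictly positive")

    @property
    def shared_covariance(self) -> np.ndarray:
        return self.loadings @ self.loadings.T

    @property
    def covariance(self) -> np.ndarray:
        return self.shared_covariance + np.diag(self.psi)


def _diag_loglik(x: np.ndarray, mu: np.ndarray, var: np.ndarray) -> float:
    var = np.maximum(var, _PSI_FLOOR)
    return float(np.sum(sps.norm.logpdf(x, loc=mu, scale=np.sqrt(var)),
                        axis=1).mean())


def fit_fa(responses: np.ndarray, rank: int, seed: int = 0,
           max_iter: int = 2000, tol: float = 1e-2,
           label: tuple | None = None) -> FAFit:
    """Maximum-likelihood factor analysis of trials x neurons responses.

    ``rank=0`` fits the pure diagonal (independent-neuron) model in
    closed form. Non-convergence of EM raises with the iteration count.
    """
    x = np.asarray(responses, float)
    if x.ndim != 2:
        raise ValueError("responses must be trials x neurons")
    n_trials, n_neurons = x.shape
    if rank < 0 or rank >= n_neurons:
        raise ValueError("rank must satisfy 0 <= R < n_neurons")
    if n_trials < rank + 2:
        raise ValueError(f"need at least R+2={rank + 2} trials, got {n_trials}")
    mu = x.mean(axis=0)
    if rank == 0:
        var = np.maximum(x.var(axis=0), _PSI_FLOOR)
        return FAFit(loadings=np.zeros((n_neurons, 0)), psi=var, mu=mu,
                     rank=0, loglik=_diag_loglik(x, mu, var), label=label)
    fa = FactorAnalysis(n_components=rank, max_iter=max_iter, tol=tol,
                        random_state=0)
    fa.fit(x)
    if fa.n_iter_ >= max_iter:
        raise RuntimeError(
            f"factor analysis did not converge in {fa.n_iter_} iterations"
        )
    return FAFit(
        loadings=fa.components_.T.copy(),
        psi=np.maximum(fa.noise_variance_, _PSI_FLOOR),
        mu=fa.mean_.copy(),
        rank=rank,
        loglik=float(fa.score(x)),
        label=label,
    )


def _cv_loglik(x: np.ndarray, rank: int, n_folds: int, seed: int) -> float:
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in kf.split(x):
        if rank == 0:
            mu = x[tr].mean(axis=0)
            var = x[tr].var(axis=0)
            scores.append(_diag_loglik(x[te], mu, var))
        else:
            fa = FactorAnalysis(n_components=rank, max_iter=2000,
                                random_state=0)
            fa.fit(x[tr])
            scores.append(float(fa.score(x[te])))
    return float(np.mean(scores))


def select_dimensionality(
    responses: np.ndarray,
    r_max: int,
    n_folds: int = 10,
    seed: int = 0,
    include_zero: bool = False,
) -> tuple[int, dict[int, float]]:
    """Shared dimensionality R* maximizing cross-validated log-likelihood.

    Scans R = 1..r_max (optionally including the independent R=0 model)
    with k-fold cross-validation; ties break toward the smaller R.
    """
    x = np.asarray(responses, float)
    n_trials, n_neurons = x.shape
    if r_max >= n_neurons:
        raise ValueError("r_max must be smaller than the number of neurons")
    if n_trials < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} trials")
    grid = ([0] if include_zero else []) + list(range(1, r_max + 1))
    scores = {r: _cv_loglik(x, r, n_folds, seed) for r in grid}
    best = max(grid, key=lambda r: (scores[r], -r))
    return best, scores


def dominant_factor(fit: FAFit) -> np.ndarray:
    """Unit vector of the factor explaining maximal shared variance.

    Factor models are rotation-invariant, so the factor space is first
    rotated to its canonical (SVD) basis, ordering factors by explained
    shared variance; the leading direction is returned with a
    deterministic sign.
    """
    if fit.rank < 1:
        raise ValueError("dominant factor requires rank >= 1")
    u, s, _ = np.linalg.svd(fit.loadings, full_matrices=False)
    w = u[:, 0]
    i = int(np.argmax(np.abs(w)))
    return w if w[i] > 0 else -w


def loading_similarity(fit: FAFit) -> float:
    """Uniformity of the dominant factor's loading weights, in [0, 1].

    1 - N * Var(w) for the unit-norm dominant loading vector w: 1 when
    every neuron loads identically, 0 when weights are maximally
    dissimilar (e.g. balanced opposite signs).
    """
    w = dominant_factor(fit)
    n = len(w)
    return float(np.clip(1.0 - n * np.var(w), 0.0, 1.0))


def percent_shared_variance(fit: FAFit) -> float:
    """Mean percentage of each neuron's variance explained by the shared
    factors, in [0, 100]."""
    shared = np.diag(fit.shared_covariance)
    total = shared + fit.psi
    return float(100.0 * np.mean(shared / total))


def alignment(axis_u: np.ndarray, axis_v: np.ndarray) -> float:
    """Absolute cosine similarity of two axes: 0 orthogonal, 1 aligned."""
    u = np.asarray(axis_u, float)
    v = np.asarray(axis_v, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("alignment requires nonzero vectors")
    return float(abs(u @ v) / (nu * nv))
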