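"""dDR projection, optimal linear population d-prime, and choice
probability.

Population discriminability of two stimuli is d'^2 = dmu^T Sigma^-1 dmu,
with dmu the mean response difference and Sigma the stimulus-independent
(within-class) covariance. Because the plug-in estimate of this quantity
is badly biased when trials are scarce relative to neurons, activity is
first projected into the two-dimensional dDR space spanned by the signal
axis (normalized dmu) and the noise axis (the dominant eigenvector of the
within-class covariance, orthogonalized against the signal axis); the
decoder is then estimated in that plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .preprocess import CORRECT_OUTCOMES, EvokedResponseSet

logger = logging.getLogger("popdecode")

CATEGORY_OF_PAIR = {
    frozenset({"target", "catch"}): "target_vs_catch",
    frozenset({"target"}): "target_vs_target",
    frozenset({"distractor"}): "distractor_vs_distractor",
}


@dataclass
class DDRSpace:
    """Two-dimensional decoding subspace (signal axis + noise axis)."""

    signal: np.ndarray
    noise: np.ndarray | None

    @property
    def projection(self) -> np.ndarray:
        if self.noise is None:
            return self.signal[None, :]
        return np.vstack([self.signal, self.noise])

    def project(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, float) @ self.projection.T


def _fix_sign(v: np.ndarray) -> np.ndarray:
    # deterministic eigenvector orientation: largest-magnitude element > 0
    i = int(np.argmax(np.abs(v)))
    return v if v[i] > 0 else -v


def residual_covariance(*classes: np.ndarray) -> np.ndarray:
    """Stimulus-independent covariance: per-class mean removed, residuals
    pooled over classes."""
    resid = np.vstack([np.asarray(x, float) - np.asarray(x, float).mean(0)
                       for x in classes])
    return np.cov(resid, rowvar=False, ddof=1)


def fit_ddr(responses_a: np.ndarray, responses_b: np.ndarray,
            tol: float = 1e-8) -> DDRSpace:
    """Fit the dDR space for one stimulus pair.

    ``responses_a``/``responses_b`` are trials x neurons. The signal axis
    is the normalized class-mean difference; the noise axis is the first
    eigenvector of the pooled within-class covariance, Gram-Schmidt
    orthogonalized against the signal axis. If that eigenvector is
    parallel to the signal axis the next one is used; if all are, a
    one-dimensional space is returned with a warning.
    """
    a = np.atleast_2d(np.asarray(responses_a, float))
    b = np.atleast_2d(np.asarray(responses_b, float))
    dmu = a.mean(0) - b.mean(0)
    nrm = float(np.linalg.norm(dmu))
    if nrm < tol:
        raise ValueError("class means are equal: signal axis undefined")
    signal = dmu / nrm
    cov = residual_covariance(a, b)
    evals, evecs = np.linalg.eigh(cov)
    for k in np.argsort(evals)[::-1]:
        e = _fix_sign(evecs[:, k])
        w = e - (e @ signal) * signal
        wn = float(np.linalg.norm(w))
        if wn > 1e-6:
            return DDRSpace(signal=signal, noise=w / wn)
    logger.warning("fit_ddr: all covariance eigenvectors parallel to the "
                   "signal axis; returning a 1-D space")
    return DDRSpace(signal=signal, noise=None)


def dprime_from_stats(dmu: np.ndarray, cov: np.ndarray,
                      ridge: float = 0.0) -> float:
    """d' = sqrt(dmu^T Sigma^-1 dmu) from summary statistics."""
    dmu = np.asarray(dmu, float)
    cov = np.atleast_2d(np.asarray(cov, float))
    if ridge:
        cov = cov + ridge * np.trace(cov) * np.eye(cov.shape[0])
    try:
        sol = np.linalg.solve(cov, dmu)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular covariance in d-prime computation: {err}"
        ) from err
    return float(np.sqrt(max(dmu @ sol, 0.0)))


def population_dprime(space: DDRSpace, responses_a: np.ndarray,
                      responses_b: np.ndarray,
                      ridge: float = 1e-6, debias: bool = True) -> float:
    """Population d' of two stimuli in the fitted dDR space.

    Sigma is the within-class covariance averaged over the two stimuli
    after projection, with a small ridge (ridge x trace) for conditioning.

    With ``debias`` (default) the standard small-sample correction for the
    plug-in Mahalanobis distance is applied,
    D^2 -> (nu - p - 1)/nu * D^2 - p (1/n_a + 1/n_b) with nu = n_a + n_b - 2
    and p the subspace dimension. The plug-in estimate inflates with
    shrinking trial counts, and because correct active trials are scarcer
    than passive presentations the inflation is state- and
    category-dependent; the correction removes that trial-count artifact.
    It is negligible when trials are plentiful.
    """
    pa = space.project(responses_a)
    pb = space.project(responses_b)
    dmu = pa.mean(0) - pb.mean(0)
    cov = np.atleast_2d(0.5 * (np.cov(pa, rowvar=False, ddof=1)
                               + np.cov(pb, rowvar=False, ddof=1)))
    d2 = dprime_from_stats(dmu, cov, ridge=ridge) ** 2
    if debias:
        p = cov.shape[0]
        na, nb = len(pa), len(pb)
        nu = na + nb - 2
        if nu > p + 1:
            d2 = (nu - p - 1) / nu * d2 - p * (1.0 / na + 1.0 / nb)
    return float(np.sqrt(max(d2, 0.0)))


def plugin_dprime(responses_a: np.ndarray, responses_b: np.ndarray,
                  ridge: float = 1e-6) -> float:
    """Naive full-space plug-in d' (same ridge convention as the decoder).

    Provided as the overfitting-prone baseline that motivates dDR: when
    trials are scarce relative to neurons the pooled covariance is (near)
    singular, its inversion is dominated by poorly estimated directions,
    and the in-sample estimate grossly overstates discriminability.
    """
    a = np.asarray(responses_a, float)
    b = np.asarray(responses_b, float)
    dmu = a.mean(0) - b.mean(0)
    cov = residual_covariance(a, b)
    return dprime_from_stats(dmu, cov, ridge=ridge)


@dataclass
class DecodingResult:
    stim_a: str
    stim_b: str
    category: str
    dprime_active: float
    dprime_passive: float

    @property
    def delta(self) -> float:
        return self.dprime_active - self.dprime_passive

    @property
    def delta_norm(self) -> float:
        s = self.dprime_active + self.dprime_passive
        return self.delta / s if s > 0 else 0.0


def results_frame(results: list[DecodingResult], **extra) -> pd.DataFrame:
    rows = [{
        "stim_a": r.stim_a, "stim_b": r.stim_b, "category": r.category,
        "dprime_active": r.dprime_active, "dprime_passive": r.dprime_passive,
        "delta": r.delta, "delta_norm": r.delta_norm, **extra,
    } for r in results]
    return pd.DataFrame(rows)


def qualifying_pairs(events: pd.DataFrame) -> list[tuple[str, str, str]]:
    """Stimulus pairs in the analyzed categories (reminders excluded)."""
    ev = events[~events["reminder"].astype(bool)]
    cat = dict(ev.groupby("stimulus")["category"].first())
    pairs = []
    for sa, sb in combinations(sorted(cat), 2):
        key = frozenset({cat[sa], cat[sb]})
        label = CATEGORY_OF_PAIR.get(key)
        if label is None:
            continue
        if label == "target_vs_catch" and cat[sa] == "catch":
            sa, sb = sb, sa  # target listed first
        pairs.append((sa, sb, label))
    return pairs


def class_matrix(responses: EvokedResponseSet, stimulus: str,
                 state: str) -> np.ndarray:
    """Trials x neurons matrix for stimulus decoding.

    Active responses are restricted to correct trials (hits and correct
    rejects); passive blocks have no outcome so all presentations count.
    """
    outcomes = CORRECT_OUTCOMES if state == "active" else None
    return responses.matrix(stimulus, state, outcomes)


def pairwise_decoding(
    responses: EvokedResponseSet,
    min_trials: int = 5,
    ridge: float = 1e-6,
) -> list[DecodingResult]:
    """dDR decoding of every qualifying stimulus pair, per state.

    The dDR fit and decoder are recomputed per pair and per state. A pair
    qualifies only if each stimulus has at least ``min_trials`` usable
    presentations in both states.
    """
    results = []
    for sa, sb, label in qualifying_pairs(responses.events):
        mats = {
            state: (class_matrix(responses, sa, state),
                    class_matrix(responses, sb, state))
            for state in ("active", "passive")
        }
        if any(len(m) < min_trials for pair in mats.values() for m in pair):
            logger.info("pairwise_decoding: skipping %s vs %s "
                        "(fewer than %d trials)", sa, sb, min_trials)
            continue
        dprimes = {}
        for state, (a, b) in mats.items():
            space = fit_ddr(a, b)
            dprimes[state] = population_dprime(space, a, b, ridge=ridge)
        results.append(DecodingResult(
            stim_a=sa, stim_b=sb, category=label,
            dprime_active=dprimes["active"],
            dprime_passive=dprimes["passive"],
        ))
    if not results:
        logger.warning("pairwise_decoding: no qualifying stimulus pairs")
    return results


def category_summary(results: pd.DataFrame | list[DecodingResult],
                     column: str = "delta_norm") -> pd.Series:
    """Session-level mean of a decoding metric per category.

    This is the unit entering cross-session tests: one value per category
    per session, the mean over that category's stimulus pairs.
    """
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    if not len(df):
        raise ValueError("no decoding results to summarize")
    return df.groupby("category")[column].mean()


def choice_probability(responses_hit: np.ndarray, responses_miss: np.ndarray,
                       min_trials: int = 5, ridge: float = 1e-6) -> float:
    """Leave-one-out percent-correct decoding of hit vs miss trials.

    Within each fold the dDR axes, the optimal discrimination axis
    (Sigma^-1 dmu in the plane) and the midpoint threshold are fitted on
    training trials only; the held-out trial is classified by its
    projection. Returns percent correct in [0, 100].
    """
    a = np.asarray(responses_hit, float)
    b = np.asarray(responses_miss, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both outcome classes must be non-empty")
    if len(a) < min_trials or len(b) < min_trials:
        raise ValueError(f"need at least {min_trials} trials per class")
    labels = np.r_[np.zeros(len(a), int), np.ones(len(b), int)]
    X = np.vstack([a, b])
    correct = 0
    for i in range(len(X)):
        keep = np.arange(len(X)) != i
        Xa = X[keep][labels[keep] == 0]
        Xb = X[keep][labels[keep] == 1]
        space = fit_ddr(Xa, Xb)
        pa, pb = space.project(Xa), space.project(Xb)
        cov = np.atleast_2d(0.5 * (np.cov(pa, rowvar=False, ddof=1)
                                   + np.cov(pb, rowvar=False, ddof=1)))
        cov = cov + ridge * np.trace(cov) * np.eye(cov.shape[0])
        w = np.linalg.solve(cov, pa.mean(0) - pb.mean(0))
        thr = float(w @ (pa.mean(0) + pb.mean(0)) / 2.0)
        score = float(w @ space.project(X[i][None, :])[0]) - thr
        predicted = 0 if score > 0 else 1
        correct += int(predicted == labels[i])
    return 100.0 * correct / len(X)
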