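"""Session-level hypothesis tests and the neural-behavioral correlation.

Every test operates on session-level values (one number per recording
session, typically the mean over stimulus pairs), which keeps the tests
conservative in the presence of within-session dependencies. All
resampling is seed-deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps

logger = logging.getLogger("popdecode")


@dataclass
class TestResult:
    name: str
    statistic: float
    pvalue: float
    n: int
    alpha: float = 0.05
    significant: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.pvalue <= 1):
            raise ValueError("p-value outside [0, 1]")


def paired_wilcoxon(session_means_a: np.ndarray, session_means_b: np.ndarray,
                    alpha: float = 0.05,
                    name: str = "wilcoxon_signed_rank") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired session means.

    Fewer than 5 pairs yields a result flagged ``underpowered``; ties
    everywhere (identical vectors) give p = 1.
    """
    a = np.asarray(session_means_a, float)
    b = np.asarray(session_means_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-D vectors")
    note = "" if len(a) >= 5 else "underpowered"
    diff = a - b
    if np.all(diff == 0):
        return TestResult(name=name, statistic=0.0, pvalue=1.0, n=len(a),
                          alpha=alpha, significant=False,
                          note=(note + " all differences zero").strip())
    stat, p = sps.wilcoxon(a, b, alternative="two-sided")
    return TestResult(name=name, statistic=float(stat), pvalue=float(p),
                      n=len(a), alpha=alpha,
                      significant=bool(p < alpha), note=note)


def bootstrap_ci(values: np.ndarray,
                 statistic: Callable[[np.ndarray], float] = np.mean,
                 n_boot: int = 1000, seed: int = 0,
                 level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of a statistic."""
    x = np.asarray(values, float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    rng = np.random.default_rng(seed)
    boots = np.array([
        statistic(x[rng.integers(len(x), size=len(x))])
        for _ in range(n_boot)
    ])
    lo = (1 - level) / 2
    return (float(np.quantile(boots, lo)),
            float(np.quantile(boots, 1 - lo)))


@dataclass
class CorrelationResult:
    r: float
    ci: tuple[float, float]
    null_quantile_975: float
    significant: bool
    pvalue: float
    n: int


def neural_behavior_correlation(
    delta_dprimes: np.ndarray,
    behavioral_dprimes: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson correlation between neural Δd' and behavioral d' across
    (session, target) pairs, with a shuffled-pairing null.

    Significance is one-sided: the observed r must exceed the 97.5th
    percentile of the null distribution built by randomly re-pairing the
    two vectors. A percentile bootstrap 95% CI on r (resampling pairs)
    is also returned.
    """
    x = np.asarray(delta_dprimes, float)
    y = np.asarray(behavioral_dprimes, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired vectors of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(sps.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    perms = np.array([rng.permutation(n) for _ in range(n_boot)])
    null = yc[perms] @ xc / denom
    q = float(np.quantile(null, 0.975))
    pvalue = float((np.sum(null >= r) + 1) / (n_boot + 1))
    sel = rng.integers(n, size=(n_boot, n))
    xs, ys = x[sel], y[sel]
    xsc = xs - xs.mean(axis=1, keepdims=True)
    ysc = ys - ys.mean(axis=1, keepdims=True)
    bden = np.sqrt((xsc ** 2).sum(axis=1) * (ysc ** 2).sum(axis=1))
    boots = np.divide((xsc * ysc).sum(axis=1), bden,
                      out=np.zeros(n_boot), where=bden > 0)
    ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
    return CorrelationResult(r=r, ci=ci, null_quantile_975=q,
                             significant=bool(r > q), pvalue=pvalue,
                             n=len(x))
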