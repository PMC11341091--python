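"""Four-model Gaussian ablation: which state-dependent parameters explain
the engagement change in decoding?

Population responses to each target and catch stimulus are regenerated
from per-stimulus, per-state factor-analysis fits, N(mu, Sigma_shared +
Psi), with a ladder of models that tie progressively fewer parameters to
the active-state estimates:

* ``null``        — mean, private and shared variance all fixed to the
                    active estimates: states statistically identical.
* ``gain_only``   — only the mean follows the state (response gain);
                    variances fixed to active.
* ``indep_var``   — mean and private variance follow the state; shared
                    covariance fixed to active.
* ``shared_var``  — all parameters follow the state (the full model).

Simulated responses feed the identical dDR decoding pipeline as real
data, so differences in how well each model reproduces the measured
selective enhancement isolate the contribution of gain, private variance
and shared covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import decoding
from .covariability import FAFit, fit_fa, select_dimensionality
from .preprocess import EvokedResponseSet

logger = logging.getLogger("popdecode")

MODELS = ("null", "gain_only", "indep_var", "shared_var")
STATES = ("active", "passive")


@dataclass
class SimSpec:
    """One ablation run: which model, how many samples, which seed."""

    model: str
    n_samples: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")


def fit_condition_params(
    responses: EvokedResponseSet,
    stimuli: list[str] | None = None,
    r_max: int = 3,
    n_folds: int = 5,
    seed: int = 0,
    min_trials: int = 5,
) -> dict[tuple[str, str], FAFit]:
    """Per-stimulus, per-state factor fits feeding the simulations.

    The rank is selected once per (stimulus, state) by cross-validated
    log-likelihood and reused across all four models. Stimuli defaults to
    every target plus the catch stimulus; active responses are restricted
    to correct trials, matching the decoding pipeline.
    """
    ev = responses.events
    if stimuli is None:
        stimuli = sorted(ev.loc[ev["category"] == "target", "stimulus"]
                         .unique()) + ["catch"]
    params: dict[tuple[str, str], FAFit] = {}
    for stim in stimuli:
        for state in STATES:
            x = decoding.class_matrix(responses, stim, state)
            if len(x) < max(min_trials, n_folds):
                logger.info("fit_condition_params: skipping %s/%s with %d "
                            "trials", stim, state, len(x))
                continue
            r_hi = min(r_max, x.shape[1] - 1, len(x) - 2)
            rank, _ = select_dimensionality(x, r_hi, n_folds=n_folds,
                                            seed=seed)
            params[(stim, state)] = fit_fa(x, rank, seed=seed,
                                           label=(stim, state))
    # a stimulus enters the ablation only with fits for both states,
    # mirroring the decoding inclusion rule
    for stim in {s for s, _ in params}:
        if not all((stim, state) in params for state in STATES):
            logger.info("fit_condition_params: dropping %s (missing one "
                        "state)", stim)
            for state in STATES:
                params.pop((stim, state), None)
    return params


def model_params(
    params: dict[tuple[str, str], FAFit],
    stimulus: str,
    model: str,
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-state (mu, loadings, psi) triple the model draws from.

    The active state always uses the active estimates; the model name
    determines which passive parameters are tied to them.
    """
    try:
        act = params[(stimulus, "active")]
        pas = params[(stimulus, "passive")]
    except KeyError as err:
        raise ValueError(
            f"missing factor-analysis fit for stimulus {stimulus!r}: {err}"
        ) from err
    table = {
        "null":       (act.mu, act.loadings, act.psi),
        "gain_only":  (pas.mu, act.loadings, act.psi),
        "indep_var":  (pas.mu, act.loadings, pas.psi),
        "shared_var": (pas.mu, pas.loadings, pas.psi),
    }
    if model not in table:
        raise ValueError(f"model must be one of {MODELS}")
    return {"active": (act.mu, act.loadings, act.psi),
            "passive": table[model]}


def simulate_population(
    spec: SimSpec,
    params: dict[tuple[str, str], FAFit],
    stimuli: list[str] | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """Draw ``n_samples`` Gaussian responses per (stimulus, state).

    Samples are x = mu + L z + sqrt(psi) eps with z, eps standard normal,
    so the population covariance is exactly L L^T + diag(psi).
    """
    if stimuli is None:
        stimuli = sorted({s for s, _ in params})
    rng = np.random.default_rng(spec.seed)
    out: dict[tuple[str, str], np.ndarray] = {}
    for stim in stimuli:
        per_state = model_params(params, stim, spec.model)
        for state in STATES:
            mu, loadings, psi = per_state[state]
            n_neurons = len(mu)
            z = rng.standard_normal((spec.n_samples, loadings.shape[1]))
            eps = rng.standard_normal((spec.n_samples, n_neurons))
            out[(stim, state)] = mu + z @ loadings.T + np.sqrt(psi) * eps
    return out


def decode_simulated(
    samples: dict[tuple[str, str], np.ndarray],
    ridge: float = 1e-6,
) -> list[decoding.DecodingResult]:
    """Run the standard dDR decoding on simulated target/catch responses."""
    stimuli = sorted({s for s, _ in samples})
    results = []
    for sa, sb in combinations(stimuli, 2):
        cats = {("catch" if s == "catch" else "target") for s in (sa, sb)}
        label = decoding.CATEGORY_OF_PAIR.get(frozenset(cats))
        if label is None:
            continue
        if label == "target_vs_catch" and sa == "catch":
            sa, sb = sb, sa
        dprimes = {}
        for state in STATES:
            a, b = samples[(sa, state)], samples[(sb, state)]
            space = decoding.fit_ddr(a, b)
            dprimes[state] = decoding.population_dprime(space, a, b,
                                                        ridge=ridge)
        results.append(decoding.DecodingResult(
            stim_a=sa, stim_b=sb, category=label,
            dprime_active=dprimes["active"],
            dprime_passive=dprimes["passive"],
        ))
    return results


def selective_enhancement(
    results: list[decoding.DecodingResult] | pd.DataFrame,
    normalized: bool = True,
) -> float:
    """Δd'(target vs catch) minus Δd'(target vs target) for one session.

    Category means are taken over stimulus pairs; by default the
    sum-normalized Δd' is used (the engagement change scaled to [-1, 1]),
    with ``normalized=False`` giving the raw difference in z-units.
    """
    column = "delta_norm" if normalized else "delta"
    summary = decoding.category_summary(results, column=column)
    for cat in ("target_vs_catch", "target_vs_target"):
        if cat not in summary.index:
            raise ValueError(f"selective enhancement undefined: no "
                             f"{cat} pairs in session")
    return float(summary["target_vs_catch"] - summary["target_vs_target"])


def run_ablation(
    responses: EvokedResponseSet,
    n_samples: int = 2000,
    seed: int = 0,
    r_max: int = 3,
    n_folds: int = 5,
    normalized: bool = True,
    params: dict[tuple[str, str], FAFit] | None = None,
) -> dict[str, float]:
    """Simulated selective enhancement of one session under all four
    models (sharing one set of per-condition factor fits)."""
    if params is None:
        params = fit_condition_params(responses, r_max=r_max,
                                      n_folds=n_folds, seed=seed)
    out = {}
    for model in MODELS:
        spec = SimSpec(model=model, n_samples=n_samples, seed=seed)
        sims = simulate_population(spec, params)
        out[model] = selective_enhancement(decode_simulated(sims),
                                           normalized=normalized)
    return out


def fit_choice_params(
    responses: EvokedResponseSet,
    target: str,
    r_max: int = 3,
    n_folds: int = 5,
    seed: int = 0,
    min_trials: int = 5,
) -> dict[tuple[str, str], FAFit]:
    """Hit/miss-conditioned factor fits for the choice ablation.

    Hit trials play the role of the anchor condition (the one whose
    estimates the ablation ties to, like the active state in the
    stimulus analysis) and miss trials the varied one.
    """
    out: dict[tuple[str, str], FAFit] = {}
    for outcome, slot in (("hit", "active"), ("miss", "passive")):
        x = responses.matrix(target, "active", outcomes=(outcome,))
        if len(x) < max(min_trials, n_folds):
            raise ValueError(
                f"need at least {max(min_trials, n_folds)} {outcome} trials "
                f"for {target!r}, got {len(x)}"
            )
        r_hi = min(r_max, x.shape[1] - 1, len(x) - 2)
        rank, _ = select_dimensionality(x, r_hi, n_folds=n_folds, seed=seed)
        out[(target, slot)] = fit_fa(x, rank, seed=seed,
                                     label=(target, outcome))
    return out


def choice_ablation(
    responses: EvokedResponseSet,
    target: str,
    n_samples: int = 2000,
    seed: int = 0,
    r_max: int = 3,
    n_folds: int = 5,
) -> dict[str, float]:
    """Choice information (hit vs miss d') under the four ablation
    models for one target stimulus.

    The null model predicts no choice information; a gain-only model
    carrying the hit/miss mean difference recovers it.
    """
    params = fit_choice_params(responses, target, r_max=r_max,
                               n_folds=n_folds, seed=seed)
    out = {}
    for model in MODELS:
        sims = simulate_population(
            SimSpec(model=model, n_samples=n_samples, seed=seed), params,
            stimuli=[target],
        )
        a, b = sims[(target, "active")], sims[(target, "passive")]
        try:
            space = decoding.fit_ddr(a, b)
            out[model] = decoding.population_dprime(space, a, b)
        except ValueError:
            out[model] = 0.0  # identical class means (null model draw)
    return out


def model_performance(simulated: np.ndarray, actual: np.ndarray) -> float:
    """Pearson correlation between simulated and actual per-session
    selective enhancement."""
    sim = np.asarray(simulated, float)
    act = np.asarray(actual, float)
    if len(sim) != len(act) or len(sim) < 3:
        raise ValueError("need >= 3 paired session values")
    return float(sps.pearsonr(sim, act).statistic)


@dataclass
class ModelComparison:
    model: str
    r: float
    boot_quantile_975: float
    significantly_worse: bool
    boot: np.ndarray = field(repr=False)


def model_comparison(
    simulated_by_model: dict[str, np.ndarray],
    actual: np.ndarray,
    full_model: str = "shared_var",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, ModelComparison]:
    """Bootstrap test of each model against the full model.

    For each model, sessions are resampled with replacement ``n_boot``
    times to build a distribution of its correlation with the actual
    values; a model is flagged significantly worse than the full model if
    the 97.5th percentile of its bootstrap distribution falls below the
    full model's observed correlation.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    actual = np.asarray(actual, float)
    r_full = model_performance(simulated_by_model[full_model], actual)
    rng = np.random.default_rng(seed)
    out: dict[str, ModelComparison] = {}
    n = len(actual)
    for model, sim in simulated_by_model.items():
        sim = np.asarray(sim, float)
        r_obs = model_performance(sim, actual)
        boot = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(n, size=n)
            sa, aa = sim[idx], actual[idx]
            if np.std(sa) == 0 or np.std(aa) == 0:
                boot[i] = 0.0
            else:
                boot[i] = sps.pearsonr(sa, aa).statistic
        q = float(np.quantile(boot, 0.975))
        out[model] = ModelComparison(
            model=model, r=r_obs, boot_quantile_975=q,
            significantly_worse=bool(q < r_full), boot=boot,
        )
    return out
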