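"""Ablation model construction, sampling fidelity and model scoring."""

from __future__ import annotations

import numpy as np
import pytest

import popdecode as pk
from popdecode.covariability import FAFit
from popdecode.simulation import (MODELS, SimSpec, model_params,
                                  simulate_population)


def _params(n=12, seed=0, mu_shift=1.0, psi_scale=1.0, rotate=0.0):
    """Per-state factor fits for one stimulus pair with controllable
    state differences."""
    rng = np.random.default_rng(seed)
    out = {}
    for stim in ("target_infdB", "catch"):
        mu_p = rng.uniform(2, 6, n)
        load_p = rng.standard_normal((n, 1))
        psi_p = rng.uniform(0.5, 1.5, n)
        mu_a = mu_p + (mu_shift if stim.startswith("target") else 0.0)
        load_a = load_p.copy()
        if rotate:
            direction = np.ones(n) / np.sqrt(n)
            load_a = ((1 - rotate) * load_p
                      + rotate * direction[:, None]
                      * np.linalg.norm(load_p))
        out[(stim, "passive")] = FAFit(loadings=load_p, psi=psi_p, mu=mu_p,
                                       rank=1, loglik=0.0)
        out[(stim, "active")] = FAFit(loadings=load_a,
                                      psi=psi_scale * psi_p, mu=mu_a,
                                      rank=1, loglik=0.0)
    return out


def test_ablation_parameter_tying_is_exact():
    """Each model ties exactly the documented parameters across states,
    bitwise."""
    params = _params(mu_shift=1.0, psi_scale=0.7, rotate=0.4)
    act = params[("target_infdB", "active")]
    pas = params[("target_infdB", "passive")]
    got = {m: model_params(params, "target_infdB", m) for m in MODELS}
    for m in MODELS:  # active side always uses active estimates
        mu, load, psi = got[m]["active"]
        assert mu is act.mu and load is act.loadings and psi is act.psi
    mu, load, psi = got["null"]["passive"]
    assert mu is act.mu and load is act.loadings and psi is act.psi
    mu, load, psi = got["gain_only"]["passive"]
    assert mu is pas.mu and load is act.loadings and psi is act.psi
    mu, load, psi = got["indep_var"]["passive"]
    assert mu is pas.mu and load is act.loadings and psi is pas.psi
    mu, load, psi = got["shared_var"]["passive"]
    assert mu is pas.mu and load is pas.loadings and psi is pas.psi


def test_missing_fit_names_stimulus():
    params = _params()
    del params[("catch", "passive")]
    with pytest.raises(ValueError, match="catch"):
        model_params(params, "catch", "null")


def test_null_model_states_statistically_identical():
    params = _params(mu_shift=2.0)
    sims = simulate_population(SimSpec("null", n_samples=2000, seed=1),
                               params)
    a = sims[("target_infdB", "active")]
    p = sims[("target_infdB", "passive")]
    se = a.std(0) / np.sqrt(len(a))
    assert np.all(np.abs(a.mean(0) - p.mean(0)) < 3 * np.sqrt(2) * se)


def test_gain_only_reduces_to_null_when_means_match():
    params = _params(mu_shift=0.0, psi_scale=0.7)
    # force exact mean equality
    for stim in ("target_infdB", "catch"):
        params[(stim, "passive")].mu = params[(stim, "active")].mu
    s_null = simulate_population(SimSpec("null", 500, seed=3), params)
    s_gain = simulate_population(SimSpec("gain_only", 500, seed=3), params)
    for key in s_null:
        assert np.array_equal(s_null[key], s_gain[key])


def test_sample_covariance_matches_generator():
    params = _params(seed=5)
    sims = simulate_population(SimSpec("shared_var", 2000, seed=5), params)
    for state in ("active", "passive"):
        fit = params[("catch", state)]
        target = fit.covariance
        got = np.cov(sims[("catch", state)], rowvar=False)
        frob = np.linalg.norm(got - target) / np.linalg.norm(target)
        assert frob < 0.10


def test_selective_enhancement_arithmetic():
    results = [
        pk.DecodingResult("t1", "catch", "target_vs_catch", 1.4, 1.0),
        pk.DecodingResult("t1", "t2", "target_vs_target", 1.1, 1.0),
    ]
    se = pk.selective_enhancement(results, normalized=False)
    assert se == pytest.approx(0.4 - 0.1)
    with pytest.raises(ValueError, match="target_vs_target"):
        pk.selective_enhancement(results[:1])


def test_model_performance_and_comparison():
    x = np.array([0.1, 0.3, 0.2, 0.5, 0.4, 0.25, 0.35, 0.15, 0.45, 0.05,
                  0.55, 0.6])
    assert pk.model_performance(x, x) == pytest.approx(1.0)
    assert pk.model_performance(-x, x) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        pk.model_performance(x[:2], x[:2])
    rng = np.random.default_rng(0)
    flat = 0.02 * rng.standard_normal(len(x))
    comp = pk.model_comparison({"shared_var": x, "gain_only": x,
                                "null": flat}, x, n_boot=500, seed=0)
    assert not comp["shared_var"].significantly_worse
    assert not comp["gain_only"].significantly_worse
    assert comp["null"].significantly_worse
    with pytest.raises(ValueError, match="n_boot"):
        pk.model_comparison({"shared_var": x}, x, n_boot=0)


def _analytic_delta(per_state):
    """Analytic normalized engagement change of target-vs-catch d' for a
    pair of per-state (mu, L, psi) Gaussians."""
    d = {}
    for state, (pa, pb) in per_state.items():
        dmu = pa[0] - pb[0]
        cov = 0.5 * (pa[1] @ pa[1].T + np.diag(pa[2])
                     + pb[1] @ pb[1].T + np.diag(pb[2]))
        d[state] = np.sqrt(dmu @ np.linalg.solve(cov, dmu))
    return (d["active"] - d["passive"]) / (d["active"] + d["passive"])


def test_model_ladder_converges_to_truth():
    """As models progressively match state-dependent parameters (gain ->
    private variance -> shared covariance), the predicted engagement
    change approaches the generating truth monotonically."""
    params = _params(n=15, seed=7, mu_shift=1.5, psi_scale=0.6, rotate=0.5)

    def per_state(model):
        mp = {s: model_params(params, s, model)
              for s in ("target_infdB", "catch")}
        return {state: (mp["target_infdB"][state], mp["catch"][state])
                for state in ("active", "passive")}

    truth = _analytic_delta(per_state("shared_var"))
    errs = {m: abs(_analytic_delta(per_state(m)) - truth)
            for m in MODELS}
    assert errs["shared_var"] == pytest.approx(0.0, abs=1e-12)
    assert errs["indep_var"] <= errs["gain_only"] + 1e-12
    assert errs["gain_only"] <= errs["null"] + 1e-12


def test_choice_ablation_recovers_outcome_gap():
    """Hit trials shifted from miss trials: the null model predicts no
    choice information while models carrying the hit/miss means do."""
    import pandas as pd

    rng = np.random.default_rng(11)
    n_neurons, n_per = 10, 40
    gap = np.zeros(n_neurons)
    gap[:4] = 1.5
    resp = rng.standard_normal((n_neurons, 2 * n_per))
    resp[:, :n_per] += gap[:, None]
    events = pd.DataFrame({
        "trial": np.arange(2 * n_per), "state": "active",
        "stimulus": "target_infdB", "category": "target",
        "snr_db": np.inf, "onset_s": np.arange(2 * n_per) * 2.0,
        "outcome": ["hit"] * n_per + ["miss"] * n_per, "reminder": False,
    })
    ers = pk.EvokedResponseSet(
        responses=resp, events=events, z_mean=np.zeros(n_neurons),
        z_sd=np.ones(n_neurons), neuron_ids=np.arange(n_neurons))
    res = pk.choice_ablation(ers, "target_infdB", n_samples=1000, seed=0)
    assert res["null"] < 0.3
    for model in ("gain_only", "indep_var", "shared_var"):
        assert res[model] > 1.0


def test_simspec_validation():
    with pytest.raises(ValueError, match="model"):
        SimSpec("bogus")
    with pytest.raises(ValueError, match="n_samples"):
        SimSpec("null", n_samples=1)
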