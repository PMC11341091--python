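"""dDR geometry, population d', pair combinatorics, choice decoding."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import popdecode as pk
from popdecode.decoding import qualifying_pairs


def _classes_with_noise(dmu, e1_dir, n=400, seed=0):
    """Two classes with mean difference dmu and residual variance
    dominated by e1_dir."""
    rng = np.random.default_rng(seed)
    dim = len(dmu)
    e1 = np.asarray(e1_dir, float)
    e1 /= np.linalg.norm(e1)
    resid = (rng.standard_normal((n, 1)) * 3.0) @ e1[None, :] \
        + 0.05 * rng.standard_normal((n, dim))
    a = np.asarray(dmu, float) + resid
    b = resid.copy()
    return a, b


def test_fit_ddr_orthogonal_axes_kept():
    a, b = _classes_with_noise([1.0, 0.0, 0.0], [0.0, 1.0, 0.0])
    space = pk.fit_ddr(a, b)
    assert np.allclose(space.signal, [1, 0, 0], atol=0.02)
    assert np.allclose(np.abs(space.noise), [0, 1, 0], atol=0.02)
    assert abs(space.signal @ space.noise) < 1e-8


def test_fit_ddr_gram_schmidt_oracle():
    """Signal (1,0) with dominant covariance along (1,1)/sqrt(2): the
    orthogonalized noise axis is (0,1), by hand Gram-Schmidt."""
    a, b = _classes_with_noise([1.0, 0.0], [1.0, 1.0])
    space = pk.fit_ddr(a, b)
    assert np.allclose(space.signal, [1, 0], atol=0.02)
    assert np.allclose(np.abs(space.noise), [0, 1], atol=0.03)


def test_fit_ddr_degenerate_means_error():
    x = np.random.default_rng(0).standard_normal((20, 4))
    with pytest.raises(ValueError, match="signal axis undefined"):
        pk.fit_ddr(x, x)


@pytest.mark.parametrize("dmu, cov, expected", [
    ([1.0, 0.0], np.eye(2), 1.0),
    ([1.0, 1.0], np.eye(2), np.sqrt(2)),
    ([1.0, 0.0], np.diag([4.0, 1.0]), 0.5),
])
def test_dprime_closed_forms(dmu, cov, expected):
    assert pk.dprime_from_stats(np.array(dmu), cov) == pytest.approx(
        expected, abs=1e-12)


def test_population_dprime_invariant_to_linear_transform():
    """d' is preserved under an invertible linear transform applied to
    both classes (checked via a random rotation at large n, 10% tol)."""
    rng = np.random.default_rng(3)
    dim = 8
    cov = np.diag(rng.uniform(0.5, 2.0, dim))
    dmu = rng.standard_normal(dim)
    chol = np.linalg.cholesky(cov)
    a = dmu + rng.standard_normal((5000, dim)) @ chol.T
    b = rng.standard_normal((5000, dim)) @ chol.T
    d0 = pk.population_dprime(pk.fit_ddr(a, b), a, b)
    q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    aq, bq = a @ q.T, b @ q.T
    d1 = pk.population_dprime(pk.fit_ddr(aq, bq), aq, bq)
    assert abs(d1 / d0 - 1) < 0.10


def test_ddr_never_beats_full_space_analytic():
    """Projection cannot create information: dDR d' stays at or below
    the full-space analytic value (anisotropic private noise, so the
    2-D plane is strictly suboptimal)."""
    rng = np.random.default_rng(5)
    dim = 12
    psi = rng.uniform(0.2, 3.0, dim)
    w = rng.standard_normal(dim)
    cov = np.diag(psi) + np.outer(w, w)
    dmu = rng.standard_normal(dim)
    analytic = np.sqrt(dmu @ np.linalg.solve(cov, dmu))
    chol = np.linalg.cholesky(cov)
    a = dmu + rng.standard_normal((5000, dim)) @ chol.T
    b = rng.standard_normal((5000, dim)) @ chol.T
    est = pk.population_dprime(pk.fit_ddr(a, b), a, b)
    assert est <= analytic * 1.02


def test_qualifying_pair_combinatorics():
    ev = pd.DataFrame({
        "stimulus": ["target_infdB", "catch", "distractor_0",
                     "distractor_1"],
        "category": ["target", "catch", "distractor", "distractor"],
        "reminder": [False] * 4,
    })
    pairs = qualifying_pairs(ev)
    labels = sorted(p[2] for p in pairs)
    assert labels == ["distractor_vs_distractor", "target_vs_catch"]
    ev2 = pd.concat([ev, pd.DataFrame({
        "stimulus": ["target_0dB"], "category": ["target"],
        "reminder": [False]})])
    labels2 = sorted(p[2] for p in qualifying_pairs(ev2))
    assert labels2.count("target_vs_catch") == 2
    assert labels2.count("target_vs_target") == 1


def test_pairwise_decoding_null_centered_on_zero():
    """Identical state parameters: engagement change distribution is
    centered on zero."""
    cfg = pk.SessionConfig(seed=21)
    truth = pk.make_ground_truth(cfg, "dPEG_like", seed=21,
                                 effect_size=0.0,
                                 pupil_coupling_scale=0.0)
    trials = pk.generate_trials(cfg)
    counts, _ = pk.generate_counts(truth, trials, cfg)
    ers = pk.evoked_response(counts)
    df = pk.results_frame(pk.pairwise_decoding(ers))
    assert len(df) >= 8
    assert abs(df["delta_norm"].mean()) < 0.08


def test_category_summary_means():
    results = [
        pk.DecodingResult("t1", "catch", "target_vs_catch", 2.0, 1.0),
        pk.DecodingResult("t2", "catch", "target_vs_catch", 3.0, 1.0),
        pk.DecodingResult("t1", "t2", "target_vs_target", 1.0, 1.0),
    ]
    s = pk.category_summary(results, column="delta")
    assert s["target_vs_catch"] == pytest.approx(1.5)
    assert s["target_vs_target"] == pytest.approx(0.0)


def test_min_trial_rule_skips_pairs():
    rng = np.random.default_rng(0)
    n_events = 30
    events = pd.DataFrame({
        "trial": np.arange(n_events),
        "state": ["active"] * 15 + ["passive"] * 15,
        "stimulus": (["target_infdB"] * 3 + ["catch"] * 12
                     + ["target_infdB"] * 8 + ["catch"] * 7),
        "category": (["target"] * 3 + ["catch"] * 12
                     + ["target"] * 8 + ["catch"] * 7),
        "snr_db": np.nan, "onset_s": np.arange(n_events) * 1.0,
        "outcome": ["hit"] * 3 + ["correct_reject"] * 12 + ["passive"] * 15,
        "reminder": False,
    })
    ers = pk.EvokedResponseSet(
        responses=rng.standard_normal((6, n_events)), events=events,
        z_mean=np.zeros(6), z_sd=np.ones(6),
        neuron_ids=np.arange(6))
    assert pk.pairwise_decoding(ers) == []  # 3 active target trials < 5


def test_choice_probability_properties():
    rng = np.random.default_rng(9)
    a = rng.standard_normal((15, 6))
    b = rng.standard_normal((15, 6)) + 0.5
    cp_ab = pk.choice_probability(a, b)
    cp_ba = pk.choice_probability(b, a)
    assert cp_ab == pytest.approx(cp_ba)
    assert 0.0 <= cp_ab <= 100.0
    with pytest.raises(ValueError):
        pk.choice_probability(a[:2], b)
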