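"""Generator tests: trial structure, count statistics, ground truth."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import popdecode as pk
from popdecode.synth import flat_hazard_counts


def test_trials_deterministic_and_structured():
    cfg = pk.SessionConfig(seed=4)
    t1 = pk.generate_trials(cfg)
    t2 = pk.generate_trials(cfg)
    pd.testing.assert_frame_equal(t1, t2)
    assert set(t1["state"]) == {"active", "passive"}
    # catch trials end with a pure-tone reminder target
    catch_trials = t1[(t1["category"] == "catch")]["trial"].unique()
    for tr in catch_trials[:20]:
        ev = t1[t1["trial"] == tr]
        assert ev.iloc[-1]["reminder"]
        assert ev.iloc[-1]["category"] == "target"
    assert t1.groupby("trial")["onset_s"].apply(
        lambda s: s.is_monotonic_increasing).all()


def test_degenerate_psychometric_rates():
    cfg = pk.SessionConfig(
        seed=1, hit_rates={-10.0: 1.0, -5.0: 1.0, 0.0: 1.0, math.inf: 1.0},
        catch_fa_rate=0.0,
    )
    trials = pk.generate_trials(cfg)
    act = trials[(trials["state"] == "active") & ~trials["reminder"]]
    target_trials = act.loc[act["category"] == "target", "trial"]
    catch_trials = act.loc[act["category"] == "catch", "trial"]
    assert (act.loc[act["trial"].isin(target_trials), "outcome"]
            == "hit").all()
    assert (act.loc[act["trial"].isin(catch_trials), "outcome"]
            == "correct_reject").all()


def test_zero_trials_rejected():
    with pytest.raises(ValueError, match="zero trials"):
        pk.generate_trials(pk.SessionConfig(trials_per_target=0,
                                            catch_trials=0))


def test_flat_hazard_stop_probability_constant():
    rng = np.random.default_rng(0)
    counts = flat_hazard_counts(rng, stop_prob=0.35, max_events=5,
                                size=10000)
    for k in range(5):
        reached = np.sum(counts >= k)
        stopped = np.sum(counts == k)
        assert abs(stopped / reached - 0.35) < 0.03


def _catch_only_trials(n_events: int) -> pd.DataFrame:
    return pd.DataFrame({
        "trial": np.arange(n_events), "state": "active",
        "stimulus": "catch", "category": "catch", "snr_db": np.nan,
        "onset_s": np.arange(n_events) * 2.0 + 1.0,
        "outcome": "correct_reject", "reminder": False,
    })


def test_count_covariance_converges_to_generator():
    """Evoked-window count mean and covariance approach mu and
    L L^T + Psi of the generating factor model."""
    cfg = pk.SessionConfig(n_neurons=20, seed=9)
    truth = pk.make_ground_truth(cfg, "dPEG_like", seed=9,
                                 pupil_coupling_scale=0.0)
    trials = _catch_only_trials(5000)
    counts, _ = pk.generate_counts(truth, trials, cfg)
    evoked = counts.counts[:, :, counts.evoked_slice].sum(axis=2)
    mu_hat = evoked.mean(axis=1)
    mu_true = truth.mu_active[:, truth.stim_index("catch")]
    assert np.all(np.abs(mu_hat - mu_true) / mu_true < 0.05)
    cov_hat = np.cov(evoked)
    cov_true = truth.covariance("active")
    frob = np.linalg.norm(cov_hat - cov_true) / np.linalg.norm(cov_true)
    assert frob < 0.10


def test_rank1_shared_axis_recovered_from_counts():
    cfg = pk.SessionConfig(n_neurons=50, seed=2)
    truth = pk.make_ground_truth(cfg, "dPEG_like", seed=2,
                                 pupil_coupling_scale=0.0)
    # keep only the dominant shared axis
    l1 = truth.loadings_passive[:, :1] * 2.0
    truth.loadings_passive = l1
    truth.loadings_active = l1
    trials = _catch_only_trials(500)
    counts, _ = pk.generate_counts(truth, trials, cfg)
    evoked = counts.counts[:, :, counts.evoked_slice].sum(axis=2)
    evals, evecs = np.linalg.eigh(np.cov(evoked))
    top = evecs[:, np.argmax(evals)]
    cos = abs(top @ l1[:, 0]) / np.linalg.norm(l1)
    assert cos > 0.95


def test_zero_pupil_coupling_gives_zero_correlation():
    cfg = pk.SessionConfig(n_neurons=15, seed=5, trials_per_target=10,
                           catch_trials=10)
    trials, counts, pupil, truth = pk.generate_session(
        cfg, "dPEG_like", pupil_coupling_scale=0.0)
    p = pk.event_pupil(pupil, trials["onset_s"].to_numpy())
    evoked = counts.counts[:, :, counts.evoked_slice].sum(axis=2)
    # per neuron, within catch events so stimulus drive does not enter
    mask = (trials["stimulus"] == "catch").to_numpy()
    rs = [np.corrcoef(evoked[i, mask], p[mask])[0, 1]
          for i in range(cfg.n_neurons)]
    assert abs(np.mean(rs)) < 0.1


def test_counts_reproducible_and_seed_sensitive():
    cfg = pk.SessionConfig(n_neurons=10, seed=3, trials_per_target=5,
                           catch_trials=5)
    t1, c1, p1, _ = pk.generate_session(cfg, "A1_like")
    t2, c2, p2, _ = pk.generate_session(cfg, "A1_like")
    assert np.array_equal(c1.counts, c2.counts)
    assert np.array_equal(p1.size, p2.size)
    cfg2 = pk.SessionConfig(n_neurons=10, seed=4, trials_per_target=5,
                            catch_trials=5)
    _, c3, _, _ = pk.generate_session(cfg2, "A1_like")
    assert not np.array_equal(c1.counts, c3.counts)


def test_nonpositive_private_variance_names_state():
    cfg = pk.SessionConfig(n_neurons=8, seed=1, trials_per_target=2,
                           catch_trials=2)
    truth = pk.make_ground_truth(cfg, "A1_like")
    truth.psi_passive = truth.psi_passive.copy()
    truth.psi_passive[0] = -1.0
    trials = pk.generate_trials(cfg)
    with pytest.raises(ValueError, match="passive"):
        pk.generate_counts(truth, trials, cfg)


def test_region_modes_shape_analytic_selectivity():
    cfg = pk.SessionConfig(seed=6)
    dpeg = pk.make_ground_truth(cfg, "dPEG_like", seed=6)
    a1 = pk.make_ground_truth(cfg, "A1_like", seed=6)
    assert pk.analytic_selective_enhancement(dpeg) > 0.05
    assert abs(pk.analytic_selective_enhancement(a1)) < 1e-9
    # uniform gain change in the primary-like mode: the evoked component
    # of every stimulus is scaled by one common factor
    base = a1.baseline_rate * cfg.evoked_window
    ev_p = a1.mu_passive - base[:, None]
    ev_a = a1.mu_active - base[:, None]
    ratio = ev_a[ev_p > 1e-9] / ev_p[ev_p > 1e-9]
    assert np.ptp(ratio) < 1e-9  # identical multiplicative profile

    # non-primary-like mode: gain change concentrates on tone-responsive
    # (target-vs-catch contrast) neurons
    gd = dpeg.gain[:, dpeg.stim_index("target_infdB")]
    tone = dpeg.tone_direction
    assert gd[tone > 0].mean() > gd[tone == 0].mean()


def test_fixture_roundtrip(tmp_path):
    path = pk.make_fixture(tmp_path / "sess", region_mode="dPEG_like",
                           seed=7,
                           config=pk.SessionConfig(n_neurons=12,
                                                   trials_per_target=6,
                                                   catch_trials=6))
    sess = pk.read_session(path)
    assert sess.pupil is not None
    assert sess.truth is not None
    assert sess.truth.region_mode == "dPEG_like"
    assert sess.counts.counts.shape[0] == 12
    assert pk.analytic_selective_enhancement(sess.truth) > 0
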