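"""Shared fixtures: synthetic session ensembles used by the end-to-end
and ablation tests.

The ensembles are generated once per test run (session scope) because the
12-session decoding + four-model ablation is the expensive part of the
suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import popdecode as pk

N_SESSIONS = 12
# engagement effect sizes spanning weak to strong, so that across-session
# variance in true selective enhancement dominates per-session estimation
# noise (a prerequisite for correlation-based model comparison)
DPEG_EFFECTS = np.linspace(0.3, 2.4, N_SESSIONS)


def _analyze(region_mode: str, seed: int, with_ablation: bool,
             **truth_kwargs) -> dict:
    cfg = pk.SessionConfig(seed=seed)
    trials, counts, pupil, truth = pk.generate_session(
        cfg, region_mode, seed=seed, **truth_kwargs
    )
    ers = pk.evoked_response(counts)
    ers, _ = pk.regress_out_pupil(ers, pupil)
    results = pk.pairwise_decoding(ers)
    out = {
        "truth": truth,
        "category": pk.category_summary(results),
        "selective_enhancement": pk.selective_enhancement(results),
        "truth_se": pk.analytic_selective_enhancement(truth),
    }
    if with_ablation:
        out["ablation"] = pk.run_ablation(ers, n_samples=2000, seed=seed)
    return out


@pytest.fixture(scope="session")
def dpeg_sessions() -> list[dict]:
    """12 non-primary-like sessions whose only state change is a
    stimulus-selective gain boost (no pupil coupling), with the four-model
    ablation run on each."""
    return [
        _analyze("dPEG_like", seed=s, with_ablation=True,
                 effect_size=float(DPEG_EFFECTS[s]),
                 pupil_coupling_scale=0.0)
        for s in range(N_SESSIONS)
    ]


@pytest.fixture(scope="session")
def a1_sessions() -> list[dict]:
    """12 primary-like sessions with a uniform engagement gain applied to
    every stimulus (pupil coupling and correction active)."""
    return [
        _analyze("A1_like", seed=s, with_ablation=False)
        for s in range(N_SESSIONS)
    ]
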