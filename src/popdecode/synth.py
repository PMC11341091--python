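"""Synthetic session-bundle generator with known ground truth.

Emulates a go/no-go tone-in-noise detection session: trials are sequences
of narrowband noise distractors (count drawn from a flat-hazard
distribution) optionally ending in a catch noise burst or a target tone at
one of four SNRs (-10, -5, 0, Inf dB). Population spike counts are drawn
from a per-state factor model, N(gain * mu, L L^T + Psi), with a slow
pupil trace linearly coupled to a subset of neurons. Two region modes set
how task engagement changes the mean response:

* ``dPEG_like`` — engagement adds a stimulus-selective boost along the
  tone-response direction, pushing all target means away from the catch
  mean by a common amount (a categorical enhancement); target-vs-target
  and distractor contrasts are untouched.
* ``A1_like`` — engagement scales every stimulus's evoked component by a
  common gain, enhancing all contrasts uniformly.

Everything is reproducible from integer seeds, and all generating
parameters are retrievable for ground-truth comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocess import PopulationCounts, PupilTrace, event_pupil

REGION_MODES = ("A1_like", "dPEG_like")
EVENT_COLUMNS = (
    "trial", "state", "stimulus", "category", "snr_db", "onset_s",
    "outcome", "reminder",
)


def target_name(snr: float) -> str:
    return f"target_{snr:g}dB"


def _default_hit_rates() -> dict[float, float]:
    # psychometric dependence on SNR: near-chance at -10 dB, near-perfect
    # for the pure tone
    return {-10.0: 0.35, -5.0: 0.55, 0.0: 0.80, math.inf: 0.95}


@dataclass
class SessionConfig:
    """Session structure and behavioral parameters.

    Stimulus timing follows the task design: 0.3 s stimuli, 0.2 s ISI,
    20 ms count bins and a 100 ms pre-stimulus baseline. ``hazard_stop``
    is the constant per-position probability that the distractor sequence
    ends (flat hazard), truncated at ``max_distractors``.
    """

    n_neurons: int = 60
    trials_per_target: int = 25
    catch_trials: int = 25
    target_snrs: tuple[float, ...] = (-10.0, -5.0, 0.0, math.inf)
    hit_rates: Mapping[float, float] = field(default_factory=_default_hit_rates)
    catch_fa_rate: float = 0.15
    n_distractors: int = 3
    hazard_stop: float = 0.35
    max_distractors: int = 5
    stim_duration: float = 0.3
    isi: float = 0.2
    inter_trial_interval: float = 1.5
    bin_width: float = 0.02
    baseline_window: float = 0.1
    evoked_window: float = 0.3
    pupil_dt: float = 0.1
    pupil_lag: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        if self.trials_per_target <= 0 and self.catch_trials <= 0:
            raise ValueError("zero trials requested")
        for name in ("stim_duration", "isi", "bin_width", "baseline_window",
                     "evoked_window", "pupil_dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.hazard_stop <= 1):
            raise ValueError("hazard_stop must be in (0, 1]")
        for snr in self.target_snrs:
            r = self.hit_rates[snr]
            if not 0 <= r <= 1:
                raise ValueError(f"hit rate for {snr} dB outside [0, 1]")
        if not 0 <= self.catch_fa_rate <= 1:
            raise ValueError("catch_fa_rate outside [0, 1]")

    @property
    def n_baseline_bins(self) -> int:
        return round(self.baseline_window / self.bin_width)

    @property
    def n_evoked_bins(self) -> int:
        return round(self.evoked_window / self.bin_width)

    @property
    def stimuli(self) -> list[str]:
        return (
            ["catch"]
            + [target_name(s) for s in self.target_snrs]
            + [f"distractor_{j}" for j in range(self.n_distractors)]
        )


@dataclass
class GroundTruth:
    """Generating parameters of one synthetic session.

    ``mu_active``/``mu_passive`` are neurons x stimuli mean evoked spike
    counts over the 300 ms window; the shared covariance per state is
    ``loadings @ loadings.T`` and private variance ``psi`` (both in
    count-variance units). ``alpha`` couples each neuron's evoked count to
    the (lagged) pupil regressor. ``effect_size`` is the session's
    engagement effect: the additive tone-direction boost (dPEG_like) or
    the multiplicative evoked gain (A1_like).
    """

    stimuli: list[str]
    mu_active: np.ndarray
    mu_passive: np.ndarray
    loadings_active: np.ndarray
    loadings_passive: np.ndarray
    psi_active: np.ndarray
    psi_passive: np.ndarray
    alpha: np.ndarray
    baseline_rate: np.ndarray
    region_mode: str
    seed: int
    effect_size: float = 0.0
    tone_direction: np.ndarray | None = None

    def validate(self) -> None:
        for state in ("active", "passive"):
            psi = getattr(self, f"psi_{state}")
            if np.any(psi <= 0):
                raise ValueError(f"non-positive private variance in {state} state")
            if not np.all(np.isfinite(getattr(self, f"loadings_{state}"))):
                raise ValueError(f"non-finite loadings in {state} state")
        if np.any(self.gain <= 0):
            raise ValueError("gain factors must be positive")

    def mu(self, state: str) -> np.ndarray:
        return self.mu_active if state == "active" else self.mu_passive

    def loadings(self, state: str) -> np.ndarray:
        return self.loadings_active if state == "active" else self.loadings_passive

    def psi(self, state: str) -> np.ndarray:
        return self.psi_active if state == "active" else self.psi_passive

    def covariance(self, state: str) -> np.ndarray:
        L = self.loadings(state)
        return L @ L.T + np.diag(self.psi(state))

    @property
    def gain(self) -> np.ndarray:
        """Multiplicative per-neuron, per-stimulus gain (active / passive)."""
        return self.mu_active / self.mu_passive

    def stim_index(self, stimulus: str) -> int:
        return self.stimuli.index(stimulus)


def make_ground_truth(
    config: SessionConfig,
    region_mode: str = "dPEG_like",
    seed: int | None = None,
    effect_size: float | None = None,
    rotate_shared: bool = False,
    private_scale: float = 1.0,
    snr_scale: Mapping[float, float] | None = None,
    pupil_coupling_scale: float = 1.0,
) -> GroundTruth:
    """Draw generating parameters for one session.

    ``rotate_shared`` rotates the dominant active-state loading toward the
    mean target-vs-catch contrast (the covariability rotation seen in
    primary cortex); ``private_scale`` multiplies active-state private
    variance. Both default to off so that, by default, the only state
    change is the mean-response (gain) effect.
    """
    if region_mode not in REGION_MODES:
        raise ValueError(f"region_mode must be one of {REGION_MODES}")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([int(seed), 11])
    n = config.n_neurons
    snr_scale = dict(snr_scale or {-10.0: 0.40, -5.0: 0.60, 0.0: 0.85,
                                   math.inf: 1.30})

    baseline_rate = rng.uniform(10.0, 30.0, n)
    base = baseline_rate * config.evoked_window  # counts from ongoing rate

    def evoked_component(amp_hi: float, frac: float) -> np.ndarray:
        mask = rng.random(n) < frac
        return rng.uniform(0.0, amp_hi, n) * mask

    catch_component = evoked_component(6.0, 0.6)
    tone = evoked_component(2.5, 0.5)
    dist_components = [evoked_component(3.0, 0.5)
                       for _ in range(config.n_distractors)]

    stimuli = config.stimuli
    mu_passive = np.empty((n, len(stimuli)))
    mu_passive[:, 0] = base + catch_component
    for k, snr in enumerate(config.target_snrs, start=1):
        mu_passive[:, k] = base + catch_component + snr_scale[snr] * tone
    for j, d in enumerate(dist_components):
        mu_passive[:, 1 + len(config.target_snrs) + j] = base + d

    # Poisson-like private noise plus a rank-2 shared component (~25 %sv)
    psi = 1.2 * mu_passive.mean(axis=1)
    w1 = 1.0 + 0.3 * rng.standard_normal(n)
    w2 = rng.choice([-1.0, 1.0], n) * np.abs(1.0 + 0.3 * rng.standard_normal(n))
    loadings = np.column_stack(
        [np.sqrt(0.25 * psi) * w1, np.sqrt(0.08 * psi) * w2]
    )

    mu_active = mu_passive.copy()
    if region_mode == "dPEG_like":
        if effect_size is None:
            effect_size = rng.uniform(0.4, 1.6)
        for k in range(1, 1 + len(config.target_snrs)):
            mu_active[:, k] = mu_passive[:, k] + effect_size * tone
    else:
        if effect_size is None:
            effect_size = rng.uniform(1.2, 1.6)
        mu_active = base[:, None] + effect_size * (mu_passive - base[:, None])

    loadings_active = loadings.copy()
    if rotate_shared:
        dmu = (mu_active[:, 1:1 + len(config.target_snrs)].mean(axis=1)
               - mu_active[:, 0])
        dmu_hat = dmu / np.linalg.norm(dmu)
        l1 = loadings[:, 0]
        blend = 0.5 * l1 / np.linalg.norm(l1) + 0.5 * dmu_hat
        loadings_active[:, 0] = (
            blend / np.linalg.norm(blend) * np.linalg.norm(l1)
        )
    psi_active = private_scale * psi

    alpha_mask = rng.random(n) < 0.3
    alpha = pupil_coupling_scale * rng.uniform(0.5, 2.0, n) * alpha_mask

    truth = GroundTruth(
        stimuli=stimuli,
        mu_active=mu_active,
        mu_passive=mu_passive,
        loadings_active=loadings_active,
        loadings_passive=loadings,
        psi_active=psi_active,
        psi_passive=psi,
        alpha=alpha,
        baseline_rate=baseline_rate,
        region_mode=region_mode,
        seed=int(seed),
        effect_size=float(effect_size),
        tone_direction=tone,
    )
    truth.validate()
    return truth


def flat_hazard_counts(rng: np.random.Generator, stop_prob: float,
                       max_events: int, size: int) -> np.ndarray:
    """Number of distractors per trial under a flat hazard function.

    The sequence ends at each position with constant probability
    ``stop_prob`` (so timing carries no information), truncated at
    ``max_events``.
    """
    draws = rng.random((size, max_events))
    stopped = draws < stop_prob
    counts = np.where(stopped.any(axis=1), stopped.argmax(axis=1), max_events)
    return counts


def generate_trials(config: SessionConfig) -> pd.DataFrame:
    """Trial/event table for active and passive blocks.

    One row per stimulus event. Outcomes are sampled independently per
    trial from the configured psychometric rates; catch trials are
    concluded by a pure-tone reminder target (flagged ``reminder`` and
    excluded from analysis by default).
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0])
    rows: list[dict] = []
    trial_id = 0
    t = 0.0
    step = config.stim_duration + config.isi
    reminder_stim = target_name(math.inf)
    for state in ("active", "passive"):
        kinds: list[tuple[str, float | None]] = []
        for snr in config.target_snrs:
            kinds += [("target", snr)] * config.trials_per_target
        kinds += [("catch", None)] * config.catch_trials
        order = rng.permutation(len(kinds))
        n_dist = flat_hazard_counts(
            rng, config.hazard_stop, config.max_distractors, len(kinds)
        )
        for j, oi in enumerate(order):
            kind, snr = kinds[oi]
            trial_id += 1
            if state == "passive":
                outcome = "passive"
            elif kind == "target":
                outcome = ("hit" if rng.random() < config.hit_rates[snr]
                           else "miss")
            else:
                outcome = ("false_alarm" if rng.random() < config.catch_fa_rate
                           else "correct_reject")
            events: list[tuple[str, str, float | None, bool]] = []
            for _ in range(int(n_dist[j])):
                d = rng.integers(config.n_distractors)
                events.append((f"distractor_{d}", "distractor", None, False))
            if kind == "target":
                events.append((target_name(snr), "target", snr, False))
            else:
                events.append(("catch", "catch", None, False))
                events.append((reminder_stim, "target", math.inf, True))
            for k, (stim, cat, ev_snr, rem) in enumerate(events):
                rows.append({
                    "trial": trial_id,
                    "state": state,
                    "stimulus": stim,
                    "category": cat,
                    "snr_db": np.nan if ev_snr is None else float(ev_snr),
                    "onset_s": t + k * step,
                    "outcome": outcome,
                    "reminder": rem,
                })
            t += len(events) * step + config.inter_trial_interval
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def generate_pupil(config: SessionConfig, trials: pd.DataFrame,
                   active_offset: float = 1.0) -> PupilTrace:
    """Slow Ornstein-Uhlenbeck-like pupil trace rescaled to [0, 1].

    ``active_offset`` (in units of the random walk's stationary SD) shifts
    pupil upward during the active block, emulating the engagement-arousal
    correlation seen in behaving animals.
    """
    rng = np.random.default_rng([int(config.seed), 1])
    duration = float(trials["onset_s"].max()) + 2.0
    nt = int(np.ceil(duration / config.pupil_dt)) + 1
    time = np.arange(nt) * config.pupil_dt
    theta, sigma = 0.2, 1.0
    x = np.zeros(nt)
    noise = rng.standard_normal(nt - 1)
    for i in range(1, nt):
        x[i] = (x[i - 1] - theta * x[i - 1] * config.pupil_dt
                + sigma * math.sqrt(config.pupil_dt) * noise[i - 1])
    stat_sd = sigma / math.sqrt(2 * theta)
    active = trials[trials["state"] == "active"]
    if len(active):
        t_hi = float(active["onset_s"].max()) + config.stim_duration
        x = x + active_offset * stat_sd * (time <= t_hi)
    lo, hi = x.min(), x.max()
    size = (x - lo) / (hi - lo) if hi > lo else np.full(nt, 0.5)
    return PupilTrace(time=time, size=size, dt=config.pupil_dt,
                      lag=config.pupil_lag)


def generate_counts(
    truth: GroundTruth,
    trials: pd.DataFrame,
    config: SessionConfig,
    pupil: PupilTrace | None = None,
) -> tuple[PopulationCounts, PupilTrace]:
    """Draw binned spike counts for every event in the trial table.

    Each event's latent population response is a multivariate Gaussian
    draw N(mu_state, L L^T + Psi) plus the pupil term alpha * p, rounded
    and clipped at zero to give the total evoked-window count, which is
    then spread across the fifteen 20 ms bins with an onset-weighted
    temporal profile. Baseline bins carry each neuron's ongoing rate.
    """
    missing = set(trials["stimulus"]) - set(truth.stimuli)
    if missing:
        raise ValueError(f"trial table uses unknown stimuli: {sorted(missing)}")
    truth.validate()
    for state in ("active", "passive"):
        cov = truth.covariance(state)
        if np.min(np.linalg.eigvalsh(cov)) < -1e-8 * np.trace(cov):
            raise ValueError(
                f"covariance for state {state!r} is not positive semi-definite"
            )
    rng = np.random.default_rng([truth.seed, 2])
    if pupil is None:
        pupil = generate_pupil(config, trials)
    p_event = event_pupil(pupil, trials["onset_s"].to_numpy(),
                          config.evoked_window, config.baseline_window)

    n = config.n_neurons
    n_events = len(trials)
    nb, ne = config.n_baseline_bins, config.n_evoked_bins
    counts = np.zeros((n, n_events, nb + ne), dtype=np.int64)

    # ongoing activity in the baseline bins
    lam = truth.baseline_rate[:, None, None] * config.bin_width
    base = np.rint(rng.normal(lam, np.sqrt(lam), size=(n, n_events, nb)))
    counts[:, :, :nb] = np.clip(base, 0, None).astype(np.int64)

    # onset-weighted within-window temporal profile, common to all neurons
    prof = np.exp(-np.arange(ne) * config.bin_width / 0.12) + 0.35
    prof /= prof.sum()

    states = trials["state"].to_numpy()
    stim_idx = np.array([truth.stim_index(s) for s in trials["stimulus"]])
    for e in range(n_events):
        s = states[e]
        mu = truth.mu(s)[:, stim_idx[e]]
        L, psi = truth.loadings(s), truth.psi(s)
        z = rng.standard_normal(L.shape[1])
        latent = (mu + L @ z + np.sqrt(psi) * rng.standard_normal(n)
                  + truth.alpha * p_event[e])
        total = np.clip(np.rint(latent), 0, None).astype(np.int64)
        counts[:, e, nb:] = rng.multinomial(total, prof)
    pc = PopulationCounts(
        counts=counts, events=trials.reset_index(drop=True),
        bin_width=config.bin_width, n_baseline_bins=nb, n_evoked_bins=ne,
    )
    return pc, pupil


def generate_session(
    config: SessionConfig,
    region_mode: str = "dPEG_like",
    **truth_kwargs,
) -> tuple[pd.DataFrame, PopulationCounts, PupilTrace, GroundTruth]:
    """Convenience wrapper: trials + counts + pupil + ground truth."""
    truth = make_ground_truth(config, region_mode, **truth_kwargs)
    trials = generate_trials(config)
    counts, pupil = generate_counts(truth, trials, config)
    return trials, counts, pupil, truth


def make_fixture(
    path: str | Path,
    region_mode: str = "dPEG_like",
    seed: int = 0,
    config: SessionConfig | None = None,
    **truth_kwargs,
) -> Path:
    """Write a session bundle (plus ground-truth sidecar) to ``path``."""
    from .session_io import write_session  # deferred: session_io imports synth

    if config is None:
        config = SessionConfig(seed=seed)
    else:
        config = dataclasses_replace_seed(config, seed)
    trials, counts, pupil, truth = generate_session(
        config, region_mode, **truth_kwargs
    )
    return write_session(Path(path), trials, counts, pupil=pupil, truth=truth,
                         config=config)


def dataclasses_replace_seed(config: SessionConfig, seed: int) -> SessionConfig:
    from dataclasses import replace

    return replace(config, seed=seed)


# ---------------------------------------------------------------------------
# analytic (ground-truth) discriminability


def analytic_dprime(truth: GroundTruth, stim_a: str, stim_b: str,
                    state: str) -> float:
    """Closed-form full-space d' = sqrt(dmu^T Sigma^-1 dmu) of the
    generating Gaussian."""
    dmu = (truth.mu(state)[:, truth.stim_index(stim_a)]
           - truth.mu(state)[:, truth.stim_index(stim_b)])
    cov = truth.covariance(state)
    return float(np.sqrt(dmu @ np.linalg.solve(cov, dmu)))


def analytic_delta_dprime(truth: GroundTruth, stim_a: str, stim_b: str,
                          normalized: bool = True) -> float:
    a = analytic_dprime(truth, stim_a, stim_b, "active")
    p = analytic_dprime(truth, stim_a, stim_b, "passive")
    return (a - p) / (a + p) if normalized else a - p


def analytic_selective_enhancement(truth: GroundTruth,
                                   normalized: bool = True) -> float:
    """Ground-truth selective enhancement: mean Δd'(target vs catch) minus
    mean Δd'(target vs target), from the generating parameters."""
    targets = [s for s in truth.stimuli if s.startswith("target_")]
    tvc = [analytic_delta_dprime(truth, t, "catch", normalized)
           for t in targets]
    tvt = [analytic_delta_dprime(truth, a, b, normalized)
           for i, a in enumerate(targets) for b in targets[i + 1:]]
    return float(np.mean(tvc) - np.mean(tvt))
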