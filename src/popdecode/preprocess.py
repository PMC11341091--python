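"""Turn binned spike counts into z-scored PSTHs and single-trial evoked
responses, and remove pupil-explainable variance.

The conventions follow common practice for trial-structured cortical
recordings: spikes are counted in 20 ms bins, each event window holds a
100 ms pre-stimulus baseline followed by a 300 ms sound-evoked window, and
single-trial responses are the mean z-scored rate over the evoked window.
Pupil-indexed arousal is removed by per-neuron, per-stimulus linear
regression of the evoked response on (lagged) pupil size, subtracting only
the centered pupil term so stimulus means are untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger("popdecode")

#: outcomes counted as "correct" in stimulus decoding
CORRECT_OUTCOMES = ("hit", "correct_reject")
#: active-trial outcomes whose responses enter the evoked set
ACTIVE_INCLUDED_OUTCOMES = ("hit", "correct_reject", "miss")


@dataclass
class PupilTrace:
    """Pupil size time series in arbitrary units.

    ``lag`` is the shift (s) applied when aligning pupil to spikes: neural
    activity at time t is paired with pupil at t - lag, accounting for the
    documented lagged coupling between cortical state and pupil diameter.
    """

    time: np.ndarray
    size: np.ndarray
    dt: float
    lag: float = 0.75

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.size = np.asarray(self.size, float)
        if self.time.shape != self.size.shape:
            raise ValueError("pupil time and size must have equal length")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("pupil time axis must be strictly increasing")

    def mean_in_window(self, start: float, stop: float) -> float:
        """Mean pupil size in [start, stop) of *pupil* time (no lag)."""
        mask = (self.time >= start) & (self.time < stop)
        if not mask.any():
            # fall back to nearest sample so short edge windows stay defined
            idx = np.argmin(np.abs(self.time - 0.5 * (start + stop)))
            return float(self.size[idx])
        return float(self.size[mask].mean())


@dataclass
class PopulationCounts:
    """Spike counts for one session: neurons x events x 20 ms bins.

    The bin axis is the 100 ms baseline followed by the 300 ms evoked
    window; ``events`` is one row per stimulus event with columns
    ``trial, state, stimulus, category, snr_db, onset_s, outcome, reminder``.
    """

    counts: np.ndarray
    events: pd.DataFrame
    bin_width: float = 0.02
    n_baseline_bins: int = 5
    n_evoked_bins: int = 15
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be neurons x events x bins")
        n, e, b = self.counts.shape
        if len(self.events) != e:
            raise ValueError(
                f"event axis mismatch: counts has {e} events, "
                f"trial table has {len(self.events)} rows"
            )
        if b != self.n_baseline_bins + self.n_evoked_bins:
            raise ValueError(
                f"bin axis has {b} bins, expected "
                f"{self.n_baseline_bins}+{self.n_evoked_bins}"
            )
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(n)

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def evoked_slice(self) -> slice:
        return slice(self.n_baseline_bins, self.n_baseline_bins + self.n_evoked_bins)


@dataclass
class EvokedResponseSet:
    """Single-trial evoked responses (z-units), neurons x events.

    ``z_mean``/``z_sd`` are the per-neuron raw-rate normalization
    parameters (pooled over both behavioral states) so the transform is
    invertible.
    """

    responses: np.ndarray
    events: pd.DataFrame
    z_mean: np.ndarray
    z_sd: np.ndarray
    neuron_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.responses.shape[1] != len(self.events):
            raise ValueError("responses and events are misaligned")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[0]

    def event_mask(
        self,
        stimulus: str | None = None,
        state: str | None = None,
        outcomes: tuple[str, ...] | None = None,
    ) -> np.ndarray:
        ev = self.events
        mask = np.ones(len(ev), bool)
        if stimulus is not None:
            mask &= (ev["stimulus"] == stimulus).to_numpy()
        if state is not None:
            mask &= (ev["state"] == state).to_numpy()
        if outcomes is not None:
            mask &= ev["outcome"].isin(outcomes).to_numpy()
        return mask

    def matrix(
        self,
        stimulus: str | None = None,
        state: str | None = None,
        outcomes: tuple[str, ...] | None = None,
    ) -> np.ndarray:
        """Trials x neurons response matrix for the selected events."""
        mask = self.event_mask(stimulus, state, outcomes)
        return self.responses[:, mask].T


def zscore_psth(
    counts: PopulationCounts, sigma: float = 0.03
) -> tuple[dict[tuple[str, str], np.ndarray], np.ndarray]:
    """Smoothed z-scored PSTH per (stimulus, state), for visualization.

    Each neuron's trial-mean binned rate is baseline-subtracted (mean over
    the 100 ms pre-stimulus bins), z-scored by that neuron's pooled rate SD,
    and smoothed with a Gaussian kernel (default sigma 30 ms). Neurons with
    zero pooled rate variance are excluded with a warning.

    Returns (psths, neuron_ids) where psths maps (stimulus, state) to an
    included-neurons x bins array.
    """
    rates = counts.counts / counts.bin_width
    sd = rates.reshape(counts.n_neurons, -1).std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "zscore_psth: excluding %d zero-variance neurons", (~keep).sum()
        )
    sigma_bins = sigma / counts.bin_width
    out: dict[tuple[str, str], np.ndarray] = {}
    ev = counts.events
    for (stim, state), idx in ev.groupby(["stimulus", "state"], observed=True).groups.items():
        loc = ev.index.get_indexer(idx)
        mean_rate = rates[keep][:, loc, :].mean(axis=1)
        baseline = mean_rate[:, : counts.n_baseline_bins].mean(axis=1, keepdims=True)
        z = (mean_rate - baseline) / sd[keep][:, None]
        out[(str(stim), str(state))] = gaussian_filter1d(
            z, sigma_bins, axis=1, mode="constant"
        )
    return out, counts.neuron_ids[keep]


def evoked_response(
    counts: PopulationCounts,
    drop_outcomes: tuple[str, ...] = ("false_alarm",),
    drop_reminders: bool = True,
) -> EvokedResponseSet:
    """Single-trial evoked responses: mean z-scored rate over the 300 ms
    evoked window.

    Z-normalization parameters (mean, SD of the binned rate) are computed
    per neuron pooled across both behavioral states so active and passive
    responses share a scale. Active false-alarm trials are dropped (hit,
    correct-reject and miss trials are kept), as are pure-tone reminder
    events appended to catch trials. Neurons with zero pooled SD are
    dropped with a log message.
    """
    ev = counts.events.reset_index(drop=True)
    keep_ev = np.ones(len(ev), bool)
    if drop_outcomes:
        keep_ev &= ~ev["outcome"].isin(drop_outcomes).to_numpy()
    if drop_reminders and "reminder" in ev.columns:
        keep_ev &= ~ev["reminder"].to_numpy(dtype=bool)
    sub = counts.counts[:, keep_ev, :] / counts.bin_width
    mean = sub.reshape(counts.n_neurons, -1).mean(axis=1)
    sd = sub.reshape(counts.n_neurons, -1).std(axis=1)
    keep_n = sd > 0
    if not keep_n.all():
        logger.info(
            "evoked_response: dropping %d neurons with zero pooled SD",
            (~keep_n).sum(),
        )
    z = (sub[keep_n] - mean[keep_n, None, None]) / sd[keep_n, None, None]
    resp = z[:, :, counts.evoked_slice].mean(axis=2)
    return EvokedResponseSet(
        responses=resp,
        events=ev.loc[keep_ev].reset_index(drop=True),
        z_mean=mean[keep_n],
        z_sd=sd[keep_n],
        neuron_ids=counts.neuron_ids[keep_n],
    )


def event_pupil(
    pupil: PupilTrace,
    onsets: np.ndarray,
    evoked_window: float = 0.3,
    baseline_window: float = 0.1,
) -> np.ndarray:
    """Scalar pupil regressor per event: mean lagged pupil over the evoked
    window.

    The event's evoked window starts ``baseline_window`` after the window
    onset recorded in the trial table; the pupil lag shifts the window back
    by ``pupil.lag`` seconds.
    """
    onsets = np.asarray(onsets, float)
    start = onsets + baseline_window - pupil.lag
    return np.array(
        [pupil.mean_in_window(s, s + evoked_window) for s in start]
    )


def regress_out_pupil(
    responses: EvokedResponseSet,
    pupil: PupilTrace,
    evoked_window: float = 0.3,
    baseline_window: float = 0.1,
    min_events: int = 3,
) -> tuple[EvokedResponseSet, pd.DataFrame]:
    """Remove pupil-explainable variance from each neuron's responses.

    For each (neuron, stimulus) group, ordinary least squares fits
    r = alpha * p + beta on the scalar per-event pupil regressor p; the
    corrected response is r - alpha * (p - p_bar), which removes
    pupil-correlated variability while preserving the per-stimulus mean
    response. Groups with fewer than ``min_events`` events are left
    uncorrected (logged).

    Returns the corrected response set and a table of per-(neuron,
    stimulus) coefficients (alpha, beta, n).
    """
    p = event_pupil(pupil, responses.events["onset_s"].to_numpy(),
                    evoked_window, baseline_window)
    corrected = responses.responses.copy()
    rows = []
    for stim, grp in responses.events.groupby("stimulus", observed=True):
        loc = responses.events.index.get_indexer(grp.index)
        pg = p[loc]
        if len(loc) < min_events:
            logger.info(
                "regress_out_pupil: skipping stimulus %r with %d events",
                stim, len(loc),
            )
            continue
        pc = pg - pg.mean()
        denom = np.dot(pc, pc)
        if denom == 0:
            logger.info(
                "regress_out_pupil: constant pupil for stimulus %r, skipped", stim
            )
            continue
        r = responses.responses[:, loc]
        alpha = (r - r.mean(axis=1, keepdims=True)) @ pc / denom
        beta = r.mean(axis=1) - alpha * pg.mean()
        corrected[:, loc] = r - alpha[:, None] * pc[None, :]
        for i, nid in enumerate(responses.neuron_ids):
            rows.append(
                {"neuron": nid, "stimulus": stim, "alpha": alpha[i],
                 "beta": beta[i], "n_events": len(loc)}
            )
    coefs = pd.DataFrame(rows)
    return replace(responses, responses=corrected), coefs
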