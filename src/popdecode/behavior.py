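"""Behavioral performance metrics from the trial table.

Behavioral sensitivity is the signal-detection d' = Phi^-1(hit rate) -
Phi^-1(catch response rate), computed per target SNR against the explicit
catch stimulus. Extreme rates (0 or 1) are clipped to 1/(2n) before the
inverse-normal transform, the standard convention when a rate is estimated
from n trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("popdecode")


def response_rates(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-stimulus response rates from active trials.

    Target rows report the hit rate per SNR; the catch row reports the
    false-alarm (response) rate, measured from explicit catch stimuli
    only. Reminder events are ignored. Stimuli with zero presentations are
    omitted with a logged warning.
    """
    act = trials[(trials["state"] == "active")
                 & ~trials["reminder"].astype(bool)]
    rows = []
    for snr, grp in act[act["category"] == "target"].groupby("snr_db",
                                                             dropna=False):
        n = grp["trial"].nunique()
        hits = grp.loc[grp["outcome"] == "hit", "trial"].nunique()
        rows.append({"stimulus": str(grp["stimulus"].iloc[0]),
                     "snr_db": float(snr), "rate": hits / n, "n": n,
                     "kind": "target"})
    catch = act[act["category"] == "catch"]
    if len(catch):
        n = catch["trial"].nunique()
        fa = catch.loc[catch["outcome"] == "false_alarm", "trial"].nunique()
        rows.append({"stimulus": "catch", "snr_db": np.nan, "rate": fa / n,
                     "n": n, "kind": "catch"})
    else:
        logger.warning("response_rates: no catch presentations in table")
    if not rows:
        raise ValueError("no active stimulus presentations found")
    return pd.DataFrame(rows)


def _clip_rate(rate: float, n: int) -> float:
    if n <= 0:
        raise ValueError("trial count must be positive")
    lo = 1.0 / (2 * n)
    return float(np.clip(rate, lo, 1.0 - lo))


def behavioral_dprime(hit_rate: float, catch_rate: float,
                      n_target: int, n_catch: int) -> float:
    """Phi^-1(hit) - Phi^-1(catch) after clipping rates to [1/2n, 1-1/2n]."""
    for r in (hit_rate, catch_rate):
        if not 0 <= r <= 1:
            raise ValueError("rates must lie in [0, 1]")
    h = _clip_rate(hit_rate, n_target)
    f = _clip_rate(catch_rate, n_catch)
    return float(sps.norm.ppf(h) - sps.norm.ppf(f))


@dataclass
class BehaviorSummary:
    """Per-SNR behavioral performance, one d' per target SNR."""

    table: pd.DataFrame  # columns: stimulus, snr_db, hit_rate, n_target,
    #                     catch_rate, n_catch, dprime

    def dprime(self, snr: float) -> float:
        row = self.table[self.table["snr_db"] == snr]
        if not len(row):
            raise KeyError(f"no target at SNR {snr}")
        return float(row["dprime"].iloc[0])


def psychometric_table(trials: pd.DataFrame) -> BehaviorSummary:
    """One behavioral d' per target SNR against the catch response rate."""
    rates = response_rates(trials)
    catch = rates[rates["kind"] == "catch"]
    if not len(catch):
        raise ValueError("psychometric table requires catch presentations")
    catch_rate = float(catch["rate"].iloc[0])
    n_catch = int(catch["n"].iloc[0])
    rows = []
    for _, r in rates[rates["kind"] == "target"].iterrows():
        rows.append({
            "stimulus": r["stimulus"], "snr_db": r["snr_db"],
            "hit_rate": r["rate"], "n_target": int(r["n"]),
            "catch_rate": catch_rate, "n_catch": n_catch,
            "dprime": behavioral_dprime(r["rate"], catch_rate,
                                        int(r["n"]), n_catch),
        })
    return BehaviorSummary(pd.DataFrame(rows).sort_values("snr_db")
                           .reset_index(drop=True))


def pretrial_pupil_by_outcome(
    trials: pd.DataFrame,
    pupil,
    window: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean pre-trial pupil per outcome class with pairwise rank tests.

    Classes are ``correct`` (hits and correct rejects), ``hit`` and
    ``miss``; the pre-trial window is the ``window`` seconds before each
    trial's first event. Returns (group means, pairwise two-sided
    rank-sum p-values).
    """
    if pupil is None:
        raise ValueError("pupil trace required for pre-trial pupil analysis")
    act = trials[trials["state"] == "active"]
    first = act.groupby("trial").agg(onset=("onset_s", "min"),
                                     outcome=("outcome", "first"))
    values = {
        t: pupil.mean_in_window(row.onset - window, row.onset)
        for t, row in first.iterrows()
    }
    first = first.assign(pupil=[values[t] for t in first.index])
    groups = {
        "correct": first.loc[first["outcome"].isin(["hit", "correct_reject"]),
                             "pupil"].to_numpy(),
        "hit": first.loc[first["outcome"] == "hit", "pupil"].to_numpy(),
        "miss": first.loc[first["outcome"] == "miss", "pupil"].to_numpy(),
    }
    means = pd.DataFrame(
        [{"group": g, "mean_pupil": (np.mean(v) if len(v) else np.nan),
          "n": len(v)} for g, v in groups.items()]
    )
    rows = []
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = groups[a], groups[b]
            if len(va) and len(vb) and (np.ptp(np.concatenate([va, vb])) > 0):
                p = float(sps.mannwhitneyu(va, vb,
                                           alternative="two-sided").pvalue)
            else:
                p = 1.0
            rows.append({"group_a": a, "group_b": b, "pvalue": p})
    return means, pd.DataFrame(rows)
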