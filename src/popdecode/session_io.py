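"""Session-bundle reading/writing, pipeline configuration and the
end-to-end driver.

A session bundle on disk is a directory with ``trials.tsv`` (one row per
stimulus event), ``counts.h5`` (dataset ``counts``: neurons x events x
bins, with bin-width and window attributes), optional ``pupil.tsv``
(time, size) and an optional ``ground_truth.json`` sidecar holding the
generating parameters of synthetic sessions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import behavior, covariability, decoding, simulation, stats
from .preprocess import (EvokedResponseSet, PopulationCounts, PupilTrace,
                         evoked_response, regress_out_pupil)
from .synth import EVENT_COLUMNS, GroundTruth, SessionConfig

logger = logging.getLogger("popdecode")

TRIALS_FILE = "trials.tsv"
COUNTS_FILE = "counts.h5"
PUPIL_FILE = "pupil.tsv"
TRUTH_FILE = "ground_truth.json"


@dataclass
class PipelineConfig:
    """All analysis constants in one place.

    Defaults are the task/analysis constants: 20 ms bins, 100 ms
    baseline, 300 ms evoked window, 750 ms pupil lag, 30 ms PSTH
    smoothing, a 5-trial inclusion rule, 100 shuffle resamples, 1000
    bootstrap resamples, 2000 simulation samples, alpha 0.05.
    """

    sessions_dir: str = "."
    output_dir: str = "results"
    min_trials: int = 5
    bin_width: float = 0.02
    evoked_window: float = 0.3
    baseline_window: float = 0.1
    pupil_lag: float = 0.75
    smoothing_sigma: float = 0.03
    n_shuffles: int = 100
    n_boot: int = 1000
    n_sim_samples: int = 2000
    alpha: float = 0.05
    seed: int = 0
    pupil_correct: bool = True
    run_simulation: bool = True
    run_single_neuron: bool = False
    run_choice: bool = False
    fa_r_max: int = 3
    fa_folds: int = 5

    def validate(self) -> None:
        for name in ("bin_width", "evoked_window", "baseline_window",
                     "smoothing_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_trials < 2:
            raise ValueError("min_trials must be at least 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class Session:
    name: str
    trials: pd.DataFrame
    counts: PopulationCounts
    pupil: PupilTrace | None = None
    truth: GroundTruth | None = None


def _truth_to_json(truth: GroundTruth) -> dict:
    out = {}
    for f in dataclasses.fields(truth):
        v = getattr(truth, f.name)
        out[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
    return out


def _truth_from_json(data: dict) -> GroundTruth:
    arrays = {f.name for f in dataclasses.fields(GroundTruth)
              if f.type.startswith("np.ndarray")}
    kwargs = {}
    for f in dataclasses.fields(GroundTruth):
        v = data[f.name]
        if f.name in arrays and v is not None:
            v = np.asarray(v, float)
        kwargs[f.name] = v
    return GroundTruth(**kwargs)


def write_session(
    path: str | Path,
    trials: pd.DataFrame,
    counts: PopulationCounts,
    pupil: PupilTrace | None = None,
    truth: GroundTruth | None = None,
    config: SessionConfig | None = None,
) -> Path:
    """Write a session bundle; returns the bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path / TRIALS_FILE, sep="\t", index=False)
    with h5py.File(path / COUNTS_FILE, "w") as fh:
        ds = fh.create_dataset("counts", data=counts.counts)
        ds.attrs["bin_width_s"] = counts.bin_width
        ds.attrs["n_baseline_bins"] = counts.n_baseline_bins
        ds.attrs["n_evoked_bins"] = counts.n_evoked_bins
    if pupil is not None:
        pd.DataFrame({"time_s": pupil.time, "size_au": pupil.size}).to_csv(
            path / PUPIL_FILE, sep="\t", index=False
        )
    if truth is not None:
        sidecar = _truth_to_json(truth)
        if config is not None:
            sidecar["session_config"] = {
                k: (None if isinstance(v, float) and np.isinf(v) else v)
                for k, v in dataclasses.asdict(config).items()
                if isinstance(v, (int, float, str, bool))
            }
        with open(path / TRUTH_FILE, "w") as fh:
            json.dump(sidecar, fh, default=_json_default)
    return path


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_session(path: str | Path) -> Session:
    """Read and validate a session bundle."""
    path = Path(path)
    trials_path = path / TRIALS_FILE
    if not trials_path.exists():
        raise FileNotFoundError(f"no trial table at {trials_path}")
    trials = pd.read_csv(trials_path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    with h5py.File(path / COUNTS_FILE, "r") as fh:
        ds = fh["counts"]
        counts = PopulationCounts(
            counts=ds[()],
            events=trials,
            bin_width=float(ds.attrs["bin_width_s"]),
            n_baseline_bins=int(ds.attrs["n_baseline_bins"]),
            n_evoked_bins=int(ds.attrs["n_evoked_bins"]),
        )
    pupil = None
    pupil_path = path / PUPIL_FILE
    if pupil_path.exists():
        pdf = pd.read_csv(pupil_path, sep="\t")
        t = pdf["time_s"].to_numpy()
        pupil = PupilTrace(time=t, size=pdf["size_au"].to_numpy(),
                           dt=float(np.median(np.diff(t))) if len(t) > 1 else 0.1)
    else:
        logger.warning("read_session: no pupil trace in %s; pupil features "
                       "disabled", path)
    truth = None
    truth_path = path / TRUTH_FILE
    if truth_path.exists():
        with open(truth_path) as fh:
            data = json.load(fh)
        data.pop("session_config", None)
        truth = _truth_from_json(data)
    return Session(name=path.name, trials=trials, counts=counts,
                   pupil=pupil, truth=truth)


def prepare_responses(session: Session,
                      config: PipelineConfig) -> EvokedResponseSet:
    """Evoked responses for one session, pupil-corrected when configured."""
    ers = evoked_response(session.counts)
    if config.pupil_correct and session.pupil is not None:
        session.pupil.lag = config.pupil_lag
        ers, _ = regress_out_pupil(
            ers, session.pupil,
            evoked_window=config.evoked_window,
            baseline_window=config.baseline_window,
        )
    return ers


def analyze_session(session: Session, config: PipelineConfig) -> dict:
    """Single-session stage of the pipeline: behavior, decoding, factor
    metrics and (optionally) the ablation simulation."""
    ers = prepare_responses(session, config)
    out: dict = {"name": session.name}

    out["behavior"] = behavior.psychometric_table(session.trials).table
    results = decoding.pairwise_decoding(ers, min_trials=config.min_trials)
    out["decoding"] = decoding.results_frame(results, session=session.name)
    if results:
        out["category_delta_norm"] = decoding.category_summary(results)

    fa_rows = []
    for state in ("active", "passive"):
        x = decoding.class_matrix(ers, "catch", state)
        if len(x) < max(config.min_trials, config.fa_folds):
            continue
        r_hi = min(config.fa_r_max, x.shape[1] - 1, len(x) - 2)
        rank, _ = covariability.select_dimensionality(
            x, r_hi, n_folds=config.fa_folds, seed=config.seed
        )
        fit = covariability.fit_fa(x, rank, seed=config.seed)
        targets = [s for s in ers.events.loc[
            ers.events["category"] == "target", "stimulus"].unique()]
        aligns = []
        for t in targets:
            mt = decoding.class_matrix(ers, t, state)
            if len(mt) < config.min_trials or len(x) < config.min_trials:
                continue
            dmu = mt.mean(0) - x.mean(0)
            if np.linalg.norm(dmu) == 0 or rank < 1:
                continue
            aligns.append(covariability.alignment(
                covariability.dominant_factor(fit), dmu))
        fa_rows.append({
            "session": session.name, "state": state, "rank": rank,
            "loading_similarity": (covariability.loading_similarity(fit)
                                   if rank >= 1 else np.nan),
            "percent_shared_variance": covariability.percent_shared_variance(fit),
            "alignment": float(np.mean(aligns)) if aligns else np.nan,
        })
    out["covariability"] = pd.DataFrame(fa_rows)

    if config.run_single_neuron:
        from . import single_neuron

        out["single_neuron"] = single_neuron.neuron_table(
            ers, n_shuffles=config.n_shuffles, seed=config.seed,
            min_trials=config.min_trials,
        )

    if config.run_choice:
        choice: dict = {}
        targets = ers.events.loc[ers.events["category"] == "target",
                                 "stimulus"].unique()
        for t in sorted(targets):
            hits = ers.matrix(t, "active", outcomes=("hit",))
            misses = ers.matrix(t, "active", outcomes=("miss",))
            if min(len(hits), len(misses)) < config.min_trials:
                continue
            entry = {"choice_probability":
                     decoding.choice_probability(hits, misses,
                                                 min_trials=config.min_trials)}
            try:
                entry["ablation"] = simulation.choice_ablation(
                    ers, t, n_samples=config.n_sim_samples,
                    seed=config.seed, r_max=config.fa_r_max,
                    n_folds=config.fa_folds,
                )
            except ValueError as err:
                logger.info("choice ablation skipped for %s: %s", t, err)
            choice[t] = entry
        out["choice"] = choice

    if config.run_simulation:
        out["simulation"] = simulation.run_ablation(
            ers, n_samples=config.n_sim_samples, seed=config.seed,
            r_max=config.fa_r_max, n_folds=config.fa_folds,
        )
        try:
            out["selective_enhancement"] = simulation.selective_enhancement(
                results)
        except ValueError:
            logger.info("analyze_session: selective enhancement undefined "
                        "for %s", session.name)
    return out


def run_pipeline(config: PipelineConfig,
                 sessions: list[Session] | None = None) -> dict:
    """End-to-end driver over a directory of session bundles.

    Per session: evoked responses (pupil-corrected), behavioral
    psychometrics, pairwise dDR decoding, catch-stimulus factor metrics
    and the four-model ablation. Across sessions: Wilcoxon category
    comparisons on session-mean normalized Δd', the neural-behavioral
    correlation over (session, target) pairs, and the ablation model
    comparison. Tables and a JSON report are written to the output
    directory.
    """
    config.validate()
    if sessions is None:
        root = Path(config.sessions_dir)
        paths = sorted(p.parent for p in root.glob(f"*/{TRIALS_FILE}"))
        if not paths:
            raise FileNotFoundError(f"no session bundles under {root}")
        sessions = [read_session(p) for p in paths]
    if not sessions:
        raise ValueError("at least one session required")

    per_session = [analyze_session(s, config) for s in sessions]
    report: dict = {
        "seed": config.seed,
        "n_sessions": len(sessions),
        "sessions": [r["name"] for r in per_session],
    }

    cats = pd.DataFrame([r["category_delta_norm"] for r in per_session
                         if "category_delta_norm" in r])
    report["category_means"] = cats.mean().to_dict()
    tests = {}
    pairs = [("target_vs_catch", "target_vs_target"),
             ("target_vs_catch", "distractor_vs_distractor"),
             ("target_vs_target", "distractor_vs_distractor")]
    for a, b in pairs:
        if a in cats.columns and b in cats.columns:
            res = stats.paired_wilcoxon(cats[a].to_numpy(),
                                        cats[b].to_numpy(),
                                        alpha=config.alpha,
                                        name=f"{a}__vs__{b}")
            tests[res.name] = dataclasses.asdict(res)
    report["category_tests"] = tests

    # neural Δd' (raw, target-vs-catch) against behavioral d', one pair
    # per (session, target)
    neural, behav = [], []
    for sess, res in zip(sessions, per_session):
        dec = res["decoding"]
        beh = res["behavior"]
        tvc = dec[dec["category"] == "target_vs_catch"]
        for _, row in tvc.iterrows():
            match = beh[beh["stimulus"] == row["stim_a"]]
            if len(match):
                neural.append(row["delta"])
                behav.append(float(match["dprime"].iloc[0]))
    if len(neural) >= 3 and np.std(behav) > 0:
        corr = stats.neural_behavior_correlation(
            np.array(neural), np.array(behav),
            n_boot=config.n_boot, seed=config.seed,
        )
        report["neural_behavior"] = dataclasses.asdict(corr)

    if config.run_simulation:
        actual = np.array([r.get("selective_enhancement", np.nan)
                           for r in per_session])
        sims = {m: np.array([r["simulation"][m] for r in per_session])
                for m in simulation.MODELS}
        ok = ~np.isnan(actual)
        if ok.sum() >= 3:
            comp = simulation.model_comparison(
                {m: v[ok] for m, v in sims.items()}, actual[ok],
                n_boot=config.n_boot, seed=config.seed,
            )
            report["model_comparison"] = {
                m: {"r": c.r, "boot_q975": c.boot_quantile_975,
                    "significantly_worse": c.significantly_worse}
                for m, c in comp.items()
            }
            report["selective_enhancement"] = {
                "actual_mean": float(np.mean(actual[ok])),
                "per_model_mean": {m: float(np.mean(v[ok]))
                                   for m, v in sims.items()},
            }

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.concat([r["decoding"] for r in per_session]).to_csv(
        out_dir / "decoding.tsv", sep="\t", index=False)
    pd.concat([r["covariability"] for r in per_session]).to_csv(
        out_dir / "covariability.tsv", sep="\t", index=False)
    pd.concat([r["behavior"].assign(session=r["name"])
               for r in per_session]).to_csv(
        out_dir / "behavior.tsv", sep="\t", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report
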