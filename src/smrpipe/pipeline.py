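"""End-to-end driver: epochs -> sources -> ERDd table -> patterns.

One :class:`PipelineConfig` object collects every fixed constant of the
analysis (bands, windows, rejection threshold, fold counts, seeds) and
round-trips through JSON, so a rerun with the same config and inputs
bit-reproduces all deterministic outputs.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import erdd as _erdd
from .ged import crossval_ged, select_erd_sources
from .montage import CHANNELS
from .preprocess import (EpochedEEG, bandpass_fir, reject_outlier_trials,
                         trial_covariances)


@dataclass
class PipelineConfig:
    """All tunable constants of the offline analysis."""

    montage: tuple = tuple(CHANNELS)
    fir_band: tuple[float, float] = (3.0, 48.0)
    ged_band: tuple[float, float] = (7.0, 27.0)
    classifier_band: tuple[float, float] = (6.0, 40.0)
    feature_search: tuple[float, float] = (7.0, 26.0)
    window: tuple[float, float] = (2.0, 6.0)
    rejection_sd: float = 2.0
    ged_folds: int = 10
    n_erd_sources: int = 2
    n_candidate_components: int = 8
    n_permutations: int = 100_000
    lrt_sims: int = 1000
    seed: int = 0

    def __post_init__(self):
        nyq = 250.0
        for name in ("fir_band", "ged_band", "classifier_band",
                     "feature_search"):
            band = getattr(self, name)
            if not (0 < band[0] < band[1] < nyq):
                raise ValueError(f"{name}={band} outside (0, {nyq}) Hz")
        if not self.window[0] < self.window[1]:
            raise ValueError("window start must precede its end")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            source = Path(source).read_text()
        raw = json.loads(source)
        for key, value in raw.items():
            if isinstance(value, list):
                raw[key] = tuple(tuple(v) if isinstance(v, list) else v
                                 for v in value)
        return cls(**raw)


def _hemisphere(pattern: np.ndarray) -> str:
    """left / right / midline by the side of the largest-|w| electrode."""
    ch = CHANNELS[int(np.argmax(np.abs(pattern)))]
    tail = ch[-1].lower()
    if tail == "z":
        return "midline"
    return "left" if int(tail) % 2 else "right"


@dataclass
class SessionResult:
    """Per-session spatial decomposition and run-level ERDd scores."""

    decomposition: object
    profile: np.ndarray            # candidate components x frequency bins
    freqs: np.ndarray
    selected: np.ndarray           # indices into the candidate components
    feature_bands: list
    hemispheres: list[str]
    erdd_table: pd.DataFrame
    keep_mask: np.ndarray          # per-trial retention after rejection


def analyze_session(eeg: EpochedEEG, config: PipelineConfig | None = None
                    ) -> SessionResult:
    """Run one session through filtering, rejection, GED and ERDd scoring.

    The run-level ERDd response is the mean score of the two strongest
    ERD sources, each evaluated on its own selected frequency band,
    comparing imagery against visual-attention windows within each run.
    """
    config = config or PipelineConfig()
    eeg = bandpass_fir(eeg, *config.fir_band)
    info = eeg.trial_info
    cond = info["condition"].to_numpy()

    # per-condition covariance homogeneity rejection
    keep = np.ones(eeg.n_trials, dtype=bool)
    cov_sets = {}
    for label in ("imagery", "visual_attention"):
        idx = np.flatnonzero(cond == label)
        covs = trial_covariances(eeg.select(idx), band=config.ged_band,
                                 window=config.window)
        covs = reject_outlier_trials(covs, n_sd=config.rejection_sd)
        keep[idx] = covs.keep_mask
        cov_sets[label] = covs

    dec = crossval_ged(cov_sets["imagery"], cov_sets["visual_attention"],
                       k=config.ged_folds, seed=config.seed)

    n_cand = min(config.n_candidate_components, dec.n_components)
    W_cand = dec.W[:, :n_cand]
    power = _erdd.stft_power(
        _erdd.component_signals(eeg, W_cand), fs=eeg.fs,
        trial_info=info, cue_onset_s=eeg.cue_onset_s)
    profile = _erdd.erdd_profile(power, window=config.window, keep_mask=keep)

    in_range = (power.freqs >= config.feature_search[0]) & \
        (power.freqs <= config.feature_search[1])
    per_comp = np.where(in_range, profile, 0.0).min(axis=1)
    from .ged import SpatialDecomposition
    cand = SpatialDecomposition(W_cand, dec.eigenvalues[:n_cand],
                                dec.A[:, :n_cand])
    selected = select_erd_sources(cand, per_comp, n=config.n_erd_sources)

    bands_all = {fb.component: fb for fb in _erdd.select_feature_bands(
        profile, power.freqs, search_range=config.feature_search,
        polarity="ERD")}
    feature_bands = [bands_all[j] for j in selected if j in bands_all]
    hemispheres = [_hemisphere(dec.A[:, j]) for j in selected]

    frames = power.frames_in(config.window)
    rows = []
    for (day, run), grp in info.groupby(["day", "run"], sort=True):
        gidx = grp.index.to_numpy()
        act = gidx[(cond[gidx] == "imagery") & keep[gidx]]
        ref = gidx[(cond[gidx] == "visual_attention") & keep[gidx]]
        if len(act) == 0 or len(ref) == 0:
            warnings.warn(f"run {run} of day {day} lost a whole condition",
                          UserWarning, stacklevel=2)
            continue
        scores = []
        for fb in feature_bands:
            bp = _erdd.band_power(power, fb)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                scores.append(_erdd.erdd_score(bp[act][:, frames],
                                               bp[ref][:, frames]))
        if not scores:
            continue
        first = grp.iloc[0]
        fb_flag = bool(first.get("feedback_flag", False))
        itype = first.get("imagery_type", "FR")
        rows.append({
            "subject": first.get("subject", "unknown"),
            "day": int(day), "run": int(run), "imageryType": itype,
            "isFeedbacked": fb_flag,
            "videoORfeed": ("video" if itype == "TRv"
                            else "feedback" if fb_flag else "no_feedback"),
            "ERDd": float(np.mean(scores)),
        })

    return SessionResult(
        decomposition=dec, profile=profile, freqs=power.freqs,
        selected=selected, feature_bands=feature_bands,
        hemispheres=hemispheres, erdd_table=pd.DataFrame(rows),
        keep_mask=keep,
    )


def match_sources_across_days(results: list[SessionResult]) -> np.ndarray:
    """Stack day-wise patterns of matching sources: (source, day, channel).

    Sources of later days are matched to day 1 greedily by absolute
    pattern correlation (forward-model signs are arbitrary and day-wise
    eigenvalue order may swap the ipsi/contralateral pair).
    """
    n_sources = min(len(r.selected) for r in results)
    if n_sources == 0:
        raise ValueError("a session has no selected ERD source")
    ref = results[0]
    ref_patterns = [ref.decomposition.A[:, j]
                    for j in ref.selected[:n_sources]]
    out = np.zeros((n_sources, len(results), len(ref_patterns[0])))
    for d, res in enumerate(results):
        avail = list(res.selected)
        for s, rp in enumerate(ref_patterns):
            rhos = [abs(np.corrcoef(rp, res.decomposition.A[:, j])[0, 1])
                    for j in avail]
            pick = avail.pop(int(np.argmax(rhos)))
            out[s, d] = res.decomposition.A[:, pick]
    return out


def run_pipeline(
    sessions: list[EpochedEEG],
    config: PipelineConfig | None = None,
) -> dict:
    """Analyze a list of sessions (days); collect table and patterns.

    Returns a dict with per-day :class:`SessionResult`s, the pooled
    run-level ERDd table, and — when at least two days are present —
    the per-source pattern stack for cross-day correlation analysis.
    """
    config = config or PipelineConfig()
    if not sessions:
        raise ValueError("no sessions to analyze")
    results = []
    for i, eeg in enumerate(sessions):
        try:
            results.append(analyze_session(eeg, config))
        except Exception as err:
            raise RuntimeError(f"stage 'analyze_session' failed on "
                               f"session {i}: {err}") from err
    table = pd.concat([r.erdd_table for r in results], ignore_index=True)
    out = {"config": config, "sessions": results, "erdd_table": table}
    if len(results) >= 2:
        try:
            out["patterns"] = match_sources_across_days(results)
        except ValueError as err:
            warnings.warn(f"pattern matching skipped: {err}", UserWarning,
                          stacklevel=2)
    return out
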