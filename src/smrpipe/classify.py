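"""Offline replica of the online motor-imagery classifier.

The online chain had four steps: 4th-order Butterworth band-pass at
6-40 Hz; GED spatial filters from the imagery/visual-attention
covariances; short-time Fourier power (1 s Hann windows, 90 % overlap);
and a Gaussian naive Bayes classifier on log band-power for the five
spatial-filter x frequency-range combinations with the most divergent
power distributions (largest |ERDd|).  Two evaluation schemes are
provided: five repetitions of two-fold cross-validation, and an
expanding-window chronological ("time-series") scheme where each trial
is classified by a model trained on all strictly earlier trials.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from . import erdd as _erdd
from .ged import ged
from .preprocess import EpochedEEG

CLASSIFIER_BAND = (6.0, 40.0)
BUTTER_ORDER = 4
N_FEATURES = 5
DECISION_WINDOW = (2.0, 6.0)
ERS_SEARCH_RANGE = (7.0, 30.0)  # ERS peaks may sit above the 26 Hz ERD cap

CLASSES = ("imagery", "visual_attention")


@dataclass
class ClassifierModel:
    """Spatial filters, feature bands and Gaussian class-conditionals."""

    spatial_filters: np.ndarray            # (n_ch, n_selected_components)
    feature_bands: list                    # FeatureBand, component indexes
    class_means: np.ndarray                # (2, n_features) log-power means
    class_vars: np.ndarray                 # (2, n_features)
    log_priors: np.ndarray                 # (2,)
    band: tuple[float, float] = CLASSIFIER_BAND
    butter_order: int = BUTTER_ORDER
    fs: float = 500.0
    feature_set: str = "erd"

    @property
    def n_features(self) -> int:
        return len(self.feature_bands)


@dataclass
class CVResult:
    """Cross-validated accuracy and classifier-output time courses."""

    scheme: str                       # "fivebytwo" or "timeseries"
    feature_set: str
    fold_accuracies: np.ndarray       # window-averaged accuracy per fold/trial
    accuracy: float                   # mean window-averaged accuracy in 2-6 s
    accuracy_majority: float          # trial accuracy by window majority vote
    time_course: np.ndarray           # mean P(imagery) per frame, imagery trials
    time_course_reference: np.ndarray  # same for visual-attention trials
    frame_starts: np.ndarray


def _butter_filter(data: np.ndarray, fs: float,
                   band=CLASSIFIER_BAND, order=BUTTER_ORDER) -> np.ndarray:
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def _feature_matrix(model: ClassifierModel, power) -> np.ndarray:
    """(trials, frames, n_features) log band-power features."""
    feats = [np.log(np.maximum(_erdd.band_power(power, fb), 1e-300))
             for fb in model.feature_bands]
    return np.stack(feats, axis=-1)


def _component_power(eeg: EpochedEEG, W: np.ndarray,
                     band, order) -> "_erdd.ComponentPowerSeries":
    filtered = _butter_filter(eeg.data, eeg.fs, band, order)
    comps = np.einsum("cj,tcs->tjs", W, filtered)
    return _erdd.stft_power(comps, fs=eeg.fs, trial_info=eeg.trial_info,
                            cue_onset_s=eeg.cue_onset_s)


def train_classifier(
    train: EpochedEEG,
    feature_set: str = "erd",
    n_features: int = N_FEATURES,
    window: tuple[float, float] = DECISION_WINDOW,
) -> ClassifierModel:
    """Fit the four-step model on labelled trials.

    ``feature_set`` is ``"erd"`` (negative-ERDd features only, as used
    online) or ``"erd+ers"`` (both polarities, adding e.g. the occipital
    alpha synchronization).  Features are ranked by the |ERDd| of their
    band-averaged power and the top ``n_features`` are kept.
    """
    labels = train.trial_info["condition"].to_numpy()
    counts = {c: int((labels == c).sum()) for c in CLASSES}
    if min(counts.values()) == 0:
        raise ValueError(f"both classes required, got {counts}")
    if min(counts.values()) < 5:
        warnings.warn(f"very few trials per class: {counts}", UserWarning,
                      stacklevel=2)

    filtered = _butter_filter(train.data, train.fs)
    times = train.times
    sel = (times >= window[0]) & (times < window[1])
    act = filtered[labels == CLASSES[0]][:, :, sel]
    ref = filtered[labels == CLASSES[1]][:, :, sel]

    def _mean_cov(segs):
        segs = segs - segs.mean(axis=2, keepdims=True)
        return np.einsum("tcs,tds->cd", segs, segs) / (
            segs.shape[0] * (segs.shape[2] - 1))

    dec = ged(_mean_cov(act), _mean_cov(ref))
    # ERD sources live at the small-eigenvalue end of the spectrum, ERS
    # (e.g. occipital alpha) at the large end; restrict the search there.
    n_comp = dec.n_components
    erd_cols = np.arange(min(8, n_comp))
    ers_cols = np.arange(max(0, n_comp - 4), n_comp)
    cols = erd_cols if feature_set == "erd" else \
        np.unique(np.concatenate([erd_cols, ers_cols]))
    if feature_set not in ("erd", "erd+ers"):
        raise ValueError("feature_set must be 'erd' or 'erd+ers'")
    W_cand = dec.W[:, cols]
    power = _component_power(train, W_cand, CLASSIFIER_BAND, BUTTER_ORDER)
    profile = _erdd.erdd_profile(power, window=window)

    candidates = list(_erdd.select_feature_bands(
        profile, power.freqs, polarity="ERD"))
    if feature_set == "erd+ers":
        candidates += _erdd.select_feature_bands(
            profile, power.freqs, search_range=ERS_SEARCH_RANGE,
            polarity="ERS")

    # re-score each candidate on its band-averaged power, then keep top-n
    scored = []
    cond = power.trial_info["condition"].to_numpy()
    frames = power.frames_in(window)
    for fb in candidates:
        bp = _erdd.band_power(power, fb)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            score = _erdd.erdd_score(bp[cond == CLASSES[0]][:, frames],
                                     bp[cond == CLASSES[1]][:, frames])
        if (feature_set == "erd" and score >= 0):
            continue
        scored.append((abs(score), fb))
    scored.sort(key=lambda t: -t[0])
    selected = [fb for _, fb in scored[:n_features]]
    if not selected:
        raise ValueError("no divergent spatio-spectral feature found")

    comp_idx = sorted({fb.component for fb in selected})
    remap = {c: i for i, c in enumerate(comp_idx)}
    W_sel = W_cand[:, comp_idx]
    bands = [_erdd.FeatureBand(remap[fb.component], fb.band, fb.peak_freq,
                               fb.peak_score, fb.polarity) for fb in selected]

    model = ClassifierModel(
        spatial_filters=W_sel,
        feature_bands=bands,
        class_means=np.zeros((2, len(bands))),
        class_vars=np.ones((2, len(bands))),
        log_priors=np.log([0.5, 0.5]),
        fs=train.fs,
        feature_set=feature_set,
    )
    # component projections are independent, so reuse the candidate power
    power_sel = _erdd.ComponentPowerSeries(
        power=power.power[:, comp_idx], freqs=power.freqs,
        frame_starts=power.frame_starts, window_s=power.window_s,
        trial_info=power.trial_info)
    feats = _feature_matrix(model, power_sel)[:, frames, :]
    for k, cls in enumerate(CLASSES):
        x = feats[cond == cls].reshape(-1, len(bands))
        model.class_means[k] = x.mean(axis=0)
        model.class_vars[k] = np.maximum(x.var(axis=0), 1e-12)
    return model


def posterior_from_features(model: ClassifierModel,
                            features: np.ndarray) -> np.ndarray:
    """Naive Bayes posterior P(imagery | features), features (..., n_feat)."""
    x = np.asarray(features, float)[..., None, :]  # broadcast over classes
    log_lik = -0.5 * (np.log(2 * np.pi * model.class_vars)
                      + (x - model.class_means) ** 2 / model.class_vars)
    joint = log_lik.sum(axis=-1) + model.log_priors
    joint -= joint.max(axis=-1, keepdims=True)
    post = np.exp(joint)
    post /= post.sum(axis=-1, keepdims=True)
    return post[..., 0]


def classify_windows(model: ClassifierModel, trial: np.ndarray,
                     fs: float | None = None,
                     cue_onset_s: float = 0.0):
    """Per-STFT-window posterior of the imagery class for one trial.

    ``trial`` is (n_channels, n_samples).  Returns (frame_starts,
    posterior) with one probability per 1 s analysis window.
    """
    fs = fs or model.fs
    trial = np.asarray(trial, float)
    if trial.shape[1] < int(model.fs):
        raise ValueError("trial shorter than the 1 s analysis window")
    eeg_like = trial[None, :, :]
    filtered = _butter_filter(eeg_like, fs, model.band, model.butter_order)
    comps = np.einsum("cj,tcs->tjs", model.spatial_filters, filtered)
    power = _erdd.stft_power(comps, fs=fs, cue_onset_s=cue_onset_s)
    feats = _feature_matrix(model, power)
    return power.frame_starts, posterior_from_features(model, feats)[0]


def _evaluate(model: ClassifierModel, test: EpochedEEG,
              window=DECISION_WINDOW):
    """Per-trial window accuracy, majority correctness and P(imagery)."""
    power = _component_power(test, model.spatial_filters,
                             model.band, model.butter_order)
    feats = _feature_matrix(model, power)
    post = posterior_from_features(model, feats)   # (trials, frames)
    frames = power.frames_in(window)
    labels = test.trial_info["condition"].to_numpy()
    is_imagery = labels == CLASSES[0]
    correct = np.where(is_imagery[:, None], post > 0.5, post < 0.5)
    win_acc = correct[:, frames].mean(axis=1)
    majority = correct[:, frames].mean(axis=1) > 0.5
    return win_acc, majority, post, power.frame_starts, is_imagery


def _result(scheme, feature_set, fold_acc, win_acc, majority, posts,
            frame_starts, is_imagery):
    posts = np.concatenate(posts) if isinstance(posts, list) else posts
    return CVResult(
        scheme=scheme,
        feature_set=feature_set,
        fold_accuracies=np.asarray(fold_acc, float),
        accuracy=float(np.mean(win_acc)),
        accuracy_majority=float(np.mean(majority)),
        time_course=posts[is_imagery].mean(axis=0)
        if is_imagery.any() else np.full(posts.shape[1], np.nan),
        time_course_reference=posts[~is_imagery].mean(axis=0)
        if (~is_imagery).any() else np.full(posts.shape[1], np.nan),
        frame_starts=frame_starts,
    )


def cv_5x2(trials: EpochedEEG, feature_set: str = "erd",
           seed: int = 0, n_repeats: int = 5) -> CVResult:
    """Five seeded stratified halvings, trained/tested in both directions.

    The headline accuracy is the mean over the 10 fold-tests of the
    fraction of correctly classified 1 s windows inside the 2-6 s
    decision interval.
    """
    labels = trials.trial_info["condition"].to_numpy()
    idx_by_class = [np.flatnonzero(labels == c) for c in CLASSES]
    if min(len(i) for i in idx_by_class) < 2:
        raise ValueError("need at least 2 trials per class to halve")
    rng = np.random.default_rng(seed)
    fold_acc, all_acc, all_maj, posts, flags = [], [], [], [], []
    frame_starts = None
    for _ in range(n_repeats):
        half_a, half_b = [], []
        for idx in idx_by_class:
            perm = rng.permutation(idx)
            half_a.extend(perm[: len(perm) // 2])
            half_b.extend(perm[len(perm) // 2:])
        for tr_idx, te_idx in ((half_a, half_b), (half_b, half_a)):
            model = train_classifier(trials.select(np.array(tr_idx)),
                                     feature_set)
            wa, mj, post, fstarts, flag = _evaluate(
                model, trials.select(np.array(te_idx)))
            fold_acc.append(wa.mean())
            all_acc.extend(wa)
            all_maj.extend(mj)
            posts.append(post)
            flags.append(flag)
            frame_starts = fstarts
    return _result("fivebytwo", feature_set, fold_acc, all_acc, all_maj,
                   posts, frame_starts, np.concatenate(flags))


def cv_timeseries(trials: EpochedEEG, feature_set: str = "erd",
                  warmup_trials: int = 12) -> CVResult:
    """Expanding-window chronological cross-validation.

    Trials must carry ``run`` and ``trial`` ordering columns; each trial
    after the warm-up (first run by default) is classified by a model
    trained on all strictly earlier trials.
    """
    info = trials.trial_info
    for col in ("run", "trial"):
        if col not in info.columns:
            raise ValueError(
                f"chronological order requires a {col!r} column in trial_info")
    order = np.lexsort((info["trial"].to_numpy(), info["run"].to_numpy()))
    ordered = trials.select(order)
    n = ordered.n_trials
    if n <= warmup_trials:
        raise ValueError("need at least one full run after the warm-up set")
    fold_acc, all_maj, posts, flags = [], [], [], []
    frame_starts = None
    for i in range(warmup_trials, n):
        model = train_classifier(ordered.select(np.arange(i)), feature_set)
        wa, mj, post, fstarts, flag = _evaluate(
            model, ordered.select(np.array([i])))
        fold_acc.append(wa[0])
        all_maj.append(mj[0])
        posts.append(post)
        flags.append(flag)
        frame_starts = fstarts
    return _result("timeseries", feature_set, fold_acc, fold_acc, all_maj,
                   posts, frame_starts, np.concatenate(flags))
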