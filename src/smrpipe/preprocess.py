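"""Filtering, epoch containers, per-trial covariances and trial rejection.

The preprocessing chain mirrors a standard motor-imagery BCI analysis:
a zero-phase band-pass FIR (3-48 Hz) cleans the broadband signal, trial
covariances are computed in the sensorimotor-rhythm band (7-27 Hz) over
the steady-state part of each trial, and trials whose covariance matrix
is far (Frobenius distance > mean + 2 SD) from the elementwise-median
covariance are discarded before any spatial decomposition.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .montage import validate_channels

#: transition width (Hz) of the windowed-sinc FIR designs
FIR_TRANSITION_HZ = 2.0


@dataclass
class EpochedEEG:
    """Trial-segmented multichannel EEG.

    ``data`` is (n_trials, n_channels, n_samples) in microvolts; trial
    time 0 is the cue onset.  ``trial_info`` carries one row per trial
    with at least ``condition`` (``imagery`` / ``visual_attention``),
    ``imagery_type``, ``day``, ``run`` and ``feedback_flag``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    trial_info: pd.DataFrame
    cue_onset_s: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        self.channel_names = validate_channels(self.channel_names)
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel count does not match channel_names")
        if len(self.trial_info) != self.data.shape[0]:
            raise ValueError("trial_info length does not match trial count")
        self.trial_info = self.trial_info.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[2]) / self.fs - self.cue_onset_s

    def select(self, mask) -> "EpochedEEG":
        """Subset trials by boolean mask or integer index array."""
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            trial_info=self.trial_info.iloc[mask].reset_index(drop=True),
        )


@dataclass
class TrialCovarianceSet:
    """Per-trial covariance matrices with a keep mask."""

    matrices: np.ndarray  # (n_trials, n_ch, n_ch)
    band: tuple[float, float]
    window: tuple[float, float]
    keep_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.keep_mask is None:
            self.keep_mask = np.ones(len(self.matrices), dtype=bool)
        self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
        if len(self.keep_mask) != len(self.matrices):
            raise ValueError("keep_mask length mismatch")

    @property
    def kept(self) -> np.ndarray:
        return self.matrices[self.keep_mask]

    def mean(self) -> np.ndarray:
        return self.kept.mean(axis=0)


def design_fir(low: float, high: float, fs: float) -> np.ndarray:
    """Windowed-sinc (Hamming) band-pass FIR with ~2 Hz transition bands."""
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz outside (0, {nyq}) Hz")
    # Hamming window: transition width ~ 3.3 / numtaps (normalised)
    numtaps = int(np.ceil(3.3 * fs / FIR_TRANSITION_HZ))
    numtaps += 1 - numtaps % 2  # odd for a type-I linear-phase filter
    return signal.firwin(numtaps, [low, high], pass_zero=False, fs=fs,
                         window="hamming")


def bandpass_fir(eeg: EpochedEEG, low: float, high: float) -> EpochedEEG:
    """Zero-phase band-pass FIR filtering (forward-backward application).

    The default offline broadband filter of the pipeline is 3-48 Hz.
    Zero-phase filtering squares the magnitude response, so the stop-band
    attenuation of the Hamming design (>50 dB single-pass) is doubled.
    """
    taps = design_fir(low, high, eeg.fs)
    n_samples = eeg.data.shape[2]
    if n_samples <= 3 * len(taps):
        raise ValueError(
            f"trials of {n_samples} samples are shorter than 3 filter "
            f"lengths ({3 * len(taps)}); use a wider band or longer trials"
        )
    filtered = signal.filtfilt(taps, [1.0], eeg.data, axis=2)
    return replace(eeg, data=filtered)


def trial_covariances(
    eeg: EpochedEEG,
    band: tuple[float, float] = (7.0, 27.0),
    window: tuple[float, float] = (2.0, 6.0),
) -> TrialCovarianceSet:
    """Per-trial sample covariance of the band-filtered window.

    Band defaults to the sensorimotor mu+beta range (7-27 Hz); the window
    defaults to the 2-6 s steady-state interval after the cue.
    """
    times = eeg.times
    sel = (times >= window[0]) & (times < window[1])
    if not sel.any():
        raise ValueError(f"window {window} s contains no samples")
    filtered = bandpass_fir(eeg, *band)
    segs = filtered.data[:, :, sel]
    segs = segs - segs.mean(axis=2, keepdims=True)
    n = segs.shape[2]
    covs = np.einsum("tcs,tds->tcd", segs, segs) / (n - 1)
    return TrialCovarianceSet(matrices=covs, band=tuple(band), window=tuple(window))


def reject_outlier_trials(
    covs: TrialCovarianceSet, n_sd: float = 2.0
) -> TrialCovarianceSet:
    """Mask trials whose covariance is far from the median covariance.

    The distance of trial *i* is the Frobenius norm of C_i minus the
    elementwise median matrix over currently-kept trials; trials with
    distance above mean + ``n_sd``*SD of the distances are masked out.
    Rejection never empties the set, and with fewer than 3 kept trials a
    warning is emitted and the mask is returned unchanged.
    """
    keep = covs.keep_mask.copy()
    idx = np.flatnonzero(keep)
    if len(idx) < 3:
        warnings.warn(
            "fewer than 3 trials: covariance-homogeneity rejection skipped",
            UserWarning,
            stacklevel=2,
        )
        return TrialCovarianceSet(covs.matrices, covs.band, covs.window, keep)
    med = np.median(covs.matrices[idx], axis=0)
    dist = np.linalg.norm(covs.matrices[idx] - med, axis=(1, 2))
    thresh = dist.mean() + n_sd * dist.std(ddof=0)
    bad = dist > thresh
    if bad.all():  # pathological: keep the closest trial
        bad[np.argmin(dist)] = False
    keep[idx[bad]] = False
    return TrialCovarianceSet(covs.matrices, covs.band, covs.window, keep)
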