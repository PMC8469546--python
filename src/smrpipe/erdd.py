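"""Component-space spectral power and the ERDd distribution-overlap score.

ERD strength is quantified without assuming any shape for the power
distribution: for a component and frequency bin, the score is

    ERDd = +/- 100 * (1/2) * integral |f_active(p) - f_reference(p)| dp

i.e. 100 times the total-variation distance between the estimated
probability densities of the spectral power in the active (imagery) and
reference (visual attention) conditions, signed negative when the
active-condition median power is the lower one (desynchronization) and
positive otherwise (synchronization).  Densities are estimated on log
power, where the heavy-tailed power distribution is well behaved.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import hann

from .preprocess import EpochedEEG

#: STFT defaults: 1 s Hann windows with 90 % overlap
WINDOW_S = 1.0
OVERLAP = 0.9

#: feature-selection defaults
SEARCH_RANGE = (7.0, 26.0)
REL_THRESHOLD = 0.30


@dataclass
class ComponentPowerSeries:
    """STFT power of component signals, trial labels carried through.

    ``power`` is (n_trials, n_components, n_frames, n_bins); each frame
    covers ``[frame_starts[i], frame_starts[i] + window_s)`` seconds
    relative to the cue; bins are spaced 1 Hz (1 s windows at 500 Hz).
    """

    power: np.ndarray
    freqs: np.ndarray
    frame_starts: np.ndarray
    window_s: float
    trial_info: pd.DataFrame

    def frames_in(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask of frames lying fully inside ``window`` (seconds)."""
        eps = 1e-9
        return (self.frame_starts >= window[0] - eps) & \
            (self.frame_starts + self.window_s <= window[1] + eps)

    def bin_index(self, freq_hz: float) -> int:
        return int(np.argmin(np.abs(self.freqs - freq_hz)))


def component_signals(eeg: EpochedEEG, W: np.ndarray) -> np.ndarray:
    """Project epochs through spatial filters: (trials, comps, samples)."""
    return np.einsum("cj,tcs->tjs", W, eeg.data)


def stft_power(
    signals: np.ndarray,
    fs: float = 500.0,
    trial_info: pd.DataFrame | None = None,
    window_s: float = WINDOW_S,
    overlap: float = OVERLAP,
    max_freq: float = 48.0,
    cue_onset_s: float = 0.0,
) -> ComponentPowerSeries:
    """Short-time Fourier power: Hann frames, 90 % overlap, 1 Hz bins.

    ``signals`` is (n_trials, n_components, n_samples); frames are the
    squared magnitudes of the one-sided DFT of Hann-windowed segments
    starting at multiples of the hop (50 samples at 500 Hz).
    """
    signals = np.atleast_3d(np.asarray(signals, float))
    n_samples = signals.shape[2]
    nwin = int(round(window_s * fs))
    hop = max(1, int(round(nwin * (1 - overlap))))
    if n_samples < nwin:
        raise ValueError(
            f"trial of {n_samples} samples is shorter than the {nwin}-sample "
            "analysis window")
    starts = np.arange(0, n_samples - nwin + 1, hop)
    win = hann(nwin, sym=False)
    freqs = rfftfreq(nwin, 1 / fs)
    keep = freqs <= max_freq + 1e-9
    # (trials, comps, frames, nwin) view -> windowed DFT power
    frames = np.stack([signals[:, :, s:s + nwin] for s in starts], axis=2)
    spec = rfft(frames * win, axis=3)
    power = np.abs(spec[..., keep]) ** 2
    if trial_info is None:
        trial_info = pd.DataFrame(index=range(signals.shape[0]))
    return ComponentPowerSeries(
        power=power,
        freqs=freqs[keep],
        frame_starts=starts / fs - cue_onset_s,
        window_s=window_s,
        trial_info=trial_info.reset_index(drop=True),
    )


def _tv_distance(log_a: np.ndarray, log_r: np.ndarray) -> float:
    """Total-variation distance between Gaussian-KDE densities."""
    sa, sr = log_a.std(ddof=1) if len(log_a) > 1 else 0.0, \
        log_r.std(ddof=1) if len(log_r) > 1 else 0.0
    if sa < 1e-12 and sr < 1e-12:
        return 0.0 if abs(np.median(log_a) - np.median(log_r)) < 1e-12 else 1.0
    if sa < 1e-12 or sr < 1e-12:
        # one side degenerate: widen it to a sliver so the KDE exists
        jitter = 1e-3 * max(sa, sr)
        rng = np.random.default_rng(0)
        if sa < 1e-12:
            log_a = log_a + jitter * rng.standard_normal(len(log_a))
        else:
            log_r = log_r + jitter * rng.standard_normal(len(log_r))
    kde_a = sps.gaussian_kde(log_a, bw_method="silverman")
    kde_r = sps.gaussian_kde(log_r, bw_method="silverman")
    bw = max(kde_a.factor * log_a.std(ddof=1),
             kde_r.factor * log_r.std(ddof=1))
    lo = min(log_a.min(), log_r.min()) - 3 * bw
    hi = max(log_a.max(), log_r.max()) + 3 * bw
    grid = np.linspace(lo, hi, 512)
    fa = kde_a(grid)
    fr = kde_r(grid)
    fa /= np.trapezoid(fa, grid)
    fr /= np.trapezoid(fr, grid)
    tv = 0.5 * np.trapezoid(np.abs(fa - fr), grid)
    return float(np.clip(tv, 0.0, 1.0))


def erdd_score(p_active: np.ndarray, p_reference: np.ndarray) -> float:
    """Signed distribution-overlap score in [-100, 100].

    Magnitude is 100x the total-variation distance between the log-power
    densities; the sign is negative when the active-condition median is
    below the reference median (ERD), positive when above (ERS).  The
    score is antisymmetric under swapping the two sample sets.
    """
    p_active = np.asarray(p_active, float).ravel()
    p_reference = np.asarray(p_reference, float).ravel()
    if len(p_active) == 0 or len(p_reference) == 0:
        raise ValueError("empty power sample set")
    if (p_active <= 0).any() or (p_reference <= 0).any():
        raise ValueError("power samples must be strictly positive")
    if min(len(p_active), len(p_reference)) < 20:
        warnings.warn("fewer than 20 power samples per side; ERDd is noisy",
                      UserWarning, stacklevel=2)
    log_a, log_r = np.log(p_active), np.log(p_reference)
    tv = _tv_distance(log_a, log_r)
    med_a, med_r = np.median(log_a), np.median(log_r)
    if med_a < med_r:
        sign = -1.0
    elif med_a > med_r:
        sign = 1.0
    else:  # median tie: fall back to means, then to zero
        diff = log_a.mean() - log_r.mean()
        sign = float(np.sign(diff))
    return float(100.0 * tv * sign)


def erdd_profile(
    power: ComponentPowerSeries,
    active_condition: str = "imagery",
    reference_condition: str = "visual_attention",
    window: tuple[float, float] = (2.0, 6.0),
    keep_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per component x frequency-bin ERDd, pooling all frames in ``window``.

    Frames are pooled over all (kept) trials of each condition within
    the steady-state window, so each score compares two samples of
    single-window power values.
    """
    cond = power.trial_info["condition"].to_numpy()
    act = cond == active_condition
    ref = cond == reference_condition
    if keep_mask is not None:
        act &= keep_mask
        ref &= keep_mask
    if not act.any() or not ref.any():
        raise ValueError(
            f"both conditions required: {active_condition!r} "
            f"({act.sum()} trials), {reference_condition!r} ({ref.sum()})")
    frames = power.frames_in(window)
    n_comp, n_bins = power.power.shape[1], power.power.shape[3]
    p_act = power.power[act][:, :, frames, :].transpose(0, 2, 1, 3) \
        .reshape(-1, n_comp, n_bins)
    p_ref = power.power[ref][:, :, frames, :].transpose(0, 2, 1, 3) \
        .reshape(-1, n_comp, n_bins)
    profile = np.zeros((n_comp, n_bins))
    for j in range(n_comp):
        for b in range(n_bins):
            a, r = p_act[:, j, b], p_ref[:, j, b]
            if (a <= 0).any() or (r <= 0).any():
                profile[j, b] = 0.0
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                profile[j, b] = erdd_score(a, r)
    return profile


@dataclass
class FeatureBand:
    """A contiguous frequency range on one component, around an ERDd peak."""

    component: int
    band: tuple[float, float]  # inclusive bin edges, Hz
    peak_freq: float
    peak_score: float
    polarity: str  # "ERD" or "ERS"

    @property
    def bins(self) -> tuple[float, float]:
        return self.band

    def to_dict(self) -> dict:
        return {"component": int(self.component),
                "band_low_hz": float(self.band[0]),
                "band_high_hz": float(self.band[1]),
                "peak_freq_hz": float(self.peak_freq),
                "peak_erdd": float(self.peak_score),
                "polarity": self.polarity}


def _grow_band(scores, peak, threshold, sign):
    """Maximal contiguous run around ``peak`` with |s|>=thr and same sign."""
    lo = hi = peak
    while lo - 1 >= 0 and abs(scores[lo - 1]) >= threshold \
            and np.sign(scores[lo - 1]) == sign:
        lo -= 1
    while hi + 1 < len(scores) and abs(scores[hi + 1]) >= threshold \
            and np.sign(scores[hi + 1]) == sign:
        hi += 1
    return lo, hi


def select_feature_bands(
    profile: np.ndarray,
    freqs: np.ndarray,
    search_range: tuple[float, float] = SEARCH_RANGE,
    rel_threshold: float = REL_THRESHOLD,
    polarity: str | None = None,
) -> list[FeatureBand]:
    """Per component, the peak-|ERDd| bin and its 30 %-of-peak band.

    The peak is the largest |score| bin inside ``search_range`` (ties
    break toward the lower frequency); the band is the maximal
    contiguous run of bins around it with |score| >= ``rel_threshold``
    x |peak| and the same sign.  ``polarity`` restricts peaks to
    "ERD" (negative) or "ERS" (positive) scores.  Components whose
    profile is all zero in the range yield no band.
    """
    profile = np.atleast_2d(np.asarray(profile, float))
    freqs = np.asarray(freqs, float)
    in_range = (freqs >= search_range[0]) & (freqs <= search_range[1])
    if not in_range.any():
        raise ValueError(f"profile does not cover search range {search_range}")
    range_idx = np.flatnonzero(in_range)
    bands: list[FeatureBand] = []
    for j, comp_scores in enumerate(profile):
        candidates = comp_scores[range_idx]
        if polarity == "ERD":
            candidates = np.where(candidates < 0, candidates, 0.0)
        elif polarity == "ERS":
            candidates = np.where(candidates > 0, candidates, 0.0)
        if np.all(candidates == 0):
            continue
        peak_local = int(np.argmax(np.abs(candidates)))  # first max = lower f
        peak = range_idx[peak_local]
        peak_score = comp_scores[peak]
        sign = np.sign(peak_score)
        lo, hi = _grow_band(comp_scores, peak,
                            rel_threshold * abs(peak_score), sign)
        bands.append(FeatureBand(
            component=j,
            band=(float(freqs[lo]), float(freqs[hi])),
            peak_freq=float(freqs[peak]),
            peak_score=float(peak_score),
            polarity="ERD" if sign < 0 else "ERS",
        ))
    return bands


def band_power(power: ComponentPowerSeries, fb: FeatureBand) -> np.ndarray:
    """Mean power across a feature band's bins: (trials, frames).

    Averaging is done on power (squared-magnitude Fourier coefficients);
    averaging complex coefficients would cancel phase and destroy the
    power feature.
    """
    sel = (power.freqs >= fb.band[0] - 1e-9) & (power.freqs <= fb.band[1] + 1e-9)
    return power.power[:, fb.component][:, :, sel].mean(axis=2)
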