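"""Synthetic sensorimotor EEG and run-level ERDd tables with known truth.

The generator emulates a longitudinal motor-imagery study: 7 subjects x
6 days, runs of twelve 6 s trials (6 kinesthetic imagery + 6 visual
attention, pseudo-random order, 2-3 s inter-stimulus intervals), imagery
types FR/FL/SR/SL/TR/TRv, and BCI feedback on days 1 and 6 only.

Each neural "source" is a fixed scalp topography driving band-limited
Gaussian noise (the standard phenomenological model of sensorimotor
rhythms); event-related desynchronization is planted by multiplying the
source envelope by ``1 - depth`` during its active condition, with
100 ms raised-cosine gates at trial boundaries so the amplitude steps do
not ring through the band-pass filters.  The background is spatially
uncorrelated 1/f noise plus 10 % white sensor noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .montage import CHANNELS, N_CHANNELS, dipolar_topography
from .preprocess import EpochedEEG

IMAGERY_TYPES = ("FR", "FL", "SR", "SL", "TR", "TRv")
FAMILIAR_TYPES = ("FR", "FL", "SR", "SL")
FEEDBACK_DAYS = (1, 6)

_GATE_RAMP_S = 0.1  # raised-cosine ramp at trial boundaries


@dataclass
class SourceSpec:
    """One statistical source: topography, band, amplitude, planted ERD.

    ``erd_depth_by_condition`` maps a condition label to the fractional
    amplitude reduction (0..1) while that condition is active.  Keys may
    be the coarse conditions ``imagery`` / ``visual_attention`` or a
    specific imagery type (specific keys take precedence).
    """

    topography: np.ndarray
    band: tuple[float, float]
    baseline_amplitude: float  # microvolt RMS outside active conditions
    erd_depth_by_condition: dict[str, float] = field(default_factory=dict)
    name: str = "source"

    def __post_init__(self):
        self.topography = np.asarray(self.topography, dtype=float)
        if self.topography.shape != (N_CHANNELS,):
            raise ValueError(f"topography must have {N_CHANNELS} weights")
        norm = np.linalg.norm(self.topography)
        if norm == 0:
            raise ValueError("topography must be nonzero")
        self.topography = self.topography / norm
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError("band_low must satisfy 0 < low < high")
        for cond, depth in self.erd_depth_by_condition.items():
            if not 0.0 <= depth <= 1.0:
                raise ValueError(f"erd_depth for {cond!r} outside [0, 1]")

    def depth_for(self, condition: str, imagery_type: str) -> float:
        d = self.erd_depth_by_condition
        if condition == "imagery" and imagery_type in d:
            return d[imagery_type]
        return d.get(condition, 0.0)


@dataclass
class RunPlan:
    imagery_type: str
    feedback_flag: bool = False
    n_trials: int = 12


@dataclass
class SessionPlan:
    """One experimental day for one subject."""

    subject_id: str
    day_index: int
    runs: list[RunPlan]
    trial_length_s: float = 6.0
    isi_range_s: tuple[float, float] = (2.0, 3.0)
    sampling_rate_hz: float = 500.0

    def __post_init__(self):
        if not 1 <= self.day_index <= 6:
            raise ValueError("day_index must be in 1..6")
        for run in self.runs:
            if run.imagery_type not in IMAGERY_TYPES:
                raise ValueError(f"unknown imagery type {run.imagery_type!r}")
            if run.feedback_flag and self.day_index not in FEEDBACK_DAYS:
                raise ValueError("feedback runs occur on days 1 and 6 only")


def default_sources(
    mu_depth: float = 0.5,
    amplitude: float = 20.0,
    include_ers: bool = False,
    ers_depth: float = 0.4,
) -> list[SourceSpec]:
    """Contralateral + ipsilateral mu sources, optional occipital alpha.

    The mu sources desynchronize (amplitude x (1-depth)) during imagery;
    the optional posterior alpha source desynchronizes during visual
    attention instead, which downstream appears as imagery-relative ERS.
    """
    sources = [
        SourceSpec(dipolar_topography("C3"), (8.0, 14.0), amplitude,
                   {"imagery": mu_depth}, name="mu_contra"),
        SourceSpec(dipolar_topography("C4"), (8.0, 14.0), amplitude,
                   {"imagery": 0.6 * mu_depth}, name="mu_ipsi"),
    ]
    if include_ers:
        sources.append(
            SourceSpec(dipolar_topography("Pz"), (9.0, 12.0), amplitude,
                       {"visual_attention": ers_depth}, name="alpha_post")
        )
    return sources


def standard_session_plan(subject_id: str, day_index: int) -> SessionPlan:
    """The study's per-day run layout.

    Days 1-4: FR x6 and FL/SR/SL x3 (15 familiar runs).  Days 5-6 add
    the novel thumb-swipe conditions TR x3 and TRv x3.  Pictogram runs
    are feedback-assisted on days 1 and 6; TRv (video-guided) never is.
    """
    runs = [RunPlan("FR")] * 6 + [RunPlan("FL")] * 3 + \
        [RunPlan("SR")] * 3 + [RunPlan("SL")] * 3
    if day_index >= 5:
        runs += [RunPlan("TR")] * 3 + [RunPlan("TRv")] * 3
    if day_index in FEEDBACK_DAYS:
        runs = [RunPlan(r.imagery_type, feedback_flag=r.imagery_type != "TRv")
                for r in runs]
    return SessionPlan(subject_id=subject_id, day_index=day_index, runs=runs)


def _one_over_f_noise(rng: np.random.Generator, n_ch: int, n: int,
                      fs: float, rms: float) -> np.ndarray:
    """Spatially uncorrelated 1/f (power exponent 1) plus 10% white noise."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** -0.5  # amplitude ~ f^-1/2 -> power ~ 1/f
    shaping[0] = 0.0
    pink = np.fft.irfft(spec * shaping, n=n, axis=1)
    pink *= rms / np.sqrt(np.mean(pink**2, axis=1, keepdims=True))
    return pink + 0.1 * rms * rng.standard_normal((n_ch, n))


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited by a zero-phase Butterworth."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.sqrt(np.mean(x**2))


def _raised_cosine_gate(n: int, fs: float, intervals, levels) -> np.ndarray:
    """Gate = 1 outside the intervals, given level inside, 100 ms ramps."""
    gate = np.ones(n)
    ramp = max(2, int(_GATE_RAMP_S * fs))
    half = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp)))
    for (start, stop), level in zip(intervals, levels):
        a, b = int(start * fs), min(int(stop * fs), n)
        if level == 1.0 or b <= a:
            continue
        gate[a:b] = level
        ra = min(ramp, b - a)
        gate[a:a + ra] = 1 + (level - 1) * half[:ra]
        gate[b - ra:b] = level + (1 - level) * half[:ra]
    return gate


def _render_run(rng, plan: SessionPlan, run: RunPlan, run_index: int,
                sources, noise_level: float):
    """Render one run as continuous data; return (data, cue_samples, rows)."""
    fs = plan.sampling_rate_hz
    tlen = plan.trial_length_s
    conditions = ["imagery"] * (run.n_trials // 2) + \
        ["visual_attention"] * (run.n_trials - run.n_trials // 2)
    order = rng.permutation(len(conditions))
    conditions = [conditions[i] for i in order]
    isis = rng.uniform(*plan.isi_range_s, size=run.n_trials)

    cue_times, t = [], 1.0  # 1 s lead-in
    for isi in isis:
        cue_times.append(t)
        t += tlen + isi
    n = int(round((t + 1.0) * fs))
    cue_samples = [int(round(c * fs)) for c in cue_times]

    data = _one_over_f_noise(rng, N_CHANNELS, n, fs, noise_level) \
        if noise_level > 0 else np.zeros((N_CHANNELS, n))
    for src in sources:
        osc = src.baseline_amplitude * _band_noise(rng, n, fs, src.band)
        intervals, levels = [], []
        for cue, cond in zip(cue_times, conditions):
            depth = src.depth_for(cond, run.imagery_type)
            intervals.append((cue, cue + tlen))
            levels.append(1.0 - depth)
        gate = _raised_cosine_gate(n, fs, intervals, levels)
        data += np.outer(src.topography, gate * osc)

    rows = [
        {
            "subject": plan.subject_id,
            "day": plan.day_index,
            "run": run_index,
            "trial": k,
            "condition": cond,
            "imagery_type": run.imagery_type,
            "feedback_flag": bool(run.feedback_flag),
        }
        for k, cond in enumerate(conditions)
    ]
    return data, cue_samples, rows


def iter_session_runs(
    plan: SessionPlan,
    sources: list[SourceSpec],
    noise_level: float = 10.0,
    seed: int = 0,
):
    """Yield (run_index, run, continuous data, cue samples, trial rows).

    The continuous per-run signal is what an acquisition system would
    record (lead-in, trials, inter-stimulus intervals); epoching the
    yielded data at the cue samples reproduces :func:`generate_session`
    exactly.
    """
    if not plan.runs:
        raise ValueError("session plan contains no runs")
    if not sources:
        raise ValueError("at least one source is required")
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    rng = np.random.default_rng(seed)
    for run_index, run in enumerate(plan.runs):
        data, cues, rows = _render_run(
            rng, plan, run, run_index, sources, noise_level)
        yield run_index, run, data, cues, rows


def generate_session(
    plan: SessionPlan,
    sources: list[SourceSpec],
    noise_level: float = 10.0,
    seed: int = 0,
) -> EpochedEEG:
    """Simulate one session and return it epoched around the cues.

    ``noise_level`` is the per-channel RMS (microvolt) of the 1/f
    background.  The same plan and seed give bit-identical output.
    """
    fs = plan.sampling_rate_hz
    n_trial = int(round(plan.trial_length_s * fs))
    epochs, rows = [], []
    for _, _, data, cues, run_rows in iter_session_runs(
            plan, sources, noise_level, seed):
        for cue in cues:
            epochs.append(data[:, cue:cue + n_trial])
        rows.extend(run_rows)
    return EpochedEEG(
        data=np.stack(epochs),
        fs=fs,
        channel_names=list(CHANNELS),
        trial_info=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# run-level ERDd tables (for exercising the mixed-effects layer without EEG)

@dataclass
class MixedEffectsTruth:
    """Generative fixed/random-effect structure for run-level ERDd scores.

    Defaults are sized from the study design: a grand-mean ERDd around
    -50 points, subject offsets with SD 15 (between-subject spread of
    ERD expression), and run-to-run residual SD 9 (which reproduces a
    feedback-contrast standard error near 2 points at 30 feedback vs 60
    no-feedback runs per subject).
    """

    intercept: float = -50.0
    feedback_effect_by_subject: dict[str, float] = field(default_factory=dict)
    imagery_type_effects: dict[str, float] = field(default_factory=dict)
    subject_random_sd: float = 15.0
    residual_sd: float = 9.0
    day_slope: float = 0.0  # optional linear drift over days

    def __post_init__(self):
        if self.subject_random_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def study_layout(n_subjects: int = 7, n_days: int = 6) -> pd.DataFrame:
    """Run-level layout of the full study (one row per run)."""
    rows = []
    for s in range(1, n_subjects + 1):
        subject = f"s{s:02d}"
        for day in range(1, n_days + 1):
            plan = standard_session_plan(subject, day)
            for run_index, run in enumerate(plan.runs):
                if run.imagery_type == "TRv":
                    vof = "video"
                elif run.feedback_flag:
                    vof = "feedback"
                else:
                    vof = "no_feedback"
                rows.append({
                    "subject": subject,
                    "day": day,
                    "run": run_index,
                    "imageryType": run.imagery_type,
                    "isFeedbacked": bool(run.feedback_flag),
                    "videoORfeed": vof,
                })
    return pd.DataFrame(rows)


def generate_erdd_table(
    truth: MixedEffectsTruth,
    layout: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw run-level ERDd responses from the planted mixed-effects model.

    response = intercept + imagery-type effect + per-subject feedback
    effect x isFeedbacked + day_slope x (day - 1) + subject random
    intercept + residual.
    """
    if layout is None:
        layout = study_layout()
    subjects = layout["subject"].unique()
    if len(subjects) < 2 or layout["day"].nunique() < 2:
        raise ValueError("layout must cover at least 2 subjects and 2 days")
    rng = np.random.default_rng(seed)
    b = dict(zip(subjects,
                 truth.subject_random_sd * rng.standard_normal(len(subjects))))
    out = layout.copy()
    resp = np.full(len(out), truth.intercept, dtype=float)
    resp += out["imageryType"].map(
        lambda t: truth.imagery_type_effects.get(t, 0.0)).to_numpy()
    resp += out["isFeedbacked"].to_numpy() * out["subject"].map(
        lambda s: truth.feedback_effect_by_subject.get(s, 0.0)).to_numpy()
    resp += truth.day_slope * (out["day"].to_numpy() - 1)
    resp += out["subject"].map(b).to_numpy()
    resp += truth.residual_sd * rng.standard_normal(len(out))
    out["ERDd"] = resp
    return out
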