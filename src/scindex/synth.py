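"""Synthetic paired PPG cohort generator.

Emulates the study design the pipeline is built for: per subject, one
5-minute baseline (no-pain, VAS 0) and one 5-minute post-operative
(pain, VAS >= 1) photoplethysmogram at 300 Hz.  The pain condition
carries a sympathetic-activation signature relative to the subject's
own baseline — faster heart rate, reduced beat-interval variability
(SDNN), reduced pulse amplitude — with magnitudes that are configurable
model choices, not clinical estimates.

A recording is a sum of per-beat pulse templates (a systolic Gaussian
lobe plus a smaller, later dicrotic lobe), amplitude-modulated by
respiration and embedded in white Gaussian noise.  Beat onsets come
from i.i.d. truncated-normal inter-beat intervals; there is no
long-range heart-rate-variability correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.stats import truncnorm

from .errors import InvalidParameterError

__all__ = [
    "SynthCohortParams",
    "PPGRecording",
    "simulate_beat_train",
    "synthesize_ppg",
    "generate_cohort",
]

#: Physiological floor on an inter-beat interval (240 beats/min).
MIN_IBI_S = 0.25

# Pulse template: systolic lobe + dicrotic lobe, in seconds after beat onset.
# Chosen so the spectral fundamental dominates its harmonics across
# 50-120 beats/min (verified by the spectral tests).
_SYS_CENTER, _SYS_WIDTH = 0.18, 0.08
_DIC_CENTER, _DIC_WIDTH, _DIC_AMP = 0.42, 0.10, 0.35
_TEMPLATE_DUR_S = 1.0


Condition = Literal["baseline", "postop"]


@dataclass(frozen=True)
class PPGRecording:
    """A single-channel PPG trace with its study metadata.

    ``label`` is derived from the visual-analog pain score: VAS > 0 is
    pain (1), VAS = 0 is no pain (0), and a missing VAS leaves the label
    undefined (``None``).
    """

    samples: np.ndarray
    fs: float
    subject_id: str
    condition: str = "baseline"
    vas: int | None = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise InvalidParameterError("samples must be a non-empty 1-D sequence")
        if not self.fs > 0:
            raise InvalidParameterError(f"fs must be positive, got {self.fs}")
        if self.vas is not None and not 0 <= self.vas <= 100:
            raise InvalidParameterError(f"vas must be in [0, 100], got {self.vas}")
        object.__setattr__(self, "samples", samples)

    @property
    def label(self) -> int | None:
        if self.vas is None:
            return None
        return 1 if self.vas > 0 else 0

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "PPGRecording":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class SynthCohortParams:
    """Generator settings for a paired pain / no-pain cohort.

    Heart rates are in beats/min, SDNN (the SD of inter-beat intervals)
    in milliseconds, respiratory rate in Hz, amplitudes in the PPG's
    arbitrary units.  Setting the pain parameters equal to the no-pain
    parameters yields a null cohort in which no statistic should
    separate the classes.
    """

    n_subjects: int = 100
    fs: float = 300.0
    duration_s: float = 300.0
    hr_mean_nopain: float = 70.0
    hr_mean_pain: float = 85.0
    hr_sd_between_subjects: float = 8.0
    sdnn_nopain: float = 50.0
    sdnn_pain: float = 30.0
    pulse_amp_nopain: float = 1.0
    pulse_amp_pain: float = 0.7
    resp_rate: float = 0.25
    resp_mod_depth: float = 0.2
    noise_sd: float = 0.05
    vas_pain_range: tuple[int, int] = (1, 100)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        for name in ("fs", "duration_s", "resp_rate"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")
        for name in ("hr_mean_nopain", "hr_mean_pain"):
            hr = getattr(self, name)
            if not 30.0 < hr < 200.0:
                raise InvalidParameterError(f"{name} must be in (30, 200), got {hr}")
        for name in ("sdnn_nopain", "sdnn_pain", "noise_sd",
                     "hr_sd_between_subjects", "pulse_amp_nopain", "pulse_amp_pain"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.resp_mod_depth < 1.0:
            raise InvalidParameterError("resp_mod_depth must be in [0, 1)")
        lo, hi = self.vas_pain_range
        if not 1 <= lo <= hi <= 100:
            raise InvalidParameterError("vas_pain_range must satisfy 1 <= lo <= hi <= 100")

    def null_cohort(self) -> "SynthCohortParams":
        """Copy with pain parameters tied to the no-pain values."""
        return replace(
            self,
            hr_mean_pain=self.hr_mean_nopain,
            sdnn_pain=self.sdnn_nopain,
            pulse_amp_pain=self.pulse_amp_nopain,
        )


def simulate_beat_train(hr_mean: float, sdnn: float, duration_s: float,
                        seed: int | np.random.Generator | None = 0) -> np.ndarray:
    """Beat-onset times (s) with i.i.d. truncated-normal inter-beat intervals.

    Intervals have mean ``60 / hr_mean`` s and SD ``sdnn / 1000`` s,
    truncated below at 0.25 s.  The first beat is at t = 0 and onsets
    are strictly increasing within ``[0, duration_s)``.  ``sdnn = 0``
    gives a perfectly regular beat train.
    """
    if not duration_s > 0:
        raise InvalidParameterError(f"duration_s must be positive, got {duration_s}")
    if not 30.0 < hr_mean < 200.0:
        raise InvalidParameterError(f"hr_mean must be in (30, 200), got {hr_mean}")
    if sdnn < 0:
        raise InvalidParameterError(f"sdnn must be >= 0, got {sdnn}")
    mean_ibi = 60.0 / hr_mean
    if sdnn == 0:
        return np.arange(0.0, duration_s, mean_ibi)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = sdnn / 1000.0
    n_draw = int(duration_s / mean_ibi * 1.5) + 20
    a = (MIN_IBI_S - mean_ibi) / sd
    intervals = truncnorm.rvs(a, np.inf, loc=mean_ibi, scale=sd,
                              size=n_draw, random_state=rng)
    onsets = np.concatenate([[0.0], np.cumsum(intervals)])
    return onsets[onsets < duration_s]


def _pulse_template(t: np.ndarray) -> np.ndarray:
    sys_lobe = np.exp(-0.5 * ((t - _SYS_CENTER) / _SYS_WIDTH) ** 2)
    dic_lobe = _DIC_AMP * np.exp(-0.5 * ((t - _DIC_CENTER) / _DIC_WIDTH) ** 2)
    return sys_lobe + dic_lobe


def synthesize_ppg(onsets: Sequence[float], params: SynthCohortParams,
                   condition: Condition, *, subject_id: str = "S000",
                   vas: int | None = None,
                   rng: np.random.Generator | None = None) -> PPGRecording:
    """Render a PPG waveform from beat onsets.

    waveform = amp * sum_beats template(t - onset)
               * (1 + resp_mod_depth * sin(2*pi*resp_rate*t)) + noise
    """
    onsets = np.asarray(onsets, dtype=np.float64)
    if onsets.size == 0:
        raise InvalidParameterError("onsets must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    fs = params.fs
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    width = int(round(_TEMPLATE_DUR_S * fs))
    for onset in onsets:
        i0 = int(np.ceil(onset * fs))
        i1 = min(i0 + width, n)
        if i0 >= n:
            continue
        x[i0:i1] += _pulse_template(t[i0:i1] - onset)
    amp = params.pulse_amp_pain if condition == "postop" else params.pulse_amp_nopain
    x *= amp
    if params.resp_mod_depth > 0:
        x *= 1.0 + params.resp_mod_depth * np.sin(2 * np.pi * params.resp_rate * t)
    if params.noise_sd > 0:
        x += rng.normal(0.0, params.noise_sd, size=n)
    return PPGRecording(samples=x, fs=fs, subject_id=subject_id,
                        condition=condition, vas=vas)


def generate_cohort(params: SynthCohortParams) -> list[PPGRecording]:
    """Paired recordings for every subject: baseline (VAS 0) + postop (VAS >= 1).

    Subject-level physiology (the subject's baseline heart rate) is
    drawn once and shared across the subject's two conditions, with the
    configured pain offsets applied on top, so the pain contrast is a
    within-subject effect as in the paired study design.  Bit-identical
    under an identical parameter set (including the seed).
    """
    root = np.random.SeedSequence(params.seed)
    hr_offset = params.hr_mean_pain - params.hr_mean_nopain
    recordings: list[PPGRecording] = []
    for i, child in enumerate(root.spawn(params.n_subjects)):
        rng = np.random.default_rng(child)
        subject_id = f"S{i:04d}"
        hr_base = float(np.clip(
            rng.normal(params.hr_mean_nopain, params.hr_sd_between_subjects),
            32.0, 198.0 - max(hr_offset, 0.0)))
        vas = int(rng.integers(params.vas_pain_range[0], params.vas_pain_range[1] + 1))
        for condition, hr, sdnn, v in (
            ("baseline", hr_base, params.sdnn_nopain, 0),
            ("postop", hr_base + hr_offset, params.sdnn_pain, vas),
        ):
            onsets = simulate_beat_train(hr, sdnn, params.duration_s, seed=rng)
            recordings.append(synthesize_ppg(
                onsets, params, condition, subject_id=subject_id, vas=v, rng=rng))
    return recordings
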