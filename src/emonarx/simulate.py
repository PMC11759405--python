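"""Synthetic physiological recordings and ground-truth intensity traces.

Two layers of synthesis are provided:

* a *biophysical* layer that emulates raw recordings: tonic skin conductance
  with stimulus-locked bi-exponential SCRs, a quasi-periodic pulse wave with
  stimulus-modulated instantaneous rate, a respiration sinusoid with
  rate/depth modulation, and a knob-style intensity trace that follows the
  nominal image intensity with a first-order lag, saturation and clipping to
  [0, 1];

* a *system-identification* layer that replaces the intensity by the output
  of a known polynomial NARX process driven by feature series
  (:class:`TrueNarxProcess`), the ground truth for parameter-recovery
  experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .narx import LagSpec, NarxDivergenceError
from .protocol import TrialPlan

__all__ = [
    "SubjectProfile",
    "StimulusEvent",
    "RawRecording",
    "TrueNarxProcess",
    "generate_recording",
    "generate_intensity_from_narx",
    "sample_profile",
    "synthesize_feature_series",
]


@dataclass(frozen=True)
class StimulusEvent:
    onset_s: float
    offset_s: float
    level: float


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject physiological response parameters.

    Defaults describe a plausible resting adult; population spread is drawn
    by :func:`sample_profile`.
    """

    # electrodermal
    scl_baseline_us: float = 5.0       # tonic skin conductance level (uS)
    scl_drift_us_per_s: float = 1e-3
    scr_gain_us: float = 0.6           # SCR amplitude per unit image level
    scr_rise_s: float = 0.75
    scr_decay_s: float = 2.5
    scr_latency_s: float = 1.0
    # cardiovascular
    hr_rest_bpm: float = 70.0
    hr_gain_bpm: float = 10.0          # rate increase per unit drive
    hr_latency_s: float = 2.0
    pulse_sharpness: float = 8.0
    # respiratory
    rsp_rate_rest_bpm: float = 15.0    # breaths/min
    rsp_depth: float = 1.0
    rsp_rate_gain: float = 0.25        # relative rate modulation per drive
    rsp_depth_gain: float = 0.3
    # intensity knob
    knob_gain: float = 1.0
    knob_lag_s: float = 1.5
    knob_tau_s: float = 3.0
    # measurement noise (per channel standard deviation)
    noise_gsr_us: float = 0.01
    noise_pulse: float = 0.02
    noise_rsp: float = 0.02
    noise_intensity: float = 0.01

    def __post_init__(self):
        if not 40.0 <= self.hr_rest_bpm <= 120.0:
            raise ValueError("resting HR outside [40, 120] bpm")
        if not 6.0 <= self.rsp_rate_rest_bpm <= 30.0:
            raise ValueError("resting respiration rate outside [6, 30] bpm")
        for v in (self.scr_rise_s, self.scr_decay_s, self.knob_tau_s):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("time constants must be positive and finite")


def sample_profile(rng: np.random.Generator) -> SubjectProfile:
    """Draw a subject from a mildly heterogeneous population."""
    return SubjectProfile(
        scl_baseline_us=float(rng.uniform(3.0, 10.0)),
        scl_drift_us_per_s=float(rng.normal(0.0, 2e-3)),
        scr_gain_us=float(rng.uniform(0.3, 1.0)),
        hr_rest_bpm=float(rng.uniform(55.0, 90.0)),
        hr_gain_bpm=float(rng.uniform(5.0, 15.0)),
        rsp_rate_rest_bpm=float(rng.uniform(10.0, 20.0)),
        knob_lag_s=float(rng.uniform(0.8, 2.5)),
        knob_tau_s=float(rng.uniform(2.0, 4.0)),
    )


@dataclass(frozen=True)
class RawRecording:
    """One trial of multichannel raw data plus the intensity trace."""

    subject: str
    trial: int
    quality: str
    fs: float
    gsr: np.ndarray
    pulse: np.ndarray
    rsp: np.ndarray
    intensity: np.ndarray
    annotations: tuple[StimulusEvent, ...] = field(default_factory=tuple)
    practice: bool = False
    trimmed: bool = False

    def __post_init__(self):
        n = self.gsr.shape[0]
        if any(c.shape[0] != n for c in (self.pulse, self.rsp, self.intensity)):
            raise ValueError("all channels must have equal length")
        if self.intensity.size and (self.intensity.min() < -1e-9
                                    or self.intensity.max() > 1 + 1e-9):
            raise ValueError("intensity trace must lie in [0, 1]")
        dur = n / self.fs
        for a in self.annotations:
            if not (-1e-9 <= a.onset_s <= a.offset_s):
                raise ValueError("malformed annotation")
            if a.offset_s > dur + 1e-9 and not self.trimmed:
                raise ValueError("annotation outside trial bounds")

    @property
    def duration_s(self) -> float:
        return self.gsr.shape[0] / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.gsr.shape[0]) / self.fs


def _scr_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Bi-exponential SCR kernel normalised to unit peak."""
    k = np.where(t >= 0, np.exp(-t / decay_s) - np.exp(-t / rise_s), 0.0)
    t_peak = (np.log(decay_s / rise_s) * rise_s * decay_s / (decay_s - rise_s)
              if decay_s != rise_s else rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return k / peak


def scr_peak_amplitude(profile: SubjectProfile, level: float) -> float:
    """Analytic SCR peak amplitude for one image of the given level."""
    return profile.scr_gain_us * level


def _stimulus_drive(plan: TrialPlan, t: np.ndarray,
                    latency_s: float, tau_s: float = 2.0) -> np.ndarray:
    """Exponentially smoothed, lagged nominal-stimulus drive in [0, ~1]."""
    target = np.zeros_like(t)
    for onset, level in zip(plan.image_onsets_s(), plan.image_levels):
        on = (t >= onset + latency_s) & (t < onset + latency_s + plan.image_s)
        target[on] = level
    dt = float(t[1] - t[0]) if t.shape[0] > 1 else 1.0
    alpha = dt / tau_s
    drive = np.empty_like(target)
    acc = 0.0
    for i, val in enumerate(target):
        acc += alpha * (val - acc)
        drive[i] = acc
    return drive


def generate_recording(plan: TrialPlan, profile: SubjectProfile,
                       fs: float, seed: int, subject: str = "S01") -> RawRecording:
    """Synthesize one trial of raw GSR / pulse / respiration / intensity."""
    n = int(round(plan.duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)

    # --- electrodermal: tonic level + drift + stimulus-locked SCRs
    gsr = profile.scl_baseline_us + profile.scl_drift_us_per_s * t
    for onset, level in zip(plan.image_onsets_s(), plan.image_levels):
        amp = scr_peak_amplitude(profile, level)
        if amp != 0.0:
            gsr = gsr + amp * _scr_kernel(t - onset - profile.scr_latency_s,
                                          profile.scr_rise_s,
                                          profile.scr_decay_s)
    gsr = gsr + rng.normal(0.0, profile.noise_gsr_us, n)

    # --- pulse: quasi-periodic wave, instantaneous rate follows the drive
    drive_hr = _stimulus_drive(plan, t, profile.hr_latency_s)
    rate_hz = (profile.hr_rest_bpm + profile.hr_gain_bpm * drive_hr) / 60.0
    phase = 2.0 * np.pi * np.cumsum(rate_hz) / fs
    kappa = profile.pulse_sharpness
    pulse = np.exp(kappa * (np.cos(phase) - 1.0))
    pulse = pulse + rng.normal(0.0, profile.noise_pulse, n)

    # --- respiration: sinusoid with rate and depth modulation
    drive_rsp = _stimulus_drive(plan, t, profile.hr_latency_s)
    rsp_rate_hz = profile.rsp_rate_rest_bpm * (
        1.0 + profile.rsp_rate_gain * drive_rsp) / 60.0
    rsp_phase = 2.0 * np.pi * np.cumsum(rsp_rate_hz) / fs
    depth = profile.rsp_depth * (1.0 + profile.rsp_depth_gain * drive_rsp)
    rsp = depth * np.sin(rsp_phase) + rng.normal(0.0, profile.noise_rsp, n)

    # --- intensity knob: first-order lag toward a saturating response
    target = np.zeros(n)
    for onset, level in zip(plan.image_onsets_s(), plan.image_levels):
        on = ((t >= onset + profile.knob_lag_s)
              & (t < onset + profile.knob_lag_s + plan.image_s))
        target[on] = profile.knob_gain * np.tanh(1.8 * level)
    alpha = (1.0 / fs) / profile.knob_tau_s
    intensity = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc += alpha * (target[i] - acc)
        intensity[i] = acc
    intensity = intensity + rng.normal(0.0, profile.noise_intensity, n)
    intensity = np.clip(intensity, 0.0, 1.0)

    annotations = tuple(
        StimulusEvent(onset, onset + plan.image_s, level)
        for onset, level in zip(plan.image_onsets_s(), plan.image_levels))
    return RawRecording(
        subject=subject, trial=plan.index, quality=plan.quality, fs=fs,
        gsr=gsr, pulse=pulse, rsp=rsp, intensity=intensity,
        annotations=annotations, practice=plan.practice)


@dataclass(frozen=True)
class TrueNarxProcess:
    """A known generating polynomial NARX process.

    y(t) = c0 + sum_i a[i] y(t-i)
         + sum_m sum_j ( b[m][j] u_m(t-n_k[m]-j) + q[m][j] u_m(t-n_k[m]-j)^2 )
         + e(t),   e ~ N(0, noise_sd^2)

    The coefficient layout mirrors the model's regressor vector; the
    innovation e(t) is the equation-error term.
    """

    spec: LagSpec
    a: tuple[float, ...]                       # n_y output-lag coefficients
    b: tuple[tuple[float, ...], ...]           # per feature, n_u + 1 linear
    q: tuple[tuple[float, ...], ...]           # per feature, n_u + 1 quadratic
    c0: float = 0.0
    noise_sd: float = 0.0
    bound: float = 1e3

    def __post_init__(self):
        if len(self.a) != self.spec.n_y:
            raise ValueError("need one output coefficient per output lag")
        for m, nu in enumerate(self.spec.n_u):
            if len(self.b[m]) != nu + 1 or len(self.q[m]) != nu + 1:
                raise ValueError("need n_u + 1 coefficients per feature")


def generate_intensity_from_narx(
    features: Mapping[str, np.ndarray],
    proc: TrueNarxProcess,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the generating recursion on the given feature series.

    Initial output values are 0.  Returns ``(raw, scaled)`` where ``scaled``
    is the min-max rescaling of ``raw`` into [0, 1] (the knob convention).
    Raises :class:`NarxDivergenceError` if |y| exceeds ``proc.bound``.
    """
    spec = proc.spec
    u = {name: np.asarray(features[name], dtype=float)
         for name in spec.features}
    T = next(iter(u.values())).shape[0]
    L = spec.max_lookback
    if T <= L:
        raise ValueError("feature series shorter than the process lookback")
    rng = np.random.default_rng(seed)
    e = (rng.normal(0.0, proc.noise_sd, T) if proc.noise_sd > 0
         else np.zeros(T))
    y = np.zeros(T)
    for t in range(L, T):
        val = proc.c0
        for i, ai in enumerate(proc.a, start=1):
            val += ai * y[t - i]
        for m, name in enumerate(spec.features):
            nk = spec.n_k[m]
            s = u[name]
            for j in range(spec.n_u[m] + 1):
                x = s[t - nk - j]
                val += proc.b[m][j] * x + proc.q[m][j] * x * x
        val += e[t]
        if not np.isfinite(val) or abs(val) > proc.bound:
            raise NarxDivergenceError(
                f"generating recursion unstable at t={t}: y={val!r}")
        y[t] = val
    lo, hi = y.min(), y.max()
    scaled = (y - lo) / (hi - lo) if hi > lo else np.zeros_like(y)
    return y, scaled


def synthesize_feature_series(
    n_features: int,
    n_samples: int,
    fs: float = 2.56,
    seed: int | None = 0,
    smoothness_s: float = 3.0,
    names: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Independent smooth standardised feature series at the analysis rate.

    Gaussian noise is smoothed by a first-order low-pass with the given time
    constant, then z-scored; a convenient stand-in for decimated
    physiological feature series in recovery experiments.
    """
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"u{i + 1}" for i in range(n_features)]
    alpha = (1.0 / fs) / smoothness_s
    out = {}
    for name in names:
        w = rng.normal(0.0, 1.0, n_samples)
        x = np.empty(n_samples)
        acc = 0.0
        for i in range(n_samples):
            acc += alpha * (w[i] - acc)
            x[i] = acc
        x = (x - x.mean()) / x.std()
        out[name] = x
    return out
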