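"""The 13 continuous physiological features and their per-trial assembly.

From three conditioned channels (GSR, pulse, respiration belt) the pipeline
derives, at the acquisition rate:

* electrodermal: filtered GSR, its derivative, its running rate;
* cardiovascular: instantaneous heart rate interpolated from systolic
  inter-beat intervals, its derivative, its running rate;
* respiratory: breath-cycle rate, its derivative, its running rate, and the
  per-cycle inspiration time, expiration time, inhalation depth and
  exhalation depth (sample-and-hold between cycle ends).

The "running rate" expresses the current windowed mean relative to a
trailing reference window.  All 13 series are then decimated by 100 to the
analysis rate of 2.56 Hz and aligned with the decimated intensity trace.
Features that cannot be computed (too few beats or breath cycles) are NaN
and flagged in an availability mask — they are excluded from a subject's
candidate set during feature selection, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import interp1d

from .preprocess import DECIMATION_FACTOR, decimate

__all__ = [
    "FEATURE_NAMES",
    "BreathCycle",
    "FeatureSet",
    "heart_rate_series",
    "breath_segmentation",
    "breath_features",
    "derivative",
    "running_rate",
    "assemble_features",
]

#: Canonical order of the 13 features (also the deterministic tie-break
#: order during forward selection).
FEATURE_NAMES = (
    "gsr_filtered",
    "gsr_deriv",
    "gsr_running_rate",
    "hr_filtered",
    "hr_deriv",
    "hr_running_rate",
    "rsp_rate",
    "rsp_rate_deriv",
    "rsp_running_rate",
    "insp_time",
    "exp_time",
    "inhal_depth",
    "exhal_depth",
)

HR_BOUNDS_BPM = (30.0, 200.0)
PULSE_REFRACTORY_S = 0.3
BREATH_MIN_CYCLE_S = 1.5
PROMINENCE_IQR_FACTOR = 0.3


@dataclass(frozen=True)
class BreathCycle:
    """One trough-peak-trough respiration cycle."""

    trough_s: float
    peak_s: float
    next_trough_s: float
    insp_time_s: float
    exp_time_s: float
    inhal_depth: float
    exhal_depth: float

    @property
    def period_s(self) -> float:
        return self.next_trough_s - self.trough_s

    @property
    def rate_bpm(self) -> float:
        return 60.0 / self.period_s


@dataclass
class FeatureSet:
    """Time-aligned 13-feature matrix plus intensity at the analysis rate."""

    subject: str
    trial: int
    quality: str
    fs: float
    features: dict[str, np.ndarray]
    intensity: np.ndarray
    available: dict[str, bool] = field(default_factory=dict)
    practice: bool = False

    def __post_init__(self):
        missing = set(FEATURE_NAMES) - set(self.features)
        if missing:
            raise ValueError(f"missing feature series: {sorted(missing)}")
        n = self.intensity.shape[0]
        for name, series in self.features.items():
            if series.shape[0] != n:
                raise ValueError(f"feature {name!r} not aligned to intensity")
        for name in FEATURE_NAMES:
            self.available.setdefault(
                name, bool(np.all(np.isfinite(self.features[name]))))

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    def candidate_features(self) -> tuple[str, ...]:
        return tuple(n for n in FEATURE_NAMES if self.available[n])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({n: self.features[n] for n in FEATURE_NAMES})
        df.insert(0, "time_s", np.arange(self.n_samples) / self.fs)
        df["intensity"] = self.intensity
        return df


#: Absolute prominence floor: extrema smaller than this (in signal units)
#: are never counted as physiological events.
PROMINENCE_FLOOR = 0.05


def _prominence(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75, 25])
    return max(PROMINENCE_IQR_FACTOR * (q75 - q25), PROMINENCE_FLOOR)


def _pulse_prominence(x: np.ndarray) -> float:
    # systolic peaks are narrow, so the inter-quartile range underestimates
    # the beat amplitude badly; a wide percentile range is scale-robust
    p98, p2 = np.percentile(x, [98, 2])
    return max(PROMINENCE_IQR_FACTOR * (p98 - p2), PROMINENCE_FLOOR)


def heart_rate_series(pulse: np.ndarray, fs: float
                      ) -> tuple[np.ndarray | None, bool]:
    """Instantaneous heart rate (bpm) on the pulse time base.

    Systolic peaks are detected with a scale-robust prominence threshold and
    a 0.3 s refractory period; inter-beat intervals outside [30, 200] bpm
    are rejected and bridged by the linear interpolation.  Returns
    ``(series, available)``; with fewer than 3 usable beats the feature is
    unavailable.
    """
    pulse = np.asarray(pulse, dtype=float)
    if not np.all(np.isfinite(pulse)):
        return None, False
    prom = _pulse_prominence(pulse)
    peaks, _ = signal.find_peaks(pulse, prominence=prom,
                                 distance=max(1, int(PULSE_REFRACTORY_S * fs)))
    if peaks.shape[0] < 3:
        return None, False
    beat_t = peaks / fs
    ibi = np.diff(beat_t)
    bpm = 60.0 / ibi
    ok = (bpm >= HR_BOUNDS_BPM[0]) & (bpm <= HR_BOUNDS_BPM[1])
    if ok.sum() < 2:
        return None, False
    # value assigned at the closing beat of each interval
    knots_t = beat_t[1:][ok]
    knots_v = bpm[ok]
    f = interp1d(knots_t, knots_v, kind="linear", bounds_error=False,
                 fill_value=(knots_v[0], knots_v[-1]))
    t = np.arange(pulse.shape[0]) / fs
    return f(t), True


def breath_segmentation(rsp: np.ndarray, fs: float) -> list[BreathCycle]:
    """Trough/peak alternation of the band-passed respiration signal.

    Extrema are prominence-thresholded (0.3 x IQR) with a minimum cycle
    duration of 1.5 s; runs of same-type extrema keep the most extreme one,
    so the surviving sequence alternates.  Degeneracy (fewer than 3 cycles)
    is expressed downstream via the availability mask, not as an error.
    """
    rsp = np.asarray(rsp, dtype=float)
    if not np.all(np.isfinite(rsp)):
        return []
    prom = _prominence(rsp)
    dist = max(1, int(BREATH_MIN_CYCLE_S * fs))
    peaks, _ = signal.find_peaks(rsp, prominence=prom, distance=dist)
    troughs, _ = signal.find_peaks(-rsp, prominence=prom, distance=dist)
    events = sorted([(i, +1) for i in peaks] + [(i, -1) for i in troughs])
    # collapse same-type runs to the most extreme sample
    alt: list[tuple[int, int]] = []
    for idx, kind in events:
        if alt and alt[-1][1] == kind:
            prev = alt[-1][0]
            better = rsp[idx] > rsp[prev] if kind > 0 else rsp[idx] < rsp[prev]
            if better:
                alt[-1] = (idx, kind)
        else:
            alt.append((idx, kind))
    cycles: list[BreathCycle] = []
    for j in range(len(alt) - 2):
        (i0, k0), (i1, k1), (i2, k2) = alt[j], alt[j + 1], alt[j + 2]
        if (k0, k1, k2) != (-1, +1, -1):
            continue
        cycles.append(BreathCycle(
            trough_s=i0 / fs, peak_s=i1 / fs, next_trough_s=i2 / fs,
            insp_time_s=(i1 - i0) / fs, exp_time_s=(i2 - i1) / fs,
            inhal_depth=float(rsp[i1] - rsp[i0]),
            exhal_depth=float(rsp[i1] - rsp[i2])))
    return cycles


def breath_features(cycles: list[BreathCycle], n_samples: int, fs: float
                    ) -> tuple[dict[str, np.ndarray], bool]:
    """Sample-and-hold cycle features on the uniform time base.

    Each cycle's values hold from that cycle's end until the next cycle's
    end (the stretch before the first cycle completes carries the first
    cycle's values).  With fewer than 3 valid cycles all five series are NaN
    and flagged unavailable.
    """
    names = ("rsp_rate", "insp_time", "exp_time", "inhal_depth", "exhal_depth")
    if len(cycles) < 3:
        nan = np.full(n_samples, np.nan)
        return {name: nan.copy() for name in names}, False
    series = {name: np.empty(n_samples) for name in names}
    ends = [int(round(c.next_trough_s * fs)) for c in cycles]
    values = [(c.rate_bpm, c.insp_time_s, c.exp_time_s, c.inhal_depth,
               c.exhal_depth) for c in cycles]
    # cycle i's values become available at its end and hold until the next
    # cycle's end; the stretch before the first completed cycle carries the
    # first cycle's values (warm-up backfill)
    bounds = [0] + ends[1:] + [n_samples]
    for (start, end, vals) in zip(bounds[:-1], bounds[1:], values):
        for name, v in zip(names, vals):
            series[name][start:end] = v
    return series, True


def derivative(series: np.ndarray, fs: float) -> np.ndarray:
    """Central-difference derivative (units per second); one-sided at the
    endpoints."""
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise ValueError("need at least 3 samples for a derivative")
    return np.gradient(series, 1.0 / fs)


def running_rate(
    series: np.ndarray,
    fs: float,
    eval_window_s: float = 5.0,
    ref_window_s: float = 10.0,
    ref_gap_s: float = 5.0,
    eps: float = 1e-6,
) -> np.ndarray:
    """Windowed level relative to a trailing moving reference interval.

    value(t) = (mean over the evaluation window ending at t
                - mean over the reference window ending at t - gap)
               / (|reference mean| + eps)

    The warm-up region where either window does not fit yet is 0.
    """
    if min(eval_window_s, ref_window_s, ref_gap_s) < 0 or \
            eval_window_s <= 0 or ref_window_s <= 0:
        raise ValueError("window lengths must be positive")
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    w_ev = max(1, int(round(eval_window_s * fs)))
    w_rf = max(1, int(round(ref_window_s * fs)))
    gap = int(round(ref_gap_s * fs))
    if n <= w_ev + gap + w_rf:
        return np.zeros(n)
    c = np.concatenate([[0.0], np.cumsum(x)])
    t = np.arange(n)
    out = np.zeros(n)
    t0 = max(w_ev - 1, gap + w_rf - 1)
    tv = t[t0:]
    mean_ev = (c[tv + 1] - c[tv + 1 - w_ev]) / w_ev
    ref_end = tv - gap
    mean_rf = (c[ref_end + 1] - c[ref_end + 1 - w_rf]) / w_rf
    out[t0:] = (mean_ev - mean_rf) / (np.abs(mean_rf) + eps)
    return out


def assemble_features(recording, factor: int = DECIMATION_FACTOR,
                      running_rate_kwargs: dict | None = None) -> "FeatureSet":
    """Compute all 13 features on a preprocessed (filtered + trimmed) trial
    and decimate them to the analysis rate.

    Degenerate channels never raise here; the affected features are NaN with
    the availability mask cleared.  Masks propagate: the derivative and
    running rate of an unavailable series are themselves unavailable.
    """
    if not getattr(recording, "trimmed", False):
        raise ValueError("recording must be trimmed exactly once before "
                         "feature extraction")
    fs = recording.fs
    n = recording.gsr.shape[0]
    rr_kw = running_rate_kwargs or {}
    feats: dict[str, np.ndarray] = {}
    avail: dict[str, bool] = {}

    gsr = np.asarray(recording.gsr, dtype=float)
    feats["gsr_filtered"] = gsr
    feats["gsr_deriv"] = derivative(gsr, fs)
    feats["gsr_running_rate"] = running_rate(gsr, fs, **rr_kw)
    avail.update(gsr_filtered=True, gsr_deriv=True, gsr_running_rate=True)

    hr, hr_ok = heart_rate_series(recording.pulse, fs)
    if hr_ok:
        feats["hr_filtered"] = hr
        feats["hr_deriv"] = derivative(hr, fs)
        feats["hr_running_rate"] = running_rate(hr, fs, **rr_kw)
    else:
        for name in ("hr_filtered", "hr_deriv", "hr_running_rate"):
            feats[name] = np.full(n, np.nan)
    avail.update(hr_filtered=hr_ok, hr_deriv=hr_ok, hr_running_rate=hr_ok)

    cycles = breath_segmentation(recording.rsp, fs)
    breath, rsp_ok = breath_features(cycles, n, fs)
    feats.update(breath)
    if rsp_ok:
        feats["rsp_rate_deriv"] = derivative(breath["rsp_rate"], fs)
        feats["rsp_running_rate"] = running_rate(breath["rsp_rate"], fs, **rr_kw)
    else:
        feats["rsp_rate_deriv"] = np.full(n, np.nan)
        feats["rsp_running_rate"] = np.full(n, np.nan)
    for name in ("rsp_rate", "rsp_rate_deriv", "rsp_running_rate",
                 "insp_time", "exp_time", "inhal_depth", "exhal_depth"):
        avail[name] = rsp_ok

    decimated = {}
    for name in FEATURE_NAMES:
        if avail[name]:
            decimated[name] = decimate(feats[name], factor)
        else:
            decimated[name] = np.full(int(np.ceil(n / factor)), np.nan)
    intensity = np.clip(decimate(recording.intensity, factor), 0.0, 1.0)
    return FeatureSet(
        subject=recording.subject, trial=recording.trial,
        quality=recording.quality, fs=fs / factor,
        features=decimated, intensity=intensity, available=avail,
        practice=getattr(recording, "practice", False))
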