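"""Signal conditioning for the raw physiological channels.

The conditioning chain reproduces typical biosignal-amplifier defaults:
electrodermal and pulse channels get a 30 Hz low-pass plus a 50 Hz mains
notch; the respiration belt gets a 0.1-30 Hz band-pass plus the same notch.
All filters are applied zero-phase (forward-backward), so features extracted
afterwards carry no group delay relative to the intensity trace.  The first
2 s of every trial are discarded (the time participants take to settle the
quality knob at trial start), and feature series are decimated by an integer
factor (100 by default: 256 Hz -> 2.56 Hz) after anti-alias filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import signal

__all__ = [
    "FilterSpec",
    "filter_cardio_eda",
    "filter_respiration",
    "trim_trial",
    "decimate",
    "preprocess_recording",
]

TRIM_SECONDS = 2.0
DECIMATION_FACTOR = 100


@dataclass(frozen=True)
class FilterSpec:
    """One stage of the conditioning cascade."""

    kind: Literal["low-pass", "band-pass", "notch"]
    corners_hz: tuple[float, ...] = ()
    order: int = 4
    notch_q: float = 30.0

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not all(0.0 < c < nyq for c in self.corners_hz):
            raise ValueError(
                f"corner frequencies {self.corners_hz} must lie strictly "
                f"inside (0, {nyq}) Hz")
        if self.kind == "band-pass":
            lo, hi = self.corners_hz
            if not lo < hi:
                raise ValueError("band-pass requires low < high corner")

    def apply(self, series: np.ndarray, fs: float) -> np.ndarray:
        self.validate(fs)
        x = np.asarray(series, dtype=float)
        if self.kind == "low-pass":
            sos = signal.butter(self.order, self.corners_hz[0], "lowpass",
                                fs=fs, output="sos")
        elif self.kind == "band-pass":
            sos = signal.butter(self.order, self.corners_hz, "bandpass",
                                fs=fs, output="sos")
        elif self.kind == "notch":
            b, a = signal.iirnotch(self.corners_hz[0], self.notch_q, fs=fs)
            sos = signal.tf2sos(b, a)
        else:
            raise ValueError(f"unknown filter kind {self.kind!r}")
        # reflect padding keeps the zero-phase pass well-behaved at the edges
        return signal.sosfiltfilt(sos, x, padtype="even")


CARDIO_EDA_CHAIN = (
    FilterSpec("low-pass", (30.0,)),
    FilterSpec("notch", (50.0,)),
)
RESPIRATION_CHAIN = (
    FilterSpec("band-pass", (0.1, 30.0)),
    FilterSpec("notch", (50.0,)),
)


def _check_fs(fs: float) -> None:
    if fs <= 100.0:
        raise ValueError(
            f"sampling rate {fs} Hz too low for the 30 Hz low-pass / 50 Hz "
            "notch cascade (need fs > 100 Hz)")


def filter_cardio_eda(series: np.ndarray, fs: float) -> np.ndarray:
    """30 Hz low-pass then 50 Hz notch, zero-phase; for GSR and pulse."""
    _check_fs(fs)
    out = np.asarray(series, dtype=float)
    for spec in CARDIO_EDA_CHAIN:
        out = spec.apply(out, fs)
    return out


def filter_respiration(series: np.ndarray, fs: float) -> np.ndarray:
    """0.1-30 Hz band-pass then 50 Hz notch, zero-phase; for the belt."""
    _check_fs(fs)
    out = np.asarray(series, dtype=float)
    for spec in RESPIRATION_CHAIN:
        out = spec.apply(out, fs)
    return out


def trim_trial(recording):
    """Drop the first 2 s of every channel, the intensity trace and the
    annotations.  Not idempotent: the returned recording carries
    ``trimmed=True`` and trimming an already-trimmed recording raises."""
    if getattr(recording, "trimmed", False):
        raise ValueError("recording already trimmed; trim exactly once")
    n = int(round(TRIM_SECONDS * recording.fs))
    if recording.gsr.shape[0] <= n:
        raise ValueError(
            f"trial of {recording.gsr.shape[0] / recording.fs:.2f} s is too "
            f"short to trim {TRIM_SECONDS} s")
    annotations = tuple(
        replace(a, onset_s=a.onset_s - TRIM_SECONDS,
                offset_s=a.offset_s - TRIM_SECONDS)
        for a in recording.annotations)
    return replace(
        recording,
        gsr=recording.gsr[n:],
        pulse=recording.pulse[n:],
        rsp=recording.rsp[n:],
        intensity=recording.intensity[n:],
        annotations=annotations,
        trimmed=True,
    )


def decimate(series: np.ndarray, factor: int, fs: float | None = None):
    """Anti-alias low-pass below the new Nyquist, then keep every
    ``factor``-th sample (indices 0, factor, 2*factor, ...).

    Implemented as zero-phase polyphase FIR decimation with edge padding
    (:func:`scipy.signal.resample_poly`), whose sharp transition keeps
    content below the new Nyquist essentially untouched while rejecting
    everything above it.  Returns the decimated series, or
    ``(series, new_fs)`` when ``fs`` is given.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"decimation factor must be a positive integer, "
                         f"got {factor}")
    factor = int(factor)
    x = np.asarray(series, dtype=float)
    if x.shape[0] < factor:
        raise ValueError("series shorter than the decimation factor")
    if factor > 1:
        x = signal.resample_poly(x, 1, factor, padtype="edge")
    if fs is not None:
        return x, fs / factor
    return x


def preprocess_recording(recording):
    """Filter all channels and trim the first 2 s.

    Feature extraction still happens at the acquisition rate; decimation is
    applied to the extracted feature series, not to the raw channels.
    """
    filtered = replace(
        recording,
        gsr=filter_cardio_eda(recording.gsr, recording.fs),
        pulse=filter_cardio_eda(recording.pulse, recording.fs),
        rsp=filter_respiration(recording.rsp, recording.fs),
    )
    return trim_trial(filtered)
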