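"""Sliding-window linear-regression baseline.

The comparator summarises each feature over sliding windows of 13 samples
(~5 s at 2.56 Hz) advanced in steps of 3 samples (~1 s) by four statistics
(max, min, mean, population std) and regresses the window-mean intensity on
them by ordinary least squares.  It never sees per-sample intensity — only
window means — which is what makes it a static baseline against the dynamic
NARX model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .narx import pearson_r

__all__ = ["WindowTable", "windowize", "SlidingWindowLR",
           "SlidingWindowLRResults", "WINDOW_SAMPLES", "WINDOW_STEP"]

WINDOW_SAMPLES = 13
WINDOW_STEP = 3
STATS = ("max", "min", "mean", "std")


@dataclass(frozen=True)
class WindowTable:
    """Per-window statistics of the selected features plus the target."""

    X: np.ndarray                  # (n_windows, 4 * n_features)
    target: np.ndarray             # window-mean intensity
    columns: tuple[str, ...]
    starts: np.ndarray             # window start indices

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.columns))
        df.insert(0, "start", self.starts)
        df["target"] = self.target
        return df


def windowize(feature_set, names: Sequence[str],
              window: int = WINDOW_SAMPLES, step: int = WINDOW_STEP
              ) -> WindowTable:
    """Build the window table for one trial.

    Windows advance by ``step`` samples; an incomplete trailing window is
    dropped, so the window count is floor((T - window) / step) + 1.
    """
    T = feature_set.n_samples
    if T < window:
        raise ValueError(f"trial of {T} samples shorter than the "
                         f"{window}-sample window")
    for name in names:
        if not feature_set.available.get(name, False):
            raise ValueError(f"feature {name!r} is masked")
    n_win = (T - window) // step + 1
    starts = np.arange(n_win) * step
    idx = starts[:, None] + np.arange(window)[None, :]
    cols: list[np.ndarray] = []
    col_names: list[str] = []
    for name in names:
        w = np.asarray(feature_set.features[name], dtype=float)[idx]
        cols.extend([w.max(axis=1), w.min(axis=1), w.mean(axis=1),
                     w.std(axis=1)])
        col_names.extend(f"{name}_{s}" for s in STATS)
    target = np.asarray(feature_set.intensity, dtype=float)[idx].mean(axis=1)
    return WindowTable(X=np.column_stack(cols), target=target,
                       columns=tuple(col_names), starts=starts)


@dataclass(frozen=True)
class SlidingWindowLRResults:
    """Fitted window regression: intercept + one coefficient per column."""

    columns: tuple[str, ...]
    intercept: float
    coef: np.ndarray

    def predict(self, table: WindowTable) -> np.ndarray:
        if table.columns != self.columns:
            raise ValueError(
                f"column registry mismatch: model {self.columns} vs table "
                f"{table.columns}")
        return self.intercept + table.X @ self.coef

    def score(self, table: WindowTable) -> float:
        """Correlation between predicted and window-mean intensity (same
        zero-variance convention as the NARX module)."""
        return pearson_r(self.predict(table), table.target)

    def summary(self) -> str:
        lines = ["Sliding-window linear regression", "=" * 40,
                 f"{'(intercept)':<26}{self.intercept: .6g}"]
        lines += [f"{c:<26}{v: .6g}" for c, v in zip(self.columns, self.coef)]
        return "\n".join(lines)


class SlidingWindowLR:
    """OLS of window-mean intensity on the window statistics, pooled over
    training trials; rank deficiency falls back to the minimum-norm
    solution."""

    def __init__(self, tables: Sequence[WindowTable]):
        if not tables:
            raise ValueError("need at least one training table")
        cols = tables[0].columns
        for t in tables[1:]:
            if t.columns != cols:
                raise ValueError("column registry mismatch across tables")
        self.columns = cols
        self._X = np.concatenate([t.X for t in tables], axis=0)
        self._y = np.concatenate([t.target for t in tables])
        if not (np.all(np.isfinite(self._X)) and np.all(np.isfinite(self._y))):
            raise ValueError("non-finite values in window table")

    def fit(self) -> SlidingWindowLRResults:
        A = np.column_stack([np.ones(self._X.shape[0]), self._X])
        beta, *_ = np.linalg.lstsq(A, self._y, rcond=None)
        return SlidingWindowLRResults(
            columns=self.columns, intercept=float(beta[0]), coef=beta[1:])
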