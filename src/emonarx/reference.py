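"""Reference per-participant results shipped with the package.

The original study's raw recordings are not publicly deposited, but its
per-participant summary tables are: the optimal feature combinations and
stage-wise correlations of the 21 intrasubject models per emotion quality
(for both the NARX and the sliding-window regression), and the ten
random-split intersubject repeats per quality with their optimised lag
parameters.  These tables, transcribed to TSV, anchor regression tests:
the medians, MADs, occurrence counts and frequent-itemset outcomes computed
from them by this package must reproduce the published summaries exactly.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_intrasubject_table",
    "load_intersubject_table",
    "best_correlations",
    "optimal_feature_sets",
    "QUALITIES",
]

QUALITIES = (1, 2, 3)


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("emonarx").joinpath(f"data/reference/{name}")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"reference table {name} is empty or corrupted")
    return df


def load_intrasubject_table(quality: int) -> pd.DataFrame:
    """Stage-wise optimal features and correlations per participant.

    Columns: participant, model ("narx" | "lr"), stage, feature, r.
    """
    if quality not in QUALITIES:
        raise ValueError(f"quality must be one of {QUALITIES}")
    df = _read(f"intra_q{quality}.tsv")
    expected = {"participant", "model", "stage", "feature", "r"}
    if set(df.columns) != expected:
        raise ValueError("intrasubject table has unexpected columns")
    if df["participant"].nunique() != 21:
        raise ValueError("intrasubject table must cover 21 participants")
    return df


def load_intersubject_table(quality: int) -> pd.DataFrame:
    """Intersubject repeats: features used, train/test subject indexes,
    optimised lag parameters (NARX rows) and mean test correlation."""
    if quality not in QUALITIES:
        raise ValueError(f"quality must be one of {QUALITIES}")
    df = _read(f"inter_q{quality}.tsv")
    expected = {"repeat", "model", "features", "train", "test", "params",
                "mean_r"}
    if set(df.columns) != expected:
        raise ValueError("intersubject table has unexpected columns")
    return df


def best_correlations(quality: int, model: str = "narx") -> pd.Series:
    """Final (best) correlation per participant, indexed by participant."""
    df = load_intrasubject_table(quality)
    df = df[df["model"] == model]
    idx = df.groupby("participant")["stage"].idxmax()
    return df.loc[idx].set_index("participant")["r"]


def optimal_feature_sets(quality: int, model: str = "narx"
                         ) -> dict[int, set[str]]:
    """Per-participant optimal feature set (all accepted stages)."""
    df = load_intrasubject_table(quality)
    df = df[df["model"] == model]
    return {int(p): set(g["feature"]) for p, g in df.groupby("participant")}


def intersubject_parameter_matrix(quality: int, features: str | None = None
                                  ) -> np.ndarray:
    """Lag-parameter vectors of the NARX intersubject repeats as an array
    of shape (repeats, n_params): [n_y, n_u1, n_k1, ...]."""
    df = load_intersubject_table(quality)
    df = df[df["model"] == "narx"]
    if features is not None:
        df = df[df["features"] == features]
    return np.array([[int(v) for v in p.split()] for p in df["params"]])
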