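"""Multiday trimmed-mean aggregation into person-time samples.

One sample is a (participant, anchor night, timescale t) feature vector: for
t >= 3 the window is the anchor night plus the t-1 most recent earlier kept
nights of that participant (calendar gaps allowed), and each feature is the
window sum minus its maximum and minimum divided by t-2, removing exactly one
occurrence of each extreme. For t = 1 the sample is the nightly value itself
(the trim formula is undefined there); t = 2 is rejected. Windows are rolling,
so a participant with k kept nights contributes max(0, k - t + 1) samples at
timescale t — sample counts are non-increasing in t.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import FEATURE_COLUMNS

__all__ = ["trimmed_mean", "build_samples", "TIMESCALES"]

#: The analysis timescales, days.
TIMESCALES = (1, 7, 14, 30)


def trimmed_mean(values) -> float:
    """Extremes-removed mean of exactly t values: (sum - max - min)/(t - 2).

    For a single value the value itself is returned; t = 2 is undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    t = len(x)
    if t == 1:
        return float(x[0])
    if t == 2:
        raise ValueError("trimmed mean is undefined for t = 2 (t - 2 = 0)")
    return float((x.sum() - x.max() - x.min()) / (t - 2))


def build_samples(
    kept_nights: pd.DataFrame,
    t: int,
    feature_columns=FEATURE_COLUMNS,
) -> pd.DataFrame:
    """Person-time samples of t-day trimmed-mean features.

    ``kept_nights`` is the QC-filtered nightly feature table (participant_id,
    night_date, feature columns). Returns one row per (participant, anchor
    night) with enough history, with columns participant_id,
    anchor_night_date, t and the trimmed features. Rows whose window contains
    a non-finite feature value are dropped.
    """
    if t != 1 and t < 3:
        raise ValueError("t must be 1 or >= 3")
    frames = []
    ordered = kept_nights.sort_values(["participant_id", "night_date"])
    for pid, group in ordered.groupby("participant_id", sort=False):
        if len(group) < t:
            continue
        feats = group[list(feature_columns)].astype(float)
        if t == 1:
            trimmed = feats.copy()
        else:
            roll = feats.rolling(window=t)
            trimmed = (roll.sum() - roll.max() - roll.min()) / (t - 2)
            trimmed = trimmed.iloc[t - 1 :]
        out = trimmed.copy()
        out.insert(0, "participant_id", pid)
        out.insert(1, "anchor_night_date", group["night_date"].iloc[t - 1 :].to_numpy()
                   if t > 1 else group["night_date"].to_numpy())
        out.insert(2, "t", t)
        frames.append(out)
    if not frames:
        return pd.DataFrame(
            columns=["participant_id", "anchor_night_date", "t", *feature_columns]
        )
    samples = pd.concat(frames, ignore_index=True)
    finite = np.isfinite(samples[list(feature_columns)].to_numpy()).all(axis=1)
    return samples.loc[finite].reset_index(drop=True)
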