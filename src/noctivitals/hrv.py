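"""Per-night HRV and heart-rate features from a beat-interval series.

SDNN is the sample standard deviation (n-1 denominator, the Task Force
convention) of the nightly beat intervals in ms. Frequency-domain indices are
Lomb-Scargle band powers (see :mod:`noctivitals.spectral`) in absolute ms^2.
The heart-rate feature is the modal per-minute mean heart rate over the night,
in integer beats/min.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import respiration as _resp
from .datatypes import FEATURE_COLUMNS, NightlyFeatures, NightRecording
from .spectral import BandPowers, band_powers

__all__ = [
    "compute_sdnn",
    "compute_band_powers",
    "compute_hr_mode",
    "compute_nightly_features",
    "extract_features",
]


def compute_sdnn(beat_intervals) -> float:
    """Sample standard deviation (ddof=1) of the beat intervals, ms."""
    x = np.asarray(beat_intervals, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need at least two beat intervals")
    if np.any(x <= 0):
        raise ValueError("beat intervals must be positive")
    return float(np.std(x, ddof=1))


def compute_band_powers(beat_times, beat_intervals) -> BandPowers:
    """Spectral band powers of the mean-subtracted tachogram (ms^2)."""
    return band_powers(beat_times, beat_intervals)


def _minute_means(beat_times, values) -> np.ndarray:
    """Mean of ``values`` grouped by the elapsed minute of each interval onset."""
    minutes = np.floor((beat_times - beat_times[0]) / 60.0).astype(int)
    sums = np.bincount(minutes, weights=values)
    counts = np.bincount(minutes)
    present = counts > 0
    return sums[present] / counts[present]


def compute_hr_mode(beat_times, beat_intervals) -> int:
    """Modal integer per-minute mean heart rate, beats/min.

    Each interval contributes its instantaneous rate (60000/interval) to the
    minute containing its onset; per-minute means are rounded half-up to
    integers and the most frequent value is returned, ties going to the
    smaller value.
    """
    t = np.asarray(beat_times, dtype=float)
    x = np.asarray(beat_intervals, dtype=float)
    if len(t) != len(x) + 1:
        raise ValueError("expected len(beat_times) == len(beat_intervals) + 1")
    if len(x) == 0 or t[-1] - t[0] < 60.0:
        raise ValueError("need at least one full elapsed minute")
    per_minute = _minute_means(t[:-1], 60000.0 / x)
    rounded = np.floor(per_minute + 0.5).astype(int)
    counts = np.bincount(rounded)
    return int(np.argmax(counts))  # argmax returns the smallest tied value


def compute_nightly_features(recording: NightRecording) -> NightlyFeatures:
    """All ten nightly statistics for one recording."""
    bp = compute_band_powers(recording.beat_times, recording.beat_intervals)
    return NightlyFeatures(
        sdnn=compute_sdnn(recording.beat_intervals),
        tp=bp.tp,
        ulf=bp.ulf,
        vlf=bp.vlf,
        lf=bp.lf,
        hf=bp.hf,
        lf_hf=bp.lf_hf,
        hr_mode=compute_hr_mode(recording.beat_times, recording.beat_intervals),
        rr_mode=_resp.compute_rr_mode(recording.rr_per_minute),
        rrf=_resp.compute_rrf(recording.rr_per_minute),
    )


def extract_features(recordings) -> pd.DataFrame:
    """Nightly feature table (one row per recording) with QC metadata columns."""
    rows = []
    for rec in recordings:
        feats = compute_nightly_features(rec)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "night_date": rec.night_date,
                **feats.as_dict(),
                "artifact_motions": rec.artifact_motions,
                "sleep_duration": rec.sleep_duration,
                "data_loss_minutes": rec.data_loss_minutes,
            }
        )
    columns = [
        "participant_id",
        "night_date",
        *FEATURE_COLUMNS,
        "artifact_motions",
        "sleep_duration",
        "data_loss_minutes",
    ]
    return pd.DataFrame(rows, columns=columns)
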