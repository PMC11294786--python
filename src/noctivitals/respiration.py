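"""Per-night respiration features from the per-minute respiratory-rate series."""

from __future__ import annotations

import numpy as np

__all__ = ["compute_rr_mode", "compute_rrf", "TACHYPNEA_THRESHOLD"]

#: Breaths/min above which a minute counts as tachypneic (strictly greater).
TACHYPNEA_THRESHOLD = 21.0


def _validate(rr_per_minute) -> np.ndarray:
    x = np.asarray(rr_per_minute, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("need at least one minute of respiration data")
    if np.any(x < 0):
        raise ValueError("respiratory rates must be non-negative")
    return x


def compute_rr_mode(rr_per_minute) -> int:
    """Modal integer respiratory rate over the night, breaths/min.

    Per-minute values are rounded half-up to integers first; ties between
    modal values go to the smaller rate.
    """
    x = _validate(rr_per_minute)
    rounded = np.floor(x + 0.5).astype(int)
    counts = np.bincount(rounded)
    return int(np.argmax(counts))


def compute_rrf(rr_per_minute) -> int:
    """Cumulative minutes with respiratory rate strictly above 21 breaths/min.

    The device reports one rate per minute, so the minute is the atomic unit;
    a minute at exactly 21 does not count.
    """
    x = _validate(rr_per_minute)
    return int(np.sum(x > TACHYPNEA_THRESHOLD))
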