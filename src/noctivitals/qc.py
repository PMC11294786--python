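"""Night-level quality-control exclusions applied before any aggregation.

A night is excluded iff any of the five rules fires:

* ``motion``       — artifact-motion count >= 600 (boundary excluded);
* ``sleep_short``  — sleep duration strictly under 5 h (exactly 5 h kept);
* ``sleep_long``   — sleep duration strictly over 9 h (exactly 9 h kept);
* ``data_loss``    — >= 60 minutes of data lost in the night (boundary excluded);
* ``zero_vital``   — modal heart rate or respiratory rate of 0;
* ``exacerbation`` — night date within [window_start - 7 days, window_end] of
  any acute-exacerbation window of that participant (calendar-date
  arithmetic on night start dates).

Decisions are independent across nights given the metadata, so the filter is
idempotent and order-free.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["QcThresholds", "QcDecision", "apply_night_exclusions", "filter_nights"]

QC_REASONS = (
    "motion",
    "sleep_short",
    "sleep_long",
    "data_loss",
    "zero_vital",
    "exacerbation",
)


@dataclass(frozen=True)
class QcThresholds:
    """Rule boundaries; defaults are the study's published criteria."""

    max_motions: int = 600  # excluded when count >= this
    min_sleep_h: float = 5.0  # excluded when strictly below
    max_sleep_h: float = 9.0  # excluded when strictly above
    max_data_loss_min: float = 60.0  # excluded when >= this
    exacerbation_lead_days: int = 7


@dataclass(frozen=True)
class QcDecision:
    participant_id: str
    night_date: dt.date
    kept: bool
    reasons: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.kept != (len(self.reasons) == 0):
            raise ValueError("kept must be equivalent to an empty reason set")


def _exacerbation_windows(roster: pd.DataFrame) -> dict[str, list[tuple]]:
    windows: dict[str, list[tuple]] = {}
    for row in roster.itertuples(index=False):
        windows.setdefault(row.participant_id, [])
        start = getattr(row, "exacerbation_start", None)
        end = getattr(row, "exacerbation_end", None)
        if pd.notna(start) and pd.notna(end):
            windows[row.participant_id].append(
                (pd.Timestamp(start).date(), pd.Timestamp(end).date())
            )
    return windows


def apply_night_exclusions(
    nights: pd.DataFrame,
    roster: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
) -> list[QcDecision]:
    """Evaluate the five exclusion rules on every night.

    ``nights`` must carry participant_id, night_date, artifact_motions,
    sleep_duration (h), data_loss_minutes, hr_mode and rr_mode; ``roster``
    must carry participant_id plus exacerbation_start/exacerbation_end (one
    row per window, blank for none).

    Raises
    ------
    KeyError
        If a night references a participant absent from the roster.
    """
    windows = _exacerbation_windows(roster)
    lead = dt.timedelta(days=thresholds.exacerbation_lead_days)
    decisions = []
    for row in nights.itertuples(index=False):
        if row.participant_id not in windows:
            raise KeyError(f"night references unknown participant {row.participant_id!r}")
        night_date = pd.Timestamp(row.night_date).date()
        reasons = []
        if row.artifact_motions >= thresholds.max_motions:
            reasons.append("motion")
        if row.sleep_duration < thresholds.min_sleep_h:
            reasons.append("sleep_short")
        if row.sleep_duration > thresholds.max_sleep_h:
            reasons.append("sleep_long")
        if row.data_loss_minutes >= thresholds.max_data_loss_min:
            reasons.append("data_loss")
        if row.hr_mode == 0 or row.rr_mode == 0:
            reasons.append("zero_vital")
        for w_start, w_end in windows[row.participant_id]:
            if w_start - lead <= night_date <= w_end:
                reasons.append("exacerbation")
                break
        decisions.append(
            QcDecision(
                participant_id=row.participant_id,
                night_date=night_date,
                kept=not reasons,
                reasons=tuple(reasons),
            )
        )
    return decisions


def decisions_to_frame(decisions) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [d.participant_id for d in decisions],
            "night_date": [d.night_date for d in decisions],
            "kept": [d.kept for d in decisions],
            "reasons": ["|".join(d.reasons) for d in decisions],
        }
    )


def filter_nights(
    nights: pd.DataFrame,
    roster: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (kept nightly rows, full decision table)."""
    decisions = apply_night_exclusions(nights, roster, thresholds)
    table = decisions_to_frame(decisions)
    kept_mask = table["kept"].to_numpy()
    return nights.loc[kept_mask].reset_index(drop=True), table
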