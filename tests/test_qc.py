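"""Night-level exclusion rules."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from noctivitals.qc import QcDecision, QcThresholds, apply_night_exclusions

D0 = dt.date(2021, 6, 1)


def _roster(windows=None):
    rows = []
    if windows:
        for start, end in windows:
            rows.append(
                {"participant_id": "P1", "exacerbation_start": start,
                 "exacerbation_end": end}
            )
    else:
        rows.append(
            {"participant_id": "P1", "exacerbation_start": pd.NaT,
             "exacerbation_end": pd.NaT}
        )
    return pd.DataFrame(rows)


def _night(**overrides):
    base = dict(
        participant_id="P1",
        night_date=D0,
        artifact_motions=10,
        sleep_duration=7.0,
        data_loss_minutes=0.0,
        hr_mode=60,
        rr_mode=15,
    )
    base.update(overrides)
    return pd.DataFrame([base])


@pytest.mark.parametrize(
    "overrides, expected_reasons",
    [
        ({}, ()),
        ({"artifact_motions": 600}, ("motion",)),  # boundary inclusive
        ({"artifact_motions": 599}, ()),
        ({"sleep_duration": 4.99}, ("sleep_short",)),
        ({"sleep_duration": 5.0}, ()),  # exactly 5 h kept ("less than")
        ({"sleep_duration": 9.0}, ()),  # exactly 9 h kept ("longer than")
        ({"sleep_duration": 9.01}, ("sleep_long",)),
        ({"data_loss_minutes": 60.0}, ("data_loss",)),  # ">=1 hour" inclusive
        ({"data_loss_minutes": 59.9}, ()),
        ({"hr_mode": 0}, ("zero_vital",)),
        ({"rr_mode": 0}, ("zero_vital",)),
        (
            {"artifact_motions": 700, "sleep_duration": 3.0},
            ("motion", "sleep_short"),
        ),
    ],
)
def test_rule_boundaries(overrides, expected_reasons):
    decisions = apply_night_exclusions(_night(**overrides), _roster())
    (decision,) = decisions
    assert decision.reasons == expected_reasons
    assert decision.kept == (not expected_reasons)


def test_exacerbation_window_boundaries():
    """Nights from 7 days before a window through its last day are excluded."""
    window = (D0, D0 + dt.timedelta(days=4))
    roster = _roster([window])
    for offset, excluded in [(-8, False), (-7, True), (0, True), (4, True), (5, False)]:
        night = _night(night_date=D0 + dt.timedelta(days=offset))
        (decision,) = apply_night_exclusions(night, roster)
        assert decision.kept == (not excluded), offset
        if excluded:
            assert decision.reasons == ("exacerbation",)


def test_unknown_participant_rejected():
    night = _night(participant_id="P9")
    with pytest.raises(KeyError, match="P9"):
        apply_night_exclusions(night, _roster())


def test_decision_invariant():
    with pytest.raises(ValueError):
        QcDecision("P1", D0, kept=True, reasons=("motion",))


def _random_nights(rng, n=1000):
    dates = [D0 + dt.timedelta(days=int(d)) for d in rng.integers(-20, 40, n)]
    return pd.DataFrame(
        {
            "participant_id": "P1",
            "night_date": dates,
            "artifact_motions": rng.integers(0, 1200, n),
            "sleep_duration": rng.uniform(3.0, 11.0, n).round(2),
            "data_loss_minutes": rng.uniform(0.0, 120.0, n).round(1),
            "hr_mode": rng.choice([0, 55, 60, 70], n, p=[0.05, 0.35, 0.35, 0.25]),
            "rr_mode": rng.choice([0, 14, 16, 22], n, p=[0.05, 0.35, 0.35, 0.25]),
        }
    )


def test_matches_brute_force_rule_oracle(rng):
    """Exhaustive re-evaluation of the rules as one boolean expression."""
    window = (D0, D0 + dt.timedelta(days=6))
    nights = _random_nights(rng)
    decisions = apply_night_exclusions(nights, _roster([window]))
    for row, decision in zip(nights.itertuples(index=False), decisions):
        in_window = (
            window[0] - dt.timedelta(days=7) <= row.night_date <= window[1]
        )
        keep = not (
            row.artifact_motions >= 600
            or row.sleep_duration < 5.0
            or row.sleep_duration > 9.0
            or row.data_loss_minutes >= 60.0
            or row.hr_mode == 0
            or row.rr_mode == 0
            or in_window
        )
        assert decision.kept == keep


def test_relaxing_thresholds_is_monotone(rng):
    """Loosening any single rule never excludes a previously kept night."""
    nights = _random_nights(rng, n=400)
    roster = _roster()
    base = apply_night_exclusions(nights, roster)
    relaxed_sets = [
        QcThresholds(max_motions=900),
        QcThresholds(min_sleep_h=4.0),
        QcThresholds(max_sleep_h=10.0),
        QcThresholds(max_data_loss_min=90.0),
        QcThresholds(exacerbation_lead_days=3),
    ]
    for thresholds in relaxed_sets:
        relaxed = apply_night_exclusions(nights, roster, thresholds)
        for before, after in zip(base, relaxed):
            if before.kept:
                assert after.kept
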