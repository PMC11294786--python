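"""Core domain types: phenotypes, cohort configuration, recordings, features."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

__all__ = [
    "FeaturePhenotype",
    "SimulationConfig",
    "ParticipantProfile",
    "NightRecording",
    "NightlyFeatures",
    "FEATURE_COLUMNS",
    "FEATURE_CATEGORIES",
]

#: Per-night feature columns, in canonical order.
FEATURE_COLUMNS = (
    "sdnn",
    "tp",
    "ulf",
    "vlf",
    "lf",
    "hf",
    "lf_hf",
    "hr_mode",
    "rr_mode",
    "rrf",
)

#: Vital-sign category membership used for category-level classification.
FEATURE_CATEGORIES = {
    "hrv": ("sdnn", "tp", "ulf", "vlf", "lf", "hf", "lf_hf"),
    "hr": ("hr_mode",),
    "respiration": ("rr_mode", "rrf"),
}

_BANDS = ("ulf", "vlf", "lf", "hf")


@dataclass(frozen=True)
class FeaturePhenotype:
    """Group-level generative parameters for one arm of the cohort.

    Band powers are median nightly levels in ms^2; per-person and per-night
    variation is lognormal on the powers (multiplicative, keeps them positive)
    and additive Gaussian on heart rate and respiratory rate. The
    between-person spreads control how far pooled person-time classification
    can get as the aggregation window grows: with no between-person spread a
    long enough window separates the groups perfectly, which real cohorts do
    not do.

    Parameters
    ----------
    mean_beat_interval : median nightly mean beat interval, ms.
    ulf, vlf, lf, hf : median nightly band powers, ms^2.
    mean_rr : median nightly respiratory rate, breaths/min.
    rr_sd : minute-to-minute spread of the respiratory-rate series, breaths/min.
    tachypnea_rate : median expected tachypneic (>21 breaths/min) minutes per
        night for a person of this group.
    band_sigma_between, band_sigma_night : lognormal sigma of the per-person /
        per-night multiplier on each band power.
    hr_sd_between, hr_sd_night : additive spread of nightly heart rate, beats/min.
    rr_sd_between, rr_sd_night : additive spread of nightly respiratory rate.
    tachypnea_sigma : lognormal sigma of the per-person tachypnea propensity.
    """

    mean_beat_interval: float
    ulf: float
    vlf: float
    lf: float
    hf: float
    mean_rr: float
    rr_sd: float
    tachypnea_rate: float
    band_sigma_between: Mapping[str, float] = field(
        default_factory=lambda: {"ulf": 0.50, "vlf": 0.50, "lf": 0.50, "hf": 0.50}
    )
    band_sigma_night: Mapping[str, float] = field(
        default_factory=lambda: {"ulf": 0.46, "vlf": 0.46, "lf": 0.46, "hf": 0.46}
    )
    hr_sd_between: float = 5.0
    hr_sd_night: float = 4.2
    rr_sd_between: float = 1.3
    rr_sd_night: float = 1.0
    tachypnea_sigma: float = 1.2

    def __post_init__(self) -> None:
        for name in ("ulf", "vlf", "lf", "hf"):
            if getattr(self, name) < 0:
                raise ValueError(f"band power {name} must be non-negative")
        if self.mean_beat_interval <= 0:
            raise ValueError("mean_beat_interval must be positive")
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.rr_sd < 0 or self.tachypnea_rate < 0:
            raise ValueError("rr_sd and tachypnea_rate must be non-negative")

    @property
    def band_targets(self) -> dict[str, float]:
        return {b: float(getattr(self, b)) for b in _BANDS}

    @property
    def total_power(self) -> float:
        return float(sum(self.band_targets.values()))

    @property
    def mean_heart_rate(self) -> float:
        return 60000.0 / self.mean_beat_interval


# Calibrated so pooled person-time AUCs of single features and categories fall
# where nocturnal COPD-vs-control monitoring places them (respiration strongest,
# HRV next, heart rate weak), with the LF/HF ratio matched between groups: cases
# have LF and HF elevated by the same multiplicative factor.
DEFAULT_CONTROL_PHENOTYPE = FeaturePhenotype(
    mean_beat_interval=984.0,  # ~61 beats/min
    ulf=1500.0,
    vlf=1000.0,
    lf=600.0,
    hf=400.0,
    mean_rr=14.8,
    rr_sd=1.0,
    tachypnea_rate=0.08,
)

DEFAULT_CASE_PHENOTYPE = FeaturePhenotype(
    mean_beat_interval=930.0,  # ~64.5 beats/min
    ulf=2163.0,
    vlf=1560.0,
    lf=1506.0,
    hf=1004.0,  # LF/HF = 1.5 in both groups
    mean_rr=16.8,
    rr_sd=1.0,
    tachypnea_rate=2.5,
    tachypnea_sigma=1.5,
)

#: Default probabilities that a recorded night violates each QC rule.
DEFAULT_QC_VIOLATION_RATES = {
    "motion": 0.02,
    "sleep_short": 0.03,
    "sleep_long": 0.02,
    "data_loss": 0.03,
    "zero_vital": 0.005,
}

NightsSpec = Union[int, tuple[float, float, float]]


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a simulated monitoring cohort.

    ``nights_per_person`` is either an exact count or a (median, q1, q3)
    target; the latter is realized as a rounded lognormal. ``compliance`` is
    the probability that a scheduled night is actually recorded.
    ``exacerbation_rate`` is expected acute-exacerbation events per case per
    30 scheduled nights.
    """

    n_cases: int = 37
    n_controls: int = 109
    nights_per_person: NightsSpec = (56.5, 32.0, 113.0)
    compliance: float = 0.73
    case_phenotype: FeaturePhenotype = DEFAULT_CASE_PHENOTYPE
    control_phenotype: FeaturePhenotype = DEFAULT_CONTROL_PHENOTYPE
    qc_violation_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_QC_VIOLATION_RATES)
    )
    exacerbation_rate: float = 0.15
    start_date: dt.date = dt.date(2021, 1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        if not 0.0 <= self.compliance <= 1.0:
            raise ValueError("compliance must be a probability")
        for key, rate in self.qc_violation_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"qc violation rate {key!r} must be in [0, 1]")
        if self.exacerbation_rate < 0:
            raise ValueError("exacerbation_rate must be non-negative")
        if isinstance(self.nights_per_person, int):
            if self.nights_per_person <= 0:
                raise ValueError("nights_per_person must be positive")


@dataclass(frozen=True)
class ParticipantProfile:
    """Roster entry for one participant."""

    participant_id: str
    group: str  # "case" | "control"
    age: int
    sex: str  # "male" | "female"
    bmi_category: str  # "<18.5" | "18.5-24" | ">=24"
    exacerbation_windows: tuple[tuple[dt.date, dt.date], ...] = ()

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValueError("group must be 'case' or 'control'")
        if self.group == "control" and self.exacerbation_windows:
            raise ValueError("controls cannot have exacerbation windows")
        for start, end in self.exacerbation_windows:
            if end < start:
                raise ValueError("exacerbation window end precedes start")


@dataclass
class NightRecording:
    """One night's raw recording: tachogram, respiration, and QC metadata.

    ``beat_times`` are seconds from 10 PM, strictly increasing;
    ``beat_intervals`` are the successive differences in ms.
    """

    participant_id: str
    night_date: dt.date
    beat_times: np.ndarray
    beat_intervals: np.ndarray
    rr_per_minute: np.ndarray
    artifact_motions: int
    sleep_duration: float  # hours
    data_loss_minutes: float

    MAX_SPAN_S = 10 * 3600.0  # 10 PM to 8 AM

    def validate(self) -> None:
        if len(self.beat_times) != len(self.beat_intervals) + 1:
            raise ValueError("len(beat_times) must be len(beat_intervals) + 1")
        diffs_ms = np.diff(self.beat_times) * 1000.0
        if not np.allclose(diffs_ms, self.beat_intervals, rtol=0, atol=1e-6):
            raise ValueError("beat_intervals do not match beat_times differences")
        if np.any(self.beat_intervals <= 0):
            raise ValueError("beat intervals must be positive")
        if self.beat_times[-1] - self.beat_times[0] > self.MAX_SPAN_S:
            raise ValueError("recording span exceeds 10 h")


@dataclass(frozen=True)
class NightlyFeatures:
    """The ten per-night statistics: HRV spectral indices, modal HR/RR, RRF."""

    sdnn: float
    tp: float
    ulf: float
    vlf: float
    lf: float
    hf: float
    lf_hf: float
    hr_mode: int
    rr_mode: int
    rrf: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_COLUMNS}
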