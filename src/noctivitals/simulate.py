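"""Synthetic multi-night cohort generation.

Two generation paths share one statistical model:

* ``generate_cohort`` emits raw :class:`NightRecording` objects — a synthesized
  tachogram (random-phase band-limited spectral synthesis integrated to beat
  times) and a per-minute respiratory-rate series — from which features are
  then *estimated* exactly as they would be from device data.
* ``generate_feature_cohort`` emits the nightly feature table directly from the
  same per-person/per-night parameter draws, with a small lognormal
  measurement-noise term standing in for spectral-estimation error. This path
  makes cohort-scale experiments (hundreds of thousands of nights) cheap.

The hierarchical model: each participant draws person-level offsets (lognormal
multipliers on band powers, additive shifts on heart and respiratory rate, a
lognormal tachypnea propensity); each recorded night then draws night-level
offsets around the person level. QC-violating nights are injected by
overriding metadata (artifact-motion count, sleep duration, data loss,
zero-vital flag) independently of the signal, so each exclusion rule can be
exercised in isolation.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    FeaturePhenotype,
    NightRecording,
    ParticipantProfile,
    SimulationConfig,
)

__all__ = [
    "simulate_tachogram",
    "simulate_respiration",
    "generate_cohort",
    "generate_feature_cohort",
    "roster_to_frame",
    "write_cohort",
    "read_cohort",
]

_BANDS = ("ulf", "vlf", "lf", "hf")
_BAND_EDGES = {"ulf": 0.0033, "vlf": 0.04, "lf": 0.15, "hf": 0.40}
_BAND_LOWER = {"ulf": 0.0, "vlf": 0.0033, "lf": 0.04, "hf": 0.15}
#: A nonzero band target needs at least this many Fourier bins inside the band.
_MIN_BINS = 12

# lognormal sigma of the estimator-noise term in the feature-level path,
# matching the observed spread of the spectral estimator on synthetic nights
_MEASUREMENT_SIGMA = {"band": 0.08, "tp": 0.08, "sdnn": 0.04, "lf_hf": 0.06}

# Cross-feature correlation structure. Vital-sign features co-vary within a
# person (one autonomic/disease-severity state drives them), so person-level
# offsets are built from shared factors: a global severity factor loading on
# every feature plus a common band factor; the weights are the variance
# fractions each factor contributes (the remainder is idiosyncratic). Night
# offsets of the four bands likewise share a common nightly factor. Marginal
# feature distributions are unchanged; what this bounds is how much a
# multivariate classifier can gain by combining features.
_PERSON_FACTOR_WEIGHTS = {
    "bands_global": 0.35,
    "bands_common": 0.35,
    "hr_global": 0.20,
    "rr_global": 0.30,
    "tachy_global": 0.30,
}
_NIGHT_BAND_COMMON_WEIGHT = 0.5

# The sympathovagal balance (LF/HF) is treated as a stable individual trait:
# the person-level LF offset equals the HF offset exactly, and the nightly
# log-ratio fluctuates with this spread. The pooled LF/HF distribution is then
# identical between groups at every level of the hierarchy.
_LF_HF_RATIO_NIGHT_SD = 0.25


def _mix(shared_terms: list[tuple[float, float]], idio: float) -> float:
    """Sum sqrt(weight)*factor terms plus the idiosyncratic remainder."""
    total = 0.0
    used = 0.0
    for weight, factor in shared_terms:
        total += math.sqrt(weight) * factor
        used += weight
    return total + math.sqrt(max(1.0 - used, 0.0)) * idio


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _round_half_up(x) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def synthesize_tachogram(
    band_powers: dict[str, float],
    mean_beat_interval: float,
    duration_h: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random-phase spectral synthesis of a beat-interval series.

    Each band's target power (ms^2) is spread uniformly over the Fourier bins
    inside the band with deterministic amplitudes and uniform random phases,
    so the realized grid variance equals the summed targets exactly. The
    modulation is sampled at nominal beat positions and integrated to beat
    times (interval i starts at the cumulative sum of intervals 0..i-1).
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    if mean_beat_interval <= 0:
        raise ValueError("mean beat interval must be positive")
    duration_s = duration_h * 3600.0
    for band, power in band_powers.items():
        if power < 0:
            raise ValueError(f"band power {band} must be non-negative")
        if power > 0 and duration_s * _BAND_EDGES[band] < _MIN_BINS:
            raise ValueError(
                f"{band.upper()} power requested but a {duration_h:.2f} h record "
                f"cannot resolve frequencies below {_BAND_EDGES[band]} Hz"
            )

    dt_s = mean_beat_interval / 1000.0
    n = int(round(duration_s / dt_s))
    if n < 2:
        raise ValueError("duration too short for the requested beat interval")

    freqs = np.fft.rfftfreq(n, d=dt_s)
    spectrum = np.zeros(len(freqs), dtype=complex)
    for band, power in band_powers.items():
        if power <= 0:
            continue
        mask = (freqs >= _BAND_LOWER[band]) & (freqs < _BAND_EDGES[band]) & (freqs > 0)
        n_bins = int(mask.sum())
        if n_bins == 0:
            raise ValueError(f"no resolvable bins in band {band}")
        amplitude = math.sqrt(2.0 * power / n_bins)
        phases = rng.uniform(0.0, 2.0 * np.pi, n_bins)
        spectrum[mask] = (n * amplitude / 2.0) * np.exp(1j * phases)

    modulation = np.fft.irfft(spectrum, n=n)
    intervals = mean_beat_interval + modulation
    if np.any(intervals <= 0):
        raise ValueError("requested band powers too large: non-positive intervals")
    beat_times = np.concatenate([[0.0], np.cumsum(intervals) / 1000.0])
    return beat_times, intervals


def simulate_tachogram(
    phenotype: FeaturePhenotype, duration_h: float, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize one night's tachogram at the phenotype's band targets."""
    rng = _as_rng(seed)
    return synthesize_tachogram(
        phenotype.band_targets, phenotype.mean_beat_interval, duration_h, rng
    )


def simulate_respiration(
    phenotype: FeaturePhenotype, duration_h: float, seed
) -> np.ndarray:
    """One respiratory-rate value (breaths/min) per elapsed minute.

    Baseline minutes are Gaussian around ``mean_rr``; a Poisson-distributed
    number of minutes (mean ``tachypnea_rate``) is replaced by tachypneic
    values above 21 breaths/min.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    rng = _as_rng(seed)
    n_min = int(round(duration_h * 60.0))
    rr = rng.normal(phenotype.mean_rr, phenotype.rr_sd, n_min)
    rr = np.clip(rr, 1.0, None)
    n_tachy = min(int(rng.poisson(phenotype.tachypnea_rate)), n_min)
    if n_tachy > 0:
        idx = rng.choice(n_min, size=n_tachy, replace=False)
        rr[idx] = rng.uniform(21.5, 30.0, n_tachy)
    return rr


# ---------------------------------------------------------------------------
# cohort-level draws
# ---------------------------------------------------------------------------

_BMI_CATEGORIES = ("<18.5", "18.5-24", ">=24")
# Demographic mix of a hospital COPD cohort vs community controls:
# cases skew old, male, and lean.
_DEMOGRAPHICS = {
    "case": {"age": (72.0, 7.0), "p_male": 0.81, "bmi_p": (0.162, 0.757, 0.081)},
    "control": {"age": (57.0, 8.0), "p_male": 0.37, "bmi_p": (0.018, 0.615, 0.367)},
}


def _draw_nights_count(spec, rng: np.random.Generator) -> int:
    if isinstance(spec, int):
        return spec
    median, q1, q3 = spec
    sigma = (math.log(q3) - math.log(q1)) / (2.0 * 0.6744897501960817)  # 2 z_0.75
    n = int(round(float(rng.lognormal(math.log(median), sigma))))
    return max(7, min(n, 400))


def _draw_participants(
    config: SimulationConfig, rng: np.random.Generator
) -> list[dict]:
    """Draw profiles plus person-level generative parameters."""
    people = []
    specs = [("case", config.n_cases, config.case_phenotype)] + [
        ("control", config.n_controls, config.control_phenotype)
    ]
    idx = 0
    for group, n_group, ph in specs:
        for _ in range(n_group):
            idx += 1
            pid = f"P{idx:04d}"
            demo = _DEMOGRAPHICS[group]
            age = int(np.clip(rng.normal(*demo["age"]), 45, 95))
            sex = "male" if rng.random() < demo["p_male"] else "female"
            bmi = _BMI_CATEGORIES[int(rng.choice(3, p=demo["bmi_p"]))]
            n_nights = _draw_nights_count(config.nights_per_person, rng)
            start = config.start_date + dt.timedelta(days=int(rng.integers(0, 600)))

            w = _PERSON_FACTOR_WEIGHTS
            severity = rng.normal()
            band_common = rng.normal()
            band_offsets = {
                b: ph.band_sigma_between[b]
                * _mix(
                    [(w["bands_global"], severity), (w["bands_common"], band_common)],
                    rng.normal(),
                )
                for b in ("ulf", "vlf", "hf")
            }
            # LF/HF set point is an individual constant: LF inherits HF's
            # person offset (band sigmas for lf and hf are kept equal)
            band_offsets["lf"] = band_offsets["hf"]
            person_hr = ph.mean_heart_rate + ph.hr_sd_between * _mix(
                [(w["hr_global"], severity)], rng.normal()
            )
            person_rr = ph.mean_rr + ph.rr_sd_between * _mix(
                [(w["rr_global"], severity)], rng.normal()
            )
            person_tachy = ph.tachypnea_rate * math.exp(
                ph.tachypnea_sigma
                * _mix([(w["tachy_global"], severity)], rng.normal())
            )

            windows: list[tuple[dt.date, dt.date]] = []
            if group == "case" and config.exacerbation_rate > 0:
                n_events = rng.poisson(config.exacerbation_rate * n_nights / 30.0)
                for _ in range(int(n_events)):
                    w_start = start + dt.timedelta(days=int(rng.integers(0, n_nights)))
                    w_len = int(rng.integers(3, 11))  # 3-10 days
                    windows.append((w_start, w_start + dt.timedelta(days=w_len - 1)))
                windows.sort()

            people.append(
                {
                    "profile": ParticipantProfile(
                        participant_id=pid,
                        group=group,
                        age=age,
                        sex=sex,
                        bmi_category=bmi,
                        exacerbation_windows=tuple(windows),
                    ),
                    "phenotype": ph,
                    "n_nights": n_nights,
                    "start": start,
                    "band_offsets": band_offsets,
                    "person_hr": max(person_hr, 35.0),
                    "person_rr": max(person_rr, 6.0),
                    "person_tachy": person_tachy,
                }
            )
    return people


def _draw_night_table(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[ParticipantProfile], pd.DataFrame]:
    """Scheduled-night realization: one row per *recorded* night.

    Columns carry the night's realized generative targets (band powers, heart
    rate, respiratory rate, tachypnea rate) plus QC metadata; downstream the
    signal path synthesizes recordings from them and the feature path maps
    them to features.
    """
    people = _draw_participants(config, rng)
    rates = config.qc_violation_rates
    rows = []
    for person in people:
        ph: FeaturePhenotype = person["phenotype"]
        for day in range(person["n_nights"]):
            if rng.random() >= config.compliance:
                continue  # scheduled night not recorded
            night_date = person["start"] + dt.timedelta(days=day)

            night_common = rng.normal()
            night_offsets = {
                b: ph.band_sigma_night[b]
                * _mix([(_NIGHT_BAND_COMMON_WEIGHT, night_common)], rng.normal())
                for b in ("ulf", "vlf", "hf")
            }
            # nightly LF/HF ratio jitter around the person's fixed set point
            night_offsets["lf"] = night_offsets["hf"] + rng.normal(
                0.0, _LF_HF_RATIO_NIGHT_SD
            )
            bands = {
                b: getattr(ph, b)
                * math.exp(person["band_offsets"][b] + night_offsets[b])
                for b in _BANDS
            }
            hr_night = max(person["person_hr"] + rng.normal(0.0, ph.hr_sd_night), 35.0)
            rr_night = max(person["person_rr"] + rng.normal(0.0, ph.rr_sd_night), 6.0)

            motion_violation = rng.random() < rates.get("motion", 0.0)
            motions = (
                int(rng.integers(600, 1200))
                if motion_violation
                else int(rng.lognormal(3.5, 1.0))
            )
            motions = min(motions, 599) if not motion_violation else motions

            sleep = float(np.clip(rng.normal(7.2, 0.6), 5.05, 8.95))
            if rng.random() < rates.get("sleep_short", 0.0):
                sleep = float(rng.uniform(3.5, 4.99))
            elif rng.random() < rates.get("sleep_long", 0.0):
                sleep = float(rng.uniform(9.01, 9.9))

            loss = float(min(rng.exponential(5.0), 59.0))
            if rng.random() < rates.get("data_loss", 0.0):
                loss = float(rng.uniform(60.0, 240.0))

            zero_vital = rng.random() < rates.get("zero_vital", 0.0)

            rows.append(
                {
                    "participant_id": person["profile"].participant_id,
                    "group": person["profile"].group,
                    "night_date": night_date,
                    "ulf_target": bands["ulf"],
                    "vlf_target": bands["vlf"],
                    "lf_target": bands["lf"],
                    "hf_target": bands["hf"],
                    "hr_night": hr_night,
                    "rr_night": rr_night,
                    "rr_minute_sd": ph.rr_sd,
                    "tachy_rate": person["person_tachy"],
                    "artifact_motions": motions,
                    "sleep_duration": sleep,
                    "data_loss_minutes": loss,
                    "zero_vital": zero_vital,
                }
            )
    table = pd.DataFrame(rows)
    return [p["profile"] for p in people], table


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[ParticipantProfile], list[NightRecording]]:
    """Generate a roster and raw per-night recordings (signal level)."""
    rng = np.random.default_rng(config.seed)
    roster, table = _draw_night_table(config, rng)
    recordings: list[NightRecording] = []
    for row in table.itertuples(index=False):
        duration = min(row.sleep_duration, 10.0)
        bands = {
            "ulf": row.ulf_target,
            "vlf": row.vlf_target,
            "lf": row.lf_target,
            "hf": row.hf_target,
        }
        beat_times, intervals = synthesize_tachogram(
            bands, 60000.0 / row.hr_night, duration, rng
        )
        n_min = int(round(duration * 60.0))
        if row.zero_vital:
            rr = np.zeros(n_min)
        else:
            rr = rng.normal(row.rr_night, row.rr_minute_sd, n_min)
            rr = np.clip(rr, 1.0, None)
            n_tachy = min(int(rng.poisson(row.tachy_rate)), n_min)
            if n_tachy > 0:
                idx = rng.choice(n_min, size=n_tachy, replace=False)
                rr[idx] = rng.uniform(21.5, 30.0, n_tachy)
        recordings.append(
            NightRecording(
                participant_id=row.participant_id,
                night_date=row.night_date,
                beat_times=beat_times,
                beat_intervals=intervals,
                rr_per_minute=rr,
                artifact_motions=int(row.artifact_motions),
                sleep_duration=float(row.sleep_duration),
                data_loss_minutes=float(row.data_loss_minutes),
            )
        )
    return roster, recordings


def generate_feature_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a roster frame and the nightly feature table directly.

    Statistically equivalent to running the full extraction on
    :func:`generate_cohort` output, with spectral-estimation error emulated by
    independent lognormal factors; used for cohort-scale experiments.
    """
    rng = np.random.default_rng(config.seed)
    roster, table = _draw_night_table(config, rng)
    n = len(table)
    sig = _MEASUREMENT_SIGMA

    band_values = {}
    for b in _BANDS:
        band_values[b] = table[f"{b}_target"].to_numpy() * np.exp(
            rng.normal(0.0, sig["band"], n)
        )
    tp_true = sum(table[f"{b}_target"].to_numpy() for b in _BANDS)
    features = pd.DataFrame(
        {
            "participant_id": table["participant_id"],
            "night_date": table["night_date"],
            "sdnn": np.sqrt(tp_true) * np.exp(rng.normal(0.0, sig["sdnn"], n)),
            "tp": tp_true * np.exp(rng.normal(0.0, sig["tp"], n)),
            "ulf": band_values["ulf"],
            "vlf": band_values["vlf"],
            "lf": band_values["lf"],
            "hf": band_values["hf"],
            "lf_hf": (
                table["lf_target"].to_numpy() / table["hf_target"].to_numpy()
            )
            * np.exp(rng.normal(0.0, sig["lf_hf"], n)),
            "hr_mode": _round_half_up(table["hr_night"].to_numpy()),
            "rr_mode": _round_half_up(table["rr_night"].to_numpy()),
            "rrf": rng.poisson(table["tachy_rate"].to_numpy()),
            "artifact_motions": table["artifact_motions"],
            "sleep_duration": table["sleep_duration"],
            "data_loss_minutes": table["data_loss_minutes"],
        }
    )
    zero = table["zero_vital"].to_numpy()
    features.loc[zero, ["rr_mode", "rrf"]] = 0
    return roster_to_frame(roster), features


def roster_to_frame(roster: Sequence[ParticipantProfile]) -> pd.DataFrame:
    """Roster as a frame with one row per exacerbation window (or one bare row)."""
    rows = []
    for p in roster:
        base = {
            "participant_id": p.participant_id,
            "group": p.group,
            "age": p.age,
            "sex": p.sex,
            "bmi_category": p.bmi_category,
        }
        if p.exacerbation_windows:
            for start, end in p.exacerbation_windows:
                rows.append({**base, "exacerbation_start": start, "exacerbation_end": end})
        else:
            rows.append({**base, "exacerbation_start": pd.NaT, "exacerbation_end": pd.NaT})
    frame = pd.DataFrame(rows)
    frame["exacerbation_start"] = pd.to_datetime(frame["exacerbation_start"])
    frame["exacerbation_end"] = pd.to_datetime(frame["exacerbation_end"])
    return frame


# ---------------------------------------------------------------------------
# delimited-text persistence
# ---------------------------------------------------------------------------


def write_cohort(out_dir, roster: Sequence[ParticipantProfile], recordings) -> None:
    """Write roster.csv, nights_index.csv and one night_<id>_<date>.csv per night.

    Night files carry the beat block (beat_time_s for every beat, interval_ms
    for every interval — the last beat row has an empty interval) and the
    respiration block (minute_index, rr) side by side as padded columns.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roster_to_frame(roster).to_csv(out / "roster.csv", index=False)

    index_rows = []
    for rec in recordings:
        name = f"night_{rec.participant_id}_{rec.night_date.isoformat()}.csv"
        n_beats = len(rec.beat_times)
        n_min = len(rec.rr_per_minute)
        n_rows = max(n_beats, n_min)

        def pad(values, length):
            col = np.full(length, np.nan)
            col[: len(values)] = values
            return col

        frame = pd.DataFrame(
            {
                "beat_time_s": pad(rec.beat_times, n_rows),
                "interval_ms": pad(rec.beat_intervals, n_rows),
                "minute_index": pad(np.arange(n_min), n_rows),
                "rr": pad(rec.rr_per_minute, n_rows),
            }
        )
        frame.to_csv(out / name, index=False)
        index_rows.append(
            {
                "participant_id": rec.participant_id,
                "night_date": rec.night_date,
                "file": name,
                "artifact_motions": rec.artifact_motions,
                "sleep_duration": rec.sleep_duration,
                "data_loss_minutes": rec.data_loss_minutes,
            }
        )
    pd.DataFrame(index_rows).to_csv(out / "nights_index.csv", index=False)


def read_cohort(in_dir) -> tuple[pd.DataFrame, list[NightRecording]]:
    """Read a cohort written by :func:`write_cohort`."""
    from pathlib import Path

    src = Path(in_dir)
    roster = pd.read_csv(
        src / "roster.csv", parse_dates=["exacerbation_start", "exacerbation_end"]
    )
    index = pd.read_csv(src / "nights_index.csv", parse_dates=["night_date"])
    recordings = []
    for row in index.itertuples(index=False):
        frame = pd.read_csv(src / row.file)
        beat_times = frame["beat_time_s"].dropna().to_numpy()
        intervals = frame["interval_ms"].dropna().to_numpy()
        rr = frame["rr"].dropna().to_numpy()
        recordings.append(
            NightRecording(
                participant_id=row.participant_id,
                night_date=row.night_date.date(),
                beat_times=beat_times,
                beat_intervals=intervals,
                rr_per_minute=rr,
                artifact_motions=int(row.artifact_motions),
                sleep_duration=float(row.sleep_duration),
                data_loss_minutes=float(row.data_loss_minutes),
            )
        )
    return roster, recordings
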