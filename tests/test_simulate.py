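"""Synthetic cohort generation: determinism, invariants, effect structure."""

import numpy as np
import pandas as pd
import pytest

import noctivitals as nv
from noctivitals.diagnostics import mann_whitney_z


def test_generate_cohort_is_deterministic():
    config = nv.SimulationConfig(n_cases=2, n_controls=2, nights_per_person=5, seed=1)
    roster_a, recs_a = nv.generate_cohort(config)
    roster_b, recs_b = nv.generate_cohort(config)
    assert roster_a == roster_b
    assert len(recs_a) == len(recs_b)
    for a, b in zip(recs_a, recs_b):
        assert a.participant_id == b.participant_id and a.night_date == b.night_date
        np.testing.assert_array_equal(a.beat_times, b.beat_times)
        np.testing.assert_array_equal(a.rr_per_minute, b.rr_per_minute)


def test_feature_cohort_is_deterministic():
    config = nv.SimulationConfig(n_cases=4, n_controls=4, nights_per_person=10, seed=3)
    roster_a, nights_a = nv.generate_feature_cohort(config)
    roster_b, nights_b = nv.generate_feature_cohort(config)
    pd.testing.assert_frame_equal(roster_a, roster_b)
    pd.testing.assert_frame_equal(nights_a, nights_b)


def test_full_compliance_yields_every_scheduled_night():
    config = nv.SimulationConfig(
        n_cases=3, n_controls=2, nights_per_person=30, compliance=1.0, seed=5
    )
    _, nights = nv.generate_feature_cohort(config)
    counts = nights.groupby("participant_id").size()
    assert len(counts) == 5
    assert (counts == 30).all()


def test_generated_recordings_satisfy_type_invariants():
    """Every generated night passes its own structural validation."""
    config = nv.SimulationConfig(
        n_cases=9, n_controls=9, nights_per_person=56, seed=11
    )
    _, recordings = nv.generate_cohort(config)
    assert len(recordings) >= 700
    for rec in recordings:
        rec.validate()  # interval/beat-time consistency, positivity, <=10 h


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="positive"):
        nv.SimulationConfig(n_cases=0, n_controls=5)
    with pytest.raises(ValueError, match="probability"):
        nv.SimulationConfig(compliance=1.5)
    with pytest.raises(ValueError):
        nv.FeaturePhenotype(
            mean_beat_interval=1000, ulf=1, vlf=1, lf=1, hf=-1,
            mean_rr=15, rr_sd=1, tachypnea_rate=0,
        )


class TestTachogramSynthesis:
    def test_zero_power_gives_constant_intervals(self):
        ph = nv.FeaturePhenotype(
            mean_beat_interval=800.0, ulf=0, vlf=0, lf=0, hf=0,
            mean_rr=15, rr_sd=1, tachypnea_rate=0,
        )
        _, intervals = nv.simulate_tachogram(ph, 2.0, 0)
        assert np.allclose(intervals, 800.0)
        assert nv.compute_sdnn(intervals) == 0.0

    def test_mean_interval_sets_mean_heart_rate(self):
        ph = nv.FeaturePhenotype(
            mean_beat_interval=1000.0, ulf=0, vlf=0, lf=100, hf=100,
            mean_rr=15, rr_sd=1, tachypnea_rate=0,
        )
        _, intervals = nv.simulate_tachogram(ph, 2.0, 0)
        assert abs(60000.0 / intervals.mean() - 60.0) < 0.5

    def test_hf_target_recovered_by_estimator(self):
        target = 500.0
        ph = nv.FeaturePhenotype(
            mean_beat_interval=900.0, ulf=0, vlf=0, lf=0, hf=target,
            mean_rr=15, rr_sd=1, tachypnea_rate=0,
        )
        bt, iv = nv.simulate_tachogram(ph, 8.0, 123)
        bp = nv.compute_band_powers(bt, iv)
        assert 0.85 * target <= bp.hf <= 1.15 * target
        assert bp.lf < 0.1 * target

    def test_unresolvable_slow_band_raises(self):
        ph = nv.DEFAULT_CONTROL_PHENOTYPE  # nonzero ULF target
        with pytest.raises(ValueError, match="ULF"):
            nv.simulate_tachogram(ph, 0.5, 0)

    def test_beat_times_integrate_intervals(self):
        bt, iv = nv.simulate_tachogram(nv.DEFAULT_CASE_PHENOTYPE, 2.0, 9)
        np.testing.assert_allclose(np.diff(bt) * 1000.0, iv, atol=1e-6)


class TestRespirationSynthesis:
    def test_degenerate_parameters_give_constant_series(self):
        ph = nv.FeaturePhenotype(
            mean_beat_interval=1000, ulf=0, vlf=0, lf=0, hf=0,
            mean_rr=14.0, rr_sd=0.0, tachypnea_rate=0.0,
        )
        rr = nv.simulate_respiration(ph, 10.0, 0)
        assert np.all(rr == 14.0)
        assert nv.compute_rrf(rr) == 0

    def test_one_value_per_minute(self):
        rr = nv.simulate_respiration(nv.DEFAULT_CONTROL_PHENOTYPE, 1.0, 0)
        assert len(rr) == 60

    def test_tachypnea_rate_controls_expected_rrf(self):
        """Monte-Carlo mean of nightly RRF tracks the requested rate."""
        ph = nv.FeaturePhenotype(
            mean_beat_interval=1000, ulf=0, vlf=0, lf=0, hf=0,
            mean_rr=15.0, rr_sd=1.0, tachypnea_rate=30.0,
        )
        rrfs = [
            nv.compute_rrf(nv.simulate_respiration(ph, 10.0, seed))
            for seed in range(200)
        ]
        assert 27.0 <= np.mean(rrfs) <= 33.0


def test_case_control_effect_directions():
    """Cases exceed controls on every feature except the LF/HF ratio."""
    config = nv.SimulationConfig(
        n_cases=50, n_controls=50, nights_per_person=30, seed=101
    )
    roster, nights = nv.generate_feature_cohort(config)
    groups = roster.drop_duplicates("participant_id").set_index("participant_id")[
        "group"
    ]
    labelled = nights.assign(group=nights["participant_id"].map(groups))
    case = labelled[labelled.group == "case"]
    ctrl = labelled[labelled.group == "control"]
    for feature in nv.FEATURE_COLUMNS:
        if feature == "lf_hf":
            continue
        res = mann_whitney_z(case[feature], ctrl[feature])
        assert res.statistic > 0, feature  # case > control direction
        assert res.p_value < 0.05, feature

    # the matched sympathovagal ratio carries no group signal: non-significant
    # in the clear majority of replicate cohorts
    non_sig = 0
    for seed in range(5):
        cfg = nv.SimulationConfig(
            n_cases=50, n_controls=50, nights_per_person=30, seed=200 + seed
        )
        roster, nights = nv.generate_feature_cohort(cfg)
        groups = roster.drop_duplicates("participant_id").set_index(
            "participant_id"
        )["group"]
        labelled = nights.assign(group=nights["participant_id"].map(groups))
        res = mann_whitney_z(
            labelled.loc[labelled.group == "case", "lf_hf"],
            labelled.loc[labelled.group == "control", "lf_hf"],
        )
        non_sig += res.p_value >= 0.05
    assert non_sig >= 4


def test_cohort_roundtrip_through_csv(tmp_path, tiny_signal_cohort):
    _, roster, recordings = tiny_signal_cohort
    nv.write_cohort(tmp_path, roster, recordings)
    roster_back, recs_back = nv.read_cohort(tmp_path)
    assert len(recs_back) == len(recordings)
    assert set(roster_back["participant_id"]) == {p.participant_id for p in roster}
    for a, b in zip(recordings, recs_back):
        np.testing.assert_allclose(a.beat_times, b.beat_times, atol=1e-6)
        np.testing.assert_allclose(a.rr_per_minute, b.rr_per_minute, atol=1e-9)
        assert a.artifact_motions == b.artifact_motions
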