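"""Scenario generator: kinematic truth, AIS sampling, RL synthesis, preset."""

import math

import numpy as np
import pandas as pd
import pytest

from ferrynoise.errors import ConfigError
from ferrynoise.kinematics import speed_through_water
from ferrynoise.pipeline import analyze
from ferrynoise.scenarios import (
    TIDAL_PERIOD_H,
    ScenarioConfig,
    gen_kinematics,
    generate_scenario,
    make_currents,
    paper_calibrated_preset,
    sample_ais,
    write_scenario,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


class TestGenKinematics:
    def test_plateau_equals_operational_speed(self, rng):
        truth = gen_kinematics(ScenarioConfig(), "outgoing", rng)
        mid = slice(len(truth["v_kn"]) // 2 - 200, len(truth["v_kn"]) // 2 + 200)
        assert np.allclose(truth["v_kn"][mid], 12.8)

    def test_ramp_integral_reaches_operational_speed(self, rng):
        truth = gen_kinematics(ScenarioConfig(), "outgoing", rng)
        i_end = int(truth["accel_window_s"][1])
        assert truth["v_kn"][i_end] == pytest.approx(truth["plateau_speed_kn"], rel=1e-6)
        assert truth["v_kn"][0] == pytest.approx(0.0, abs=1e-3)

    def test_duration_near_study_average(self):
        durations = [
            gen_kinematics(ScenarioConfig(), "outgoing", np.random.default_rng(s))["total_min"]
            for s in range(24)
        ]
        assert all(65.0 <= d <= 85.0 for d in durations)
        assert abs(np.mean(durations) - 75.0) <= 10.0

    def test_event_between_peaks(self, rng):
        for direction in ("outgoing", "incoming"):
            truth = gen_kinematics(ScenarioConfig(), direction, rng)
            p1, p2 = truth["event_peaks_s"]
            assert p1 < truth["t_event_s"] < p2
            lo, hi = truth["event_window_s"]
            assert lo <= truth["t_event_s"] <= hi

    def test_phases_must_fit(self, rng):
        config = ScenarioConfig(transit_duration_mean_min=20.0, transit_duration_sd_min=0.0)
        with pytest.raises(ConfigError):
            gen_kinematics(config, "outgoing", rng)

    def test_phase_time_share_matches_study(self):
        """Across a 24-transit batch, ~20% of transit time is in speed change."""
        shares = []
        for s in range(24):
            t = gen_kinematics(ScenarioConfig(), "outgoing", np.random.default_rng(s))
            shares.append(100.0 * (t["accel_min"] + t["decel_min"]) / t["total_min"])
        assert abs(np.mean(shares) - 20.0) <= 3.0


class TestSampleAIS:
    def test_zero_current_sog_equals_water_speed(self, rng):
        config = ScenarioConfig(current_amp_kn=0.0)
        truth = gen_kinematics(config, "outgoing", rng)
        currents = make_currents(config, 1, slack_hour=3.0)
        start = pd.Timestamp("2020-07-22 08:02-04:00")
        ais = sample_ais(truth, currents, config, start)
        v = np.interp(
            (pd.DatetimeIndex(ais["timestamp"]) - start).total_seconds(),
            truth["t_s"], truth["v_kn"], left=0.0, right=0.0,
        )
        assert np.allclose(ais["sog_kn"], v, atol=1e-9)

    def test_tail_current_adds_to_sog(self, rng):
        config = ScenarioConfig(current_amp_kn=2.0)
        truth = gen_kinematics(config, "outgoing", rng)  # heading 270
        currents = pd.DataFrame(
            {
                "timestamp": pd.date_range(
                    "2020-07-22 00:00", periods=48, freq="h", tz="-04:00"
                ),
                "orientation_deg": 270.0,  # pure tail current for a westbound leg
                "speed_kn": 2.0,
            }
        )
        start = pd.Timestamp("2020-07-22 08:02-04:00")
        ais = sample_ais(truth, currents, config, start)
        mid = len(ais) // 2
        v_mid = np.interp(
            (ais["timestamp"].iloc[mid] - start).total_seconds(), truth["t_s"], truth["v_kn"]
        )
        assert ais["sog_kn"].iloc[mid] == pytest.approx(v_mid + 2.0, abs=1e-9)

    def test_stw_round_trip(self, rng):
        config = ScenarioConfig()
        truth = gen_kinematics(config, "incoming", rng)
        currents = make_currents(config, 1, slack_hour=5.0)
        start = pd.Timestamp("2020-07-22 10:00-04:00")
        ais = sample_ais(truth, currents, config, start)
        joined = pd.merge_asof(
            ais.sort_values("timestamp"), currents, on="timestamp", direction="nearest"
        )
        stw = speed_through_water(
            joined["sog_kn"], joined["cog_deg"], joined["orientation_deg"], joined["speed_kn"]
        )
        v = np.interp(
            (pd.DatetimeIndex(ais["timestamp"]) - start).total_seconds(),
            truth["t_s"], truth["v_kn"], left=0.0, right=0.0,
        )
        assert np.max(np.abs(stw - v)) < 0.01


class TestGenRL:
    def test_rest_blocks_equal_ambient_model(self):
        config = paper_calibrated_preset()
        config.ambient_jitter_db = 0.0
        config.source.unpaired_fraction = 0.0
        sc = generate_scenario(config, 1, 0, seed=3)
        truth = sc.truth[0]
        start = pd.Timestamp(truth["start"])
        rest = sc.rl[sc.rl.index < start]
        assert len(rest) > 0
        # flat ambient: all bands identical, and within the tidal excursion band
        assert np.allclose(rest.to_numpy(), rest.to_numpy()[:, [0]])
        assert rest.to_numpy().min() >= config.ambient_band_db - 1e-9
        assert rest.to_numpy().max() <= config.ambient_band_db + config.ambient_tidal_amp_db + 1e-9

    def test_ambient_minima_at_slack(self):
        """The ambient modulation is quiet at slack water (|sin| phase zero)."""
        config = paper_calibrated_preset()
        config.ambient_jitter_db = 0.0
        sc = generate_scenario(config, 1, 0, seed=3)
        # slack times are where the current speed vanishes; ambient and current
        # share the same tidal phase by construction
        cur = sc.currents.set_index("timestamp")["speed_kn"]
        slack_times = cur[cur < 0.05 * config.current_amp_kn].index
        truth = sc.truth[0]
        start = pd.Timestamp(truth["start"])
        rest = sc.rl[sc.rl.index < start]
        if len(rest) and len(slack_times):
            # at any rest block within 10 min of slack, ambient is near its floor
            for t in rest.index:
                near_slack = (abs((slack_times - t).total_seconds()) < 600).any()
                if near_slack:
                    assert rest.loc[t].iloc[0] <= config.ambient_band_db + 0.3

    def test_silent_ship_blocks_are_pure_ambient(self):
        config = paper_calibrated_preset()
        sc = generate_scenario(config, 1, 0, seed=5)
        truth = sc.truth[0]
        start = pd.Timestamp(truth["start"])
        rest = sc.rl[sc.rl.index < start]
        # rest blocks were generated without any ship term: bounded by
        # base + tide + a few jitter sigmas
        cap = config.ambient_band_db + config.ambient_tidal_amp_db + 5 * config.ambient_jitter_db
        assert rest.to_numpy().max() < cap


class TestPresetCalibration:
    def test_preset_truths_equal_reported_means(self):
        src = paper_calibrated_preset().source
        assert src.cpa_bb == {"outgoing": 172.07, "incoming": 170.42}
        assert src.acc_bb == {"outgoing": 182.14, "incoming": 183.34}
        assert src.delta_center == {"outgoing": 8.04, "incoming": 11.50}

    def test_unpaired_delta_closed_form(self):
        src = paper_calibrated_preset().source
        for d in ("outgoing", "incoming"):
            q = src.unpaired_fraction
            mix = (1 - q) * (src.cpa_bb[d] + src.delta_center[d]) + q * (
                src.cpa_bb[d] + src.unpaired_delta(d)
            )
            assert mix == pytest.approx(src.acc_bb[d], abs=1e-9)

    def test_implied_aspect_offsets(self):
        src = paper_calibrated_preset().source
        assert src.port_starboard_offset == pytest.approx(1.65, abs=0.01)
        assert src.stern_aspect_offset == pytest.approx(1.20, abs=0.01)

    def test_batch_truth_moments_match_preset(self):
        config = paper_calibrated_preset()
        sc = generate_scenario(config, 40, 40, seed=9)
        truth = pd.DataFrame(sc.truth)
        for d in ("outgoing", "incoming"):
            rows = truth[truth["direction"] == d]
            paired = rows[~rows["unpaired"]]
            assert paired["delta_true"].mean() == pytest.approx(
                config.source.delta_center[d], abs=1e-6
            )
            assert paired["delta_true"].std(ddof=0) == pytest.approx(
                config.source.delta_sigma[d], abs=1e-6
            )
            assert rows["bb_acc_true"].mean() == pytest.approx(
                config.source.acc_bb[d], abs=0.15
            )

    def test_detection_robustness_across_seeds(self):
        """The double-peak event is detected in ≥95% of preset transits."""
        detected = total = 0
        for seed in range(10):
            sc = generate_scenario(paper_calibrated_preset(), 3, 3, seed=100 + seed)
            res = analyze(sc)
            total += 6
            detected += len(res.summaries)
        assert detected / total >= 0.95


class TestDeterminism:
    def test_byte_identical_outputs(self, tmp_path):
        for run in ("a", "b"):
            sc = generate_scenario(paper_calibrated_preset(), 2, 2, seed=21)
            write_scenario(sc, tmp_path / run, seed=21)
        for name in ("ais.csv", "currents.csv", "rl_spectra.csv", "truth.json", "environment.yaml"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
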