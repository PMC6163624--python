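"""Window segmentation and time/frequency feature extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import dft_oracle

import riskpipe as rp
from riskpipe.features import (
    EXTENDED_FEATURES,
    MOTION_AXES,
    SPECTRAL_DESCRIPTORS,
    TIME_FEATURES,
    Window,
    segment_windows,
    spectral_features,
    time_features,
)


def make_window(motion=None, scalars=None, cumulative=None, index=0):
    if motion is None:
        motion = np.zeros((8, 9))
    base_scalars = {"heart_rate": 60.0, "skin_temperature": 33.0, "pace": 0.0, "speed": 0.0, "ultraviolet": 0.0}
    base_cum = {"steps": 0.0, "distance": 0.0, "calories": 0.0}
    if scalars:
        base_scalars.update(scalars)
    if cumulative:
        base_cum.update(cumulative)
    return Window(user_id="u", index=index, start=float(index), motion=np.asarray(motion, dtype=float), scalars=base_scalars, cumulative=base_cum)


class TestSegmentation:
    def test_full_seconds_only(self, profile):
        stream = rp.simulate_normal(profile, 600, seed=1)
        # truncate motion frames to 10.6 s: only 10 complete windows survive
        for name in ("accelerometer", "gyroscope"):
            f = stream.frames[name]
            stream.frames[name] = f[f["timestamp_ms"] < 10600]
        ws = segment_windows(stream)
        assert len(ws) == 10
        assert ws.motion.shape == (10, 8, 9)

    def test_window_count_matches_duration(self, short_normal):
        ws = segment_windows(short_normal)
        assert len(ws) == 600

    def test_slow_sensor_carry_forward(self, short_normal):
        ws = segment_windows(short_normal)
        skin = short_normal.frames["skin_temperature"]
        # every window in [0, 30) carries the t=0 reading
        first = skin["celsius"].iloc[0]
        assert np.allclose(ws.scalars["skin_temperature"][:30], first)

    def test_interior_gap_rejected(self, short_normal):
        stream = rp.simulate_normal(rp.make_profile(9, user_id="u9"), 30, seed=2)
        acc = stream.frames["accelerometer"]
        # remove one sample inside second 5 -> that window is incomplete
        stream.frames["accelerometer"] = acc.drop(acc.index[acc["timestamp_ms"] // 1000 == 5][:1])
        ws = segment_windows(stream)
        assert 5 not in set(ws.index)
        assert len(ws) == 29


class TestTimeFeatures:
    def test_vector_has_26_named_entries(self):
        tf = time_features(make_window())
        assert len(tf) == 26
        assert list(tf.index) == list(TIME_FEATURES)

    def test_constant_axis_mean_and_zero_std(self):
        motion = np.full((8, 9), 3.5)
        tf = time_features(make_window(motion))
        for ax in MOTION_AXES:
            assert tf[f"mean_{ax}"] == pytest.approx(3.5)
            assert tf[f"std_{ax}"] == pytest.approx(0.0)

    def test_sample_std_uses_n_minus_1(self):
        motion = np.zeros((8, 9))
        motion[:, 0] = np.arange(1, 9)
        tf = time_features(make_window(motion))
        assert tf["mean_gyro_accel_x"] == pytest.approx(4.5)
        assert tf["std_gyro_accel_x"] == pytest.approx(np.std(np.arange(1, 9), ddof=1))
        assert tf["std_gyro_accel_x"] == pytest.approx(2.449, abs=5e-4)

    def test_deltas_against_previous_window(self):
        prev = make_window(cumulative={"steps": 10.0, "distance": 500.0, "calories": 1.0})
        cur = make_window(cumulative={"steps": 13.0, "distance": 725.0, "calories": 1.5}, index=1)
        tf = time_features(cur, prev)
        assert tf["delta_steps"] == pytest.approx(3.0)
        assert tf["delta_distance"] == pytest.approx(225.0)
        assert tf["delta_calories"] == pytest.approx(0.5)
        assert time_features(cur, None)["delta_steps"] == 0.0

    @given(shift=st.floats(min_value=0.0, max_value=1e6))
    @settings(max_examples=25, deadline=None)
    def test_delta_invariant_to_counter_offset(self, shift):
        prev = make_window(cumulative={"steps": 10.0})
        cur = make_window(cumulative={"steps": 14.0}, index=1)
        base = time_features(cur, prev)["delta_steps"]
        prev2 = make_window(cumulative={"steps": 10.0 + shift})
        cur2 = make_window(cumulative={"steps": 14.0 + shift}, index=1)
        assert time_features(cur2, prev2)["delta_steps"] == pytest.approx(base)


class TestSpectralFeatures:
    def test_zero_signal_conventions(self):
        sf = spectral_features(np.zeros(8))
        assert sf["fft_energy"] == 0.0
        assert sf["peak_magnitude"] == 0.0
        assert sf["entropy"] == 0.0
        assert sf["spectral_entropy"] == 0.0
        assert sf["peak_frequency"] == 0.0

    def test_constant_signal(self):
        sf = spectral_features(np.ones(8))
        # one-sided |DFT| = (8, 0, 0, 0, 0): all energy in DC
        assert sf["fft_energy"] == pytest.approx(64.0)
        assert sf["peak_magnitude"] == pytest.approx(8.0)
        assert sf["peak_dft_bin"] == 0
        assert sf["spectral_entropy"] == pytest.approx(0.0)
        assert sf["peak_frequency"] == 0.0  # DC excluded

    def test_single_tone_peak_frequency(self):
        t = np.arange(8) / 8.0
        sf = spectral_features(np.cos(2 * np.pi * 2 * t), fs=8.0)
        assert sf["peak_frequency"] == pytest.approx(2.0)
        assert sf["peak_dft_bin"] == 2

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            spectral_features(np.zeros(7))

    def test_matches_dft_definition_oracle(self, rng):
        for _ in range(200):
            x = rng.normal(size=8) * rng.choice([1e-3, 1.0, 50.0])
            got = spectral_features(x)
            want = dft_oracle(x)
            for name in SPECTRAL_DESCRIPTORS:
                assert got[name] == pytest.approx(want[name], rel=1e-9, abs=1e-12), name

    def test_parseval_identity(self, rng):
        for _ in range(50):
            x = rng.normal(size=8)
            F = np.array([np.sum(x * np.exp(-2j * np.pi * k * np.arange(8) / 8)) for k in range(8)])
            assert np.sum(x**2) == pytest.approx(np.sum(np.abs(F) ** 2) / 8, rel=1e-12)

    def test_spectral_entropy_bounded(self, rng):
        for _ in range(100):
            sf = spectral_features(rng.normal(size=8))
            assert 0.0 <= sf["spectral_entropy"] <= np.log(5) + 1e-12
            assert 0.0 <= sf["peak_frequency"] <= 4.0


class TestExtendedVector:
    def test_98_features_90_spectral_uv_last(self):
        ev = rp.extended_vector(make_window())
        assert len(ev) == 98
        spectral = [n for n in EXTENDED_FEATURES if any(n.startswith(d) for d in SPECTRAL_DESCRIPTORS)]
        assert len(spectral) == 90
        assert EXTENDED_FEATURES[-1] == "ultraviolet"

    def test_pinned_positions_from_published_listing(self):
        # the published feature listing pins several positions: F5 peak DFT
        # bin, F7 peak magnitude, F10 peak energy in block 1; F18 entropy in
        # block 2; F38 entropy in block 4; F98 ultraviolet
        assert EXTENDED_FEATURES[4] == "peak_dft_bin_gyro_accel_x"
        assert EXTENDED_FEATURES[6] == "peak_magnitude_gyro_accel_x"
        assert EXTENDED_FEATURES[9] == "peak_energy_gyro_accel_x"
        assert EXTENDED_FEATURES[17] == "entropy_gyro_accel_y"
        assert EXTENDED_FEATURES[37] == "entropy_gyro_angvel_x"
        assert EXTENDED_FEATURES[97] == "ultraviolet"

    def test_matrix_modes_and_row_counts(self, short_normal):
        mt = rp.extract_matrix([short_normal], mode="time")
        me = rp.extract_matrix([short_normal], mode="extended")
        assert len(mt.feature_names) == 26
        assert len(me.feature_names) == 98
        assert len(mt) == len(me) == 600
        assert (mt.df["label"] == "normal").all()

    def test_batch_rows_equal_per_window_vectors(self, short_normal):
        ws = segment_windows(short_normal)
        mt = rp.extract_matrix([short_normal], mode="time")
        me = rp.extract_matrix([short_normal], mode="extended")
        for i in (0, 5, 127):
            prev = ws[i - 1] if i > 0 else None
            np.testing.assert_allclose(
                mt.features.iloc[i].to_numpy(), time_features(ws[i], prev).to_numpy(), rtol=1e-12
            )
            np.testing.assert_allclose(
                me.features.iloc[i].to_numpy(), rp.extended_vector(ws[i], prev).to_numpy(), rtol=1e-12
            )

    def test_empty_input_keeps_schema(self):
        m = rp.extract_matrix([], mode="extended")
        assert len(m) == 0
        assert m.feature_names == list(EXTENDED_FEATURES)

    def test_csv_round_trip(self, time_matrix, tmp_path):
        path = tmp_path / "m.csv"
        time_matrix.to_csv(path)
        back = rp.FeatureMatrix.from_csv(path)
        assert back.feature_names == time_matrix.feature_names
        np.testing.assert_allclose(back.X, time_matrix.X, rtol=1e-6)
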