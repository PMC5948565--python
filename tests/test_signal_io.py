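"""Reading, resampling, virtual channels and configuration derivation."""

import numpy as np
import pytest

from strideseg.signal_io import (
    CompoundSignal,
    CyclicityConfig,
    RawSeries,
    derive_channels,
    read_sensor_table,
    resample_equidistant,
    write_sensor_table,
)


def write(tmp_path, text, name="sig.csv"):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestReadSensorTable:
    def test_identity_read_seconds(self, tmp_path):
        path = write(tmp_path, "t,acc_x\n0,0\n0.04,1\n0.08,0\n")
        raw = read_sensor_table(path)
        np.testing.assert_allclose(raw.timestamps, [0, 0.04, 0.08])
        np.testing.assert_allclose(raw.values[:, 0], [0, 1, 0])
        assert raw.time_unit == "s"
        assert raw.channel_labels == ["acc_x"]

    def test_millisecond_autodetection(self, tmp_path):
        path = write(tmp_path, "time,a\n0,1\n40,2\n80,3\n")
        raw = read_sensor_table(path)
        assert raw.time_unit == "ms"
        np.testing.assert_allclose(raw.timestamps, [0, 0.04, 0.08])

    def test_unit_override(self, tmp_path):
        path = write(tmp_path, "time,a\n0,1\n40,2\n80,3\n")
        raw = read_sensor_table(path, time_unit="s")
        np.testing.assert_allclose(raw.timestamps, [0, 40, 80])

    def test_duplicate_timestamp_names_row(self, tmp_path):
        path = write(tmp_path, "t,a\n0,1\n0.04,2\n0.04,3\n")
        with pytest.raises(ValueError, match="duplicated timestamp at row 4"):
            read_sensor_table(path)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        path = write(tmp_path, "t,a\n0,1\n0.04,oops\n")
        with pytest.raises(ValueError, match="row 3 column 'a'"):
            read_sensor_table(path)

    def test_missing_time_column(self, tmp_path):
        path = write(tmp_path, "t,a\n0,1\n1,2\n")
        with pytest.raises(ValueError, match="missing time column"):
            read_sensor_table(path, time_column="zeit")

    def test_channel_map_renames(self, tmp_path):
        path = write(tmp_path, "t,ax\n0,1\n1,2\n")
        raw = read_sensor_table(path, channel_map={"ax": "acc_x"})
        assert raw.channel_labels == ["acc_x"]

    def test_tab_delimited(self, tmp_path):
        path = write(tmp_path, "t\ta\n0\t1\n1\t2\n")
        raw = read_sensor_table(path)
        np.testing.assert_allclose(raw.values[:, 0], [1, 2])

    def test_roundtrip_with_writer(self, tmp_path):
        sig = CompoundSignal(
            np.column_stack([np.sin(np.arange(50) / 3), np.cos(np.arange(50))]),
            ["acc_x", "gyr_z"],
            25.0,
        )
        path = str(tmp_path / "round.csv")
        write_sensor_table(sig, path)
        raw = read_sensor_table(path)
        back = resample_equidistant(raw, 25.0)
        assert back.channel_labels == sig.channel_labels
        np.testing.assert_allclose(back.samples, sig.samples, atol=1e-7)


class TestResample:
    def test_linear_segment(self):
        raw = RawSeries(np.array([0.0, 1.0]), np.array([[0.0], [2.0]]), ["a"])
        out = resample_equidistant(raw, 4.0)
        np.testing.assert_allclose(out.samples[:, 0], [0, 0.5, 1, 1.5, 2])
        assert out.fsamp == 4.0

    def test_equidistant_input_is_fixed_point(self):
        t = np.arange(10) / 25.0
        v = np.sin(t * 7)[:, None]
        out = resample_equidistant(RawSeries(t, v, ["a"]), 25.0)
        np.testing.assert_allclose(out.samples, v, atol=1e-12)

    def test_exact_on_piecewise_linear(self, rng):
        """Resampling reproduces any signal linear between the input knots."""
        t = np.sort(rng.uniform(0, 4, 40))
        t[0], t[-1] = 0.0, 4.0
        v = rng.normal(size=(40, 1))
        out = resample_equidistant(RawSeries(t, v, ["a"]), 25.0)
        grid = np.arange(out.n_samples) / 25.0
        want = np.interp(grid, t, v[:, 0])  # oracle: direct interpolation
        np.testing.assert_allclose(out.samples[:, 0], want, atol=1e-12)

    def test_jittered_sine_close_to_ideal(self, rng):
        t = np.arange(0, 10, 0.04) + rng.uniform(-0.004, 0.004, 250)
        t = np.sort(t)
        v = np.sin(2 * np.pi * 1.0 * t)[:, None]
        out = resample_equidistant(RawSeries(t, v, ["a"]), 25.0)
        grid = t[0] + np.arange(out.n_samples) / 25.0
        ideal = np.sin(2 * np.pi * grid)
        # linear interpolation error bound ~ (h^2/8) * max|f''|
        h = np.diff(t).max()
        bound = (2 * np.pi) ** 2 * h**2 / 8
        assert np.abs(out.samples[:, 0] - ideal).max() < bound + 1e-9

    def test_errors(self):
        raw = RawSeries(np.array([0.0, 1.0]), np.zeros((2, 1)), ["a"])
        with pytest.raises(ValueError):
            resample_equidistant(raw, 0.0)
        single = RawSeries(np.array([0.0]), np.zeros((1, 1)), ["a"])
        with pytest.raises(ValueError):
            resample_equidistant(single, 25.0)


class TestDeriveChannels:
    def make(self, acc=None, gyr=None, n=100):
        cols, labels = [], []
        for prefix, arr in (("acc", acc), ("gyr", gyr)):
            if arr is not None:
                for i, ax in enumerate("xyz"):
                    cols.append(arr[:, i])
                    labels.append(f"{prefix}_{ax}")
        return CompoundSignal(np.column_stack(cols), labels, 25.0)

    def test_pythagorean_magnitude(self):
        acc = np.tile([3.0, 4.0, 0.0], (50, 1))
        sig = derive_channels(self.make(acc=acc), ("AM",))
        np.testing.assert_allclose(sig.channel("AM"), 5.0)

    def test_zero_gyro_zero_energy(self):
        sig = derive_channels(self.make(gyr=np.zeros((50, 3))), ("GE",))
        np.testing.assert_allclose(sig.channel("GE"), 0.0)

    def test_ge_matches_windowed_sum_oracle(self, rng):
        gyr = rng.normal(size=(200, 3))
        win = 4
        sig = derive_channels(self.make(gyr=gyr), ("GE",), ge_window=win)
        sq = (gyr**2).sum(axis=1)
        # oracle: direct centred partial-window mean
        want = np.empty(200)
        for n in range(200):
            lo = max(0, n - win // 2)
            hi = min(200, n + win - win // 2)
            want[n] = sq[lo:hi].mean()
        np.testing.assert_allclose(sig.channel("GE"), want, atol=1e-9)

    def test_existing_channels_untouched(self, rng):
        acc = rng.normal(size=(50, 3))
        base = self.make(acc=acc)
        out = derive_channels(base, ("AM",))
        np.testing.assert_array_equal(out.samples[:, :3], base.samples)
        assert out.channel_labels[:3] == base.channel_labels

    def test_missing_axes_raise(self):
        sig = CompoundSignal(np.zeros((10, 1)), ["acc_x"], 25.0)
        with pytest.raises(ValueError, match="AM requires"):
            derive_channels(sig, ("AM",))


class TestConfig:
    def test_band_derivation_at_25hz(self):
        cfg = CyclicityConfig(fsamp=25.0)
        assert cfg.nmax == 50  # 2 s at 25 Hz
        assert cfg.nmin == 8  # ~0.33 s at 25 Hz
        assert cfg.eta == 2

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            CyclicityConfig(fsamp=25.0, fmin=3.0, fmax=0.5)
        with pytest.raises(ValueError):
            CyclicityConfig(fsamp=25.0, eta=100)
        with pytest.raises(ValueError):
            CyclicityConfig(fsamp=25.0, estimators=(1, 7))
        with pytest.raises(ValueError):
            CyclicityConfig(fsamp=25.0, hv=1.5)

    def test_hr_defaults_by_channel_type(self):
        cfg = CyclicityConfig(fsamp=25.0)
        assert cfg.hr_for("acc_x") == pytest.approx(0.1)
        assert cfg.hr_for("gyr_z") == pytest.approx(5.0)
        assert cfg.hr_for("mag_y") == 0.0
        cfg2 = CyclicityConfig(fsamp=25.0, hr={"acc_x": 0.7})
        assert cfg2.hr_for("acc_x") == pytest.approx(0.7)
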