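"""Fiducial-point functions, replication voting and reliability filtering."""

import numpy as np
import pytest

from strideseg import CompoundSignal, CyclicityConfig
from strideseg.fiducial import (
    FiducialSpec,
    StrideTriplets,
    apply_fiducial,
    collect_candidates,
    consolidate,
    filter_unreliable,
    parse_method_spec,
)
from strideseg.fiducial import _RawCandidates
from strideseg.stride_time import sweep_windows

NMAX = 30


def window_with(values_at, n=2 * NMAX + 1, base=0.0):
    w = np.full(n, base)
    for idx, val in values_at.items():
        w[NMAX + idx] = val
    return w


class TestApplyFiducial:
    def test_paired_maximum(self):
        n = 20
        w = window_with({5: 3.0, 5 - n: 3.0, 12: 2.0})
        assert apply_fiducial(w, n, FiducialSpec("M", "a")) == 5

    def test_paired_minimum(self):
        n = 20
        w = window_with({7: -3.0, 7 - n: -3.0, 2: -1.0})
        assert apply_fiducial(w, n, FiducialSpec("m", "a")) == 7

    def test_monotone_ramp_has_no_zero_crossing(self):
        w = np.linspace(1.0, 5.0, 2 * NMAX + 1)  # strictly positive ramp
        assert apply_fiducial(w, 20, FiducialSpec("z", "a")) is None

    def test_zero_crossing_found(self):
        nu = np.arange(-NMAX, NMAX + 1)
        w = np.sin(2 * np.pi * nu / 20.0)  # crosses zero every 10 samples
        m = apply_fiducial(w, 20, FiducialSpec("z", "a"))
        assert m is not None
        # returned lag sits at a sign change of the channel
        assert w[NMAX + m - 2 : NMAX + m + 2].min() <= 0 <= w[
            NMAX + m - 2 : NMAX + m + 2
        ].max()

    def test_abrupt_negative_spike(self):
        w = np.zeros(2 * NMAX + 1)
        w[NMAX + 9] = 2.0
        w[NMAX + 10] = -4.0  # steepest negative first difference at m=10
        assert apply_fiducial(w, 20, FiducialSpec("h", "a")) == 10

    def test_zero_energy_plateau_midpoint(self):
        w = np.ones(2 * NMAX + 1)
        w[NMAX + 4 : NMAX + 13] = 0.0  # quiet run m in [4, 12], midpoint 8
        assert apply_fiducial(w, 20, FiducialSpec("s", "a"), hr=0.5) == 8

    def test_zero_energy_without_quiet_run(self):
        w = np.ones(2 * NMAX + 1)
        assert apply_fiducial(w, 20, FiducialSpec("s", "a"), hr=0.5) is None

    def test_max_matches_exhaustive_search(self, rng):
        """Definition functions agree with a direct scan over all lags."""
        for _ in range(20):
            w = rng.normal(size=2 * NMAX + 1)
            n = int(rng.integers(8, NMAX + 1))
            got = apply_fiducial(w, n, FiducialSpec("M", "a"))
            pairs = [w[NMAX + m] + w[NMAX + m - n] for m in range(n + 1)]
            assert got == int(np.argmax(pairs))
            got_min = apply_fiducial(w, n, FiducialSpec("m", "a"))
            assert got_min == int(np.argmin(pairs))


class TestConsolidate:
    def make(self, t, d, v):
        return _RawCandidates(np.asarray(t), np.asarray(d), np.asarray(v), None)

    def test_modal_stride_time(self):
        cand = self.make([50] * 10, [25] * 7 + [26] * 3, [0.5] * 10)
        tri = consolidate(cand, eta=2, h=0.5)
        assert list(tri.d) == [25]

    def test_mean_confidence(self):
        cand = self.make([50, 50], [25, 25], [0.2, 0.4])
        tri = consolidate(cand, eta=2, h=0.01)
        assert tri.v[0] == pytest.approx(0.3)

    def test_replication_filter_keeps_and_drops(self):
        """lexp = 40/2 = 20 votes expected; 18 kept at h=0.75, 10 dropped."""
        t = [100] * 18 + [300] * 10
        d = [40] * 28
        cand = self.make(t, d, [0.5] * 28)
        tri = consolidate(cand, eta=2, h=0.75)
        assert list(tri.t) == [100]

    def test_merge_tolerance_groups_neighbours(self):
        cand = self.make([100, 100, 101, 200], [25, 25, 25, 25], [0.4] * 4)
        tri = consolidate(cand, eta=25, h=0.5)  # lexp = 1 per position
        assert list(tri.t) == [100, 200]

    def test_idempotent_on_own_output(self):
        cand = self.make([100, 100, 100, 140, 140], [30, 30, 31, 30, 30],
                         [0.5, 0.7, 0.6, 0.4, 0.4])
        tri = consolidate(cand, eta=2, h=0.1)
        again = consolidate(
            _RawCandidates(tri.t, tri.d, tri.v, None), eta=2, h=0.01
        )
        np.testing.assert_array_equal(again.t, tri.t)
        np.testing.assert_array_equal(again.d, tri.d)
        np.testing.assert_allclose(again.v, tri.v)

    def test_printed_lexp_variant_drops_late_strides(self):
        """The unamended expected count t/eta grows with absolute time, so a
        late stride with a full complement of votes still fails the test."""
        cand = self.make([1000] * 15, [30] * 15, [0.5] * 15)
        assert len(consolidate(cand, eta=2, h=0.75)) == 1
        assert len(
            consolidate(cand, eta=2, h=0.75, use_printed_lexp=True)
        ) == 0


class TestFilterUnreliable:
    def make_signal(self):
        x = np.zeros(200)
        x[100:130] = np.sin(np.linspace(0, np.pi, 30))  # one active burst
        return CompoundSignal(x[:, None], ["acc_x"], 25.0)

    def test_confidence_threshold(self):
        tri = StrideTriplets([50, 60], [25, 25], [0.05, 0.5],
                             FiducialSpec("M", "acc_x"))
        out = filter_unreliable(tri, hv=0.11, hr=0.0)
        assert list(out.t) == [60]

    def test_noise_variability_threshold_drops_flat_interval(self):
        sig = self.make_signal()
        tri = StrideTriplets([60, 129], [25, 25], [0.5, 0.5],
                             FiducialSpec("M", "acc_x"))
        out = filter_unreliable(tri, hv=0.0, hr=0.1, signal=sig)
        assert list(out.t) == [129]  # the burst interval survives

    def test_zero_thresholds_are_identity(self):
        tri = StrideTriplets([10, 20], [8, 8], [0.0, 0.9],
                             FiducialSpec("M", "acc_x"))
        out = filter_unreliable(tri, hv=0.0, hr=0.0)
        np.testing.assert_array_equal(out.t, tri.t)

    def test_output_is_ordered_subset(self, rng):
        t = np.sort(rng.choice(1000, size=30, replace=False))
        tri = StrideTriplets(t, np.full(30, 25), rng.random(30),
                             FiducialSpec("M", "acc_x"))
        out = filter_unreliable(tri, hv=0.5, hr=0.0)
        assert set(out.t) <= set(tri.t)
        assert (np.diff(out.t) > 0).all()


class TestMethodSpecParser:
    def test_full_notation(self):
        est, specs = parse_method_spec("1234-AccGyr-A-[M|m]")
        assert est == (1, 2, 3, 4)
        channels = {s.channel for s in specs}
        assert channels == {f"{p}_{a}" for p in ("acc", "gyr") for a in "xyz"}
        assert len(specs) == 12  # 6 channels x 2 fiducial kinds

    def test_single_axis_and_kind(self):
        est, specs = parse_method_spec("Gyr-z-[m]")
        assert est == (1, 2, 3, 4)  # default estimator set
        assert len(specs) == 1
        assert specs[0] == FiducialSpec("m", "gyr_z")

    def test_virtual_channels(self):
        _, specs = parse_method_spec("123-AM-A-[M]")
        assert specs == [FiducialSpec("M", "AM")]
        _, specs = parse_method_spec("GE-x-[s]")
        assert specs == [FiducialSpec("s", "GE")]

    def test_absent_channel_rejected(self):
        with pytest.raises(ValueError, match="absent channels"):
            parse_method_spec("1-Gyr-z-[m]", channel_labels=["acc_x"])

    def test_malformed_strings_rejected(self):
        for bad in ("", "1234", "Acc-[Q]", "99-Acc-A-[M]"):
            with pytest.raises(ValueError):
                parse_method_spec(bad)


def test_candidates_pile_on_true_peaks(config25):
    """On a periodic signal with one sharp peak per cycle the candidate
    votes pile on the true peak positions with ~d/eta replications."""
    period = 25
    n = 800
    t = np.arange(n)
    x = np.exp(-0.5 * (((t % period) - 12) / 1.5) ** 2)
    sig = CompoundSignal(x[:, None], ["acc_x"], 25.0)
    series = sweep_windows(sig, config25)
    spec = FiducialSpec("M", "acc_x")
    cands = collect_candidates(sig, series, [spec], config25)[spec]
    true_peaks = np.arange(12, n, period)
    # every candidate is on (or within 1 of) a true peak
    dist = np.min(np.abs(cands.t[:, None] - true_peaks[None, :]), axis=1)
    assert np.median(dist) <= 1
    # interior peaks receive about d/eta votes each
    interior = true_peaks[(true_peaks > 2 * config25.nmax)
                          & (true_peaks < n - 2 * config25.nmax)]
    votes = [(np.abs(cands.t - p) <= 1).sum() for p in interior]
    expected = period / config25.eta
    assert np.median(votes) == pytest.approx(expected, rel=0.3)


def test_empty_series_yields_empty_candidates(config25):
    import warnings

    sig = CompoundSignal(np.zeros((10, 1)), ["acc_x"], 25.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series = sweep_windows(sig, config25)
    cands = collect_candidates(sig, series, [FiducialSpec("M", "acc_x")], config25)
    assert len(cands[FiducialSpec("M", "acc_x")]) == 0
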