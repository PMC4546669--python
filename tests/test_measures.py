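"""Analysis statistics, checked against constructed spike records with
known structure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cholwave import (
    bursting_measure,
    center_of_activity,
    classify_regime,
    detect_upstates,
    isi_phase_distribution,
    make_fixture,
    phi_preference,
    upstate_statistics,
    wave_speed,
)
from cholwave.network import EXC
from cholwave.simulate import SpikeRecord


def record_from(cells, times, n_cells=4, L=25.0, duration=5000.0):
    """Small hand-built spike record on a square of n_cells sites."""
    side = int(round(math.sqrt(n_cells)))
    pos = np.array(
        [[i, j] for i in range(side) for j in range(side)], dtype=float
    )
    order = np.argsort(times, kind="stable")
    return SpikeRecord(
        cell_ids=np.asarray(cells, dtype=np.int64)[order],
        times=np.asarray(times, dtype=float)[order],
        positions=pos,
        species=np.zeros(n_cells, dtype=np.int64),
        L=L,
        duration_ms=duration,
    )


class TestBurstingMeasure:
    def test_single_periodic_cell(self):
        rec = record_from([0] * 10, np.arange(10) * 100.0, n_cells=1)
        # zero ISI variance, one cell: B = (0 - 1)/sqrt(1)
        assert bursting_measure(rec) == pytest.approx(-1.0)

    def test_coincident_spikes_match_closed_form(self):
        rec = make_fixture("synchronous", n_cells=100, duration_ms=5000.0)
        n = 100
        expected = math.sqrt(1.0 - 1.0 / n) - 1.0 / math.sqrt(n)
        assert bursting_measure(rec) == pytest.approx(expected, abs=1e-6)

    def test_poisson_pooled_isis_near_zero(self):
        rec = make_fixture("asynchronous", n_cells=100, rate_hz=20.0, seed=3)
        assert abs(bursting_measure(rec)) < 2.0 / math.sqrt(100)

    def test_undefined_below_three_spikes(self):
        rec = record_from([0, 1], [10.0, 20.0])
        assert math.isnan(bursting_measure(rec))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        shift=st.floats(-1e3, 1e3),
        scale=st.floats(0.1, 10.0),
    )
    def test_invariant_under_time_translation_and_rescaling(self, shift, scale):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 1000, size=60))
        cells = rng.integers(0, 5, size=60)
        a = record_from(cells, times, n_cells=9)
        b = record_from(cells, times * scale + shift, n_cells=9)
        assert bursting_measure(a) == pytest.approx(bursting_measure(b), abs=1e-9)


class TestUpstates:
    def test_gap_rule_run_lengths(self):
        rec = record_from([0] * 5, [0.0, 10.0, 20.0, 500.0, 510.0])
        ups = detect_upstates(rec, gap_ms=100.0)
        got = [(u.n_spikes, u.start, u.end) for u in ups.of(0)]
        assert got == [(3, 0.0, 20.0), (2, 500.0, 510.0)]

    def test_empty_and_singleton(self):
        assert detect_upstates(record_from([], [])).n_upstates == 0
        assert detect_upstates(record_from([0], [100.0])).n_upstates == 0

    def test_statistics_of_single_upstate(self):
        rec = record_from([0] * 3, [0.0, 10.0, 20.0])
        stats = upstate_statistics(detect_upstates(rec))
        assert stats["mean_spikes"] == 3.0
        assert stats["sd_spikes"] == 0.0
        assert stats["mean_isi"] == 10.0

    def test_empty_statistics_sentinel(self):
        stats = upstate_statistics(detect_upstates(record_from([], [])))
        assert stats["n_upstates"] == 0 and math.isnan(stats["mean_spikes"])


class TestIsiPhase:
    def test_identical_trains_mass_at_zero(self):
        t = np.arange(20) * 10.0
        rec = record_from(
            np.r_[np.zeros(20, int), np.ones(20, int)], np.r_[t, t]
        )
        counts, edges = isi_phase_distribution(rec, n_bins=9)
        assert counts.sum() > 0
        assert counts[4] == counts.sum()  # central bin straddles phase 0

    def test_antiphase_trains_mass_at_pi(self):
        t = np.arange(20) * 10.0
        rec = record_from(
            np.r_[np.zeros(20, int), np.ones(20, int)], np.r_[t, t + 5.0]
        )
        counts, edges = isi_phase_distribution(rec, n_bins=8)
        # all mass in the two outermost bins (phase +/- pi)
        assert counts[0] + counts[-1] == counts.sum()

    def test_no_overlap_gives_empty_histogram(self):
        rec = record_from(
            [0, 0, 1, 1], [0.0, 10.0, 3000.0, 3010.0]
        )
        counts, _ = isi_phase_distribution(rec)
        assert counts.sum() == 0


class TestCenterOfActivity:
    def test_single_active_cell(self):
        pos = np.array([[3.0, 7.0], [10.0, 10.0]])
        c = center_of_activity(np.array([5.0, 0.0]), pos, 25.0)
        np.testing.assert_allclose(c, [3.0, 7.0], atol=1e-9)

    def test_wraparound_mean(self):
        pos = np.array([[24.0, 0.0], [1.0, 0.0]])
        c = center_of_activity(np.array([1.0, 1.0]), pos, 25.0)
        assert c[0] == pytest.approx(0.0, abs=1e-9) or c[0] == pytest.approx(25.0)

    def test_uniform_activity_undefined(self):
        side = 10
        pos = np.array([[i, j] for i in range(side) for j in range(side)], float)
        assert center_of_activity(np.ones(100), pos * 2.5, 25.0) is None

    def test_silent_undefined(self):
        assert center_of_activity(np.zeros(3), np.zeros((3, 2)), 25.0) is None

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(dx=st.floats(0, 24.9), dy=st.floats(0, 24.9))
    def test_translation_equivariance(self, dx, dy):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 25, size=(30, 2))
        w = rng.uniform(0.1, 1, size=30)
        # keep the mass localized so the center is defined
        pos = pos * 0.2 + 5.0
        c0 = center_of_activity(w, pos, 25.0)
        c1 = center_of_activity(w, (pos + [dx, dy]) % 25.0, 25.0)
        d = np.abs((c1 - c0 - [dx, dy] + 12.5) % 25.0 - 12.5)
        assert d.max() < 1e-6


class TestWaveSpeed:
    def test_stationary_fixture_speed_near_zero(self):
        rec = make_fixture("stationary", n_cells=625, duration_ms=5000.0)
        track = wave_speed(rec)
        assert track.valid
        assert track.mean_speed < 0.005

    @pytest.mark.parametrize("speed", [0.02, 0.05])
    def test_traveling_fixture_recovers_speed(self, speed):
        # 0.05 units/ms crosses the periodic boundary ten times in 5 s
        rec = make_fixture("traveling", n_cells=625, duration_ms=5000.0, speed=speed)
        track = wave_speed(rec)
        assert track.valid
        assert track.mean_speed == pytest.approx(speed, rel=0.05)

    def test_overcrowded_bin_flagged(self):
        rec = make_fixture("synchronous", n_cells=625, duration_ms=5000.0)
        track = wave_speed(rec)
        assert track.exclusions["too_many_active"]
        assert track.exclusions["synchronized"]
        assert not track.valid

    def test_time_reversal_leaves_speed_unchanged(self):
        rec = make_fixture("traveling", n_cells=625, duration_ms=5000.0, speed=0.03)
        rev = SpikeRecord(
            cell_ids=rec.cell_ids[::-1].copy(),
            times=(rec.duration_ms - rec.times)[::-1].copy(),
            positions=rec.positions, species=rec.species,
            L=rec.L, duration_ms=rec.duration_ms,
        )
        a = wave_speed(rec, avg_window_ms=rec.duration_ms)
        b = wave_speed(rev, avg_window_ms=rec.duration_ms)
        assert a.mean_speed == pytest.approx(b.mean_speed, rel=0.02)


class TestPhi:
    def test_extremes_and_symmetry(self):
        n = 16
        region = np.arange(4)
        win = (0.0, 2000.0)
        inside = record_from([0, 1, 2, 3] * 5, np.arange(20) * 100.0, n_cells=n)
        assert phi_preference(inside, region, window=win) == 1.0
        outside = record_from([5, 6, 7, 8] * 5, np.arange(20) * 100.0, n_cells=n)
        assert phi_preference(outside, region, window=win) == -1.0

    def test_balanced_rates_give_zero(self):
        n = 16
        region = np.arange(8)
        cells = list(range(16)) * 4
        rec = record_from(cells, np.linspace(0, 4000, 64, endpoint=False), n_cells=n)
        assert phi_preference(rec, region, window=(0.0, 4000.0)) == pytest.approx(0.0)

    def test_antisymmetric_under_region_swap(self):
        n = 16
        rng = np.random.default_rng(2)
        cells = rng.integers(0, n, 200)
        times = np.sort(rng.uniform(0, 4000, 200))
        rec = record_from(cells, times, n_cells=n)
        region = np.arange(5)
        complement = np.arange(5, n)
        a = phi_preference(rec, region, window=(0.0, 4000.0))
        b = phi_preference(rec, complement, window=(0.0, 4000.0))
        assert a == pytest.approx(-b)

    def test_silent_window_is_nan(self):
        rec = record_from([0], [10.0], n_cells=16)
        assert math.isnan(phi_preference(rec, np.arange(4)))


class TestClassify:
    def test_quiescent(self):
        rec = make_fixture("quiescent", n_cells=625)
        assert classify_regime(rec).label == "quiescent"

    def test_synchronous_is_global_burst(self):
        rec = make_fixture("synchronous", n_cells=625)
        assert classify_regime(rec).label == "global_burst"

    def test_stationary_and_traveling_fixtures(self):
        stat = make_fixture("stationary", n_cells=625)
        trav = make_fixture("traveling", n_cells=625, speed=0.05)
        assert classify_regime(stat).label == "stationary_bump"
        assert classify_regime(trav).label == "traveling_bump"

    def test_planar_fixture(self):
        rec = make_fixture("planar", n_cells=625, speed=0.05)
        assert classify_regime(rec).label == "planar_wave"

    def test_pure_function(self):
        rec = make_fixture("traveling", n_cells=625, speed=0.05)
        assert classify_regime(rec).label == classify_regime(rec).label
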