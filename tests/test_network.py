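import math

import numpy as np
import pytest

from meapipe.network import (
    detect_network_bursts,
    nb_stats,
    sttc_pair,
    sttc_summary,
)

from conftest import make_recording, nb_enumerator, sttc_interval_oracle, sttc_raster_oracle


def _interleaved_nb(n_electrodes=5, n_spikes=50, spacing=0.005, t0=1.0):
    """Pooled train of `n_spikes` at `spacing`, cycling over electrodes."""
    elecs = [f"1{c}" for c in range(1, 5)] + ["21", "22", "23", "24"]
    trains: dict[str, list[float]] = {}
    for k in range(n_spikes):
        e = elecs[k % n_electrodes]
        trains.setdefault(e, []).append(t0 + k * spacing)
    return trains


class TestNetworkBurstDetection:
    def test_fifty_spikes_five_channels_one_nb(self):
        rec = make_recording({"A1": _interleaved_nb()}, 300.0)
        nbs = detect_network_bursts(rec, "A1")
        assert len(nbs) == 1
        assert nbs[0].n_spikes == 50
        assert len(nbs[0].channels) == 5
        assert nbs[0].duration_s == pytest.approx(49 * 0.005)

    def test_four_channels_rejected(self):
        rec = make_recording({"A1": _interleaved_nb(n_electrodes=4)}, 300.0)
        assert detect_network_bursts(rec, "A1") == []

    def test_forty_nine_spikes_rejected(self):
        rec = make_recording({"A1": _interleaved_nb(n_spikes=49, n_electrodes=6)}, 300.0)
        assert detect_network_bursts(rec, "A1") == []

    def test_matches_exhaustive_enumerator_on_random_pools(self, rng):
        for _ in range(100):
            n = int(rng.integers(0, 300))
            times = np.sort(rng.uniform(0, 20, n))
            elecs = rng.choice([f"1{c}" for c in range(1, 5)] + ["21", "22"], n)
            rec = make_recording(
                {"A1": {e: list(times[elecs == e]) for e in np.unique(elecs)}}, 30.0
            )
            got = detect_network_bursts(rec, "A1", min_spikes=20, min_channels=3)
            exp = nb_enumerator(list(times), list(elecs), 0.100, 20, 3)
            assert len(got) == len(exp)
            for nb, (s, e, k, ch) in zip(got, exp):
                assert nb.start_s == pytest.approx(s)
                assert nb.end_s == pytest.approx(e)
                assert nb.n_spikes == k
                assert len(nb.channels) == ch

    def test_time_shift_invariance(self, rng):
        times = np.sort(rng.uniform(0, 10, 200))
        elecs = rng.choice([f"1{c}" for c in range(1, 5)] + ["21"], 200)
        base = {e: list(times[elecs == e]) for e in np.unique(elecs)}
        shifted = {e: [t + 7.5 for t in ts] for e, ts in base.items()}
        r1 = make_recording({"A1": base}, 20.0)
        r2 = make_recording({"A1": shifted}, 27.5)
        n1 = detect_network_bursts(r1, "A1", min_spikes=20, min_channels=3)
        n2 = detect_network_bursts(r2, "A1", min_spikes=20, min_channels=3)
        assert len(n1) == len(n2)

    def test_nb_stats_counts_and_intervals(self):
        trains = _interleaved_nb(t0=1.0)
        more = _interleaved_nb(t0=10.0)
        for e, ts in more.items():
            trains[e] = trains.get(e, []) + ts
        rec = make_recording({"A1": trains}, 300.0)
        nbs = detect_network_bursts(rec, "A1")
        s = nb_stats(nbs, rec, "A1")
        assert s.n_nbs == 2
        assert s.nb_rate_hz == pytest.approx(2 / 300)
        assert s.mean_inter_nb_interval_s == pytest.approx(9.0)
        assert s.pct_spikes_in_nbs == pytest.approx(100.0)


class TestSTTCPair:
    def test_identical_trains_give_one(self, rng):
        t = np.sort(rng.uniform(0, 100, 50))
        assert sttc_pair(t, t, 100.0) == pytest.approx(1.0, abs=1e-12)

    def test_hand_derived_distant_singletons(self):
        # P_A = P_B = 0; T_A = T_B = 0.02 -> 1/2 * (-0.02 - 0.02) = -0.02
        assert sttc_pair([1.0], [5.0], duration_s=10.0, dt_s=0.1) == pytest.approx(
            -0.02, abs=1e-12
        )

    def test_empty_train_undefined(self):
        assert math.isnan(sttc_pair([], [1.0], 10.0))
        assert math.isnan(sttc_pair([1.0], [], 10.0))

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            sttc_pair([1.0], [2.0], 10.0, dt_s=0.0)

    def test_symmetric_under_swap(self, rng):
        for _ in range(50):
            a = np.sort(rng.uniform(0, 50, int(rng.integers(1, 80))))
            b = np.sort(rng.uniform(0, 50, int(rng.integers(1, 80))))
            assert sttc_pair(a, b, 50.0) == pytest.approx(sttc_pair(b, a, 50.0), abs=1e-14)

    def test_matches_exact_interval_oracle(self, rng):
        for _ in range(500):
            d = float(rng.uniform(5, 30))
            a = np.sort(rng.uniform(0, d, int(rng.integers(1, 100))))
            b = np.sort(rng.uniform(0, d, int(rng.integers(1, 100))))
            dt = float(rng.uniform(0.01, 0.5))
            got = sttc_pair(a, b, d, dt)
            exp = sttc_interval_oracle(a, b, d, dt)
            assert got == pytest.approx(exp, abs=1e-12)

    def test_matches_rasterized_oracle_on_grid_aligned_trains(self, rng):
        fs, dt = 12500.0, 0.1
        w = int(round(dt * fs))
        for _ in range(25):
            n = int(round(float(rng.uniform(2, 6)) * fs))
            ka = np.unique(rng.integers(0, n, int(rng.integers(1, 40))))
            kb = np.unique(rng.integers(0, n, int(rng.integers(1, 40))))
            # skip draws with a pair exactly at the tiling edge: the float
            # comparison there is ambiguous while the raster is not
            if np.any(np.abs(ka[:, None] - kb[None, :]) == w):
                continue
            a, b = ka / fs, kb / fs
            got = sttc_pair(a, b, n / fs, dt)
            exp = sttc_raster_oracle(a, b, n / fs, dt, fs)
            assert got == pytest.approx(exp, abs=1e-6)

    def test_time_shift_invariance_for_interior_trains(self, rng):
        # with all tiling windows interior to [0, duration], a rigid shift
        # of both trains changes nothing
        a = np.sort(rng.uniform(1, 10, 40))
        b = np.sort(rng.uniform(1, 10, 60))
        assert sttc_pair(a + 5.0, b + 5.0, 20.0) == pytest.approx(
            sttc_pair(a, b, 20.0), abs=1e-12
        )


class TestSTTCSummary:
    def test_identical_trains_mean_one_skew_zero_flagged(self):
        t = list(np.linspace(1, 290, 40))
        rec = make_recording({"A1": {"11": t, "12": t, "13": t}}, 300.0)
        s = sttc_summary(rec, "A1")
        assert s.mean_sttc == pytest.approx(1.0)
        assert s.skewness_sttc == 0.0
        assert s.zero_variance
        assert s.n_pairs_used == 3

    def test_matrix_symmetric_with_unit_diagonal(self, rng):
        trains = {
            f"1{c}": list(np.sort(rng.uniform(0, 300, 60))) for c in range(1, 5)
        }
        rec = make_recording({"A1": trains}, 300.0)
        m = sttc_summary(rec, "A1").matrix
        sub = m.loc[["11", "12", "13", "14"], ["11", "12", "13", "14"]]
        assert np.allclose(sub, sub.T)
        assert np.allclose(np.diag(sub), 1.0)

    def test_independent_poisson_trains_center_near_zero(self, rng):
        trains = {
            f"{r}{c}": list(np.sort(rng.uniform(0, 300, rng.poisson(300))))
            for r in range(1, 5)
            for c in range(1, 5)
        }
        rec = make_recording({"A1": trains}, 300.0)
        s = sttc_summary(rec, "A1")
        assert s.n_pairs_used == 120
        assert abs(s.mean_sttc) < 0.05

    def test_fewer_than_two_trains_undefined(self):
        rec = make_recording({"A1": {"11": [1.0, 2.0]}}, 300.0)
        s = sttc_summary(rec, "A1")
        assert s.n_pairs_used == 0
        assert math.isnan(s.mean_sttc)

    def test_nb_restriction_uses_compressed_time_axis(self):
        trains = _interleaved_nb(n_electrodes=6, n_spikes=60)
        rec = make_recording({"A1": trains}, 300.0)
        s = sttc_summary(rec, "A1", restrict_to_nb=True)
        assert s.restricted_to_nb
        assert s.n_pairs_used == 15  # 6 electrodes with spikes
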