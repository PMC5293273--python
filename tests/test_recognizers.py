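import numpy as np
import pandas as pd
import pytest

from tumblecm import (
    GammaTumbleDist,
    SimConfig,
    ThermalStep,
    compare_recognizers,
    headings_from_trajectories,
    heuristic_recognize,
    np_thresholds,
    simulate_ensemble,
    systematic_recognize,
)


class TestThresholds:
    def test_printed_operating_point(self, ecoli_dist):
        thr = np_thresholds(ecoli_dist, ThermalStep(0.05, 0.5), alpha1=0.05)
        assert np.degrees(thr.dtheta_crit) == pytest.approx(24.0, abs=0.5)
        assert thr.r_crit == pytest.approx(2.3, abs=0.05)
        assert thr.alpha2 == pytest.approx(0.06, abs=0.005)

    def test_alpha1_limits(self, ecoli_dist):
        thr = np_thresholds(ecoli_dist, ThermalStep(0.05, 0.5), alpha1=0.999)
        assert thr.dtheta_crit == pytest.approx(np.pi, abs=0.05)
        with pytest.raises(ValueError):
            np_thresholds(ecoli_dist, ThermalStep(0.05, 0.5), alpha1=0.0)
        with pytest.raises(ValueError):
            np_thresholds(ecoli_dist, ThermalStep(0.05, 0.5), alpha1=1.0)

    def test_monotone_in_alpha1(self, ecoli_dist):
        step = ThermalStep(0.05, 0.5)
        alphas = [0.01, 0.05, 0.1, 0.2, 0.4]
        thrs = [np_thresholds(ecoli_dist, step, a) for a in alphas]
        dcrits = [t.dtheta_crit for t in thrs]
        a2s = [t.alpha2 for t in thrs]
        # a larger allowed miss probability pushes the threshold up and the
        # false-alarm probability down
        assert np.all(np.diff(dcrits) > 0)
        assert np.all(np.diff(a2s) < 0)


class TestSystematic:
    def test_trivial_calls(self, ecoli_dist, small_ensemble):
        thr = np_thresholds(ecoli_dist, ThermalStep(0.06, 0.5), 0.05)
        hs = headings_from_trajectories(small_ensemble)
        calls = systematic_recognize(hs, 0.5, thr)
        zero = calls[calls.dtheta <= 1e-9]
        assert not zero["tumble"].any()
        assert calls.loc[calls.dtheta > 3.0, "tumble"].all()

    @staticmethod
    def _rates(trajs, thr, dt):
        hs = headings_from_trajectories(trajs)
        calls = systematic_recognize(hs, dt, thr)
        lookup = {}
        for tr in trajs:
            for t_ev in tr.tumble_times:
                lookup.setdefault(tr.track_id, []).append(t_ev)
        miss_n = miss_d = fa_n = fa_d = 0
        for row in calls.itertuples():
            evs = [t for t in lookup.get(row.track_id, [])
                   if row.t < t <= row.t + dt + 1e-9]
            if len(evs) == 1:
                miss_d += 1
                miss_n += not row.tumble
            elif len(evs) == 0:
                fa_d += 1
                fa_n += row.tumble
        return miss_n / miss_d, fa_n / fa_d

    def test_miss_rate_matches_alpha1(self, ecoli_dist):
        """With weak thermal smearing the realized miss rate is alpha1: the
        threshold cuts exactly the alpha1 quantile of the tumble-angle law."""
        d_rot, dt = 0.005, 0.5
        cfg = SimConfig(lambda0=0.2, tumble_dist=ecoli_dist, seed=21,
                        d_rot=d_rot, n_tracks=400, duration=10.0)
        trajs = simulate_ensemble(cfg)
        thr = np_thresholds(ecoli_dist, ThermalStep(d_rot, dt), 0.05)
        miss, _ = self._rates(trajs, thr, dt)
        assert miss == pytest.approx(thr.alpha1, abs=0.02)

    def test_false_alarm_rate_matches_alpha2(self, ecoli_dist):
        """Tumble-free windows are mislabeled at the designed type-II rate."""
        d_rot, dt = 0.05, 0.5
        cfg = SimConfig(lambda0=0.2, tumble_dist=ecoli_dist, seed=22,
                        d_rot=d_rot, n_tracks=400, duration=10.0)
        trajs = simulate_ensemble(cfg)
        thr = np_thresholds(ecoli_dist, ThermalStep(d_rot, dt), 0.05)
        _, fa = self._rates(trajs, thr, dt)
        assert fa == pytest.approx(thr.alpha2, abs=0.015)

    def test_likelihood_ratio_consistent_with_threshold(self, ecoli_dist,
                                                        small_ensemble):
        d_rot, dt = 0.06, 0.5
        thr = np_thresholds(ecoli_dist, ThermalStep(d_rot, dt), 0.05)
        hs = headings_from_trajectories(small_ensemble)
        calls = systematic_recognize(hs, dt, thr, ThermalStep(d_rot, dt),
                                     ecoli_dist)
        # R < r_crit iff the angular threshold fires (monotone R)
        agree = (calls["R"] < thr.r_crit) == calls["tumble"]
        assert agree.mean() > 0.99


class TestHeuristic:
    def make_straight(self, n=200, frame_dt=0.05, v=20.0):
        t = np.arange(n) * frame_dt
        return t, v * t, np.zeros(n)

    def test_straight_track_no_events(self):
        t, x, y = self.make_straight()
        calls = heuristic_recognize(t, x, y)
        assert not calls["tumble"].any()

    def test_injected_turn_detected_once(self):
        # 120-degree turn with a speed dip at t = 5 s
        frame_dt = 0.05
        n1, n_stop, n2 = 100, 4, 100
        t = np.arange(n1 + n_stop + n2) * frame_dt
        x = np.concatenate([
            20 * frame_dt * np.arange(n1),
            np.full(n_stop, 20 * frame_dt * (n1 - 1)),
        ])
        x0 = x[-1]
        phi = np.radians(120)
        x = np.concatenate([x, x0 + 20 * frame_dt * np.cos(phi) * np.arange(1, n2 + 1)])
        y = np.concatenate([
            np.zeros(n1 + n_stop),
            20 * frame_dt * np.sin(phi) * np.arange(1, n2 + 1),
        ])
        calls = heuristic_recognize(t, x, y)
        from tumblecm.recognizers import events_from_calls

        events = events_from_calls(calls)
        assert len(events) == 1
        assert events[0] == pytest.approx(n1 * frame_dt, abs=0.5)

    def test_event_counts_track_ground_truth(self, ecoli_dist):
        from scipy.stats import spearmanr

        from tumblecm.recognizers import events_from_calls

        cfg = SimConfig(lambda0=0.39, tumble_dist=ecoli_dist, seed=31,
                        d_rot=0.06, n_tracks=150, duration=10.0)
        trajs = simulate_ensemble(cfg)
        found, truth = [], []
        for tr in trajs:
            calls = heuristic_recognize(tr.times, tr.positions[:, 0],
                                        tr.positions[:, 1])
            found.append(len(events_from_calls(calls)))
            truth.append(len(tr.tumble_times))
        rho = spearmanr(found, truth).statistic
        assert rho > 0.8

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            heuristic_recognize([0, 0.05, 0.1], [0, 1, 2], [0, 0, 0])


class TestCompare:
    def base_calls(self, labels):
        return pd.DataFrame({
            "track_id": 0,
            "t": np.arange(len(labels)) * 0.5,
            "tumble": labels,
        })

    def test_identical_and_complementary(self):
        a = self.base_calls([True, False, True, False])
        frac, table = compare_recognizers(a, a)
        assert frac == 1.0
        b = self.base_calls([False, True, False, True])
        frac, table = compare_recognizers(a, b)
        assert frac == 0.0
        assert table.to_numpy().sum() == 4

    def test_disjoint_time_bases_rejected(self):
        a = self.base_calls([True, False])
        b = self.base_calls([True, False])
        b["t"] += 1000.0
        with pytest.raises(ValueError):
            compare_recognizers(a, b)
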