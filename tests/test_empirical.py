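import numpy as np
import pandas as pd
import pytest

from tumblecm import (
    FilterRules,
    GammaTumbleDist,
    SimConfig,
    apply_filters,
    empirical_cms,
    ensemble_to_table,
    headings_from_positions,
    headings_from_trajectories,
    simulate_ensemble,
    theoretical_cms,
)
from tumblecm.empirical import validate_tracks
from tumblecm.theory import MotilityParams


def make_track(track_id, t, x, y):
    return pd.DataFrame({"track_id": track_id, "t": t, "x": x, "y": y})


def straight_track(track_id=0, n=101, frame_dt=0.05, vx=20.0, vy=0.0):
    t = np.arange(n) * frame_dt
    return make_track(track_id, t, vx * t, vy * t)


class TestHeadings:
    def test_axis_aligned_motion(self):
        hs = headings_from_positions(straight_track(vx=20, vy=0))
        np.testing.assert_allclose(hs.theta[0], 0.0, atol=1e-12)
        hs = headings_from_positions(straight_track(vx=-20, vy=0))
        np.testing.assert_allclose(np.abs(hs.theta[0]), np.pi, atol=1e-12)

    def test_zero_displacement_flagged(self):
        df = make_track(0, [0, 0.05, 0.1], [0, 0, 1], [0, 0, 0])
        hs = headings_from_positions(df)
        assert list(hs.valid[0]) == [False, True]

    def test_simulator_round_trip(self, ecoli_dist):
        cfg = SimConfig(lambda0=0.39, tumble_dist=ecoli_dist, seed=5,
                        d_rot=0.0, n_tracks=3, duration=5.0)
        trajs = simulate_ensemble(cfg)
        hs_pos = headings_from_positions(ensemble_to_table(trajs))
        hs_true = headings_from_trajectories(trajs)
        for a, b in zip(hs_pos.theta, hs_true.theta):
            # positions recover headings up to winding
            diff = (a - b + np.pi) % (2 * np.pi) - np.pi
            np.testing.assert_allclose(diff, 0.0, atol=1e-9)

    def test_non_constant_spacing_rejected(self):
        df = make_track(0, [0.0, 0.05, 0.2], [0, 1, 2], [0, 0, 0])
        with pytest.raises(ValueError):
            validate_tracks(df)


class TestFilters:
    def test_straight_track_survives(self):
        df = straight_track(n=101)  # 5 s, 100 um displacement
        out, report = apply_filters(df, FilterRules(curvature_fraction=0.0))
        assert report["n_surviving"] == 1
        # 0.5 s trimmed from each end
        assert out["t"].min() == pytest.approx(0.5)
        assert out["t"].max() == pytest.approx(4.5)

    def test_long_track_discarded(self):
        long = straight_track(0, n=241)  # 12 s
        short = straight_track(1, n=101)
        df = pd.concat([long, short])
        out, report = apply_filters(df, FilterRules(curvature_fraction=0.0))
        assert report["removed_duration"] == 1
        assert out["track_id"].unique().tolist() == [1]

    def test_mixed_fixture_counts(self, ecoli_dist):
        """10 synthetic tracks: 2 violate displacement, 2 are wobbliest -> 6 left."""
        rng = np.random.default_rng(0)
        tracks = []
        for i in range(8):
            # straight movers with mild curvature i
            t = np.arange(121) * 0.05
            wig = 0.002 * i * np.sin(2 * np.pi * t)
            tracks.append(
                make_track(i, t, 15 * t, np.cumsum(wig) + 0.01 * rng.random(len(t)))
            )
        for i in (8, 9):
            # stallers: displacement below 10 um
            t = np.arange(121) * 0.05
            tracks.append(make_track(i, t, 0.5 * t, np.zeros_like(t)))
        out, report = apply_filters(pd.concat(tracks), FilterRules())
        assert report["removed_displacement"] == 2
        assert report["removed_curvature"] == 2  # 20% of the 8 survivors, rounded
        assert out["track_id"].nunique() == 6

    def test_empty_survivors_error(self):
        df = straight_track(n=241)  # only a too-long track
        with pytest.raises(ValueError):
            apply_filters(df, FilterRules(curvature_fraction=0.0))


class TestEmpiricalCMs:
    def test_constant_heading_gives_zero(self):
        hs = headings_from_positions(straight_track())
        cm = empirical_cms(hs, 0.5)
        np.testing.assert_allclose(cm.values, 0.0)

    def test_single_pair(self):
        # two headings 0.5 rad apart at lag 0.5 s -> m1 = 1.0, m2 = 0.5
        t = [0, 0.5, 1.0]
        x = [0, 1.0, 1.0 + np.cos(0.5)]
        y = [0, 0.0, np.sin(0.5)]
        hs = headings_from_positions(make_track(0, t, x, y))
        cm = empirical_cms(hs, 0.5, orders=(1, 2), min_weight=0.5)
        assert cm.values[0] == pytest.approx(1.0)
        assert cm.values[1] == pytest.approx(0.5)
        assert cm.n_pairs == 1

    def test_lag_must_divide_frames(self, small_ensemble):
        hs = headings_from_trajectories(small_ensemble)
        with pytest.raises(ValueError):
            empirical_cms(hs, 0.52)

    def test_all_left_endpoints_used(self, small_ensemble):
        hs = headings_from_trajectories(small_ensemble)
        lag = 10
        cm = empirical_cms(hs, 0.5)
        expected = sum(len(th) - lag for th in hs.theta)
        assert cm.n_pairs == expected

    def test_rotation_invariance_unconditioned(self, small_ensemble):
        hs = headings_from_trajectories(small_ensemble)
        cm0 = empirical_cms(hs, 0.5)
        import copy

        hs_rot = copy.deepcopy(hs)
        hs_rot.theta = [th + 1.234 for th in hs.theta]
        cm1 = empirical_cms(hs_rot, 0.5)
        np.testing.assert_allclose(cm0.values, cm1.values, rtol=1e-12)

    def test_kernel_is_circular(self, small_ensemble):
        hs = headings_from_trajectories(small_ensemble)
        a = empirical_cms(hs, 0.5, theta_cond=0.3)
        b = empirical_cms(hs, 0.5, theta_cond=0.3 + 2 * np.pi)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)
        assert a.z_k == pytest.approx(b.z_k)

    def test_wide_kernel_matches_unconditioned(self, small_ensemble):
        hs = headings_from_trajectories(small_ensemble)
        wide = empirical_cms(hs, 0.5, theta_cond=1.0, delta_theta=1e4)
        flat = empirical_cms(hs, 0.5)
        np.testing.assert_allclose(wide.values, flat.values, rtol=1e-5)

    def test_matches_theory_within_mc_error(self, ecoli_dist):
        """Ensemble CMs agree with the closed forms at mild conditions where
        the leading-order formulas are accurate."""
        lam, d, dt = 0.1, 0.01, 0.5
        cfg = SimConfig(lambda0=lam, tumble_dist=ecoli_dist, seed=77,
                        d_rot=d, n_tracks=400, duration=10.0)
        hs = headings_from_trajectories(simulate_ensemble(cfg))
        cm = empirical_cms(hs, dt, orders=(1, 2, 3, 4))
        theo = theoretical_cms(MotilityParams(lam, d, ecoli_dist), dt,
                               orders=(1, 2, 3, 4)).values
        # overlapping lag pairs are correlated; allow a generous band
        np.testing.assert_allclose(cm.values, theo, rtol=0.1)

    def test_low_weight_flagged(self):
        hs = headings_from_positions(straight_track(n=30))
        with pytest.warns(UserWarning):
            cm = empirical_cms(hs, 0.5, min_weight=1e6)
        assert cm.low_confidence
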