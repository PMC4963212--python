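import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import vonmises

from curvetracks import (TrackSet, bias_angles, chi2_uniform_gof,
                         circular_mean, deviation_distance,
                         persistence_angles, simulate_walk,
                         straightness_index, vonmises_concentration,
                         WalkModel)
from curvetracks.directional import AngleDistribution, wrap_angle
from curvetracks.exceptions import (EmptyInputError, ParameterError,
                                    UndefinedAngleError)
from curvetracks.surfaces import Plane


def tracks2d(points, track_id=0):
    pts = np.asarray(points, dtype=float)
    df = pd.DataFrame({"track_id": track_id, "t": np.arange(len(pts)),
                       "u": pts[:, 0], "v": pts[:, 1]})
    return TrackSet.from_dataframe(df, method_tag="test")


class TestBiasAngles:
    def test_step_toward_target_is_zero(self):
        ts = tracks2d([[0, 0], [1, 0]])
        d = bias_angles(ts, np.array([5.0, 0.0]), bins=8)
        assert d.angles[0] == pytest.approx(0.0)

    def test_orthogonal_step_is_plus_half_pi(self):
        # step (0,1) with target along +x: counterclockwise positive
        # from the target direction to the step
        ts = tracks2d([[0, 0], [0, 1]])
        d = bias_angles(ts, np.array([5.0, 0.0]), bins=8)
        assert d.angles[0] == pytest.approx(np.pi / 2)

    def test_zero_length_steps_excluded_and_counted(self):
        ts = tracks2d([[0, 0], [0, 0], [1, 0]])
        d = bias_angles(ts, np.array([5.0, 0.0]), bins=8)
        assert d.n == 1 and d.n_excluded == 1

    def test_target_on_origin_rejected(self):
        ts = tracks2d([[0, 0], [1, 0]])
        with pytest.raises(UndefinedAngleError):
            bias_angles(ts, np.array([0.0, 0.0]), bins=8)


class TestPersistenceAngles:
    def test_straight_track_all_zero(self):
        ts = tracks2d([[0, 0], [1, 0], [2, 0], [3, 0]])
        d = persistence_angles(ts, bins=8)
        assert np.allclose(d.angles, 0.0)

    def test_square_spiral_constant_quarter_turns(self):
        # left turns: +pi/2 under the counterclockwise convention
        ts = tracks2d([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]])
        d = persistence_angles(ts, bins=8)
        assert np.allclose(d.angles, np.pi / 2)

    def test_persistent_walk_kappa_recovered(self):
        sim = simulate_walk(Plane(extent=1e9),
                            WalkModel(persistence_strength=2.0,
                                      step_length=1.0),
                            n_tracks=1, n_steps=10 ** 4, seed=5)
        from curvetracks import project_xy
        d = persistence_angles(project_xy(sim.tracks3d))
        fit = vonmises_concentration(d.angles)
        lo, hi = fit["kappa_ci"]
        assert lo < 2.0 < hi
        mu, R = circular_mean(d.angles)
        assert abs(mu) < 0.05

    def test_single_step_tracks_have_no_pairs(self):
        ts = tracks2d([[0, 0], [1, 0]])
        with pytest.raises(EmptyInputError):
            persistence_angles(ts, bins=8)


class TestStraightness:
    def test_straight_is_one_outback_is_zero(self):
        assert straightness_index(tracks2d([[0, 0], [1, 0], [2, 0]]))[0] \
            == pytest.approx(1.0)
        assert straightness_index(tracks2d([[0, 0], [1, 0], [0, 0]]))[0] \
            == pytest.approx(0.0)

    def test_brownian_straightness_decays_like_sqrt_n(self):
        """E[D] ~ n^(-1/2) for planar Brownian walks (Monte Carlo)."""
        meds = []
        for n_steps in (25, 100, 400):
            sim = simulate_walk(Plane(extent=1e9),
                                WalkModel(step_length=1.0),
                                n_tracks=60, n_steps=n_steps, seed=8)
            meds.append(straightness_index(sim.tracks3d).median())
        ratios = np.array(meds[:-1]) / np.array(meds[1:])
        assert np.all(ratios > 1.5) and np.all(ratios < 2.7)

    def test_zero_path_length_rejected(self):
        with pytest.raises(UndefinedAngleError):
            straightness_index(tracks2d([[1, 1], [1, 1]]))


class TestDeviationDistance:
    def test_identical_distributions_zero(self):
        u = AngleDistribution.uniform(36)
        assert deviation_distance(u, u) == 0.0

    def test_disjoint_masses_maximal(self):
        a = AngleDistribution.from_angles(np.full(100, -2.0), bins=36)
        b = AngleDistribution.from_angles(np.full(100, 2.0), bins=36)
        assert deviation_distance(a, b) == pytest.approx(1.0)

    def test_uniform_vs_vonmises_matches_quadrature(self):
        """TV(uniform, VM(1)) on 36 bins equals the direct numerical
        integral of the binned TV formula."""
        u = AngleDistribution.uniform(36)
        v = AngleDistribution.from_density(lambda a: vonmises.pdf(a, 1.0),
                                           bins=36)
        edges = u.bin_edges
        tv_direct = 0.0
        for i in range(36):
            p, _ = quad(lambda a: vonmises.pdf(a, 1.0), edges[i],
                        edges[i + 1], epsabs=1e-12)
            w = edges[i + 1] - edges[i]
            tv_direct += 0.5 * abs(p / w - 1 / (2 * np.pi)) * w
        assert deviation_distance(v, u) == pytest.approx(tv_direct,
                                                         abs=1e-6)

    def test_binning_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            deviation_distance(AngleDistribution.uniform(36),
                               AngleDistribution.uniform(18))

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=25, deadline=None)
    def test_metric_properties_on_random_histograms(self, seed):
        rng = np.random.default_rng(seed)
        ds = [AngleDistribution.from_angles(
            rng.vonmises(rng.uniform(-3, 3), rng.uniform(0, 2), 400),
            bins=12) for _ in range(3)]
        ab = deviation_distance(ds[0], ds[1])
        ba = deviation_distance(ds[1], ds[0])
        assert ab == pytest.approx(ba)
        ac = deviation_distance(ds[0], ds[2])
        cb = deviation_distance(ds[2], ds[1])
        assert ab <= ac + cb + 1e-12
        assert 0 <= ab <= 1

    def test_ks_variant_needs_raw_angles(self):
        u = AngleDistribution.uniform(36)
        with pytest.raises(ParameterError):
            deviation_distance(u, u, kind="ks")


class TestInvariants:
    def test_rotation_invariance_of_angle_statistics(
            self, plane_brownian_small):
        from curvetracks import project_xy
        t2 = project_xy(plane_brownian_small.tracks3d)
        th = 0.83
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rot = t2.with_positions(t2.positions() @ R.T)
        tgt = np.array([7.0, -3.0])
        a = bias_angles(t2, tgt)
        b = bias_angles(rot, R @ tgt)
        assert np.allclose(np.sort(a.angles), np.sort(b.angles), atol=1e-9)
        pa = persistence_angles(t2)
        pb = persistence_angles(rot)
        assert np.allclose(pa.angles, pb.angles, atol=1e-9)

    def test_histograms_integrate_to_one(self, rng):
        for _ in range(5):
            d = AngleDistribution.from_angles(
                rng.uniform(-np.pi, np.pi, 50), bins=9)
            assert np.isclose(np.sum(d.density) * d.bin_width, 1.0,
                              atol=1e-12)

    def test_wrap_angle_range(self):
        a = wrap_angle(np.array([-3 * np.pi, np.pi, 7.0, -0.1]))
        assert np.all(a >= -np.pi) and np.all(a < np.pi)
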