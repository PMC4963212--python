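import numpy as np
import pytest
from scipy import special, stats as sps

from curvetracks import (WalkModel, simulate_walk, tangent_step,
                         true_angle_distribution)
from curvetracks.directional import AngleDistribution, deviation_distance
from curvetracks.exceptions import ParameterError
from curvetracks.surfaces import Cylinder, Plane, Sphere
from curvetracks.walks import preset_model, preset_surface


class TestTangentStep:
    def test_plane_step_exact(self):
        pl = Plane()
        q = tangent_step(pl, [[0.0, 0.0, 0.0]], [np.pi / 4], 1.0)
        assert np.allclose(q, [[np.cos(np.pi / 4), np.sin(np.pi / 4), 0.0]])

    def test_sphere_small_step_matches_great_circle(self):
        s = Sphere(radius=1.0)
        p = np.array([[0.0, 0.0, 1.0]])
        L = 0.01
        q = tangent_step(s, p, [0.0], L)
        e1, e2 = s.tangent_basis(p)
        exact = np.cos(L) * p + np.sin(L) * e1  # great circle
        assert np.linalg.norm(q - exact) < 1e-5

    def test_cylinder_axis_heading_stays_on_generator(self):
        c = Cylinder(radius=1.0)
        p = np.array([[1.0, 0.0, 0.0]])
        e1, e2 = c.tangent_basis(p)
        # find the heading pointing along +z in the local frame
        heading = np.arctan2(e2[0] @ [0, 0, 1], e1[0] @ [0, 0, 1])
        q = tangent_step(c, p, [heading], 0.5)
        assert np.allclose(q, [[1.0, 0.0, 0.5]], atol=1e-12)

    def test_off_surface_start_rejected(self):
        with pytest.raises(ParameterError):
            tangent_step(Sphere(radius=1.0), [[0.0, 0.0, 2.0]], [0.0], 0.1)


class TestSimulateWalk:
    def test_seed_determinism(self):
        s = Sphere(radius=1.0)
        m = WalkModel(step_length=0.02)
        a = simulate_walk(s, m, 5, 50, seed=9)
        b = simulate_walk(s, m, 5, 50, seed=9)
        assert np.array_equal(a.tracks3d.positions(), b.tracks3d.positions())
        assert a.intrinsic.equals(b.intrinsic)

    def test_points_stay_on_surface(self, hemisphere_brownian):
        sim = hemisphere_brownian
        f = sim.surface.implicit(sim.tracks3d.positions())
        assert np.max(np.abs(f)) < 1e-8 * sim.surface.scale

    def test_step_lengths_conserved(self, hemisphere_brownian):
        from curvetracks import steps
        st = steps(hemisphere_brownian.tracks3d)
        ln = np.linalg.norm(st[["dx", "dy", "dz"]].to_numpy(), axis=1)
        L = hemisphere_brownian.model.step_length
        assert np.all(ln <= L + 1e-12) and np.all(ln >= 0.99 * L)

    def test_brownian_plane_angles_uniform(self, plane_brownian_small):
        from curvetracks import chi2_uniform_gof, persistence_angles, \
            project_xy, bias_angles
        t2 = project_xy(plane_brownian_small.tracks3d)
        pa = persistence_angles(t2)
        assert chi2_uniform_gof(pa)[1] > 0.01
        ba = bias_angles(t2, np.array([9.0, 7.0]))
        assert chi2_uniform_gof(ba)[1] > 0.01

    def test_uniform_heading_changes_on_full_sphere(self):
        sim = simulate_walk(Sphere(radius=1.0), WalkModel(step_length=0.02),
                            n_tracks=100, n_steps=200, seed=4)
        # thin to every other turn: consecutive turning angles share a
        # heading draw, and the KS p value assumes independent samples
        turns = sim.intrinsic.groupby("track_id")["turn_angle"] \
            .apply(lambda s: s.dropna().iloc[::2])
        u = (turns.to_numpy() + np.pi) / (2 * np.pi)
        assert sps.kstest(u, "uniform").pvalue > 0.01

    def test_pure_persistence_limit_is_straight(self):
        sim = simulate_walk(Plane(), WalkModel(persistence_strength=1e6,
                                               step_length=0.1),
                            n_tracks=3, n_steps=80, seed=2)
        from curvetracks import straightness_index
        D = straightness_index(sim.tracks3d)
        assert np.all(D > 0.999)

    def test_bias_concentration_monotone_in_strength(self):
        """Mean resultant length of bias angles grows with the bias
        concentration and tracks the von Mises moment A(kappa)."""
        target = np.array([1e5, 0.0, 0.0])  # effectively fixed direction
        R = []
        for kb in [0.5, 1.0, 2.0, 4.0]:
            sim = simulate_walk(
                Plane(), WalkModel(bias_strength=kb, target=target,
                                   step_length=0.1),
                n_tracks=20, n_steps=150, seed=11)
            ang = sim.intrinsic["bias_angle"].dropna().to_numpy()
            R.append(np.abs(np.exp(1j * ang).mean()))
            expected = special.i1(kb) / special.i0(kb)
            assert abs(R[-1] - expected) < 0.03
        assert np.all(np.diff(R) > 0)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            simulate_walk(Plane(), WalkModel(), 5, 0, seed=0)
        with pytest.raises(ParameterError):
            WalkModel(bias_strength=1.0)  # target missing
        with pytest.raises(ParameterError):
            WalkModel(step_length=0.0)


class TestTrueDistributions:
    def test_brownian_flat_and_normalized(self):
        for which in ("bias", "persistence"):
            d = true_angle_distribution(WalkModel(), which)
            assert np.allclose(d.density, 1 / (2 * np.pi))
            assert np.isclose(np.sum(d.density) * d.bin_width, 1.0)

    def test_bias_only_bias_density_is_vonmises(self):
        m = WalkModel(bias_strength=2.0, target=np.array([1.0, 0, 0]))
        d = true_angle_distribution(m, "bias", bins=72)
        centers = 0.5 * (d.bin_edges[1:] + d.bin_edges[:-1])
        assert np.allclose(d.density, sps.vonmises.pdf(centers, 2.0),
                           atol=2e-3)

    def test_bias_only_persistence_matches_monte_carlo(self):
        """Self-convolution series for the turning angles of a
        bias-only walk agrees with direct simulation (L1 < 0.01)."""
        kb = 2.0
        m = WalkModel(bias_strength=kb, target=np.array([1.0, 0, 0]))
        d = true_angle_distribution(m, "persistence", bins=36)
        rng = np.random.default_rng(0)
        th = rng.vonmises(0.0, kb, size=10 ** 6)
        turns = np.diff(th)
        mc = AngleDistribution.from_angles(turns, bins=36)
        l1 = np.sum(np.abs(mc.density - d.density)) * d.bin_width
        assert l1 < 0.01

    def test_persistence_only_bias_flat(self):
        m = WalkModel(persistence_strength=3.0)
        d = true_angle_distribution(m, "bias")
        assert np.allclose(d.density, 1 / (2 * np.pi))

    def test_combined_model_stationary_chain_reproducible(self):
        m = WalkModel(bias_strength=2.0, persistence_strength=1.0,
                      target=np.array([1.0, 0, 0]))
        a = true_angle_distribution(m, "bias")
        b = true_angle_distribution(m, "bias")
        assert np.array_equal(a.density, b.density)
        # biased-persistent bias distribution is unimodal at zero
        centers = 0.5 * (a.bin_edges[1:] + a.bin_edges[:-1])
        assert centers[np.argmax(a.density)] == pytest.approx(0, abs=0.2)


def test_presets_resolve():
    for name in ("plane", "cylinder", "hemisphere", "sphere",
                 "ellipsoid_mild", "ellipsoid_thin"):
        surface, region, L, target = preset_surface(name)
        assert L > 0
        m = preset_model("biased_persistent", name)
        assert m.bias_strength > 0 and m.target is not None
        assert np.abs(surface.implicit(m.target[None])) < 1e-6 * surface.scale
    with pytest.raises(ParameterError):
        preset_surface("moebius")
    with pytest.raises(ParameterError):
        preset_model("levy", "plane")
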