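"""Worm-like-chain generator, lumenal point processes, volume rendering."""

import numpy as np
import pytest
from scipy import stats

from mtlumen import (PackingError, ParticleSet, ProcessSpec, RenderSpec,
                     annotate_defects, build_domain, place_particles,
                     render_volume, simulate_ensemble, simulate_filament)
from mtlumen.simulate import GeometryError

from conftest import straight_trace


class TestWormLikeChain:
    def test_rigid_rod_limit(self):
        tr = simulate_filament(11, 20.0, 1e9, seed=3)
        t = np.diff(tr.points, axis=0)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        assert np.abs(t - t[0]).max() < 1e-3
        steps = np.linalg.norm(np.diff(tr.points, axis=0), axis=1)
        assert np.allclose(steps, 20.0)

    def test_tangent_correlation_analytic_decay(self):
        # ensemble mean of t(0).t(s) at s = 1000 nm with Lp = 1000 nm is e^-1
        chains = simulate_ensemble(2000, 52, 20.0, 1000.0, seed=4)
        dots = []
        for tr in chains:
            t = np.diff(tr.points, axis=0)
            t /= np.linalg.norm(t, axis=1, keepdims=True)
            dots.append(t[0] @ t[50])
        mc_se = np.std(dots) / np.sqrt(len(dots))
        assert abs(np.mean(dots) - np.exp(-1)) < 4 * mc_se + 1e-3

    def test_equal_steps_and_seed_determinism(self):
        a = simulate_filament(30, 20.0, 30000.0, seed=9)
        b = simulate_filament(30, 20.0, 30000.0, seed=9)
        assert np.array_equal(a.points, b.points)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_filament(10, -1.0, 1000.0, seed=1)
        with pytest.raises(ValueError):
            simulate_filament(10, 20.0, 0.0, seed=1)


class TestPlaceParticles:
    def test_csr_zero_intensity_empty(self, straight_domain):
        ps = place_particles(straight_domain, ProcessSpec(kind="csr", intensity=0.0, seed=1))
        assert len(ps) == 0

    def test_csr_counts_poisson_distributed(self, straight_domain):
        # chi-square GOF of counts over 200 replicates vs Poisson(lambda V)
        lam = 2e-4 * straight_domain.tube_volume()
        counts = [len(place_particles(straight_domain,
                                      ProcessSpec(kind="csr", intensity=2e-4, seed=s)))
                  for s in range(200)]
        counts = np.asarray(counts)
        # pool tails so expected counts are >= 5
        lo, hi = int(lam - 3 * np.sqrt(lam)), int(lam + 3 * np.sqrt(lam))
        edges = np.arange(lo, hi + 1)
        obs = np.array([(counts <= lo).sum()]
                       + [(counts == k).sum() for k in range(lo + 1, hi)]
                       + [(counts >= hi).sum()])
        pm = stats.poisson(lam)
        exp = np.array([pm.cdf(lo)] + [pm.pmf(k) for k in range(lo + 1, hi)]
                       + [1 - pm.cdf(hi - 1)]) * 200
        keep = exp >= 5
        obs_p, exp_p = obs[keep], exp[keep]
        exp_p = exp_p * obs_p.sum() / exp_p.sum()
        chi2 = ((obs_p - exp_p) ** 2 / exp_p).sum()
        p = 1 - stats.chi2.cdf(chi2, df=keep.sum() - 1)
        assert p > 0.01

    def test_all_particles_strictly_inside_lumen(self, straight_domain):
        for kind, kw in [("csr", {"intensity": 3e-4}),
                         ("quasi_periodic", {"spacing_mean": 9.0, "spacing_sd": 1.5,
                                             "hardcore_distance": 7.0}),
                         ("hardcore", {"intensity": 1e-4, "hardcore_distance": 7.0})]:
            ps = place_particles(straight_domain, ProcessSpec(kind=kind, seed=5, **kw))
            d, _ = straight_domain.distance_and_arclength(ps.positions())
            assert (d <= straight_domain.lumen_radius).all()

    def test_hardcore_min_distance_brute_force(self, straight_domain):
        ps = place_particles(straight_domain,
                             ProcessSpec(kind="hardcore", intensity=2e-4,
                                         hardcore_distance=7.0, seed=2))
        pos = ps.positions()
        diff = pos[:, None, :] - pos[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 7.0

    def test_hardcore_infeasible_packing_errors_with_count(self, straight_domain):
        with pytest.raises(PackingError) as ei:
            place_particles(straight_domain,
                            ProcessSpec(kind="hardcore", intensity=5e-3,
                                        hardcore_distance=8.0, seed=2))
        assert ei.value.achieved < ei.value.target

    def test_quasi_periodic_respects_hardcore_and_mode(self, straight_domain):
        ps = place_particles(straight_domain,
                             ProcessSpec(kind="quasi_periodic", spacing_mean=9.0,
                                         spacing_sd=1.5, hardcore_distance=7.0,
                                         radial_jitter=2.0, seed=8))
        gaps = np.diff(np.sort(ps.arclengths()))
        assert gaps.min() >= 7.0 - 1e-9
        assert 8.0 <= np.median(gaps) <= 10.0

    def test_anchored_cluster_enriches_window(self):
        dom = build_domain(straight_trace(length=2000.0), 8.5)
        dom = annotate_defects(dom, break_arclengths=[1000.0])
        ps = place_particles(dom, ProcessSpec(kind="anchored_cluster", intensity=2e-4,
                                              cluster_domain=300.0,
                                              cluster_multiplier=6.0, seed=3))
        s = ps.arclengths()
        inside = ((s > 850) & (s < 1150)).sum() / 300.0
        outside = ((s <= 850) | (s >= 1150)).sum() / 1700.0
        assert inside > 2 * outside

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ProcessSpec(kind="nope")
        with pytest.raises(ValueError):
            ProcessSpec(kind="csr", intensity=-1.0)
        with pytest.raises(ValueError):
            ProcessSpec(kind="quasi_periodic", spacing_mean=5.0, hardcore_distance=7.0)


class TestAnnotateDefects:
    def test_no_defects_leaves_domain_unchanged(self, straight_domain):
        out = annotate_defects(straight_domain)
        assert out.break_anchors == ()
        assert out.open_ends == frozenset()
        assert out.tube_volume() == straight_domain.tube_volume()

    def test_break_anchor_coordinate_by_arclength_interpolation(self, straight_domain):
        out = annotate_defects(straight_domain, break_arclengths=[500.0])
        anchors = out.anchor_points()
        assert np.allclose(anchors, [[500.0, 0.0, 0.0]])

    def test_open_end_anchor_coordinates(self, straight_domain):
        out = annotate_defects(straight_domain, open_ends=["start", "end"])
        anchors = out.anchor_points()
        assert np.allclose(sorted(anchors[:, 0]), [0.0, 1000.0])

    def test_out_of_range_break_rejected(self, straight_domain):
        with pytest.raises(ValueError):
            annotate_defects(straight_domain, break_arclengths=[2000.0])


class TestRenderVolume:
    def test_empty_scene_is_constant_background(self):
        spec = RenderSpec(noise_sd=0.0, background_level=0.7, seed=1)
        vol, truth = render_volume([], ParticleSet.empty(), 300.0, spec)
        assert np.allclose(vol.grid, 0.7)
        assert len(truth) == 0

    def test_integrated_intensity_2_to_1_mass_ratio(self):
        # voxel-sum oracle: blobs of mass m and 2m integrate 1:2 within 1%
        ps = ParticleSet.from_arrays([[40, 40, 40], [120, 40, 40]], mt_id=0)
        spec = RenderSpec(noise_sd=0.0, seed=1)
        vol, _ = render_volume([], ps, np.array([150.0, 300.0]), spec)
        g = vol.grid.astype(np.float64)
        i1 = g[:int(80 / spec.voxel_size)].sum()
        i2 = g[int(80 / spec.voxel_size):].sum()
        assert i1 / i2 == pytest.approx(0.5, rel=0.01)

    def test_integrated_intensity_linear_in_mass(self):
        # regression of voxel-sum vs mass over the 200-400 kDa range
        masses = np.array([200.0, 250.0, 300.0, 350.0, 400.0])
        sums = []
        for m in masses:
            ps = ParticleSet.from_arrays([[40, 40, 40]], mt_id=0)
            vol, _ = render_volume([], ps, m, RenderSpec(noise_sd=0.0, seed=1))
            sums.append(vol.grid.astype(np.float64).sum())
        r = np.corrcoef(masses, sums)[0, 1]
        assert r**2 > 0.999

    def test_ground_truth_complete_and_inside_lumen(self):
        tr = straight_trace(length=600.0)
        dom = build_domain(tr, 8.5)
        ps = place_particles(dom, ProcessSpec(kind="csr", intensity=3e-4, seed=6))
        spec = RenderSpec(noise_sd=0.1, ribosome_count=3, seed=6)
        vol, truth = render_volume([tr], ps, 300.0, spec)
        lum = truth[truth["kind"] == "lumenal"]
        assert len(lum) == len(ps)
        d, _ = dom.distance_and_arclength(lum[["x_nm", "y_nm", "z_nm"]].to_numpy())
        assert (d <= 8.5).all()
        ribo = truth[truth["kind"] == "ribosome"]
        assert len(ribo) == 3
        dr, _ = dom.distance_and_arclength(ribo[["x_nm", "y_nm", "z_nm"]].to_numpy())
        assert (dr > spec.wall_outer_radius).all()

    def test_box_too_small_rejected(self):
        ps = ParticleSet.from_arrays([[100, 0, 0]], mt_id=0)
        with pytest.raises(GeometryError):
            render_volume([], ps, 300.0, RenderSpec(seed=1),
                          origin=np.zeros(3), shape=(50, 50, 50))
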