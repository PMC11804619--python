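"""Concentration, NN analysis, Ripley's L in tubes, group comparisons."""

import numpy as np
import pytest

from mtlumen import (FilamentTrace, ParticleSet, ProcessSpec, StatCurve,
                     build_domain, compare_groups, concentration, csr_envelope,
                     domain_size, nn_distances, place_particles, ripley_L,
                     ripley_L_bivariate)
from mtlumen.spatial import _csr_replicate, fibonacci_sphere

from conftest import segment_trace, straight_trace


class TestConcentration:
    def test_empty_set_is_zero(self, straight_domain):
        res = concentration(ParticleSet.empty(), straight_domain)
        assert res.count == 0 and res.per_um3 == 0.0

    def test_ten_particles_straight_tube(self, straight_domain):
        pos = np.column_stack([np.linspace(50, 950, 10), np.zeros(10), np.zeros(10)])
        ps = ParticleSet.from_arrays(pos, mt_id=0)
        res = concentration(ps, straight_domain)
        # 10 / (pi * 8.5^2 * 1000) nm^-3 = 4.406e4 um^-3
        assert res.per_um3 == pytest.approx(4.406e4, rel=1e-3)
        assert res.per_100nm == pytest.approx(1.0)


class TestNearestNeighbour:
    def test_pair_distance(self):
        ps = ParticleSet.from_arrays([[0, 0, 0], [12, 0, 0]], mt_id=0)
        res = nn_distances(ps)
        assert np.allclose(res.distances, 12.0)

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 100, (30, 3))
        ps = ParticleSet.from_arrays(pos, mt_id=0)
        res = nn_distances(ps)
        diff = pos[:, None] - pos[None, :]
        d = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert np.allclose(np.sort(res.distances), np.sort(d.min(axis=1)))

    def test_sparse_mts_excluded_and_counted(self):
        sets = [ParticleSet.from_arrays([[0, 0, 0], [9, 0, 0]], mt_id=0),
                ParticleSet.from_arrays([[0, 0, 0]], mt_id=1)]
        res = nn_distances(ParticleSet.concat(sets))
        assert res.n_excluded_mts == 1 and res.distances.size == 2

    def test_quasi_periodic_mode_in_printed_band(self, straight_domain):
        ps = place_particles(straight_domain,
                             ProcessSpec(kind="quasi_periodic", spacing_mean=9.0,
                                         spacing_sd=1.5, hardcore_distance=7.0,
                                         radial_jitter=2.0, seed=21))
        res = nn_distances(ps, bin_width=2.0)
        assert 8.0 <= res.mode_bin_center <= 10.0

    def test_mode_tie_takes_smaller_bin(self):
        ps = ParticleSet.concat([
            ParticleSet.from_arrays([[0, 0, 0], [3, 0, 0]], mt_id=0),
            ParticleSet.from_arrays([[0, 0, 0], [9, 0, 0]], mt_id=1)])
        res = nn_distances(ps, bin_width=2.0)
        assert res.mode_bin_center == 3.0


class TestCsrEnvelope:
    def test_constant_statistic_collapses(self, segment_domain):
        lo, hi = csr_envelope(segment_domain, 10, lambda ps: np.array([3.5]),
                              n_reps=25, seed=1)
        assert lo[0] == hi[0] == 3.5

    def test_fixed_seed_bit_identical(self, segment_domain):
        stat = lambda ps: np.array([ps.arclengths().mean(), len(ps)])
        a = csr_envelope(segment_domain, 20, stat, n_reps=30, seed=5)
        b = csr_envelope(segment_domain, 20, stat, n_reps=30, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_nn_mean_envelope_brackets_poisson_closed_form(self):
        # unbounded-Poisson NN mean 0.554 lambda^(-1/3); a fat tube with the
        # statistic restricted to interior particles keeps edge effects small
        lam = 3e-4
        tr = FilamentTrace(0, [[0, 0, 0], [600.0, 0, 0]], resampled=True, spacing=600.0)
        dom = build_domain(tr, 150.0)
        n = int(lam * dom.tube_volume())
        expect = 0.554 * lam ** (-1 / 3)

        def interior_nn_mean(ps):
            pos = ps.positions()
            d, s = dom.distance_and_arclength(pos)
            interior = ((d < 150.0 - 3 * expect) & (s > 3 * expect)
                        & (s < 600.0 - 3 * expect))
            from scipy.spatial import cKDTree
            nn, _ = cKDTree(pos).query(pos[interior], k=2)
            return np.array([nn[:, 1].mean()])

        lo, hi = csr_envelope(dom, n, interior_nn_mean, n_reps=49, seed=2)
        assert lo[0] < expect < hi[0]
        assert abs((lo[0] + hi[0]) / 2 - expect) / expect < 0.05


class TestRipleyL:
    def test_uncorrected_K_equals_pair_count_oracle(self):
        # all-inside toy geometry: fat short tube makes every weight 1
        tr = FilamentTrace(0, [[-200, 100, 100], [400, 100, 100]],
                           resampled=True, spacing=600.0)
        dom = build_domain(tr, 400.0)
        rng = np.random.default_rng(4)
        pos = rng.uniform(90, 110, (12, 3))
        ps = ParticleSet.from_arrays(pos, mt_id=0)
        radii = np.array([5.0, 10.0, 20.0, 40.0])
        curve = ripley_L(ps, dom, radii=radii, n_reps=0)
        diff = pos[:, None] - pos[None, :]
        d = np.sqrt((diff**2).sum(-1))
        iu = np.triu_indices(12, k=1)
        pair_counts = np.array([(d[iu] <= r).sum() for r in radii])
        K_oracle = dom.tube_volume() / (12 * 11) * 2 * pair_counts
        L_oracle = np.cbrt(3 * K_oracle / (4 * np.pi))
        assert np.allclose(curve.observed, L_oracle, rtol=1e-12)

    def test_csr_observed_within_envelope_at_most_radii(self, segment_domain):
        ps = _csr_replicate([segment_domain], {0: 25}, 77)
        radii = np.arange(10.0, 101.0, 10.0)
        curve = ripley_L(ps, segment_domain, radii=radii, n_reps=99, seed=3)
        inside = ((curve.observed >= curve.envelope_lo)
                  & (curve.observed <= curve.envelope_hi))
        assert inside.mean() >= 0.8

    def test_regular_pattern_below_envelope_at_small_radii(self, segment_domain):
        # quasi-periodic neuron-like packing is more uniform than random
        ps = place_particles(segment_domain,
                             ProcessSpec(kind="quasi_periodic", spacing_mean=9.0,
                                         spacing_sd=1.5, hardcore_distance=7.0,
                                         radial_jitter=2.0, seed=9))
        # radii where CSR virtually always has pairs but the regular
        # pattern (hardcore 7 nm) has none
        radii = np.arange(4.0, 21.0, 2.0)
        curve = ripley_L(ps, segment_domain, radii=radii, n_reps=99, seed=5)
        small = curve.radii <= 6.0
        assert (curve.observed[small] < curve.envelope_lo[small]).all()

    def test_isometry_invariance(self, segment_domain):
        ps = _csr_replicate([segment_domain], {0: 20}, 11)
        radii = np.arange(5.0, 21.0, 5.0)
        base = ripley_L(ps, segment_domain, radii=radii, n_reps=0,
                        n_correction_samples=8192)
        # rotate + translate everything rigidly
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        t = np.array([30.0, -12.0, 5.0])
        pos2 = ps.positions() @ R.T + t
        tr2 = FilamentTrace(0, segment_domain.centerline.points @ R.T + t,
                            resampled=True, spacing=1000.0)
        dom2 = build_domain(tr2, 8.5)
        ps2 = ParticleSet.from_arrays(pos2, mt_id=0)
        rot = ripley_L(ps2, dom2, radii=radii, n_reps=0,
                       n_correction_samples=8192)
        # NN and concentration are exactly invariant
        assert np.allclose(np.sort(nn_distances(ps).distances),
                           np.sort(nn_distances(ps2).distances))
        assert concentration(ps2, dom2).per_um3 == pytest.approx(
            concentration(ps, segment_domain).per_um3)
        # L invariant up to the finite sphere-sampling of the correction
        assert np.allclose(rot.observed, base.observed, rtol=0.03)

    def test_fewer_than_two_particles_rejected(self, segment_domain):
        ps = ParticleSet.from_arrays([[10.0, 0, 0]], mt_id=0)
        with pytest.raises(ValueError):
            ripley_L(ps, segment_domain, radii=np.array([10.0]), n_reps=0)


class TestRipleyBivariate:
    def test_no_particles_within_radius_gives_zero(self, segment_domain):
        dom = segment_domain.with_defects(break_arclengths=[500.0])
        ps = ParticleSet.from_arrays([[950.0, 0, 0]], mt_id=0)
        curve = ripley_L_bivariate(ps, dom, radii=np.arange(10.0, 101.0, 10.0),
                                   n_reps=0)
        assert np.allclose(curve.observed, 0.0)

    def test_single_anchor_step_locations(self, segment_domain):
        dom = segment_domain.with_defects(break_arclengths=[500.0])
        ps = ParticleSet.from_arrays([[550.0, 0, 0], [650.0, 0, 0]], mt_id=0)
        radii = np.arange(10.0, 201.0, 10.0)
        curve = ripley_L_bivariate(ps, dom, radii=radii, n_reps=0,
                                   n_correction_samples=4096)
        K = 4 * np.pi * np.asarray(curve.observed) ** 3 / 3
        jumps = np.where(np.diff(K) > 1e-6)[0]
        # steps exactly at the particle distances 50 and 150 nm
        assert list(curve.radii[jumps + 1]) == [50.0, 150.0]

    def test_fibonacci_sphere_is_quasi_uniform(self):
        dirs = fibonacci_sphere(1000)
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0)
        assert np.abs(dirs.mean(axis=0)).max() < 0.01


class TestDomainSize:
    def make_curve(self, above_until):
        radii = np.arange(10.0, 501.0, 10.0)
        hi = np.full(radii.size, 1.0)
        obs = np.where(radii <= above_until, 2.0, 0.5)
        return StatCurve(radii=radii, observed=obs,
                         envelope_lo=np.zeros(radii.size), envelope_hi=hi,
                         n_reps=99, n_points=10)

    def test_inside_envelope_everywhere_gives_zero(self):
        assert domain_size(self.make_curve(above_until=0.0)) == 0.0

    def test_contiguous_band_to_300(self):
        assert domain_size(self.make_curve(above_until=300.0)) == 300.0

    def test_band_must_start_at_first_radius(self):
        radii = np.arange(10.0, 101.0, 10.0)
        obs = np.where(radii >= 50.0, 2.0, 0.5)  # late-onset band
        c = StatCurve(radii=radii, observed=obs, envelope_lo=np.zeros(10),
                      envelope_hi=np.ones(10))
        assert domain_size(c) == 0.0


class TestCompareGroups:
    def test_exact_mann_whitney_enumeration(self):
        res = compare_groups([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1 / 3, rel=1e-12)

    def test_identical_groups_zero_percent_change(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.percent_change == 0.0
        assert res.pvalue > 0.9

    def test_welch_t_direction(self):
        res = compare_groups([10.0, 11.0, 12.0], [5.0, 6.0, 7.0], test="t_test")
        assert res.pvalue < 0.01
        assert res.percent_change == pytest.approx((11 - 6) / 11 * 100)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])
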