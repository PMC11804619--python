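"""Gaussian low-pass, merge-tree persistence detection, refinement."""

import numpy as np
import pytest
from scipy import ndimage

from mtlumen import (DensityVolume, ParticleSet, RenderSpec, build_domain,
                     gaussian_lowpass, persistence_maxima, refine_and_assign,
                     render_volume)
from mtlumen.detect import _masked_adjacency, lumen_mask, masked_persistence

from conftest import straight_trace


def level_sweep_persistence(grid):
    """Exhaustive oracle: descending-threshold 26-connected labelling.

    A maximum dies at the highest level at which its superlevel component
    contains a higher maximum; survivors persist to the global minimum.
    Requires distinct values.
    """
    struct = np.ones((3, 3, 3), dtype=int)
    flat = np.sort(np.unique(grid))[::-1]
    # local maxima: strictly greater than the 26-neighbourhood
    mx = grid == ndimage.maximum_filter(grid, size=3, mode="constant", cval=-np.inf)
    maxima = list(map(tuple, np.argwhere(mx)))
    alive = {m: None for m in maxima}
    pers = {}
    for v in flat:
        lab, _ = ndimage.label(grid >= v, structure=struct)
        comp_of = {m: lab[m] for m in maxima if grid[m] >= v}
        groups = {}
        for m, c in comp_of.items():
            groups.setdefault(c, []).append(m)
        for members in groups.values():
            live = [m for m in members if m in alive]
            if len(live) > 1:
                live.sort(key=lambda m: -grid[m])
                for m in live[1:]:
                    pers[m] = grid[m] - v
                    del alive[m]
    for m in alive:
        pers[m] = grid[m] - grid.min()
    return pers


class TestGaussianLowpass:
    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        vol = DensityVolume(rng.random((8, 9, 10)).astype(np.float32), 1.0)
        out = gaussian_lowpass(vol, 0.0)
        assert np.array_equal(out.grid, vol.grid)

    def test_delta_spike_conserves_total_intensity(self):
        g = np.zeros((21, 21, 21), dtype=np.float32)
        g[10, 10, 10] = 7.0
        out = gaussian_lowpass(DensityVolume(g, 1.0), 0.5)
        assert out.grid.sum() == pytest.approx(7.0, rel=1e-6)
        # matches direct convolution with the same discrete kernel
        direct = ndimage.gaussian_filter(g.astype(np.float64), 0.5, mode="nearest")
        assert np.abs(out.grid - direct).max() < 1e-6

    def test_negative_sigma_rejected(self):
        vol = DensityVolume(np.zeros((4, 4, 4)), 1.0)
        with pytest.raises(ValueError):
            gaussian_lowpass(vol, -1.0)


class TestPersistenceMaxima:
    def hand_profile(self):
        # 1D profile [0,5,1,4,0] as a 1-voxel-thick masked line
        vals = np.array([0, 5, 1, 4, 0], dtype=np.float32)
        vol = DensityVolume(vals.reshape(5, 1, 1), 1.0)
        mask = np.ones((5, 1, 1), dtype=bool)
        return vol, mask

    def test_hand_merge_tree(self):
        vol, mask = self.hand_profile()
        peaks, _ = persistence_maxima(vol, mask=mask, persistence_threshold=2.0,
                                      min_separation=0.5,
                                      exclude_boundary_maxima=False)
        got = sorted((p.height, p.persistence) for p in peaks)
        assert got == [(4.0, 3.0), (5.0, 5.0)]

    def test_hand_merge_tree_higher_threshold(self):
        vol, mask = self.hand_profile()
        peaks, _ = persistence_maxima(vol, mask=mask, persistence_threshold=3.5,
                                      min_separation=0.5,
                                      exclude_boundary_maxima=False)
        assert [(p.height, p.persistence) for p in peaks] == [(5.0, 5.0)]

    def test_constant_volume_yields_no_maxima(self):
        vol = DensityVolume(np.full((6, 6, 6), 2.0, dtype=np.float32), 1.0)
        peaks, rep = persistence_maxima(vol, mask=np.ones((6, 6, 6), bool),
                                        persistence_threshold=0.0,
                                        exclude_boundary_maxima=False)
        assert peaks == []

    def test_empty_mask_warns_and_returns_empty(self):
        vol = DensityVolume(np.zeros((4, 4, 4)), 1.0)
        with pytest.warns(UserWarning, match="empty"):
            peaks, rep = persistence_maxima(vol, mask=np.zeros((4, 4, 4), bool))
        assert peaks == [] and rep["n_after_separation"] == 0

    def test_two_rendered_blobs_found_within_one_voxel(self):
        ps = ParticleSet.from_arrays([[40, 30, 30], [60, 30, 30]], mt_id=0)
        vol, _ = render_volume([], ps, 300.0, RenderSpec(noise_sd=0.0, seed=1))
        filt = gaussian_lowpass(vol, 0.5)
        mask = np.ones(filt.grid.shape, bool)
        peaks, _ = persistence_maxima(filt, mask=mask, persistence_threshold=0.3,
                                      exclude_boundary_maxima=False)
        assert len(peaks) == 2
        pos = np.array(sorted(p.position.tolist() for p in peaks))
        assert np.abs(pos - [[40, 30, 30], [60, 30, 30]]).max() <= 1.0

    def test_detection_count_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        vol = DensityVolume(rng.random((12, 12, 12)).astype(np.float32), 1.0)
        mask = np.ones((12, 12, 12), bool)
        counts = []
        for thr in [0.0, 0.1, 0.2, 0.4, 0.8]:
            peaks, _ = persistence_maxima(vol, mask=mask, persistence_threshold=thr,
                                          min_separation=0.0,
                                          exclude_boundary_maxima=False)
            counts.append(len(peaks))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_tree_matches_level_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.random((8, 8, 8))
        mask = np.ones((8, 8, 8), bool)
        indptr, indices, coords = _masked_adjacency(mask)
        is_max, pers = masked_persistence(grid[mask], indptr, indices)
        got = {tuple(coords[i]): pers[i] for i in np.where(is_max)[0]}
        expect = level_sweep_persistence(grid)
        assert set(got) == set(expect)
        for m in expect:
            assert got[m] == pytest.approx(expect[m], abs=1e-12)

    def test_persistence_shift_invariant_scale_equivariant(self):
        rng = np.random.default_rng(7)
        grid = rng.random((8, 8, 8))
        mask = np.ones((8, 8, 8), bool)
        indptr, indices, _ = _masked_adjacency(mask)
        m0, p0 = masked_persistence(grid[mask], indptr, indices)
        m_shift, p_shift = masked_persistence(grid[mask] + 5.0, indptr, indices)
        m_scale, p_scale = masked_persistence(grid[mask] * 3.0, indptr, indices)
        assert np.array_equal(m_shift, m0) and np.array_equal(m_scale, m0)
        assert np.allclose(p_shift[m0], p0[m0])
        assert np.allclose(p_scale[m0], 3.0 * p0[m0])


class TestRefineAndAssign:
    def test_symmetric_blob_centroid_subvoxel(self):
        ps = ParticleSet.from_arrays([[40.0, 30.0, 30.0]], mt_id=0)
        vol, _ = render_volume([], ps, 300.0, RenderSpec(noise_sd=0.0, seed=1))
        tr = straight_trace(length=80.0, origin=(0.0, 30.0, 30.0))
        dom = build_domain(tr, 8.5)
        peaks, _ = persistence_maxima(vol, mask=lumen_mask(vol, [dom]),
                                      persistence_threshold=0.3)
        out, rep = refine_and_assign(peaks, vol, [dom])
        assert len(out) == 1
        assert np.abs(out.positions()[0] - [40.0, 30.0, 30.0]).max() < 0.1
        assert out.table["s_nm"].iloc[0] == pytest.approx(40.0, abs=0.1)

    def test_equidistant_peak_assigned_to_lower_mt_id(self):
        tr0 = straight_trace(length=200.0, mt_id=0, origin=(0, 0, 0))
        tr1 = straight_trace(length=200.0, mt_id=1, origin=(0, 10, 0))
        doms = [build_domain(t, 8.5) for t in (tr0, tr1)]
        g = np.zeros((10, 16, 10), dtype=np.float32)
        vol = DensityVolume(g, 1.0, origin=np.array([95.0, -5.0, -5.0]))
        from mtlumen.detect import Peak
        pk = Peak(index=(5, 10, 5), position=np.array([100.5, 5.0, 0.0]),
                  height=1.0, persistence=1.0)
        out, _ = refine_and_assign([pk], vol, doms)
        assert out.table["mt_id"].iloc[0] == 0

    def test_peak_outside_all_domains_dropped_and_counted(self):
        tr = straight_trace(length=200.0)
        dom = build_domain(tr, 8.5)
        g = np.zeros((10, 10, 10), dtype=np.float32)
        vol = DensityVolume(g, 1.0, origin=np.array([0.0, 50.0, 50.0]))
        from mtlumen.detect import Peak
        pk = Peak(index=(5, 5, 5), position=np.array([5.5, 55.5, 55.5]),
                  height=1.0, persistence=1.0)
        out, rep = refine_and_assign([pk], vol, [dom])
        assert len(out) == 0 and rep["n_dropped_outside"] == 1
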