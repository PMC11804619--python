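"""Low-pass filtering and pairwise cross-correlation of small density maps.

Mirrors the similarity analysis of ring-shaped lumenal-particle averages:
maps are filtered to a common resolution (default comparison resolution
25 Å), compared by Pearson cross-correlation over voxels, and grouped by
average-linkage hierarchical clustering of 1 - CC, cut at the CC > 0.8
similarity criterion.  Maps are assumed pre-aligned on identical grids;
rigid-body alignment and fitting are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .volume import DensityVolume

__all__ = ["CCMatrix", "lowpass_to_resolution", "cross_correlation", "cc_cluster",
           "DEFAULT_COMPARISON_RESOLUTION_A", "DEFAULT_CC_THRESHOLD"]

DEFAULT_COMPARISON_RESOLUTION_A = 25.0
DEFAULT_CC_THRESHOLD = 0.8


@dataclass(frozen=True)
class CCMatrix:
    labels: tuple
    values: np.ndarray  # symmetric, unit diagonal, entries in [-1, 1]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("CC matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("CC matrix diagonal must be 1")
        if np.any(v < -1 - 1e-8) or np.any(v > 1 + 1e-8):
            raise ValueError("CC values must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_maps(cls, maps: dict) -> "CCMatrix":
        labels = tuple(maps.keys())
        n = len(labels)
        v = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                v[i, j] = v[j, i] = cross_correlation(maps[labels[i]], maps[labels[j]])
        return cls(labels=labels, values=v)


def lowpass_to_resolution(vol: DensityVolume, resolution_angstrom: float) -> DensityVolume:
    """Fourier-space Gaussian low-pass falling to 0.5 amplitude at 1/resolution.

    ``resolution_angstrom`` is in Å (voxel sizes are nm); it must be at least
    twice the voxel size (Nyquist).
    """
    res_nm = resolution_angstrom / 10.0
    if res_nm < 2 * vol.voxel_size:
        raise ValueError("resolution beyond Nyquist for this voxel size")
    freqs = [np.fft.fftfreq(n, d=vol.voxel_size) for n in vol.grid.shape]
    f2 = (freqs[0][:, None, None] ** 2 + freqs[1][None, :, None] ** 2
          + freqs[2][None, None, :] ** 2)
    # H(f) = exp(-f^2 / (2 sf^2)) with H(1/res) = 0.5
    sf2 = (1.0 / res_nm) ** 2 / (2.0 * np.log(2.0))
    H = np.exp(-f2 / (2.0 * sf2))
    out = np.fft.ifftn(np.fft.fftn(vol.grid.astype(np.float64)) * H).real
    return DensityVolume(out.astype(np.float32), vol.voxel_size, vol.origin.copy())


def cross_correlation(a: DensityVolume, b: DensityVolume) -> float:
    """Pearson correlation over voxels of two maps on identical grids."""
    if a.grid.shape != b.grid.shape:
        raise ValueError("maps must share a grid")
    if abs(a.voxel_size - b.voxel_size) > 1e-9:
        raise ValueError("maps must share a voxel size")
    x = a.grid.astype(np.float64).ravel()
    y = b.grid.astype(np.float64).ravel()
    x = x - x.mean()
    y = y - y.mean()
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance map")
    return float(np.clip(x @ y / (nx * ny), -1.0, 1.0))


def cc_cluster(matrix: CCMatrix, threshold: float = DEFAULT_CC_THRESHOLD) -> list[list]:
    """Group maps by average-linkage clustering of 1 - CC, cut at 1 - threshold."""
    n = len(matrix.labels)
    if n == 1:
        return [[matrix.labels[0]]]
    dist = np.clip(1.0 - matrix.values, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    assign = fcluster(Z, t=1.0 - threshold, criterion="distance")
    groups: dict[int, list] = {}
    for lab, g in zip(matrix.labels, assign):
        groups.setdefault(int(g), []).append(lab)
    return [groups[g] for g in sorted(groups)]
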