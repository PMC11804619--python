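"""Synthetic cryo-ET stand-ins: curved filaments, lumenal point patterns, and
rendered density volumes with ground truth.

The generator emulates the statistical structure of MT lumenal-particle data:

* MT centerlines are discrete worm-like chains (WLC) whose ensemble tangent
  correlation obeys ``<t(u) . t(u+s)> = exp(-s / persistence_length)`` (3D
  convention), with persistence lengths in the 20-45 µm range typical of
  cellular MTs.
* Lumenal particles (6-8 nm globular densities, 200-400 kDa) are placed
  inside the ~17 nm diameter lumen by one of four processes: complete spatial
  randomness (csr), hardcore (random sequential adsorption), quasi-periodic
  axial packing with an 8-10 nm spacing mode, or CSR plus anchored clusters
  at lattice breaks / open ends.
* Volumes are rendered at a physical voxel size with soft-edged hollow
  cylindrical MT walls, Gaussian particle blobs whose integrated intensity is
  proportional to mass, ribosome-sized reference densities outside the MTs,
  and additive Gaussian noise.

Every stochastic operation takes an explicit seed; derived generators use
fixed increments so pipelines are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .filaments import FilamentTrace, LumenDomain
from .particles import ParticleSet
from .volume import DensityVolume

__all__ = [
    "ProcessSpec", "RenderSpec", "PackingError", "GeometryError",
    "simulate_filament", "simulate_ensemble", "place_particles",
    "render_volume", "draw_masses",
]


class PackingError(RuntimeError):
    """Requested intensity exceeds hardcore capacity; carries achieved count."""

    def __init__(self, achieved: int, target: int):
        self.achieved = achieved
        self.target = target
        super().__init__(
            f"hardcore packing failed: placed {achieved} of {target} particles "
            f"within the retry budget")


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Worm-like chains
# ---------------------------------------------------------------------------

def _kappa_from_mean_cos(m: float) -> float:
    """Solve coth(k) - 1/k = m for the vMF concentration k (m in (0, 1))."""
    if m <= 0 or m >= 1:
        raise ValueError("mean cosine must be in (0, 1)")
    # standard starting approximation, then Newton
    k = m * (3.0 - m * m) / (1.0 - m * m)
    for _ in range(50):
        if k > 500.0:  # coth(k) == 1 to double precision
            k_new = 1.0 / (1.0 - m)
            return k_new
        f = 1.0 / np.tanh(k) - 1.0 / k - m
        fp = 1.0 / k**2 - 1.0 / np.sinh(k) ** 2
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2
        if abs(k_new - k) < 1e-12 * k:
            return k_new
        k = k_new
    return k


def _sample_step_cos(kappa: float, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF sample of cos(theta) from p(c) ~ exp(kappa * c) on [-1, 1]."""
    if kappa > 700.0:
        return 1.0 + np.log(np.maximum(u, 1e-300)) / kappa
    return 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa


def simulate_ensemble(n_chains: int, n_points: int, step: float,
                      persistence_length: float, seed: int,
                      start: Sequence[float] = (0.0, 0.0, 0.0),
                      direction: Sequence[float] | None = None,
                      mt_id_offset: int = 0) -> list[FilamentTrace]:
    """Simulate ``n_chains`` discrete worm-like chains with equal step lengths.

    Per-step tangent deflections are drawn from the WLC equilibrium
    distribution ``p(cos t) ~ exp(kappa cos t)`` with ``kappa`` chosen so that
    ``E[cos t] = exp(-step / persistence_length)``; successive deflections are
    independent, hence the ensemble tangent correlation at arclength lag
    ``s = k * step`` is exactly ``exp(-s / persistence_length)``.

    ``direction=None`` gives each chain an independent uniformly random
    initial tangent.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if step <= 0 or persistence_length <= 0:
        raise ValueError("step and persistence_length must be positive")
    rng = np.random.default_rng(seed)
    delta = step / persistence_length
    kappa = _kappa_from_mean_cos(float(np.exp(-delta)))

    if direction is None:
        v = rng.normal(size=(n_chains, 3))
        t = v / np.linalg.norm(v, axis=1, keepdims=True)
    else:
        d = np.asarray(direction, dtype=float)
        t = np.tile(d / np.linalg.norm(d), (n_chains, 1))

    pts = np.empty((n_chains, n_points, 3))
    pts[:, 0] = np.asarray(start, dtype=float)
    for i in range(1, n_points):
        pts[:, i] = pts[:, i - 1] + step * t
        if i < n_points - 1:
            c = _sample_step_cos(kappa, rng.random(n_chains))
            phi = rng.uniform(0, 2 * np.pi, n_chains)
            # orthonormal frame per chain
            helper = np.where(np.abs(t[:, [0]]) < 0.9,
                              np.tile([1.0, 0.0, 0.0], (n_chains, 1)),
                              np.tile([0.0, 1.0, 0.0], (n_chains, 1)))
            e1 = np.cross(t, helper)
            e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
            e2 = np.cross(t, e1)
            s = np.sqrt(np.maximum(0.0, 1.0 - c**2))
            t = (c[:, None] * t
                 + (s * np.cos(phi))[:, None] * e1
                 + (s * np.sin(phi))[:, None] * e2)
            t /= np.linalg.norm(t, axis=1, keepdims=True)
    return [FilamentTrace(mt_id=mt_id_offset + j, points=pts[j],
                          resampled=True, spacing=float(step))
            for j in range(n_chains)]


def simulate_filament(n_points: int, step: float, persistence_length: float,
                      seed: int, start=(0.0, 0.0, 0.0), direction=None,
                      mt_id: int = 0) -> FilamentTrace:
    """Single discrete worm-like chain; see :func:`simulate_ensemble`."""
    return simulate_ensemble(1, n_points, step, persistence_length, seed,
                             start=start, direction=direction,
                             mt_id_offset=mt_id)[0]


# ---------------------------------------------------------------------------
# Point processes in the lumen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProcessSpec:
    """Generative model for lumenal particle placement.

    ``intensity`` is in particles per nm^3 of lumen volume (csr / hardcore /
    anchored_cluster background).  ``spacing_mean``/``spacing_sd`` are the
    axial gap distribution of the quasi-periodic walk; gaps are drawn from a
    Normal truncated symmetrically to ``[hardcore, 2*mean - hardcore]``, which
    enforces the minimum separation while preserving the nominal mean.  The
    optional end-zone fields let the gap distribution differ within
    ``end_zone`` nm of an open MT end (tighter packing near freshly
    polymerized plus ends).
    """

    kind: str = "csr"  # csr | hardcore | quasi_periodic | anchored_cluster
    intensity: float = 0.0          # nm^-3
    hardcore_distance: float = 0.0  # nm, min centre-to-centre separation
    spacing_mean: float = 9.0       # nm
    spacing_sd: float = 1.5         # nm
    radial_jitter: float = 2.0      # nm, max radial offset of quasi-periodic walk
    anchor_positions: tuple = ()    # arclengths nm (defaults to domain anchors)
    cluster_domain: float = 300.0   # nm, axial extent around each anchor
    cluster_multiplier: float = 4.0 # intensity boost inside the cluster window
    end_zone: float | None = None   # nm from the open end
    end_spacing_mean: float | None = None
    end_spacing_sd: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in {"csr", "hardcore", "quasi_periodic", "anchored_cluster"}:
            raise ValueError(f"unknown process kind {self.kind!r}")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.hardcore_distance < 0:
            raise ValueError("hardcore_distance must be >= 0")
        if self.kind == "quasi_periodic" and self.spacing_mean <= self.hardcore_distance:
            raise ValueError("spacing_mean must exceed hardcore_distance")
        if self.kind == "anchored_cluster" and self.cluster_domain <= 0:
            raise ValueError("cluster_domain must be positive for anchored_cluster")


def _normal_frame(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(tangent[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(tangent, helper)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(tangent, e1)


def _tube_points(domain: LumenDomain, s: np.ndarray, r: np.ndarray,
                 phi: np.ndarray) -> np.ndarray:
    """Map tube coordinates (arclength, radial offset, azimuth) to 3D nm."""
    cl = domain.centerline
    s = np.atleast_1d(np.asarray(s, dtype=float))
    r = np.atleast_1d(np.asarray(r, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    pts = np.atleast_2d(cl.point_at(s))
    eps = min(1.0, domain.length / 10)
    lo = np.maximum(0.0, s - eps)
    hi = np.minimum(domain.length, s + eps)
    tang = np.atleast_2d(cl.point_at(hi)) - np.atleast_2d(cl.point_at(lo))
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    helper = np.where(np.abs(tang[:, [0]]) < 0.9,
                      np.array([[1.0, 0.0, 0.0]]), np.array([[0.0, 1.0, 0.0]]))
    e1 = np.cross(tang, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(tang, e1)
    return pts + r[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)


def _sample_csr_tube(domain: LumenDomain, n: int, rng,
                     s_range: tuple[float, float] | None = None,
                     r_max: float | None = None):
    """Uniform points in the tube (optionally an axial sub-window)."""
    lo, hi = s_range if s_range is not None else (0.0, domain.length)
    r_max = domain.lumen_radius if r_max is None else r_max
    s = rng.uniform(lo, hi, n)
    r = r_max * np.sqrt(rng.random(n)) * (1 - 1e-9)
    phi = rng.uniform(0, 2 * np.pi, n)
    if n == 0:
        return np.empty((0, 3)), s
    return _tube_points(domain, s, r, phi), s


def _truncated_gap(rng, mean: float, sd: float, hardcore: float) -> float:
    """Normal gap truncated symmetrically to [hardcore, 2*mean - hardcore]."""
    hi = 2 * mean - hardcore
    if sd <= 0:
        return mean
    for _ in range(1000):
        g = rng.normal(mean, sd)
        if hardcore <= g <= hi:
            return g
    return mean


def place_particles(domain: LumenDomain, spec: ProcessSpec) -> ParticleSet:
    """Place particle centres strictly inside the lumen tube.

    csr: homogeneous Poisson in the tube.  hardcore: random sequential
    placement rejecting centres closer than ``hardcore_distance`` (retries
    capped at 100x the target count, then :class:`PackingError`).
    quasi_periodic: a walk along the centerline with truncated-Normal axial
    gaps and small radial jitter.  anchored_cluster: CSR background plus
    ``intensity * (cluster_multiplier - 1)`` extra CSR intensity within
    ``+-cluster_domain/2`` of each anchor.
    """
    rng = np.random.default_rng(spec.seed)
    L = domain.length
    r_jit = min(spec.radial_jitter, domain.lumen_radius)

    if spec.kind == "csr":
        n = rng.poisson(spec.intensity * domain.tube_volume())
        pos, s = _sample_csr_tube(domain, n, rng)
        return ParticleSet.from_arrays(pos, mt_id=domain.mt_id, s_nm=s)

    if spec.kind == "hardcore":
        target = int(rng.poisson(spec.intensity * domain.tube_volume()))
        placed: list[np.ndarray] = []
        placed_s: list[float] = []
        attempts = 0
        max_attempts = 100 * max(target, 1)
        while len(placed) < target and attempts < max_attempts:
            attempts += 1
            p, s = _sample_csr_tube(domain, 1, rng)
            p, s = p[0], s[0]
            if placed:
                d2 = np.sum((np.asarray(placed) - p) ** 2, axis=1)
                if d2.min() < spec.hardcore_distance**2:
                    continue
            placed.append(p)
            placed_s.append(float(s))
        if len(placed) < target:
            raise PackingError(achieved=len(placed), target=target)
        pos = np.asarray(placed).reshape(-1, 3)
        return ParticleSet.from_arrays(pos, mt_id=domain.mt_id, s_nm=np.asarray(placed_s))

    if spec.kind == "quasi_periodic":
        open_at_end = "end" in domain.open_ends and "start" not in domain.open_ends

        def gap_params(s_here: float) -> tuple[float, float]:
            if spec.end_zone is not None and spec.end_spacing_mean is not None:
                dist_from_end = (L - s_here) if open_at_end else s_here
                if dist_from_end < spec.end_zone:
                    return spec.end_spacing_mean, spec.end_spacing_sd or 0.0
            return spec.spacing_mean, spec.spacing_sd

        m0, s0 = gap_params(0.0)
        ss = []
        s = rng.uniform(0, m0)
        while s < L:
            ss.append(s)
            m, sd = gap_params(s)
            s += _truncated_gap(rng, m, sd, spec.hardcore_distance)
        ss = np.asarray(ss)
        if open_at_end:
            ss = np.sort(L - ss)
        n = ss.size
        r = r_jit * np.sqrt(rng.random(n)) * (1 - 1e-9)
        phi = rng.uniform(0, 2 * np.pi, n)
        pos = _tube_points(domain, ss, r, phi) if n else np.empty((0, 3))
        return ParticleSet.from_arrays(pos, mt_id=domain.mt_id, s_nm=ss)

    # anchored_cluster
    anchors = spec.anchor_positions or domain.break_anchors \
        or tuple(0.0 if e == "start" else L for e in sorted(domain.open_ends))
    if not anchors:
        raise ValueError("anchored_cluster requires anchors (spec or domain)")
    n_bg = rng.poisson(spec.intensity * domain.tube_volume())
    pos_bg, s_bg = _sample_csr_tube(domain, n_bg, rng)
    parts = [(pos_bg, s_bg)]
    area = np.pi * domain.lumen_radius**2
    extra_rate = spec.intensity * (spec.cluster_multiplier - 1.0)
    for a in anchors:
        lo = max(0.0, a - spec.cluster_domain / 2)
        hi = min(L, a + spec.cluster_domain / 2)
        n_ex = rng.poisson(extra_rate * area * (hi - lo))
        pos_ex, s_ex = _sample_csr_tube(domain, n_ex, rng, s_range=(lo, hi))
        parts.append((pos_ex, s_ex))
    pos = np.vstack([p for p, _ in parts])
    s = np.concatenate([s for _, s in parts])
    order = np.argsort(s)
    return ParticleSet.from_arrays(pos[order], mt_id=domain.mt_id, s_nm=s[order])


def draw_masses(n: int, seed: int, low: float = 200.0, high: float = 400.0) -> np.ndarray:
    """Particle masses (kDa) uniform in the observed lumenal-particle range."""
    return np.random.default_rng(seed).uniform(low, high, n)


# ---------------------------------------------------------------------------
# Volume rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderSpec:
    """Rendering geometry and contrast.

    Wall radii default to the MT geometry (lumen radius ~8.5 nm, outer wall
    ~12.5 nm).  A particle of ``reference_mass`` is a 3D Gaussian of standard
    deviation ``particle_sigma_ref`` and peak amplitude ``peak_amplitude_ref``;
    other masses scale the width as ``(mass / reference_mass)^(1/3)``, so the
    integrated intensity is proportional to mass and the peak amplitude is
    mass-independent.  Density is rendered bright-on-dark (mass = positive
    intensity above ``background_level``).
    """

    voxel_size: float = 1.0           # nm
    wall_inner_radius: float = 8.5    # nm
    wall_outer_radius: float = 12.5   # nm
    wall_level: float = 1.0           # intensity of the MT wall shell
    wall_edge_sigma: float = 0.75     # nm, softness of the shell edges
    particle_sigma_ref: float = 2.5   # nm at reference mass
    reference_mass: float = 300.0     # kDa
    peak_amplitude_ref: float = 1.0   # intensity units
    noise_sd: float = 0.0             # intensity units
    background_level: float = 0.0     # intensity units
    ribosome_mass: float = 3200.0     # kDa
    ribosome_count: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not (self.wall_outer_radius > self.wall_inner_radius > 0):
            raise ValueError("need wall_outer_radius > wall_inner_radius > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def sigma_for_mass(self, mass: float) -> float:
        return self.particle_sigma_ref * (mass / self.reference_mass) ** (1.0 / 3.0)

    def integrated_intensity(self, mass: float) -> float:
        s = self.sigma_for_mass(mass)
        return self.peak_amplitude_ref * (2 * np.pi) ** 1.5 * s**3


def _splat_gaussian(grid: np.ndarray, vol: DensityVolume, center: np.ndarray,
                    sigma: float, amplitude: float) -> None:
    vs = vol.voxel_size
    idx = vol.position_to_index(center)
    half = int(np.ceil(4 * sigma / vs))
    lo = np.maximum(np.floor(idx).astype(int) - half, 0)
    hi = np.minimum(np.floor(idx).astype(int) + half + 1, grid.shape)
    if np.any(lo >= hi):
        return
    axes = [vol.axis_coords(a)[lo[a]:hi[a]] - center[a] for a in range(3)]
    g = np.exp(-(axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2 +
                 axes[2][None, None, :] ** 2) / (2 * sigma**2))
    grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (amplitude * g).astype(np.float32)


def _soft_shell(rho: np.ndarray, spec: RenderSpec) -> np.ndarray:
    from scipy.special import erf
    s = spec.wall_edge_sigma * np.sqrt(2.0)
    return 0.5 * spec.wall_level * (erf((rho - spec.wall_inner_radius) / s)
                                    - erf((rho - spec.wall_outer_radius) / s))


def _centerline_distance_field(vol: DensityVolume,
                               filaments: Sequence[FilamentTrace]) -> np.ndarray:
    """Distance (nm) from each voxel centre to the nearest MT centerline.

    The centerlines are rasterized at sub-voxel sampling and the distance
    field is obtained by a Euclidean distance transform; the rasterization
    error is below half a voxel diagonal, well under the wall edge softness.
    """
    occ = np.ones(vol.grid.shape, dtype=bool)
    vs = vol.voxel_size
    for tr in filaments:
        fine = max(2 * int(np.ceil(tr.length / (0.5 * vs))), 2)
        s = np.linspace(0, tr.length, fine)
        pts = np.atleast_2d(tr.point_at(s))
        ijk = np.clip(np.round(vol.position_to_index(pts)).astype(int), 0,
                      np.asarray(vol.grid.shape) - 1)
        occ[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = False
    return ndimage.distance_transform_edt(occ, sampling=vs).astype(np.float32)


def render_volume(filaments: Sequence[FilamentTrace], particles: ParticleSet,
                  masses: np.ndarray | float, spec: RenderSpec,
                  origin: np.ndarray | None = None,
                  shape: tuple | None = None) -> tuple[DensityVolume, pd.DataFrame]:
    """Render filaments + particles into a density volume with ground truth.

    If ``origin``/``shape`` are omitted the box is fitted around the content
    with padding.  Returns the volume and a ground-truth table listing every
    rendered object (lumenal particles and ribosomes) with position and mass.
    Raises :class:`GeometryError` when an explicit box does not contain the
    content.
    """
    rng = np.random.default_rng(spec.seed)
    masses = np.broadcast_to(np.atleast_1d(np.asarray(masses, dtype=float)),
                             (len(particles),)).copy() if len(particles) else np.empty(0)
    sig_ribo = spec.sigma_for_mass(spec.ribosome_mass)

    pts_list = [tr.points for tr in filaments]
    if len(particles):
        pts_list.append(particles.positions())
    pad = spec.wall_outer_radius + 4 * max(spec.particle_sigma_ref, spec.wall_edge_sigma) + 2.0
    if spec.ribosome_count > 0:
        pad = max(pad, spec.wall_outer_radius + 8 * sig_ribo)
    if origin is None or shape is None:
        if not pts_list:
            lo = np.zeros(3)
            hi = np.full(3, 10 * spec.voxel_size)
        else:
            allpts = np.vstack(pts_list)
            lo = allpts.min(axis=0) - pad
            hi = allpts.max(axis=0) + pad
        origin = lo
        shape = tuple(int(np.ceil((hi[a] - lo[a]) / spec.voxel_size)) for a in range(3))
    else:
        origin = np.asarray(origin, dtype=float)
        shape = tuple(int(n) for n in shape)
        if pts_list:
            allpts = np.vstack(pts_list)
            upper = origin + np.asarray(shape) * spec.voxel_size
            margin = 4 * spec.particle_sigma_ref
            if np.any(allpts - margin < origin) or np.any(allpts + margin > upper):
                raise GeometryError("content does not fit in the requested box")

    grid = np.full(shape, spec.background_level, dtype=np.float32)
    vol = DensityVolume(grid, spec.voxel_size, origin)
    grid = vol.grid

    dist_field = None
    if filaments:
        dist_field = _centerline_distance_field(vol, filaments)
        sel = dist_field <= spec.wall_outer_radius + 4 * spec.wall_edge_sigma
        grid[sel] += _soft_shell(dist_field[sel], spec).astype(np.float32)

    truth_rows = []
    pos = particles.positions() if len(particles) else np.empty((0, 3))
    for i in range(pos.shape[0]):
        sigma = spec.sigma_for_mass(masses[i])
        _splat_gaussian(grid, vol, pos[i], sigma, spec.peak_amplitude_ref)
        row = particles.table.iloc[i]
        truth_rows.append({"kind": "lumenal", "mt_id": row["mt_id"],
                           "x_nm": pos[i, 0], "y_nm": pos[i, 1], "z_nm": pos[i, 2],
                           "s_nm": row["s_nm"], "mass_kda": masses[i]})

    if spec.ribosome_count > 0:
        min_clear = spec.wall_outer_radius + 2 * sig_ribo
        if dist_field is not None:
            cand = np.argwhere(dist_field > min_clear)
        else:
            cand = np.argwhere(np.ones(shape, dtype=bool))
        # keep the full integration shell (1.5 x 3 sigma) clear of the box edge
        edge = int(np.ceil(5 * sig_ribo / spec.voxel_size))
        ok = np.all((cand >= edge) & (cand < np.asarray(shape) - edge), axis=1)
        cand = cand[ok]
        if cand.shape[0] < spec.ribosome_count:
            raise GeometryError("box too small to place the requested ribosomes")
        # greedy selection with mutual clearance so references do not overlap
        perm = rng.permutation(cand.shape[0])
        chosen: list[np.ndarray] = []
        min_sep_vox = 6 * sig_ribo / spec.voxel_size
        for ci in perm:
            c = cand[ci]
            if chosen and np.min(np.linalg.norm(np.asarray(chosen) - c, axis=1)) < min_sep_vox:
                continue
            chosen.append(c)
            if len(chosen) == spec.ribosome_count:
                break
        if len(chosen) < spec.ribosome_count:
            raise GeometryError("box too small to place the requested ribosomes")
        pick = np.asarray(chosen)
        rpos = vol.index_to_position(pick) + rng.uniform(-0.5, 0.5, (spec.ribosome_count, 3)) * spec.voxel_size
        for i in range(spec.ribosome_count):
            _splat_gaussian(grid, vol, rpos[i], sig_ribo, spec.peak_amplitude_ref)
            truth_rows.append({"kind": "ribosome", "mt_id": -1,
                               "x_nm": rpos[i, 0], "y_nm": rpos[i, 1],
                               "z_nm": rpos[i, 2], "s_nm": np.nan,
                               "mass_kda": spec.ribosome_mass})

    if spec.noise_sd > 0:
        grid += rng.normal(0.0, spec.noise_sd, grid.shape).astype(np.float32)

    truth = pd.DataFrame(truth_rows, columns=["kind", "mt_id", "x_nm", "y_nm",
                                              "z_nm", "s_nm", "mass_kda"])
    return vol, truth
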