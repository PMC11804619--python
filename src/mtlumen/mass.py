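"""Approximate molecular masses from integrated density, calibrated against
ribosomes as an internal standard.

Cryo-ET intensities have no absolute scale, but the background-subtracted
integrated density of a particle is proportional to its molecular mass
within one tomogram.  Ribosomes (~3.2 MDa, configurable) present in the same
volume provide the proportionality constant, which is then applied to the
lumenal particles.  Mass estimates are invariant under global additive
offsets (background subtraction) and equivariant under multiplicative
intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import DensityVolume

__all__ = ["MassCalibration", "integrate_density", "calibrate", "estimate_mass",
           "RIBOSOME_MASS_KDA", "DEFAULT_PARTICLE_RADIUS_NM"]

#: Nominal mammalian 80S ribosome mass used as the internal reference (kDa).
#: A named configuration constant, not a measurement.
RIBOSOME_MASS_KDA = 3200.0

#: Default integration radius for 6-8 nm lumenal particles.
DEFAULT_PARTICLE_RADIUS_NM = 5.0

SHELL_OUTER_FACTOR = 1.5


@dataclass(frozen=True)
class MassCalibration:
    reference_intensities: np.ndarray
    reference_mass: float   # kDa
    scale: float            # kDa per intensity unit
    scale_se: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("calibration scale must be positive")
        if len(self.reference_intensities) < 3:
            raise ValueError("a valid calibration needs >= 3 references")


def integrate_density(vol: DensityVolume, center, radius: float,
                      background: str = "shell") -> float:
    """Background-subtracted integrated intensity in a sphere.

    Sums ``voxel - background`` over voxels whose centres lie within
    ``radius`` of ``center``.  ``background='shell'`` uses the median
    intensity in the spherical shell [radius, 1.5 * radius] (robust to
    crowding gradients); ``'global'`` uses the median of the whole volume.
    Raises if the integration sphere (including the shell) is clipped by the
    volume edge.
    """
    center = np.asarray(center, dtype=float)
    outer = radius * (SHELL_OUTER_FACTOR if background == "shell" else 1.0)
    lo_w = center - outer
    hi_w = center + outer
    upper = vol.origin + np.asarray(vol.grid.shape) * vol.voxel_size
    if np.any(lo_w < vol.origin - 1e-9) or np.any(hi_w > upper + 1e-9):
        raise ValueError("integration sphere clipped by the volume edge")
    lo = np.maximum(np.floor(vol.position_to_index(lo_w)).astype(int), 0)
    hi = np.minimum(np.ceil(vol.position_to_index(hi_w)).astype(int) + 1,
                    vol.grid.shape)
    sub = vol.grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(np.float64)
    axes = [vol.axis_coords(a)[lo[a]:hi[a]] - center[a] for a in range(3)]
    r2 = (axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2
          + axes[2][None, None, :] ** 2)
    inside = r2 <= radius**2
    if background == "shell":
        shell = (r2 > radius**2) & (r2 <= outer**2)
        bg = float(np.median(sub[shell]))
    elif background == "global":
        bg = float(np.median(vol.grid))
    else:
        raise ValueError(f"unknown background mode {background!r}")
    return float(np.sum(sub[inside] - bg))


def calibrate(reference_intensities, reference_mass: float = RIBOSOME_MASS_KDA
              ) -> MassCalibration:
    """Internal-standard calibration: kDa per intensity unit.

    ``scale = reference_mass / mean(reference_intensities)``; the standard
    error propagates the SD of the reference intensities through the mean.
    """
    ri = np.asarray(reference_intensities, dtype=float)
    if ri.size < 3:
        raise ValueError("need >= 3 reference intensities")
    mean = ri.mean()
    if mean <= 0:
        raise ValueError("non-positive mean reference intensity")
    scale = reference_mass / mean
    se_mean = ri.std(ddof=1) / np.sqrt(ri.size)
    return MassCalibration(reference_intensities=ri, reference_mass=reference_mass,
                           scale=float(scale),
                           scale_se=float(reference_mass * se_mean / mean**2))


def estimate_mass(particle_intensity: float, calib: MassCalibration
                  ) -> tuple[float, float, bool]:
    """Mass (kDa), propagated SE, and a flag for clipped negative intensities."""
    if particle_intensity < 0:
        return 0.0, 0.0, True
    mass = calib.scale * particle_intensity
    return float(mass), float(calib.scale_se * particle_intensity), False
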