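"""Isotropic Gaussian smoothing of density maps, parameterized by FWHM in mm.

Smoothing is specified the way the neuroimaging literature does — by the
full-width-at-half-maximum of the kernel in world units — and converted to a
per-axis sigma in voxels, so anisotropic voxel sizes are handled correctly.
The kernel has unit mass (a constant field is unchanged) and the boundary is
handled by nearest-value extension to avoid darkening at the brain edge.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datamodel import GMDensityMap, NormativeDatabase, VoxelGrid

__all__ = ["FWHM_TO_SIGMA", "fwhm_to_sigma_voxels", "smooth_array", "smooth_map", "smooth_ndb"]

#: FWHM = 2 * sqrt(2 * ln 2) * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: kernel truncation in units of sigma
TRUNCATE_SIGMAS = 4.0


def fwhm_to_sigma_voxels(fwhm_mm: float, grid: VoxelGrid) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    return fwhm_mm * FWHM_TO_SIGMA / grid.voxel_size_mm


def smooth_array(values: np.ndarray, fwhm_mm: float, grid: VoxelGrid) -> np.ndarray:
    if fwhm_mm < 0:
        raise ValueError(f"FWHM must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return np.asarray(values, dtype=float)
    sigma = fwhm_to_sigma_voxels(fwhm_mm, grid)
    return ndimage.gaussian_filter(
        np.asarray(values, dtype=float), sigma=sigma, mode="nearest", truncate=TRUNCATE_SIGMAS
    )


def smooth_map(map_: GMDensityMap, fwhm_mm: float = 8.0) -> GMDensityMap:
    """Smooth a GM density map with an isotropic Gaussian kernel.

    ``fwhm_mm = 0`` is the identity. Smoothing is applied to the full
    volume (before any masking).
    """
    return map_.with_values(smooth_array(map_.values, fwhm_mm, map_.grid))


def smooth_ndb(ndb: NormativeDatabase, fwhm_mm: float = 8.0) -> NormativeDatabase:
    """Return an NDB whose maps have all been smoothed once."""
    if fwhm_mm == 0:
        return ndb
    return ndb.with_maps([smooth_map(m, fwhm_mm) for m in ndb.maps])
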