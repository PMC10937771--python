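"""Core data model: voxel grids, gray-matter density maps, masks, metadata.

All volumes live on a shared :class:`VoxelGrid` (a common analysis grid,
nominally MNI space). Maps are modulated gray-matter density fields, i.e.
unitless nonnegative scalars whose spatial integral tracks tissue amount.
No resampling or reorientation is performed here: inputs are assumed to be
spatially normalized upstream, and grids must agree exactly (affines to a
small tolerance) or assembly fails loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "GMDensityMap",
    "GMMask",
    "SubjectMeta",
    "NormativeDatabase",
    "GridMismatchError",
]

#: entrywise tolerance (mm) when comparing affines of supposedly-shared grids
AFFINE_TOL_MM = 1e-4


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel grid with a voxel-to-world affine (mm).

    Parameters
    ----------
    shape
        Number of voxels along each axis, all >= 1.
    affine
        4x4 voxel-index -> world-coordinate (mm) transform. Voxel indices
        are 0-based; world space is nominally MNI.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(affine)):
            raise ValueError("affine must be finite")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @classmethod
    def isotropic(cls, shape: Sequence[int], voxel_size_mm: float = 1.5) -> "VoxelGrid":
        """Convenience constructor for an axis-aligned isotropic grid."""
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        # center the grid on the world origin, MNI-style
        affine[:3, 3] = -voxel_size_mm * (np.asarray(shape, dtype=float) - 1) / 2.0
        return cls(tuple(int(s) for s in shape), affine)

    def matches(self, other: "VoxelGrid", tol_mm: float = AFFINE_TOL_MM) -> bool:
        return self.shape == other.shape and bool(
            np.all(np.abs(self.affine - other.affine) <= tol_mm)
        )

    def require_match(self, other: "VoxelGrid", what: str = "volume") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"{what} grid mismatch: shape {other.shape} vs {self.shape} "
                f"or affine differs beyond {AFFINE_TOL_MM} mm"
            )


@dataclass(frozen=True)
class GMDensityMap:
    """One subject's modulated GM density field on a shared grid."""

    subject_id: str
    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"map shape {values.shape} does not match grid shape {self.grid.shape}"
            )
        n_bad = int(np.size(values) - np.isfinite(values).sum())
        if n_bad:
            raise ValueError(
                f"GM map '{self.subject_id}' contains {n_bad} non-finite voxel(s)"
            )
        if np.any(values < 0):
            raise ValueError(f"GM map '{self.subject_id}' contains negative densities")
        object.__setattr__(self, "values", values)

    def with_values(self, values: np.ndarray) -> "GMDensityMap":
        return replace(self, values=values)


@dataclass(frozen=True)
class GMMask:
    """Binary analysis mask on a grid (the standard GM mask in MNI space)."""

    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid shape")
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be strictly binary (0/1)")
        values = values.astype(bool)
        if not values.any():
            raise ValueError("mask is empty")
        object.__setattr__(self, "values", values)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject covariates: age and TIV are the GLM nuisance covariates."""

    subject_id: str
    age_years: float
    sex: str = "unknown"
    tiv_ml: float | None = None
    scanner_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 < float(self.age_years) < 120):
            raise ValueError(f"age {self.age_years} outside (0, 120) for {self.subject_id}")
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"sex must be male/female/unknown, got {self.sex!r}")
        if self.tiv_ml is not None and not (500 < float(self.tiv_ml) < 2500):
            raise ValueError(f"TIV {self.tiv_ml} ml outside (500, 2500) for {self.subject_id}")


@dataclass(frozen=True)
class NormativeDatabase:
    """Ordered collection of GM maps + metadata + shared mask/grid.

    Maps and metadata are kept sorted by subject id so assembly is
    insensitive to input file order. The stacked value array is exposed via
    :meth:`stack` for vectorized voxelwise statistics.
    """

    maps: tuple[GMDensityMap, ...]
    meta: tuple[SubjectMeta, ...]
    mask: GMMask
    grid: VoxelGrid = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        maps = tuple(self.maps)
        meta = tuple(self.meta)
        if len(maps) != len(meta):
            raise ValueError(f"{len(maps)} maps but {len(meta)} metadata rows")
        if len(maps) < 3:
            raise ValueError(
                f"an NDB needs >= 3 scans (leave-one-out needs >= 2 references), got {len(maps)}"
            )
        order = np.argsort([m.subject_id for m in maps], kind="stable")
        maps = tuple(maps[i] for i in order)
        meta_by_id = {m.subject_id: m for m in meta}
        if len(meta_by_id) != len(meta):
            raise ValueError("duplicate subject_id in metadata")
        ids = [m.subject_id for m in maps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id in maps")
        if set(ids) != set(meta_by_id):
            missing = set(ids) ^ set(meta_by_id)
            raise ValueError(f"maps and metadata ids do not correspond: {sorted(missing)}")
        meta = tuple(meta_by_id[i] for i in ids)
        grid = self.grid if self.grid is not None else maps[0].grid
        for m in maps:
            grid.require_match(m.grid, f"map '{m.subject_id}'")
        grid.require_match(self.mask.grid, "mask")
        object.__setattr__(self, "maps", maps)
        object.__setattr__(self, "meta", meta)
        object.__setattr__(self, "grid", grid)

    def __len__(self) -> int:
        return len(self.maps)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(m.subject_id for m in self.maps)

    def stack(self) -> np.ndarray:
        """(n_subjects, *grid.shape) array of map values."""
        return np.stack([m.values for m in self.maps])

    def subset(self, keep_ids: Iterable[str]) -> "NormativeDatabase":
        keep = set(keep_ids)
        maps = tuple(m for m in self.maps if m.subject_id in keep)
        meta = tuple(m for m in self.meta if m.subject_id in keep)
        return NormativeDatabase(maps, meta, self.mask, self.grid)

    def with_maps(self, maps: Sequence[GMDensityMap]) -> "NormativeDatabase":
        return NormativeDatabase(tuple(maps), self.meta, self.mask, self.grid)
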