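"""Shared fixtures: tiny grids, toy NDBs, and synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from vbmqc import (
    GMDensityMap,
    GMMask,
    NormativeDatabase,
    SubjectMeta,
    VoxelGrid,
)


@pytest.fixture
def grid() -> VoxelGrid:
    return VoxelGrid.isotropic((4, 4, 4), 1.5)


@pytest.fixture
def full_mask(grid) -> GMMask:
    return GMMask(np.ones(grid.shape, dtype=np.uint8), grid)


def make_constant_ndb(values, grid, mask, prefix="s") -> NormativeDatabase:
    """NDB whose maps are spatially constant, one value per subject."""
    maps = tuple(
        GMDensityMap(f"{prefix}{i:02d}", np.full(grid.shape, float(v)), grid)
        for i, v in enumerate(values)
    )
    meta = tuple(SubjectMeta(f"{prefix}{i:02d}", age_years=60.0) for i in range(len(values)))
    return NormativeDatabase(maps, meta, mask)


def make_random_ndb(
    rng: np.random.Generator,
    n: int,
    grid: VoxelGrid,
    mask: GMMask,
    loc: float = 0.5,
    scale: float = 0.05,
    ages=None,
    tivs=None,
) -> NormativeDatabase:
    """NDB of i.i.d. Gaussian maps (clipped at 0) with optional covariates."""
    maps, meta = [], []
    for i in range(n):
        vals = np.clip(rng.normal(loc, scale, grid.shape), 0, None)
        maps.append(GMDensityMap(f"r{i:02d}", vals, grid))
        meta.append(
            SubjectMeta(
                f"r{i:02d}",
                age_years=float(ages[i]) if ages is not None else 60.0,
                tiv_ml=float(tivs[i]) if tivs is not None else 1400.0,
            )
        )
    return NormativeDatabase(tuple(maps), tuple(meta), mask)


@pytest.fixture
def toy_ndb_123(grid, full_mask) -> NormativeDatabase:
    """Three spatially constant scans with values 1, 2, 3."""
    return make_constant_ndb([1.0, 2.0, 3.0], grid, full_mask)
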