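"""Synthetic GM density maps with the statistical structure VBM assumes.

The generator produces modulated-GM-like volumes on a small common grid:
an ellipsoid-shell "cortex" template (peak density ~0.8, hollow center
standing in for white matter/ventricles), smooth Gaussian between-subject
variability with a controlled correlation length, linear age-related GM
decline, multiplicative head-size (TIV) coupling, and optional smooth
multiplicative scanner fields. Outlier scans (global scaling, focal
lesions, lobar shifts, acquisition bias) and focal atrophy (spheres with a
fractional GM reduction) are injected on top, with ground truth retained —
so every pipeline stage can be exercised end to end without any download.

No claim of MR physics or anatomical realism is made; the point is the
variance structure, which is what the cleaning method operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .datamodel import GMDensityMap, GMMask, NormativeDatabase, SubjectMeta, VoxelGrid
from .smoothing import TRUNCATE_SIGMAS, fwhm_to_sigma_voxels

__all__ = [
    "SyntheticConfig",
    "OutlierSpec",
    "AtrophySpec",
    "LabeledSubject",
    "make_template",
    "sample_ndb",
    "sample_subject",
    "inject_outlier",
    "inject_atrophy",
    "generate_experiment",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic cohort generator (units in comments)."""

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 1.5
    n_ndb: int = 20
    template_peak: float = 0.8          # peak GM density of the shell template
    subject_sd: float = 0.05            # voxelwise between-subject SD (density units)
    field_smoothness_mm: float = 6.0    # FWHM of the subject random fields
    scanner_effect_amplitude: float = 0.03   # SD of the multiplicative scanner field
    scanner_field_smoothness_mm: float = 18.0
    n_scanners: int = 1
    age_slope: float = -0.002           # density change per year, relative to peak
    age_range: tuple[float, float] = (50.0, 80.0)
    tiv_mean_ml: float = 1370.0
    tiv_sd_ml: float = 150.0
    tiv_coupling: float = 0.3           # relative density change per relative TIV change
    mask_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ndb < 4:
            raise ValueError("n_ndb must be >= 4")
        if any(s < 8 for s in self.shape):
            raise ValueError("grid too small for a shell template")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid.isotropic(self.shape, self.voxel_size_mm)


@dataclass(frozen=True)
class OutlierSpec:
    """An injectable deviant scan.

    kinds: ``global_scale`` multiplies everything by (1 + amplitude);
    ``focal_lesion`` multiplies a sphere by (1 - amplitude);
    ``lobar_shift`` adds a smooth one-sided (hemispheric) field of the given
    amplitude; ``acquisition_bias`` multiplies by a low-order polynomial
    field of the given relative amplitude.
    """

    kind: str
    amplitude: float
    center_mm: tuple[float, float, float] | None = None
    radius_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.kind not in ("global_scale", "focal_lesion", "lobar_shift", "acquisition_bias"):
            raise ValueError(f"unknown outlier kind {self.kind!r}")
        if self.amplitude == 0:
            raise ValueError("an injected outlier needs amplitude != 0")


@dataclass(frozen=True)
class AtrophySpec:
    """A spherical focal GM reduction with known ground truth."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    amplitude: float                      # fractional reduction in (0, 1]
    label: str = "custom"

    def __post_init__(self) -> None:
        if not (0 < self.amplitude <= 1):
            raise ValueError("atrophy amplitude must be in (0, 1]")


@dataclass(frozen=True)
class LabeledSubject:
    map: GMDensityMap
    meta: SubjectMeta
    has_atrophy: bool
    truth_mask: np.ndarray | None = None
    atrophy_spec: AtrophySpec | None = None


# ---------------------------------------------------------------------------
# smooth random fields

def _field_norm(shape: tuple[int, ...], sigma_vox: np.ndarray) -> float:
    """sqrt(sum of squared kernel weights): the SD of filtered unit noise."""
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    response = ndimage.gaussian_filter(impulse, sigma=sigma_vox, truncate=TRUNCATE_SIGMAS)
    return float(np.sqrt((response**2).sum()))


def smooth_random_field(
    rng: np.random.Generator, grid: VoxelGrid, sd: float, smoothness_fwhm_mm: float
) -> np.ndarray:
    """Zero-mean Gaussian field with voxelwise SD ``sd`` and a given
    correlation length, built by filtering white noise and rescaling by the
    kernel's L2 norm (exact in the interior; edges are mildly inflated by
    the nearest-extension boundary)."""
    noise = rng.standard_normal(grid.shape)
    if smoothness_fwhm_mm == 0:
        return sd * noise
    sigma = fwhm_to_sigma_voxels(smoothness_fwhm_mm, grid)
    smoothed = ndimage.gaussian_filter(noise, sigma=sigma, mode="nearest", truncate=TRUNCATE_SIGMAS)
    return sd * smoothed / _field_norm(grid.shape, sigma)


def _world_coords(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.meshgrid(*[np.arange(s, dtype=float) for s in grid.shape], indexing="ij")
    A, b = grid.affine[:3, :3], grid.affine[:3, 3]
    coords = [A[i, 0] * idx[0] + A[i, 1] * idx[1] + A[i, 2] * idx[2] + b[i] for i in range(3)]
    return coords[0], coords[1], coords[2]


def _sphere_mask(grid: VoxelGrid, center_mm: Sequence[float], radius_mm: float) -> np.ndarray:
    x, y, z = _world_coords(grid)
    cx, cy, cz = center_mm
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius_mm**2


# ---------------------------------------------------------------------------
# template and cohorts

def make_template(config: SyntheticConfig) -> tuple[GMDensityMap, GMMask]:
    """Deterministic ellipsoid-shell GM template and its mask.

    Density peaks at ``template_peak`` on a shell at ~60% of the brain
    radius and decays as a Gaussian of the normalized radial distance; the
    mask keeps voxels above ``mask_threshold``.
    """
    grid = config.grid
    x, y, z = _world_coords(grid)
    semi_axes = 0.45 * np.asarray(config.shape) * config.voxel_size_mm
    rho = np.sqrt((x / semi_axes[0]) ** 2 + (y / semi_axes[1]) ** 2 + (z / semi_axes[2]) ** 2)
    values = config.template_peak * np.exp(-(((rho - 0.6) / 0.25) ** 2))
    values[rho > 1.2] = 0.0
    template = GMDensityMap("template", values, grid)
    mask = GMMask((values > config.mask_threshold).astype(np.uint8), grid)
    return template, mask


def _sample_meta(rng: np.random.Generator, config: SyntheticConfig, subject_id: str) -> SubjectMeta:
    age = float(rng.uniform(*config.age_range))
    tiv = float(np.clip(rng.normal(config.tiv_mean_ml, config.tiv_sd_ml), 600, 2400))
    sex = "male" if rng.random() < 0.5 else "female"
    scanner = f"scanner{int(rng.integers(config.n_scanners))}"
    return SubjectMeta(subject_id, age_years=age, sex=sex, tiv_ml=tiv, scanner_id=scanner)


def _scanner_fields(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """One reproducible multiplicative field per scanner id."""
    fields = {}
    for i in range(config.n_scanners):
        rng = np.random.default_rng([config.seed, 7001, i])
        if config.scanner_effect_amplitude == 0:
            fields[f"scanner{i}"] = np.ones(config.shape)
        else:
            f = smooth_random_field(
                rng, config.grid, config.scanner_effect_amplitude,
                config.scanner_field_smoothness_mm,
            )
            fields[f"scanner{i}"] = 1.0 + f
    return fields


def sample_subject(
    config: SyntheticConfig,
    subject_id: str,
    sub_seed: int,
    template: np.ndarray | None = None,
    scanner_fields: dict[str, np.ndarray] | None = None,
) -> LabeledSubject:
    """Draw one subject: template x age x TIV x scanner + smooth noise, clipped at 0."""
    grid = config.grid
    if template is None:
        template = make_template(config)[0].values
    if scanner_fields is None:
        scanner_fields = _scanner_fields(config)
    rng = np.random.default_rng([config.seed, sub_seed])
    meta = _sample_meta(rng, config, subject_id)
    age_mid = 0.5 * (config.age_range[0] + config.age_range[1])
    age_factor = 1.0 + config.age_slope * (meta.age_years - age_mid) / config.template_peak
    tiv_factor = 1.0 + config.tiv_coupling * (meta.tiv_ml - config.tiv_mean_ml) / config.tiv_mean_ml
    base = template * age_factor * tiv_factor * scanner_fields[meta.scanner_id]
    field = smooth_random_field(rng, grid, config.subject_sd, config.field_smoothness_mm)
    values = np.clip(base + field, 0.0, None)
    return LabeledSubject(GMDensityMap(subject_id, values, grid), meta, has_atrophy=False)


def sample_ndb(config: SyntheticConfig) -> NormativeDatabase:
    """Sample a normative database of ``config.n_ndb`` healthy scans."""
    template_map, mask = make_template(config)
    scanner_fields = _scanner_fields(config)
    subjects = [
        sample_subject(config, f"ndb{i:03d}", 1000 + i, template_map.values, scanner_fields)
        for i in range(config.n_ndb)
    ]
    return NormativeDatabase(
        tuple(s.map for s in subjects), tuple(s.meta for s in subjects), mask
    )


# ---------------------------------------------------------------------------
# injections

def inject_outlier(map_: GMDensityMap, spec: OutlierSpec) -> GMDensityMap:
    """Apply an outlier perturbation to a GM map; result clipped at 0."""
    grid = map_.grid
    values = map_.values
    if spec.kind == "global_scale":
        out = values * (1.0 + spec.amplitude)
    elif spec.kind == "focal_lesion":
        center = spec.center_mm if spec.center_mm is not None else (0.0, 0.0, 0.0)
        sphere = _sphere_mask(grid, center, spec.radius_mm)
        out = values.copy()
        out[sphere] *= 1.0 - spec.amplitude
    elif spec.kind == "lobar_shift":
        x = _world_coords(grid)[0]
        half_extent = 0.5 * grid.shape[0] * grid.voxel_size_mm[0]
        ramp = np.clip(x / half_extent, 0.0, 1.0)  # one hemisphere only
        out = values + spec.amplitude * ramp * (values > 0)
    else:  # acquisition_bias
        x, y, z = _world_coords(grid)
        ext = np.asarray(grid.shape) * grid.voxel_size_mm
        poly = (x / ext[0]) + (y / ext[1]) ** 2 - (z / ext[2])
        poly = poly / max(np.abs(poly).max(), 1e-12)
        out = values * (1.0 + spec.amplitude * poly)
    out = np.clip(out, 0.0, None)
    if not out.any():
        raise ValueError("outlier injection produced an all-zero map")
    return map_.with_values(out)


def inject_atrophy(map_: GMDensityMap, spec: AtrophySpec, mask: GMMask | None = None
                   ) -> tuple[GMDensityMap, np.ndarray]:
    """Reduce GM in a sphere by the fractional amplitude; returns truth mask."""
    sphere = _sphere_mask(map_.grid, spec.center_mm, spec.radius_mm)
    truth = sphere & mask.values if mask is not None else sphere
    if not truth.any():
        raise ValueError("atrophy region does not intersect the mask")
    values = map_.values.copy()
    values[sphere] *= 1.0 - spec.amplitude
    return map_.with_values(values), truth


def default_atrophy_spec(rng: np.random.Generator, mask: GMMask) -> AtrophySpec:
    """Random sphere centered on an in-mask voxel; ~0.6–4 ml at 15–35% loss."""
    grid = mask.grid
    idx = np.argwhere(mask.values)
    center_vox = idx[int(rng.integers(idx.shape[0]))]
    center_mm = tuple((grid.affine[:3, :3] @ center_vox + grid.affine[:3, 3]).tolist())
    return AtrophySpec(
        center_mm=center_mm,
        radius_mm=float(rng.uniform(6.0, 10.0)),
        amplitude=float(rng.uniform(0.15, 0.35)),
    )


def generate_experiment(
    config: SyntheticConfig,
    n_patients: int = 10,
    n_hc: int = 10,
    outlier_specs: Sequence[OutlierSpec] = (),
    atrophy_specs: Sequence[AtrophySpec] | None = None,
) -> tuple[NormativeDatabase, list[LabeledSubject], list[str]]:
    """Desk-scale cohort: an NDB with injected outliers + labeled test subjects.

    Outlier specs are applied to the first ``len(outlier_specs)`` NDB scans.
    Patients receive focal atrophy (from ``atrophy_specs`` cyclically, or
    random spheres when None); healthy controls receive none. Returns the
    NDB, the labeled test subjects, and the injected-outlier scan ids.
    """
    ndb = sample_ndb(config)
    mask = ndb.mask
    outlier_ids: list[str] = []
    if outlier_specs:
        if len(outlier_specs) > len(ndb):
            raise ValueError("more outlier specs than NDB scans")
        maps = list(ndb.maps)
        for i, spec in enumerate(outlier_specs):
            maps[i] = inject_outlier(maps[i], spec)
            outlier_ids.append(maps[i].subject_id)
        ndb = ndb.with_maps(maps)

    template = make_template(config)[0].values
    scanner_fields = _scanner_fields(config)
    subjects: list[LabeledSubject] = []
    for j in range(n_patients + n_hc):
        is_patient = j < n_patients
        sid = f"{'pat' if is_patient else 'hc'}{j:03d}"
        subj = sample_subject(config, sid, 5000 + j, template, scanner_fields)
        if is_patient:
            if atrophy_specs:
                spec = atrophy_specs[j % len(atrophy_specs)]
            else:
                spec_rng = np.random.default_rng([config.seed, 9000 + j])
                spec = default_atrophy_spec(spec_rng, mask)
            atro_map, truth = inject_atrophy(subj.map, spec, mask)
            subj = replace(subj, map=atro_map, has_atrophy=True,
                           truth_mask=truth, atrophy_spec=spec)
        subjects.append(subj)
    return ndb, subjects, outlier_ids
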