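"""Single-subject voxel-based morphometry against a normative database.

The test is a voxelwise two-sample GLM with a single-subject "group": the
design stacks the test subject on top of the n NDB scans with columns
[group indicator (1 = test subject), intercept, mean-centered age,
mean-centered TIV], and the t statistic on the group coefficient is the
single-subject t-map. With one subject in the deviant group only the pooled
variance is estimable, so this is a pooled-variance (SPM-style, not Welch)
two-sample t; df = (n + 1) - rank(design).

Atrophy maps threshold the t-map one-sided in the GM-loss direction at an
uncorrected voxel p (default 0.005), label connected components, and report
total atrophy volume = suprathreshold voxel count x voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure
from sklearn.base import BaseEstimator

from .datamodel import GMDensityMap, GMMask, NormativeDatabase, SubjectMeta, VoxelGrid
from .smoothing import smooth_map, smooth_ndb

__all__ = [
    "StatMap",
    "DesignSpec",
    "ClusterTable",
    "AtrophyResult",
    "fit_voxelwise_glm",
    "threshold_stat_map",
    "label_clusters",
    "total_atrophy_volume",
    "SingleSubjectVBM",
    "run_single_subject_vbm",
]

_CONNECTIVITY_TO_SKIMAGE = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class DesignSpec:
    """GLM design: group indicator + intercept + optional nuisance covariates.

    Covariates are mean-centered over all rows (subject + NDB), the standard
    ANCOVA encoding, so the group contrast compares the subject to the NDB
    at the covariate mean.
    """

    covariates: tuple[str, ...] = ("age", "tiv")

    def __post_init__(self) -> None:
        bad = set(self.covariates) - {"age", "tiv"}
        if bad:
            raise ValueError(f"unknown covariates: {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return 2 + len(self.covariates)

    def build_matrix(self, subject_meta: SubjectMeta, ndb: NormativeDatabase) -> np.ndarray:
        """(n+1, k) design; row 0 is the test subject."""
        metas = [subject_meta, *ndb.meta]
        n_rows = len(metas)
        cols = [np.r_[1.0, np.zeros(n_rows - 1)], np.ones(n_rows)]
        for name in self.covariates:
            if name == "age":
                vals = np.array([m.age_years for m in metas], dtype=float)
            else:
                tivs = [m.tiv_ml for m in metas]
                missing = [m.subject_id for m, t in zip(metas, tivs) if t is None]
                if missing:
                    raise ValueError(
                        f"TIV covariate requested but TIV missing for: {missing}; "
                        "drop 'tiv' from the design or supply TIV"
                    )
                vals = np.array(tivs, dtype=float)
            cols.append(vals - vals.mean())
        X = np.column_stack(cols)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(
                "rank-deficient design matrix (e.g. a constant covariate column); "
                "drop the offending covariate"
            )
        return X


@dataclass(frozen=True)
class StatMap:
    """Voxelwise t-statistic field with degrees of freedom and direction.

    ``df`` may be a scalar (pooled-variance GLM) or a voxelwise array
    (Welch). ``direction`` states how the contrast was signed:
    'lower' means negative t marks the effect of interest (GM loss).
    """

    values: np.ndarray
    df: float | np.ndarray
    direction: str
    grid: VoxelGrid
    mask: GMMask | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("lower", "higher", "two_sided"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass(frozen=True)
class ClusterTable:
    """Connected suprathreshold components, largest first."""

    rows: tuple[dict, ...]

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_voxels_total(self) -> int:
        return int(sum(r["n_voxels"] for r in self.rows))

    @property
    def largest_n_voxels(self) -> int:
        return int(self.rows[0]["n_voxels"]) if self.rows else 0

    def to_frame(self) -> pd.DataFrame:
        cols = ["label", "n_voxels", "volume_ml", "peak_stat", "peak_voxel"]
        return pd.DataFrame(list(self.rows), columns=cols)


@dataclass(frozen=True)
class AtrophyResult:
    binary_map: np.ndarray
    p_threshold: float
    clusters: ClusterTable
    total_volume_ml: float
    tmap: StatMap | None = None
    subject_id: str | None = None

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "p_threshold": self.p_threshold,
            "n_suprathreshold_voxels": int(self.binary_map.sum()),
            "total_volume_ml": self.total_volume_ml,
            "n_clusters": len(self.clusters),
            "largest_cluster_voxels": self.clusters.largest_n_voxels,
        }


def fit_voxelwise_glm(
    subject: GMDensityMap,
    subject_meta: SubjectMeta,
    ndb: NormativeDatabase,
    design: DesignSpec = DesignSpec(),
) -> StatMap:
    """Voxelwise two-sample GLM t-test of one subject against the NDB.

    Ordinary least squares per in-mask voxel on the (n+1)-row design; the
    returned t is the group-indicator coefficient over its standard error,
    so negative t means the subject's GM density is below the (covariate-
    adjusted) NDB mean. Voxels with zero residual variance get t = 0.
    """
    ndb.grid.require_match(subject.grid, "subject map")
    X = design.build_matrix(subject_meta, ndb)
    n_rows, rank = X.shape[0], X.shape[1]  # build_matrix guarantees full rank
    df = n_rows - rank

    mask = ndb.mask.values
    Y = np.vstack([subject.values[mask][None, :], ndb.stack()[:, mask]])
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    c = np.zeros(X.shape[1])
    c[0] = 1.0  # group-indicator contrast
    var_scale = float(c @ XtX_inv @ c)
    se = np.sqrt(sigma2 * var_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[0] / se
    t[se == 0] = 0.0

    t_vol = np.zeros(ndb.grid.shape)
    t_vol[mask] = t
    return StatMap(values=t_vol, df=float(df), direction="lower", grid=ndb.grid, mask=ndb.mask)


def threshold_stat_map(stat: StatMap, p: float = 0.005) -> np.ndarray:
    """Binary suprathreshold field at uncorrected voxel-level p.

    One-sided in the map's direction ('lower': t below the p-quantile of
    the central t distribution; 'higher': above the (1-p)-quantile;
    'two_sided': |t| above the (1-p/2)-quantile).
    """
    if not (0 < p <= 0.5):
        raise ValueError(f"p must be in (0, 0.5], got {p}")
    df = np.asarray(stat.df, dtype=float)
    if not np.all(np.isfinite(df)) or np.any(df <= 0):
        raise ValueError("degrees of freedom must be finite and positive")
    t = stat.values
    if stat.direction == "lower":
        supra = t < stats.t.ppf(p, df)
    elif stat.direction == "higher":
        supra = t > stats.t.ppf(1 - p, df)
    else:
        supra = np.abs(t) > stats.t.ppf(1 - p / 2, df)
    if stat.mask is not None:
        supra = supra & stat.mask.values
    return supra


def label_clusters(
    binary: np.ndarray,
    grid: VoxelGrid,
    connectivity: int = 18,
    stat_values: np.ndarray | None = None,
) -> ClusterTable:
    """Connected components of a binary map as a deterministic cluster table.

    Components use face (6), edge (18) or corner (26) adjacency. Rows are
    ordered by descending size, ties broken by the lexicographically
    smallest peak voxel index. The peak voxel maximizes |stat| within the
    cluster (lexicographic tie-break); without a stat map it is the
    lexicographically smallest member.
    """
    if connectivity not in _CONNECTIVITY_TO_SKIMAGE:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    binary = np.asarray(binary).astype(bool)
    labels = measure.label(binary, connectivity=_CONNECTIVITY_TO_SKIMAGE[connectivity])
    rows = []
    for lab in range(1, labels.max() + 1):
        idx = np.argwhere(labels == lab)
        n_vox = idx.shape[0]
        if stat_values is not None:
            vals = np.abs(stat_values[tuple(idx.T)])
            best = np.flatnonzero(vals == vals.max())
            # argwhere output is already lexicographically sorted
            peak = tuple(int(v) for v in idx[best[0]])
            peak_stat = float(stat_values[peak])
        else:
            peak = tuple(int(v) for v in idx[0])
            peak_stat = float("nan")
        rows.append(
            {
                "n_voxels": int(n_vox),
                "volume_ml": n_vox * grid.voxel_volume_ml,
                "peak_stat": peak_stat,
                "peak_voxel": peak,
            }
        )
    rows.sort(key=lambda r: (-r["n_voxels"], r["peak_voxel"]))
    for i, r in enumerate(rows):
        r["label"] = i + 1
    return ClusterTable(tuple(rows))


def total_atrophy_volume(binary: np.ndarray, grid: VoxelGrid) -> float:
    """Suprathreshold volume in ml: voxel count x single-voxel volume."""
    return float(np.asarray(binary).astype(bool).sum()) * grid.voxel_volume_ml


class SingleSubjectVBM(BaseEstimator):
    """Single-subject VBM model: fit on an NDB, predict atrophy for a subject.

    ``fit`` smooths the NDB maps once (``smooth_fwhm_mm``; 0 for
    pre-smoothed inputs); ``predict`` smooths the subject map, runs the
    voxelwise GLM with the configured nuisance covariates, thresholds
    one-sided in the GM-loss direction at ``p``, labels clusters and
    computes the total atrophy volume.

    Attributes
    ----------
    ndb_ : the (smoothed) NormativeDatabase used as reference
    """

    def __init__(
        self,
        smooth_fwhm_mm: float = 8.0,
        p: float = 0.005,
        covariates: tuple[str, ...] = ("age", "tiv"),
        connectivity: int = 18,
        min_cluster_voxels: int = 0,
        two_sided: bool = False,
    ):
        self.smooth_fwhm_mm = smooth_fwhm_mm
        self.p = p
        self.covariates = covariates
        self.connectivity = connectivity
        self.min_cluster_voxels = min_cluster_voxels
        self.two_sided = two_sided

    def fit(self, ndb: NormativeDatabase, y=None) -> "SingleSubjectVBM":
        self.ndb_ = smooth_ndb(ndb, self.smooth_fwhm_mm)
        self.design_ = DesignSpec(covariates=tuple(self.covariates))
        return self

    def predict(self, subject: GMDensityMap, subject_meta: SubjectMeta) -> AtrophyResult:
        if not hasattr(self, "ndb_"):
            raise RuntimeError("model is not fitted")
        smoothed = smooth_map(subject, self.smooth_fwhm_mm)
        stat = fit_voxelwise_glm(smoothed, subject_meta, self.ndb_, self.design_)
        if self.two_sided:
            stat = StatMap(stat.values, stat.df, "two_sided", stat.grid, stat.mask)
        supra = threshold_stat_map(stat, self.p)
        clusters = label_clusters(supra, stat.grid, self.connectivity, stat.values)
        if self.min_cluster_voxels > 1:
            from .group import apply_extent_filter  # local import, avoids cycle

            supra, clusters = apply_extent_filter(
                supra, stat.grid, self.min_cluster_voxels, self.connectivity, stat.values
            )
        return AtrophyResult(
            binary_map=supra,
            p_threshold=self.p,
            clusters=clusters,
            total_volume_ml=total_atrophy_volume(supra, stat.grid),
            tmap=stat,
            subject_id=subject.subject_id,
        )


def run_single_subject_vbm(
    subject: GMDensityMap,
    subject_meta: SubjectMeta,
    ndb: NormativeDatabase,
    smooth_fwhm_mm: float = 8.0,
    p: float = 0.005,
    covariates: tuple[str, ...] = ("age", "tiv"),
    connectivity: int = 18,
) -> AtrophyResult:
    """One-shot wrapper: smooth -> GLM -> threshold -> clusters -> volume."""
    model = SingleSubjectVBM(
        smooth_fwhm_mm=smooth_fwhm_mm, p=p, covariates=covariates, connectivity=connectivity
    )
    return model.fit(ndb).predict(subject, subject_meta)
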