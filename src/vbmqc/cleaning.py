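"""Normative-database quality control via leave-one-out z-score maps.

Each scan in the normative database (NDB) is scored against the remaining
scans: a voxelwise leave-one-out z-map

    z = (scan - mean of the other scans) / SD of the other scans

restricted to the GM mask (the mask exists precisely to keep the SD away
from zero), summarized by three scan-level quality metrics:

* ``z_sum``          — sum of |z| over the mask (sensitive to global,
                       scanner-like effects),
* ``z_max``          — maximum |z| over the mask (focal effects),
* ``n_significant``  — number of in-mask voxels with |z| > z_cut
                       (spatially extended but milder effects).

A scan is flagged on a metric when its value is *at or above* the upper
Tukey-style fence Q3 + k * IQR of that metric across the NDB (k = 1.0 by
default — a deliberately sensitive cutoff), and is an overall outlier when
flagged on at least ``min_metrics_flagged`` metrics (default 1, i.e. the
union). Cleaning removes the overall outliers in a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .datamodel import GMMask, NormativeDatabase
from .smoothing import smooth_ndb

__all__ = [
    "ZScoreMap",
    "QualityMetrics",
    "OutlierReport",
    "compute_loo_zmap",
    "compute_quality_metrics",
    "upper_fence",
    "detect_outliers",
    "clean_ndb",
    "NDBOutlierDetector",
]

#: reference SDs below this (in GM-density units) are treated as degenerate
SD_EPS = 1e-6

METRIC_NAMES = ("z_sum", "z_max", "n_significant")


@dataclass(frozen=True)
class ZScoreMap:
    """Leave-one-out z-score field for one NDB scan (zero outside the mask)."""

    subject_id: str
    z: np.ndarray
    n_reference: int
    n_degenerate_voxels: int = 0

    def __post_init__(self) -> None:
        if self.n_reference < 2:
            raise ValueError("leave-one-out reference needs >= 2 scans")


@dataclass(frozen=True)
class QualityMetrics:
    subject_id: str
    z_sum: float
    z_max: float
    n_significant: int
    z_cut: float = 2.5

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "z_sum": self.z_sum,
            "z_max": self.z_max,
            "n_significant": self.n_significant,
            "z_cut": self.z_cut,
        }


@dataclass(frozen=True)
class OutlierReport:
    """Per-scan metrics, per-metric fences/flags, and the overall outlier set."""

    metrics: tuple[QualityMetrics, ...]
    fences: dict[str, float]
    k: float
    per_metric_flags: dict[str, dict[str, bool]]
    overall_outliers: frozenset[str]
    min_metrics_flagged: int = 1
    n_degenerate_voxels: dict[str, int] = field(default_factory=dict)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(m.subject_id for m in self.metrics)

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "min_metrics_flagged": self.min_metrics_flagged,
            "fences": dict(self.fences),
            "metrics": [m.as_dict() for m in self.metrics],
            "per_metric_flags": {m: dict(v) for m, v in self.per_metric_flags.items()},
            "overall_outliers": sorted(self.overall_outliers),
            "n_degenerate_voxels": dict(self.n_degenerate_voxels),
        }


def _loo_mean_sd(stack_masked: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out mean and sample SD for every scan at once.

    ``stack_masked`` is (n_scans, n_voxels); returns two arrays of the same
    shape: for row i, the mean and sample SD (n-1 denominator) over all
    rows except i.
    """
    n = stack_masked.shape[0]
    total = stack_masked.sum(axis=0, keepdims=True)
    total_sq = (stack_masked**2).sum(axis=0, keepdims=True)
    loo_mean = (total - stack_masked) / (n - 1)
    # sum of squared deviations of the n-1 remaining values
    ss = total_sq - stack_masked**2 - (n - 1) * loo_mean**2
    loo_var = np.clip(ss, 0.0, None) / (n - 2)
    return loo_mean, np.sqrt(loo_var)


def _loo_z_stack(ndb: NormativeDatabase, sd_eps: float = SD_EPS) -> tuple[np.ndarray, np.ndarray]:
    """(n_scans, n_mask_voxels) LOO z-scores and per-scan degenerate counts."""
    if len(ndb) < 3:
        raise ValueError("NDB must hold >= 3 scans for leave-one-out z-maps")
    mask = ndb.mask.values
    stack = ndb.stack()[:, mask]
    loo_mean, loo_sd = _loo_mean_sd(stack)
    degenerate = loo_sd < sd_eps
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (stack - loo_mean) / loo_sd
    z[degenerate] = 0.0
    return z, degenerate.sum(axis=1)


def compute_loo_zmap(ndb: NormativeDatabase, index: int, sd_eps: float = SD_EPS) -> ZScoreMap:
    """Leave-one-out z-score map for scan ``index`` of the NDB.

    Per in-mask voxel: z = (value - mean over the other scans) / sample SD
    over the other scans. Voxels whose reference SD falls below ``sd_eps``
    get z = 0 and are counted in ``n_degenerate_voxels``.
    """
    n = len(ndb)
    if not (0 <= index < n):
        raise IndexError(f"scan index {index} out of range for NDB of size {n}")
    z_stack, degen = _loo_z_stack(ndb, sd_eps)
    z_vol = np.zeros(ndb.grid.shape)
    z_vol[ndb.mask.values] = z_stack[index]
    return ZScoreMap(
        subject_id=ndb.subject_ids[index],
        z=z_vol,
        n_reference=n - 1,
        n_degenerate_voxels=int(degen[index]),
    )


def compute_quality_metrics(zmap: ZScoreMap, mask: GMMask, z_cut: float = 2.5) -> QualityMetrics:
    """Scan-level quality metrics of a LOO z-map over the GM mask.

    ``n_significant`` uses a strict inequality: a voxel with |z| exactly
    equal to ``z_cut`` is not counted.
    """
    abs_z = np.abs(zmap.z[mask.values])
    if abs_z.size == 0:
        raise ValueError("empty mask")
    return QualityMetrics(
        subject_id=zmap.subject_id,
        z_sum=float(abs_z.sum()),
        z_max=float(abs_z.max()),
        n_significant=int((abs_z > z_cut).sum()),
        z_cut=z_cut,
    )


def upper_fence(values, k: float = 1.0) -> float:
    """Upper Tukey-style fence Q3 + k * IQR.

    Quartiles use linear interpolation of order statistics (position
    (n-1)p + 1, numpy's default quantile rule). Requires >= 4 finite values.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError(f"fence needs >= 4 values, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValueError("fence values must be finite")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return float(q3 + k * (q3 - q1))


def detect_outliers(
    ndb: NormativeDatabase,
    k: float = 1.0,
    z_cut: float = 2.5,
    min_metrics_flagged: int = 1,
    sd_eps: float = SD_EPS,
) -> OutlierReport:
    """Flag NDB scans whose quality metrics sit at or above the upper fence.

    A scan is flagged on a metric when value >= Q3 + k*IQR (inclusive, as
    the rule is stated), except that when a metric's IQR is exactly zero the
    comparison becomes strict — otherwise a perfectly homogeneous NDB would
    flag every scan. A scan is an overall outlier when flagged on at least
    ``min_metrics_flagged`` metrics.
    """
    if len(ndb) < 4:
        raise ValueError("outlier detection needs an NDB of >= 4 scans")
    z_stack, degen = _loo_z_stack(ndb, sd_eps)
    abs_z = np.abs(z_stack)
    ids = ndb.subject_ids
    metrics = tuple(
        QualityMetrics(
            subject_id=ids[i],
            z_sum=float(abs_z[i].sum()),
            z_max=float(abs_z[i].max()),
            n_significant=int((abs_z[i] > z_cut).sum()),
            z_cut=z_cut,
        )
        for i in range(len(ndb))
    )
    fences: dict[str, float] = {}
    flags: dict[str, dict[str, bool]] = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in metrics], dtype=float)
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        fence = float(q3 + k * (q3 - q1))
        fences[name] = fence
        if q3 - q1 == 0:
            flagged = vals > fence
        else:
            flagged = vals >= fence
        flags[name] = {ids[i]: bool(flagged[i]) for i in range(len(ids))}
    n_flagged = {
        sid: sum(flags[name][sid] for name in METRIC_NAMES) for sid in ids
    }
    overall = frozenset(sid for sid, c in n_flagged.items() if c >= min_metrics_flagged)
    return OutlierReport(
        metrics=metrics,
        fences=fences,
        k=k,
        per_metric_flags=flags,
        overall_outliers=overall,
        min_metrics_flagged=min_metrics_flagged,
        n_degenerate_voxels={ids[i]: int(degen[i]) for i in range(len(ids))},
    )


def clean_ndb(ndb: NormativeDatabase, report: OutlierReport) -> NormativeDatabase:
    """Remove the report's overall outliers from the NDB (single pass)."""
    unknown = report.overall_outliers - set(ndb.subject_ids)
    if unknown:
        raise ValueError(f"report references scans not in this NDB: {sorted(unknown)}")
    keep = [sid for sid in ndb.subject_ids if sid not in report.overall_outliers]
    if len(keep) < 3:
        raise ValueError(
            f"cleaning would leave {len(keep)} scans; an NDB needs >= 3"
        )
    return ndb.subset(keep)


class NDBOutlierDetector(BaseEstimator):
    """Quality-control detector for normative databases.

    Fitting computes leave-one-out z-maps for every scan (optionally after
    Gaussian smoothing, matching the maps used downstream for VBM), derives
    the three quality metrics, and places an upper fence per metric.

    Parameters
    ----------
    k : float
        Fence multiplier in Q3 + k*IQR. 1.0 is sensitive; 1.5 is the more
        restrictive conventional choice.
    z_cut : float
        |z| threshold for the significant-voxel count metric.
    min_metrics_flagged : int
        Number of metrics a scan must be flagged on to be an overall
        outlier (1 = union rule).
    smooth_fwhm_mm : float
        FWHM of Gaussian smoothing applied once to the NDB maps before
        scoring; 0 disables (use when maps are pre-smoothed).

    Attributes
    ----------
    report_ : OutlierReport
    outliers_ : frozenset of flagged subject ids
    fences_ : dict metric -> fence value
    """

    def __init__(
        self,
        k: float = 1.0,
        z_cut: float = 2.5,
        min_metrics_flagged: int = 1,
        smooth_fwhm_mm: float = 8.0,
        sd_eps: float = SD_EPS,
    ):
        self.k = k
        self.z_cut = z_cut
        self.min_metrics_flagged = min_metrics_flagged
        self.smooth_fwhm_mm = smooth_fwhm_mm
        self.sd_eps = sd_eps

    def fit(self, ndb: NormativeDatabase, y=None) -> "NDBOutlierDetector":
        smoothed = smooth_ndb(ndb, self.smooth_fwhm_mm)
        self.report_ = detect_outliers(
            smoothed,
            k=self.k,
            z_cut=self.z_cut,
            min_metrics_flagged=self.min_metrics_flagged,
            sd_eps=self.sd_eps,
        )
        self.outliers_ = self.report_.overall_outliers
        self.fences_ = self.report_.fences
        return self

    def transform(self, ndb: NormativeDatabase) -> NormativeDatabase:
        """Return ``ndb`` with the fitted outliers removed (unsmoothed maps kept)."""
        if not hasattr(self, "report_"):
            raise RuntimeError("detector is not fitted")
        return clean_ndb(ndb, self.report_)

    def fit_transform(self, ndb: NormativeDatabase, y=None) -> NormativeDatabase:
        return self.fit(ndb).transform(ndb)
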