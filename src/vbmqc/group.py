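"""Voxelwise heteroscedastic (Welch) comparison between two normative databases.

Used to contrast two NDBs (e.g. a single-scanner vs a multi-scanner
database) voxel by voxel without assuming equal variances. Thresholding is
one-sided at an uncorrected voxel p, run separately in each direction, and
clusters below a minimum extent (default 296 voxels, i.e. 1 ml at 1.5 mm
isotropic) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import NormativeDatabase, VoxelGrid
from .vbm import ClusterTable, StatMap, label_clusters, threshold_stat_map, total_atrophy_volume

__all__ = ["GroupCompareResult", "welch_tmap", "apply_extent_filter", "compare_ndbs"]


@dataclass(frozen=True)
class GroupCompareResult:
    tmap: StatMap
    suprathreshold: dict[str, np.ndarray]          # per direction: "a_gt_b", "a_lt_b"
    clusters: dict[str, ClusterTable]
    total_volume_ml: dict[str, float]
    p_threshold: float
    min_extent_voxels: int
    n_degenerate_voxels: int = 0

    def as_dict(self) -> dict:
        return {
            "p_threshold": self.p_threshold,
            "min_extent_voxels": self.min_extent_voxels,
            "total_volume_ml": dict(self.total_volume_ml),
            "n_clusters": {d: len(c) for d, c in self.clusters.items()},
            "n_degenerate_voxels": self.n_degenerate_voxels,
        }


def welch_tmap(group_a: NormativeDatabase, group_b: NormativeDatabase) -> StatMap:
    """Voxelwise Welch t between two groups with voxelwise Satterthwaite df.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b); df estimated per
    voxel because the variances themselves vary across the brain. Voxels
    with zero variance in both groups get t = 0 and df = n_a + n_b - 2 and
    are counted as degenerate.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("Welch test needs >= 2 scans per group")
    group_a.grid.require_match(group_b.grid, "group B")
    mask = group_a.mask.values
    a = group_a.stack()[:, mask]
    b = group_b.stack()[:, mask]
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sa, sb = va / na, vb / nb
    denom2 = sa + sb
    degenerate = denom2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(denom2)
        df = denom2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    t[degenerate] = 0.0
    df[degenerate] = na + nb - 2

    t_vol = np.zeros(group_a.grid.shape)
    df_vol = np.full(group_a.grid.shape, float(na + nb - 2))
    t_vol[mask] = t
    df_vol[mask] = df
    stat = StatMap(values=t_vol, df=df_vol, direction="higher", grid=group_a.grid, mask=group_a.mask)
    object.__setattr__(stat, "n_degenerate_voxels", int(degenerate.sum()))
    return stat


def apply_extent_filter(
    binary: np.ndarray,
    grid: VoxelGrid,
    min_extent_voxels: int = 296,
    connectivity: int = 18,
    stat_values: np.ndarray | None = None,
) -> tuple[np.ndarray, ClusterTable]:
    """Drop clusters smaller than ``min_extent_voxels`` (inclusive survival).

    Returns the pruned binary map and the table of surviving clusters.
    """
    if min_extent_voxels < 1:
        raise ValueError("min_extent_voxels must be >= 1")
    clusters = label_clusters(binary, grid, connectivity, stat_values)
    surviving = tuple(r for r in clusters.rows if r["n_voxels"] >= min_extent_voxels)
    if len(surviving) == len(clusters.rows):
        return np.asarray(binary).astype(bool), clusters
    from skimage import measure

    conn = {6: 1, 18: 2, 26: 3}[connectivity]
    labels = measure.label(np.asarray(binary).astype(bool), connectivity=conn)
    sizes = np.bincount(labels.ravel())
    keep_labels = np.flatnonzero(sizes >= min_extent_voxels)
    keep_labels = keep_labels[keep_labels > 0]
    pruned = np.isin(labels, keep_labels)
    rows = []
    for i, r in enumerate(surviving):
        r = dict(r)
        r["label"] = i + 1
        rows.append(r)
    return pruned, ClusterTable(tuple(rows))


def compare_ndbs(
    group_a: NormativeDatabase,
    group_b: NormativeDatabase,
    p: float = 0.005,
    min_extent_voxels: int = 296,
    connectivity: int = 18,
) -> GroupCompareResult:
    """Welch comparison of two NDBs with per-direction thresholding.

    Each direction (a > b and a < b) is thresholded one-sided at ``p``
    uncorrected and extent-filtered separately, and volumes are reported
    per direction.
    """
    tmap = welch_tmap(group_a, group_b)
    supra: dict[str, np.ndarray] = {}
    clusters: dict[str, ClusterTable] = {}
    volumes: dict[str, float] = {}
    for key, direction in (("a_gt_b", "higher"), ("a_lt_b", "lower")):
        directed = StatMap(tmap.values, tmap.df, direction, tmap.grid, tmap.mask)
        binary = threshold_stat_map(directed, p)
        binary, table = apply_extent_filter(
            binary, tmap.grid, min_extent_voxels, connectivity, tmap.values
        )
        supra[key] = binary
        clusters[key] = table
        volumes[key] = total_atrophy_volume(binary, tmap.grid)
    return GroupCompareResult(
        tmap=tmap,
        suprathreshold=supra,
        clusters=clusters,
        total_volume_ml=volumes,
        p_threshold=p,
        min_extent_voxels=min_extent_voxels,
        n_degenerate_voxels=getattr(tmap, "n_degenerate_voxels", 0),
    )
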