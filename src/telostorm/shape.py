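"""Per-telomere cluster shape analysis: Rg, filters, and group tables.

The scalar shape statistic is the radius of gyration of a localization
cluster,

.. math:: R_g^2 = \\frac{1}{N} \\sum_{k=1}^{N} \\lVert \\vec r_k - \\vec r_{\\mathrm{com}} \\rVert^2,

the root-mean-square distance of the N localization points from their center
of mass — computed in 3D by default (the data are 3D STORM), with a 2D
(XY-projected) mode available.  Clusters are found by density-based
clustering (DBSCAN), screened by the study's quality filters — strictly more
than ``min_points`` localizations, and a center of mass near the focal plane
— and aggregated into a per-(group, nucleus, telomere) table from which the
irregular-shape fraction above a reference-group-mean cutoff and the usual
distribution summaries are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import DBSCAN

from telostorm.localizations import LocalizationTable


class DegenerateClusterError(ValueError):
    """Raised when a shape statistic is undefined for a cluster."""


def radius_of_gyration(points: "np.ndarray | TelomereCluster", dims: int = 3) -> float:
    """Radius of gyration of a point set, in the units of the coordinates.

    Parameters
    ----------
    points
        (N, 3) coordinate array or a :class:`TelomereCluster`.
    dims
        3 for the full 3D Rg (default), 2 to use only the XY projection.

    Rg is invariant under rigid motions, scales linearly with the
    coordinates, and is zero iff all points coincide.  Raises on N = 0.
    """
    if isinstance(points, TelomereCluster):
        points = points.positions
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (N, 3) array")
    if len(pts) == 0:
        raise ValueError("radius of gyration is undefined for an empty cluster")
    if dims == 2:
        pts = pts[:, :2]
    elif dims != 3:
        raise ValueError("dims must be 2 or 3")
    com = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - com) ** 2, axis=1))))


@dataclass
class TelomereCluster:
    """One telomere: a localization subset with its derived shape quantities."""

    positions: np.ndarray
    nucleus_id: str | int = 0
    telomere_id: int = 0
    member_index: np.ndarray | None = None  # row indices into the source table

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if len(self.positions) == 0:
            raise ValueError("a cluster must contain at least one localization")

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def center_of_mass(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    @property
    def rg(self) -> float:
        return radius_of_gyration(self.positions)

    def rg_2d(self) -> float:
        return radius_of_gyration(self.positions, dims=2)


def cluster_localizations(
    table: LocalizationTable,
    linkage_radius: float = 75.0,
    min_cluster_seed: int = 10,
    nucleus_id: str | int = 0,
) -> list[TelomereCluster]:
    """Segment a molecule list into telomere clusters with DBSCAN in 3D.

    ``linkage_radius`` is the DBSCAN neighborhood radius (nm) and
    ``min_cluster_seed`` the core-point neighbor count; defaults suit
    telomere foci that are well separated relative to their ~80 nm Rg.
    Localizations assigned to no cluster are background.  Clusters are
    returned ordered by label (ascending), translation-invariantly.
    """
    if linkage_radius <= 0:
        raise ValueError("linkage_radius must be > 0")
    if len(table) == 0:
        return []
    pos = table.positions
    labels = DBSCAN(eps=linkage_radius, min_samples=min_cluster_seed).fit_predict(pos)
    clusters = []
    for tid, lab in enumerate(sorted(set(labels) - {-1})):
        idx = np.where(labels == lab)[0]
        clusters.append(
            TelomereCluster(
                pos[idx], nucleus_id=nucleus_id, telomere_id=tid, member_index=idx
            )
        )
    return clusters


@dataclass
class ClusterFilterPolicy:
    """Quality screen for telomere clusters.

    ``min_points`` is a strictly-greater threshold — a cluster passes only
    with more than ``min_points`` localizations (the study's ">200
    localizations" rule, so N = 200 is excluded and N = 201 kept).
    ``focal_window`` bounds |z_com − focal plane| in nm.  An optional
    ``reference_mask`` (2D boolean image with ``mask_pixel_size`` nm pixels
    and ``mask_origin`` at its [0, 0] corner) gates the XY center of mass,
    emulating overlay-based exclusion of nontelomeric background.
    """

    min_points: int = 200
    focal_window: float = 250.0
    reference_mask: np.ndarray | None = None
    mask_pixel_size: float = 160.0
    mask_origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.min_points < 0:
            raise ValueError("min_points must be >= 0")
        if self.focal_window <= 0:
            raise ValueError("focal_window must be > 0")
        if self.reference_mask is not None:
            self.reference_mask = np.asarray(self.reference_mask, bool)


def filter_clusters(
    clusters: Sequence[TelomereCluster],
    policy: ClusterFilterPolicy,
    focal_plane_z: float = 0.0,
) -> list[TelomereCluster]:
    """Apply the quality screen; order is preserved, empty output is valid."""
    out = []
    for c in clusters:
        if c.n <= policy.min_points:
            continue
        com = c.center_of_mass
        if abs(com[2] - focal_plane_z) > policy.focal_window:
            continue
        if policy.reference_mask is not None:
            col = int((com[0] - policy.mask_origin[0]) / policy.mask_pixel_size)
            row = int((com[1] - policy.mask_origin[1]) / policy.mask_pixel_size)
            shape = policy.reference_mask.shape
            if not (0 <= row < shape[0] and 0 <= col < shape[1]):
                continue
            if not policy.reference_mask[row, col]:
                continue
        out.append(c)
    return out


def cluster_anisotropy(cluster: "TelomereCluster | np.ndarray") -> np.ndarray:
    """Principal-axis spreads of a cluster: √eigenvalues of the position
    covariance (population normalization), sorted descending, in nm.

    The squares sum to Rg² (trace identity).  A uniform ball gives three
    nearly equal values; the irregular "compact in one dimension" class shows
    a distinctly smaller third value.  Raises
    :class:`DegenerateClusterError` for N < 3 or (near-)collinear clusters,
    for which a 3D shape is not defined; planar clusters (third value 0) are
    fine.
    """
    pts = cluster.positions if isinstance(cluster, TelomereCluster) else np.asarray(cluster, float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("positions must be (N, 3)")
    if len(pts) < 3:
        raise DegenerateClusterError("anisotropy needs at least 3 points")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    if eig[0] > 0 and eig[1] / eig[0] < 1e-12:
        raise DegenerateClusterError("collinear cluster: anisotropy is degenerate")
    if eig[0] == 0:
        raise DegenerateClusterError("all points coincide")
    return np.sqrt(eig)


@dataclass
class GroupShapeTable:
    """Tidy (group, nucleus, telomere) → (Rg, N) records for group analysis."""

    records: pd.DataFrame  # columns: group, nucleus, telomere, rg_nm, n_locs

    COLUMNS = ("group", "nucleus", "telomere", "rg_nm", "n_locs")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"GroupShapeTable missing columns: {missing}")
        if (self.records["rg_nm"] < 0).any():
            raise ValueError("Rg values must be >= 0")
        dup = self.records.duplicated(subset=["group", "nucleus", "telomere"])
        if dup.any():
            raise ValueError("(group, nucleus, telomere) keys must be unique")

    @classmethod
    def from_clusters(
        cls, clusters_by_group: dict[str, Sequence[TelomereCluster]], dims: int = 3
    ) -> "GroupShapeTable":
        rows = []
        for group, clusters in clusters_by_group.items():
            for c in clusters:
                rows.append(
                    {
                        "group": group,
                        "nucleus": c.nucleus_id,
                        "telomere": c.telomere_id,
                        "rg_nm": radius_of_gyration(c.positions, dims=dims),
                        "n_locs": c.n,
                    }
                )
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.records["group"]))

    def rg_by_group(self) -> dict[str, np.ndarray]:
        return {g: sub["rg_nm"].to_numpy(float) for g, sub in self.records.groupby("group", sort=False)}

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroupShapeTable":
        return cls(pd.read_csv(path))


def fraction_irregular(
    table: GroupShapeTable, reference_group: str
) -> tuple[dict[str, float], float]:
    """Per-group fraction of telomeres with Rg at or above the reference cutoff.

    The cutoff is the arithmetic mean Rg of ``reference_group``, recomputed
    from the data at hand (never a hard-coded constant); "equal or greater"
    is inclusive, so a telomere exactly at the cutoff counts as irregular.

    Returns ({group: fraction}, cutoff_nm); empty groups get NaN.
    """
    by_group = table.rg_by_group()
    if reference_group not in by_group or len(by_group[reference_group]) == 0:
        raise ValueError(f"reference group {reference_group!r} absent or empty")
    cutoff = float(np.mean(by_group[reference_group]))
    fractions = {
        g: (float(np.mean(v >= cutoff)) if len(v) else float("nan"))
        for g, v in by_group.items()
    }
    return fractions, cutoff


def summarize_shape_distribution(
    table: GroupShapeTable, confidence: float = 0.95
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group and per-(group, nucleus) summaries of the Rg distribution.

    The group summary holds mean, median, interquartile range, s.e.m. and the
    t-based confidence interval of the mean; the group mean is the mean over
    all telomere records (every telomere weighted equally, not a mean of
    nucleus means).  Returns (group_summary, nucleus_summary).
    """

    def _summ(v: np.ndarray) -> dict:
        v = np.asarray(v, float)
        n = len(v)
        mean = float(np.mean(v))
        sd = float(np.std(v, ddof=1)) if n > 1 else 0.0
        sem_ = sd / np.sqrt(n) if n > 1 else float("nan")
        if n > 1 and sd > 0:
            half = sps.t.ppf(0.5 + confidence / 2.0, n - 1) * sem_
            ci = (mean - half, mean + half)
        else:
            ci = (mean, mean)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return {
            "n": n,
            "mean_rg_nm": mean,
            "median_rg_nm": float(med),
            "iqr_low_nm": float(q1),
            "iqr_high_nm": float(q3),
            "sem_nm": sem_,
            "ci_low_nm": float(ci[0]),
            "ci_high_nm": float(ci[1]),
        }

    g_rows = [{"group": g, **_summ(v)} for g, v in table.rg_by_group().items()]
    n_rows = [
        {"group": g, "nucleus": nuc, **_summ(sub["rg_nm"].to_numpy(float))}
        for (g, nuc), sub in table.records.groupby(["group", "nucleus"], sort=False)
    ]
    return pd.DataFrame(g_rows), pd.DataFrame(n_rows)


def rg_count_correlation(table: GroupShapeTable) -> dict[str, float]:
    """Pearson correlation of Rg vs localization count, per group.

    NaN for groups with fewer than 3 telomeres or zero variance in either
    variable (correlation undefined).
    """
    out = {}
    for g, sub in table.records.groupby("group", sort=False):
        rg = sub["rg_nm"].to_numpy(float)
        n = sub["n_locs"].to_numpy(float)
        if len(rg) < 3 or np.std(rg) == 0 or np.std(n) == 0:
            out[g] = float("nan")
        else:
            out[g] = float(sps.pearsonr(rg, n).statistic)
    return out
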