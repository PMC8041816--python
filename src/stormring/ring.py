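"""Ring-center identification from top-view localizations.

The center of each ring is found in three steps mirroring the analysis
this package automates: (1) k-means clustering of the event coordinates
with the number of clusters selected by the mean silhouette score over
k = 6..15, (2) removal of the two clusters with the lowest summed event
intensity (background suppression), (3) a least-squares circle fit to the
remaining cluster centers, gated at R² > 0.9.  The circle center is the
ring center used by the radial analysis.

Clustering uses coordinates only; intensity enters solely through the
background-removal rule, so uniformly rescaling intensities changes
nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import (DegenerateDataError, GeometryError,
                     InsufficientDataError)
from .io import LocalizationTable

CIRCLE_R2_THRESHOLD = 0.9


@dataclass
class ClusterModel:
    """A silhouette-selected k-means partition of one ring's events."""

    k_selected: int
    labels: np.ndarray
    cluster_centers: np.ndarray       # (k, 2) nm
    cluster_intensity: np.ndarray     # summed event intensity per cluster
    silhouette_by_k: dict[int, float]
    removed_background: tuple[int, ...]

    @property
    def retained_centers(self) -> np.ndarray:
        keep = [i for i in range(self.k_selected)
                if i not in self.removed_background]
        return self.cluster_centers[keep]


@dataclass
class CircleFit:
    """Least-squares circle through cluster centers, with radial-residual R²."""

    center: tuple[float, float]
    radius: float
    r_squared: float
    passed_qc: bool
    n_points: int = 0


def select_k_by_silhouette(points: np.ndarray, intensity: np.ndarray,
                           k_min: int, k_max: int, seed: int = 0,
                           n_init: int = 20
                           ) -> tuple[int, np.ndarray, np.ndarray, dict[int, float]]:
    """k-means over k in [k_min, k_max]; pick k maximising mean silhouette.

    Ties break toward smaller k.  Returns (k, labels, centers, score map).
    Shared by ring-center finding (k 6..15) and cluster counting (k 3..15).
    """
    n = points.shape[0]
    if n < k_max + 1:
        raise InsufficientDataError(
            f"need at least k_max+1 = {k_max + 1} events, got {n}")
    if np.allclose(points, points[0], atol=1e-9):
        raise DegenerateDataError("all events coincident; cannot cluster")
    best = None
    scores: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(points)
        # a k-means solution can leave a cluster empty only pathologically;
        # silhouette requires >= 2 distinct labels
        if len(np.unique(km.labels_)) < 2:
            continue
        s = float(silhouette_score(points, km.labels_))
        scores[k] = s
        if best is None or s > best[0] + 1e-12:
            best = (s, k, km.labels_, km.cluster_centers_)
    if best is None:
        raise DegenerateDataError("no valid clustering in the k range")
    _, k_sel, labels, centers = best
    return k_sel, labels, centers, scores


def cluster_events(table: LocalizationTable, k_min: int = 6, k_max: int = 15,
                   seed: int = 0, n_init: int = 20) -> ClusterModel:
    """Cluster one ring's events and flag the background clusters.

    The two clusters with the smallest summed event intensity are flagged
    as background (``removed_background``); when k_selected ≤ 2 only
    k_selected − 1 clusters are flagged so the model is never emptied.
    Intensity ties break toward the lower cluster index, deterministically.
    """
    k_sel, labels, centers, scores = select_k_by_silhouette(
        table.xy, table.intensity, k_min, k_max, seed, n_init)
    csum = np.bincount(labels, weights=table.intensity, minlength=k_sel)
    n_remove = min(2, k_sel - 1)
    order = np.lexsort((np.arange(k_sel), csum))  # stable: intensity, then index
    removed = tuple(int(i) for i in order[:n_remove])
    return ClusterModel(
        k_selected=k_sel,
        labels=labels,
        cluster_centers=centers,
        cluster_intensity=csum,
        silhouette_by_k=scores,
        removed_background=removed,
    )


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    p = points - points.mean(axis=0)
    sv = np.linalg.svd(p, compute_uv=False)
    return sv.size < 2 or sv[1] <= tol * max(sv[0], 1.0)


def fit_circle(points: np.ndarray, weights: np.ndarray | None = None
               ) -> CircleFit:
    """Geometric least-squares circle fit.

    An algebraic (Kåsa) fit initialises a Levenberg–Marquardt refinement
    of the radial residuals d_i − r, with the radius profiled out
    (optimal r given a center is the weighted mean distance).  R² is
    positional: 1 − Σ‖p_i − p̂_i‖² / Σ‖p_i − p̄‖², where p̂_i is the
    nearest point of the fitted circle (so the numerator is the radial
    residual sum Σ(d_i − r)²) and p̄ the weighted centroid.  It is
    translation/rotation invariant, 1 for points exactly on a circle,
    and drops sharply when off-circle clusters poison the fit.  QC
    passes when R² > 0.9.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
        raise GeometryError("circle fit needs >= 3 planar points")
    if _collinear(points):
        raise GeometryError("points are collinear; no finite circle")
    w = np.ones(points.shape[0]) if weights is None else np.asarray(weights, float)
    if (w <= 0).any():
        raise GeometryError("weights must be positive")
    x, y = points[:, 0], points[:, 1]

    # Kåsa: minimise ||x² + y² − 2ax − 2by − c|| — linear least squares
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A * w[:, None], b * w, rcond=None)
    cx0, cy0 = sol[0], sol[1]

    def radial_residuals(c):
        d = np.hypot(x - c[0], y - c[1])
        r = np.average(d, weights=w)
        return np.sqrt(w) * (d - r)

    res = least_squares(radial_residuals, x0=[cx0, cy0], method="lm")
    cx, cy = res.x
    d = np.hypot(x - cx, y - cy)
    r = float(np.average(d, weights=w))
    ss_res = float(np.sum(w * (d - r) ** 2))
    centroid = np.average(points, axis=0, weights=w)
    ss_tot = float(np.sum(w * np.sum((points - centroid) ** 2, axis=1)))
    r2 = 1.0 if ss_res <= 1e-12 * max(ss_tot, 1.0) or ss_tot == 0 \
        else 1.0 - ss_res / ss_tot
    return CircleFit(center=(float(cx), float(cy)), radius=r,
                     r_squared=float(r2), passed_qc=bool(r2 > CIRCLE_R2_THRESHOLD),
                     n_points=points.shape[0])


def find_ring_center(table: LocalizationTable, k_min: int = 6, k_max: int = 15,
                     seed: int = 0, n_init: int = 20
                     ) -> tuple[ClusterModel, CircleFit]:
    """Full ring-center identification: cluster → drop background → circle fit.

    A fit with R² ≤ 0.9 is returned with ``passed_qc=False`` rather than
    discarded; the caller decides what to do with failing structures.
    """
    model = cluster_events(table, k_min=k_min, k_max=k_max, seed=seed,
                           n_init=n_init)
    centers = model.retained_centers
    if centers.shape[0] < 3:
        raise GeometryError(
            f"only {centers.shape[0]} cluster centers after background removal")
    fit = fit_circle(centers)
    return model, fit
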