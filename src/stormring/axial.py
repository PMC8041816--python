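"""Axial (side-view) distance estimation between two parallel structures.

A side view shows the target protein and a reference structure as two
roughly parallel bars.  The analysis (1) splits the events into two
clusters with a two-component full-covariance Gaussian mixture, (2)
canonicalizes the frame — the midpoint of the two cluster centers moves
to the origin and the scene is rotated so the intensity-weighted major
axis of the *brighter* cluster lies along X, with the dimmer cluster at
positive Y — and (3) bins intensities along X and Y at 2 nm and fits the
Y histogram with a sum of two Gaussians.  The distance between the two
fitted means is the inter-structure axial distance, gated at R² ≥ 0.7.

Cohorts are averaged by summing the per-dataset X and Y histograms,
normalizing by dataset count, refitting the summed Y distribution, and
rendering the outer product of the two normalized histograms as the
averaged image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

from .errors import (FitFailureError, InsufficientDataError, UsageError)
from .io import LocalizationTable

BIN_WIDTH_NM = 2.0
AXIAL_R2_THRESHOLD = 0.7
_ISOTROPY_EIGENRATIO = 1.05


@dataclass
class SplitResult:
    """Two-cluster partition of a side view with brightness bookkeeping."""

    labels: np.ndarray              # 0/1 per event
    means: np.ndarray               # (2, 2) hard-assignment cluster centers
    brighter: int                   # index of the brighter cluster
    summed_intensity: np.ndarray    # (2,)
    provenance: dict = field(default_factory=dict)


@dataclass
class AxialFit:
    """Result of the two-Gaussian axial fit for one canonical side view."""

    component_means: np.ndarray     # (2, 2) cluster centers, canonical frame
    rotation: float                 # rad applied to reach the canonical frame
    y_edges: np.ndarray
    y_profile: np.ndarray
    x_edges: np.ndarray
    x_profile: np.ndarray
    gaussian_params: tuple          # (A1, mu1, s1, A2, mu2, s2)
    distance: float                 # |mu2 − mu1| nm
    r_squared: float
    passed_qc: bool
    provenance: dict = field(default_factory=dict)


def split_two_clusters(table: LocalizationTable, seed: int = 0,
                       n_init: int = 10) -> SplitResult:
    """Split events into two clusters with a seeded Gaussian mixture.

    Full covariances accommodate elongated bars.  Events are
    hard-assigned by maximum responsibility.  If the point cloud is
    numerically collinear the mixture degenerates, and a 1D split along
    the principal axis (threshold at the midpoint of the two 1D means) is
    used instead, flagged in provenance.  The brighter cluster is the one
    with the larger summed event intensity; ties break toward the cluster
    with more events, flagged.
    """
    if len(table) < 10:
        raise InsufficientDataError("need >= 10 events for a two-cluster split")
    pts = table.xy
    prov: dict = {}
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        # collinear: 1D two-means along the principal axis
        u = np.linalg.svd(centered, full_matrices=False)[2][0]
        t = centered @ u
        order = np.argsort(t)
        ts = t[order]
        gaps = np.diff(ts)
        cut = ts[np.argmax(gaps)] + gaps.max() / 2
        labels = (t > cut).astype(int)
        prov["degenerate_1d_split"] = True
    else:
        gm = GaussianMixture(n_components=2, covariance_type="full",
                             n_init=n_init, random_state=seed).fit(pts)
        labels = gm.predict(pts)
        prov["gmm_means"] = gm.means_
        prov["responsibilities"] = gm.predict_proba(pts)
    if len(np.unique(labels)) < 2:
        raise InsufficientDataError("mixture collapsed to a single cluster")
    means = np.vstack([pts[labels == c].mean(axis=0) for c in (0, 1)])
    csum = np.array([table.intensity[labels == c].sum() for c in (0, 1)])
    if np.isclose(csum[0], csum[1]):
        counts = np.bincount(labels, minlength=2)
        brighter = int(np.argmax(counts))
        prov["brightness_tie_broken_by_count"] = True
    else:
        brighter = int(np.argmax(csum))
    return SplitResult(labels=labels, means=means, brighter=brighter,
                       summed_intensity=csum, provenance=prov)


def weighted_moment_ellipse(points: np.ndarray, weights: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intensity-weighted second-moment ellipse of a point cloud.

    Returns (weighted mean, eigenvalues descending, eigenvectors as
    columns matching the eigenvalue order).
    """
    w = weights / weights.sum()
    mu = (points * w[:, None]).sum(axis=0)
    c = points - mu
    cov = (c * w[:, None]).T @ c
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return mu, vals[order], vecs[:, order]


def canonicalize_frame(table: LocalizationTable, split: SplitResult
                       ) -> tuple[LocalizationTable, float, dict]:
    """Translate and rotate a side view into the canonical frame.

    Origin = midpoint of the two cluster centers; X axis = major axis of
    the brighter cluster's intensity-weighted ellipse; the dimmer
    cluster's mean Y is made positive (by rotating a further π when
    needed, keeping the motion rigid).  If the brighter cluster is
    near-isotropic (eigenvalue ratio < 1.05) its axis is uninformative
    and the orientation is taken perpendicular to the inter-center axis,
    flagged in provenance.
    """
    prov: dict = {}
    center = split.means.mean(axis=0)
    bright_mask = split.labels == split.brighter
    _, vals, vecs = weighted_moment_ellipse(table.xy[bright_mask],
                                            table.intensity[bright_mask])
    if vals[1] <= 0 or vals[0] / max(vals[1], 1e-300) >= _ISOTROPY_EIGENRATIO:
        major = vecs[:, 0]
    else:
        d = split.means[1 - split.brighter] - split.means[split.brighter]
        major = np.array([-d[1], d[0]])
        major /= np.linalg.norm(major)
        prov["isotropic_brighter_cluster"] = True
    angle = np.arctan2(major[1], major[0])
    rotation = -angle
    shifted = table.translated(-center[0], -center[1]).rotated(rotation)
    # sign convention: dimmer cluster at +Y
    dim_mask = split.labels == 1 - split.brighter
    if shifted.y[dim_mask].mean() < 0:
        rotation += np.pi
        shifted = shifted.rotated(np.pi)
    prov["center"] = center
    prov["ellipse_eigenvalues"] = vals
    return shifted, float(rotation), prov


def _two_gauss(yv, a1, m1, s1, a2, m2, s2):
    return (a1 * np.exp(-((yv - m1) ** 2) / (2 * s1**2))
            + a2 * np.exp(-((yv - m2) ** 2) / (2 * s2**2)))


def _axis_histogram(values: np.ndarray, weights: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """2 nm histogram on a grid anchored at multiples of 2 nm."""
    lo = np.floor(values.min() / BIN_WIDTH_NM) * BIN_WIDTH_NM
    hi = np.floor(values.max() / BIN_WIDTH_NM) * BIN_WIDTH_NM + BIN_WIDTH_NM
    edges = np.arange(lo, hi + BIN_WIDTH_NM / 2, BIN_WIDTH_NM)
    idx = np.minimum(((values - lo) / BIN_WIDTH_NM).astype(int),
                     edges.size - 2)
    mass = np.bincount(idx, weights=weights, minlength=edges.size - 1)
    return edges, mass


def fit_two_gaussian_histogram(edges: np.ndarray, mass: np.ndarray,
                               mu_init: tuple[float, float]
                               ) -> tuple[tuple, float]:
    """Least-squares sum-of-two-Gaussians fit; returns (params, R²)."""
    centers = edges[:-1] + BIN_WIDTH_NM / 2
    total = mass.sum()
    if total <= 0 or np.count_nonzero(mass) < 6:
        raise InsufficientDataError("histogram too sparse for a two-Gaussian fit")
    s0 = max(float(np.sqrt(np.sum(mass * (centers - np.average(
        centers, weights=mass)) ** 2) / total)) / 2, BIN_WIDTH_NM)
    a0 = float(mass.max())
    last = None
    for m1, m2 in [(mu_init[0], mu_init[1]),
                   (mu_init[0] - s0, mu_init[1] + s0),
                   (np.average(centers, weights=mass) - s0,
                    np.average(centers, weights=mass) + s0)]:
        try:
            popt, _ = curve_fit(
                _two_gauss, centers, mass,
                p0=[a0, m1, s0, a0, m2, s0],
                bounds=([0, -np.inf, 1e-3, 0, -np.inf, 1e-3],
                        [np.inf, np.inf, np.inf, np.inf, np.inf, np.inf]),
                maxfev=20000)
            pred = _two_gauss(centers, *popt)
            ss_res = float(np.sum((mass - pred) ** 2))
            ss_tot = float(np.sum((mass - mass.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
            return tuple(float(p) for p in popt), r2
        except RuntimeError as exc:
            last = exc
    raise FitFailureError(f"two-Gaussian fit did not converge: {last}")


def fit_axial_distance(table: LocalizationTable,
                       split: SplitResult | None = None,
                       rotation: float = 0.0) -> AxialFit:
    """Two-Gaussian axial-distance fit of a canonical side view.

    ``table`` must already be in the canonical frame.  Initial means come
    from the cluster-center Y values when a split is given, else from the
    intensity-weighted means of the y < 0 and y ≥ 0 halves.  The distance
    is |μ₂ − μ₁|; QC passes at R² ≥ 0.7 on the Y histogram.
    """
    y_edges, y_mass = _axis_histogram(table.y, table.intensity)
    x_edges, x_mass = _axis_histogram(table.x, table.intensity)
    if split is not None:
        pts = table.xy
        mu_init = (float(pts[split.labels == 0][:, 1].mean()),
                   float(pts[split.labels == 1][:, 1].mean()))
        means = np.vstack([pts[split.labels == c].mean(axis=0) for c in (0, 1)])
    else:
        neg, pos = table.y < 0, table.y >= 0
        if not (neg.any() and pos.any()):
            m = float(np.average(table.y, weights=table.intensity))
            mu_init = (m - BIN_WIDTH_NM, m + BIN_WIDTH_NM)
        else:
            mu_init = (float(np.average(table.y[neg], weights=table.intensity[neg])),
                       float(np.average(table.y[pos], weights=table.intensity[pos])))
        means = np.array([[0.0, mu_init[0]], [0.0, mu_init[1]]])
    try:
        params, r2 = fit_two_gaussian_histogram(y_edges, y_mass, mu_init)
        dist = abs(params[4] - params[1])
        qc = r2 >= AXIAL_R2_THRESHOLD
        prov = {}
    except (FitFailureError, InsufficientDataError) as exc:
        params, r2, dist, qc = (np.nan,) * 6, -np.inf, np.nan, False
        prov = {"error": str(exc)}
    return AxialFit(component_means=means, rotation=rotation,
                    y_edges=y_edges, y_profile=y_mass,
                    x_edges=x_edges, x_profile=x_mass,
                    gaussian_params=tuple(params), distance=float(dist),
                    r_squared=float(r2), passed_qc=bool(qc),
                    provenance=prov)


def analyze_side_view(table: LocalizationTable, seed: int = 0,
                      n_init: int = 10) -> AxialFit:
    """Full per-dataset chain: split → canonicalize → two-Gaussian fit."""
    split = split_two_clusters(table, seed=seed, n_init=n_init)
    canon, rotation, prov = canonicalize_frame(table, split)
    fit = fit_axial_distance(canon, split=split, rotation=rotation)
    fit.provenance.update(prov)
    return fit


@dataclass
class CohortAxialResult:
    """Averaged side-view cohort: summed profiles, image, cohort fit."""

    y_edges: np.ndarray
    y_profile: np.ndarray            # summed / n_datasets
    x_edges: np.ndarray
    x_profile: np.ndarray
    image: np.ndarray                # outer product of normalized profiles
    summary: AxialFit
    n_datasets: int


def _merge_histograms(edge_list, mass_list):
    lo = min(e[0] for e in edge_list)
    hi = max(e[-1] for e in edge_list)
    edges = np.arange(lo, hi + BIN_WIDTH_NM / 2, BIN_WIDTH_NM)
    total = np.zeros(edges.size - 1)
    for e, m in zip(edge_list, mass_list):
        start = int(round((e[0] - lo) / BIN_WIDTH_NM))
        total[start:start + m.size] += m
    return edges, total


def average_side_views(fits: list[AxialFit]) -> CohortAxialResult:
    """Average a cohort of side views and refit the summed Y distribution.

    Per-axis histograms (all on the 2 nm grid anchored at multiples of
    2 nm in the canonical frame, so bins align) are summed and normalized
    by the number of datasets; the averaged image is the outer product of
    the normalized Y and X distributions; the summed Y distribution is
    refit with two Gaussians for the cohort distance.
    """
    fits = [f for f in fits if f.passed_qc]
    if not fits:
        raise UsageError("average_side_views needs at least one passing fit")
    n = len(fits)
    y_edges, y_total = _merge_histograms([f.y_edges for f in fits],
                                         [f.y_profile for f in fits])
    x_edges, x_total = _merge_histograms([f.x_edges for f in fits],
                                         [f.x_profile for f in fits])
    y_avg, x_avg = y_total / n, x_total / n
    mu_init = (float(np.mean([min(f.gaussian_params[1], f.gaussian_params[4])
                              for f in fits])),
               float(np.mean([max(f.gaussian_params[1], f.gaussian_params[4])
                              for f in fits])))
    params, r2 = fit_two_gaussian_histogram(y_edges, y_avg, mu_init)
    dist = abs(params[4] - params[1])
    summary = AxialFit(
        component_means=np.array([[0.0, params[1]], [0.0, params[4]]]),
        rotation=0.0, y_edges=y_edges, y_profile=y_avg,
        x_edges=x_edges, x_profile=x_avg,
        gaussian_params=params, distance=float(dist), r_squared=float(r2),
        passed_qc=bool(r2 >= AXIAL_R2_THRESHOLD),
        provenance={"n_datasets": n})
    ynorm = y_avg / y_avg.sum() if y_avg.sum() > 0 else y_avg
    xnorm = x_avg / x_avg.sum() if x_avg.sum() > 0 else x_avg
    image = np.outer(ynorm, xnorm)
    return CohortAxialResult(y_edges=y_edges, y_profile=y_avg,
                             x_edges=x_edges, x_profile=x_avg,
                             image=image, summary=summary, n_datasets=n)
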