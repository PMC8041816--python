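"""Shared fixtures and independent oracles for the stormring test suite.

Oracles here are deliberately naive (exhaustive enumeration, grid
refinement, closed forms) and share no code with the implementation
paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from stormring import LocalizationTable, TopViewConfig, generate_top_view
from stormring.simulate import add_decoy_clusters

#: decoy-cluster positions used by the background-removal fixtures:
#: one at the ring center, one in a far corner of the crop, both well
#: away from the ring annulus.
DECOY_POSITIONS = [(0.0, 0.0), (-210.0, 210.0)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def noiseless_ring(n_clusters: int = 9, radius: float = 150.0,
                   center=(0.0, 0.0), intensity: float = 100.0
                   ) -> LocalizationTable:
    """One event per cluster, exactly on the circle, no noise."""
    ang = 2 * np.pi * np.arange(n_clusters) / n_clusters
    return LocalizationTable(center[0] + radius * np.cos(ang),
                             center[1] + radius * np.sin(ang),
                             np.full(n_clusters, intensity))


def blob_ring(seed: int, n_per_cluster: int = 20, spread: float = 8.0,
              radius: float = 150.0, n_clusters: int = 9,
              intensity: float = 100.0) -> LocalizationTable:
    """Nine tight blobs on a circle — a clean, well-separated fixture."""
    r = np.random.default_rng(seed)
    ang = 2 * np.pi * np.arange(n_clusters) / n_clusters
    xs, ys = [], []
    for a in ang:
        xs.append(radius * np.cos(a) + r.normal(0, spread, n_per_cluster))
        ys.append(radius * np.sin(a) + r.normal(0, spread, n_per_cluster))
    x = np.concatenate(xs)
    return LocalizationTable(x, np.concatenate(ys),
                             np.full(x.size, intensity))


def ring_with_decoys(seed: int) -> LocalizationTable:
    """Default synthetic ring (no uniform background) plus two dim decoys."""
    table, _ = generate_top_view(TopViewConfig(seed=seed, background_events=0))
    return add_decoy_clusters(table, DECOY_POSITIONS, seed=seed)


# ----------------------------------------------------------------- oracles

def silhouette_brute_force(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette from the definition: s(i) = (b−a)/max(a,b) with a(i)
    the mean intra-cluster distance and b(i) the smallest mean distance to
    another cluster; singleton clusters score 0."""
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    scores = []
    for i in range(n):
        same = (labels == labels[i])
        n_same = same.sum()
        if n_same == 1:
            scores.append(0.0)
            continue
        a = d[i, same].sum() / (n_same - 1)
        b = min(d[i, labels == c].mean()
                for c in np.unique(labels) if c != labels[i])
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def circle_fit_grid_oracle(points: np.ndarray, levels: int = 6,
                           span: float = 60.0, grid: int = 41
                           ) -> tuple[float, float, float]:
    """Brute-force circle fit: nested grid search of the center minimising
    Σ(dᵢ − mean d)², refined over several zoom levels."""
    cx, cy = points.mean(axis=0)
    for _ in range(levels):
        xs = np.linspace(cx - span, cx + span, grid)
        ys = np.linspace(cy - span, cy + span, grid)
        best = None
        for gx in xs:
            # d shape (grid, n): distances of all points to (gx, ys[j])
            d = np.hypot((points[:, 0] - gx)[None, :],
                         points[:, 1][None, :] - ys[:, None])
            r = d.mean(axis=1)
            cost = ((d - r[:, None]) ** 2).sum(axis=1)
            j = int(np.argmin(cost))
            if best is None or cost[j] < best[0]:
                best = (cost[j], gx, ys[j])
        cx, cy = best[1], best[2]
        span /= grid / 4
    r = float(np.hypot(points[:, 0] - cx, points[:, 1] - cy).mean())
    return float(cx), float(cy), r


def gaussian_partition_loglik(points: np.ndarray, mask: np.ndarray) -> float:
    """Complete-data log-likelihood of a two-cluster Gaussian partition
    with per-cluster MLE mean/full covariance and mixing proportions."""
    n = len(points)
    ll = 0.0
    for sub in (points[mask], points[~mask]):
        m = len(sub)
        if m < 3:
            return -np.inf
        mu = sub.mean(axis=0)
        c = sub - mu
        cov = c.T @ c / m + 1e-9 * np.eye(2)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            return -np.inf
        inv = np.linalg.inv(cov)
        quad = np.einsum("ij,jk,ik->i", c, inv, c).sum()
        ll += -0.5 * (m * (2 * np.log(2 * np.pi) + logdet) + quad)
        ll += m * np.log(m / n)
    return ll


def best_two_cluster_partition(points: np.ndarray) -> np.ndarray:
    """Exhaustive best two-cluster partition under the complete-data
    Gaussian likelihood (for small n only)."""
    n = len(points)
    assert n <= 20
    best_ll, best_mask = -np.inf, None
    for bits in range(1, 2 ** (n - 1)):  # fix point 0's side: halves the work
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        ll = gaussian_partition_loglik(points, mask)
        if ll > best_ll:
            best_ll, best_mask = ll, mask
    return best_mask
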