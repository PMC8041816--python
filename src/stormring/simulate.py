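"""Synthetic SMLM localization data with the structure the analysis assumes.

The generator emulates the acquisitions this pipeline is built for: a
protein decorating the base of a cilium appears in a *top view* as a ring
of ~9 discrete clusters (one per microtubule-doublet-associated docking
site) and in a *side view* as two parallel bars (the target plus a
reference structure at a known axial offset).  Each cluster hosts several
immunolabelled molecules; each fluorophore blinks repeatedly, and each
blink is localized with a 10–30 nm error, so one docking site yields a
small cloud of events with lognormal-like intensities on top of a uniform
background of spurious localizations.

Ground truth (true center, radius, per-fluorophore epitope positions,
event-to-fluorophore assignment) is returned as a sidecar record and is
never written into the molecule list itself, so the analysis cannot
accidentally consume it.

Per-cluster random streams are spawned from the master seed, so deleting
clusters via ``missing_cluster_indices`` leaves every other cluster's
events bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import UsageError, ValidationError
from .io import LocalizationTable
from .linkage import LinkageConfig

__all__ = [
    "TopViewConfig", "SideViewConfig", "LinkageConfig",
    "TopViewTruth", "SideViewTruth",
    "generate_top_view", "generate_side_view", "apply_linkage",
]


@dataclass(frozen=True)
class TopViewConfig:
    """Study conditions for one simulated top-view ring.

    Defaults describe a typical transition-zone protein acquisition:
    nine docking-site clusters on a ~150 nm-radius circle, a handful of
    labelled molecules per site, ~10 blinks per fluorophore, ~10 nm
    localization error and a sparse uniform background.
    """

    n_clusters: int = 9
    ring_radius: float = 150.0           # nm
    cluster_angular_jitter: float = 0.05  # rad, sd around ideal 2πj/n
    fluorophores_per_cluster: int = 5
    cluster_spread: float = 5.0          # nm, sd of fluorophores about site
    blinks_per_fluorophore: float = 10.0  # Poisson mean, floored at 1
    localization_sd: float = 10.0        # nm, isotropic per-blink error
    intensity_log_mean: float = 6.0      # lognormal params (median ≈ 400)
    intensity_log_sd: float = 0.5
    background_events: int = 10
    field_half_width: float = 250.0      # nm (tight crop around one ring)
    missing_cluster_indices: tuple[int, ...] = ()
    seed: int = 0
    exact_blinks: bool = False           # fixed blink count instead of Poisson

    def __post_init__(self):
        bad = []
        if self.n_clusters < 1:
            bad.append("n_clusters")
        if self.ring_radius <= 0:
            bad.append("ring_radius")
        for f in ("cluster_angular_jitter", "cluster_spread",
                  "localization_sd", "intensity_log_sd"):
            if getattr(self, f) < 0:
                bad.append(f)
        if self.fluorophores_per_cluster < 1:
            bad.append("fluorophores_per_cluster")
        if self.blinks_per_fluorophore <= 0:
            bad.append("blinks_per_fluorophore")
        if self.background_events < 0:
            bad.append("background_events")
        if self.field_half_width <= 0:
            bad.append("field_half_width")
        if not set(self.missing_cluster_indices) <= set(range(self.n_clusters)):
            bad.append("missing_cluster_indices")
        if bad:
            raise ValidationError(f"invalid TopViewConfig fields: {bad}", bad)


@dataclass(frozen=True)
class SideViewConfig:
    """Study conditions for one simulated side view: two parallel bars.

    The reference bar (the brighter one, e.g. a nuclear-pore marker used
    as a stipulated reference) sits at −separation/2 along the
    pre-rotation Y axis, the target bar at +separation/2.
    """

    bar_separation: float = 190.0     # nm, true axial distance
    bar_length: float = 300.0         # nm
    bar_thickness_sd: float = 10.0    # nm
    brightness_ratio: float = 2.0     # reference / target total intensity
    events_per_bar: int = 300
    localization_sd: float = 10.0     # nm
    intensity_log_mean: float = 6.0
    intensity_log_sd: float = 0.5
    background_events: int = 20
    rotation: float = 0.0             # rad, applied to the whole scene
    field_half_width: float = 400.0   # nm (background extent)
    seed: int = 0

    def __post_init__(self):
        bad = []
        if self.bar_separation < 0:
            bad.append("bar_separation")
        if self.bar_length <= 0:
            bad.append("bar_length")
        if self.brightness_ratio <= 0:
            bad.append("brightness_ratio")
        if self.events_per_bar < 1:
            bad.append("events_per_bar")
        for f in ("bar_thickness_sd", "localization_sd", "intensity_log_sd"):
            if getattr(self, f) < 0:
                bad.append(f)
        if self.background_events < 0:
            bad.append("background_events")
        if bad:
            raise ValidationError(f"invalid SideViewConfig fields: {bad}", bad)


@dataclass
class TopViewTruth:
    """Sidecar ground truth for a simulated top view."""

    center: tuple[float, float]
    radius: float
    cluster_angles: np.ndarray          # realized angles, per retained cluster
    cluster_centers: np.ndarray         # (n_kept, 2)
    fluorophore_positions: np.ndarray   # (n_fluor, 2) epitope positions
    fluorophore_cluster: np.ndarray     # cluster index per fluorophore
    event_fluorophore: np.ndarray       # fluorophore index per event, −1 = bg
    localization_sd: float

    def to_json(self, path) -> None:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in dataclasses.asdict(self).items()}
        Path(path).write_text(json.dumps(d))


@dataclass
class SideViewTruth:
    """Sidecar ground truth for a simulated side view."""

    bar_separation: float
    rotation: float
    reference_index: int                # 0 = reference bar (brighter)
    event_bar: np.ndarray               # 0/1 per event, −1 = background
    fluorophore_positions: np.ndarray   # (n, 2) true emitter positions
    event_fluorophore: np.ndarray
    localization_sd: float

    def to_json(self, path) -> None:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in dataclasses.asdict(self).items()}
        Path(path).write_text(json.dumps(d))


def _blink_counts(rng: np.random.Generator, mean: float, n: int,
                  exact: bool) -> np.ndarray:
    if exact:
        return np.full(n, int(round(mean)), dtype=int)
    return np.maximum(1, rng.poisson(mean, size=n))


def generate_top_view(config: TopViewConfig
                      ) -> tuple[LocalizationTable, TopViewTruth]:
    """Simulate one top-view ring; returns (molecule list, ground truth).

    Clusters sit at angles 2πj/n plus Gaussian jitter on a circle of the
    configured radius centred at the origin; fluorophores scatter
    isotropically about their cluster center; blink counts are
    max(1, Poisson); each blink adds isotropic Gaussian localization
    error; intensities are lognormal; background events are uniform over
    the square field.  Identical config (incl. seed) gives bit-identical
    output.
    """
    n = config.n_clusters
    streams = np.random.SeedSequence(config.seed).spawn(n + 1)
    keep = [j for j in range(n) if j not in set(config.missing_cluster_indices)]

    xs, ys, inten = [], [], []
    fl_pos, fl_cluster, ev_fl = [], [], []
    angles_kept, centers_kept = [], []
    n_fl_total = 0
    for j in keep:
        rng = np.random.default_rng(streams[j])
        ang = 2 * np.pi * j / n + rng.normal(0.0, config.cluster_angular_jitter)
        cx = config.ring_radius * np.cos(ang)
        cy = config.ring_radius * np.sin(ang)
        angles_kept.append(ang)
        centers_kept.append((cx, cy))
        m = config.fluorophores_per_cluster
        fpos = np.column_stack([cx + rng.normal(0, config.cluster_spread, m),
                                cy + rng.normal(0, config.cluster_spread, m)])
        blinks = _blink_counts(rng, config.blinks_per_fluorophore, m,
                               config.exact_blinks)
        for i in range(m):
            k = blinks[i]
            pts = fpos[i] + rng.normal(0, config.localization_sd, (k, 2))
            xs.append(pts[:, 0]); ys.append(pts[:, 1])
            inten.append(rng.lognormal(config.intensity_log_mean,
                                       config.intensity_log_sd, k))
            ev_fl.append(np.full(k, n_fl_total + i))
        fl_pos.append(fpos)
        fl_cluster.append(np.full(m, j))
        n_fl_total += m

    rng_bg = np.random.default_rng(streams[n])
    nb = config.background_events
    if nb:
        w = config.field_half_width
        xs.append(rng_bg.uniform(-w, w, nb))
        ys.append(rng_bg.uniform(-w, w, nb))
        inten.append(rng_bg.lognormal(config.intensity_log_mean,
                                      config.intensity_log_sd, nb))
        ev_fl.append(np.full(nb, -1))

    table = LocalizationTable(
        np.concatenate(xs), np.concatenate(ys), np.concatenate(inten),
        {"kind": "top_view", "seed": config.seed},
    )
    truth = TopViewTruth(
        center=(0.0, 0.0),
        radius=config.ring_radius,
        cluster_angles=np.array(angles_kept),
        cluster_centers=np.array(centers_kept).reshape(-1, 2),
        fluorophore_positions=(np.vstack(fl_pos) if fl_pos
                               else np.empty((0, 2))),
        fluorophore_cluster=(np.concatenate(fl_cluster) if fl_cluster
                             else np.empty(0, int)),
        event_fluorophore=np.concatenate(ev_fl),
        localization_sd=config.localization_sd,
    )
    return table, truth


def add_decoy_clusters(table: LocalizationTable, positions,
                       events_per_decoy: int = 10,
                       intensity_scale: float = 0.1,
                       spread: float = 5.0, seed: int = 0
                       ) -> LocalizationTable:
    """Append tight, dim decoy clusters (background blobs) to a table.

    Each decoy gets ``events_per_decoy`` events scattered with ``spread``
    nm sd around its position, with intensities scaled down by
    ``intensity_scale`` relative to the table's median event intensity —
    the kind of sparse nonspecific-binding blob the two-dimmest-cluster
    removal rule is meant to absorb.
    """
    rng = np.random.default_rng(seed)
    med = float(np.median(table.intensity))
    xs, ys, ii = [table.x], [table.y], [table.intensity]
    for px, py in positions:
        xs.append(px + rng.normal(0, spread, events_per_decoy))
        ys.append(py + rng.normal(0, spread, events_per_decoy))
        ii.append(np.full(events_per_decoy, intensity_scale * med))
    return LocalizationTable(np.concatenate(xs), np.concatenate(ys),
                             np.concatenate(ii), dict(table.metadata))


def generate_side_view(config: SideViewConfig
                       ) -> tuple[LocalizationTable, SideViewTruth]:
    """Simulate one side view: two parallel bars along X, separated along Y.

    The reference bar carries ``brightness_ratio`` times the target bar's
    intensity in expectation; the whole scene (bars and background) is
    rotated rigidly by ``config.rotation`` about the origin at the end.
    """
    rng = np.random.default_rng(config.seed)
    half_sep = config.bar_separation / 2.0
    n = config.events_per_bar

    def bar(y0: float, scale: float):
        ex = rng.uniform(-config.bar_length / 2, config.bar_length / 2, n)
        ey = y0 + rng.normal(0, config.bar_thickness_sd, n)
        pos = np.column_stack([ex, ey])
        obs = pos + rng.normal(0, config.localization_sd, (n, 2))
        ii = scale * rng.lognormal(config.intensity_log_mean,
                                   config.intensity_log_sd, n)
        return pos, obs, ii

    ref_pos, ref_obs, ref_i = bar(-half_sep, config.brightness_ratio)
    tgt_pos, tgt_obs, tgt_i = bar(+half_sep, 1.0)

    xs = [ref_obs[:, 0], tgt_obs[:, 0]]
    ys = [ref_obs[:, 1], tgt_obs[:, 1]]
    inten = [ref_i, tgt_i]
    bars = [np.zeros(n, int), np.ones(n, int)]
    fl = [np.arange(n), np.arange(n, 2 * n)]
    if config.background_events:
        w = config.field_half_width
        nb = config.background_events
        xs.append(rng.uniform(-w, w, nb))
        ys.append(rng.uniform(-w, w, nb))
        inten.append(rng.lognormal(config.intensity_log_mean,
                                   config.intensity_log_sd, nb))
        bars.append(np.full(nb, -1))
        fl.append(np.full(nb, -1))

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    c, s = np.cos(config.rotation), np.sin(config.rotation)
    xr, yr = c * x - s * y, s * x + c * y
    table = LocalizationTable(xr, yr, np.concatenate(inten),
                              {"kind": "side_view", "seed": config.seed})
    true_pos = np.vstack([ref_pos, tgt_pos])
    true_pos = true_pos @ np.array([[c, s], [-s, c]])  # same rotation
    truth = SideViewTruth(
        bar_separation=config.bar_separation,
        rotation=config.rotation,
        reference_index=0,
        event_bar=np.concatenate(bars),
        fluorophore_positions=true_pos,
        event_fluorophore=np.concatenate(fl),
        localization_sd=config.localization_sd,
    )
    return table, truth


def apply_linkage(table: LocalizationTable, truth: TopViewTruth,
                  config: LinkageConfig, seed: int = 0
                  ) -> tuple[LocalizationTable, TopViewTruth]:
    """Displace labels from epitopes per the coplanar antibody geometry.

    Each fluorophore's epitope is assigned one antibody orientation drawn
    uniformly in the plane.  ``direct`` mode places the label uniformly
    along the primary antibody segment (epitope → epitope + L·ω̂);
    ``indirect`` mode places it at the secondary centroid, L along the
    primary orientation plus ``secondary_offset`` along an independent
    uniform planar orientation.  Blink scatter is re-drawn around the
    displaced label positions; background events are untouched.
    """
    if truth is None or truth.fluorophore_positions.size == 0:
        raise UsageError("apply_linkage requires ground-truth fluorophore positions")
    rng = np.random.default_rng(seed)
    n_fl = truth.fluorophore_positions.shape[0]
    L = config.antibody_length
    theta = rng.uniform(0, 2 * np.pi, n_fl)
    omega = np.column_stack([np.cos(theta), np.sin(theta)])
    if config.mode == "direct":
        d = rng.uniform(0, 1, n_fl)[:, None] * L
        labels = truth.fluorophore_positions + d * omega
    else:
        phi = rng.uniform(0, 2 * np.pi, n_fl)
        omega2 = np.column_stack([np.cos(phi), np.sin(phi)])
        labels = (truth.fluorophore_positions + L * omega
                  + config.secondary_offset * omega2)

    x = table.x.copy()
    y = table.y.copy()
    ev = truth.event_fluorophore
    real = ev >= 0
    k = int(real.sum())
    scatter = rng.normal(0, truth.localization_sd, (k, 2))
    x[real] = labels[ev[real], 0] + scatter[:, 0]
    y[real] = labels[ev[real], 1] + scatter[:, 1]
    meta = dict(table.metadata)
    meta["label_mode"] = config.mode
    out = LocalizationTable(x, y, table.intensity, meta)
    new_truth = dataclasses.replace(truth)
    return out, new_truth
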