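"""End-to-end cohort runs: simulate/load → detect → fit → average → report.

A cohort is a set of structures (top-view rings or side views) analysed
with shared thresholds.  Structure-level failures never abort a cohort:
each excluded structure carries a reason code, and the QC attrition is
first-class output because reported n values reflect exactly this
attrition.  Runs are deterministic given the seeds recorded in the
manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .axial import (AxialFit, average_side_views, analyze_side_view,
                    AXIAL_R2_THRESHOLD)
from .errors import StormringError, ValidationError
from .io import LocalizationTable, read_molecule_list
from .linkage import LinkageConfig, LinkageEstimate, estimate_linkage
from .radial import (RadialProfile, RingFit, average_profiles, fit_radial,
                     radial_profile, RADIAL_R2_THRESHOLD)
from .ring import find_ring_center, CIRCLE_R2_THRESHOLD
from .simulate import (SideViewConfig, TopViewConfig, generate_side_view,
                       generate_top_view)

log = logging.getLogger("stormring")


@dataclass
class RunConfig:
    """Thresholds, ranges and seeds for a cohort run."""

    circle_r2: float = CIRCLE_R2_THRESHOLD
    radial_r2: float = RADIAL_R2_THRESHOLD
    axial_r2: float = AXIAL_R2_THRESHOLD
    k_min: int = 6
    k_max: int = 15
    count_k_min: int = 3
    kmeans_restarts: int = 20
    bin_width: float = 2.0
    seed: int = 0
    review: bool = False

    def __post_init__(self):
        bad = []
        for f in ("circle_r2", "radial_r2", "axial_r2"):
            v = getattr(self, f)
            if not (0 < v <= 1):
                bad.append(f)
        if self.bin_width <= 0:
            bad.append("bin_width")
        if not (1 <= self.k_min <= self.k_max):
            bad.append("k_min/k_max")
        if bad:
            raise ValidationError(f"invalid RunConfig fields: {bad}", bad)


@dataclass
class CohortReport:
    """Per-structure results plus cohort summary for one protein/condition."""

    kind: str                       # "top_view" | "side_view"
    label: str
    per_structure: pd.DataFrame
    n_input: int
    n_passing: int
    attrition: dict[str, int]       # reason code -> count
    mean: float | None              # cohort mean radius or distance, nm
    sem: float | None
    averaged_fit: object | None     # RingFit or AxialFit of the averaged data
    linkage: LinkageEstimate | None = None
    manifest: dict = field(default_factory=dict)


def _sem(values) -> float | None:
    v = np.asarray(values, float)
    if v.size == 0:
        return None
    if v.size == 1:
        return 0.0
    return float(v.std(ddof=1) / math.sqrt(v.size))


def analyze_ring(table: LocalizationTable, config: RunConfig, seed: int
                 ) -> dict:
    """One top-view structure: center, radial profile, ring fit, QC trail."""
    row: dict = {"reason": ""}
    try:
        model, circle = find_ring_center(table, k_min=config.k_min,
                                         k_max=config.k_max, seed=seed,
                                         n_init=config.kmeans_restarts)
    except StormringError as exc:
        row.update(passed=False, reason=f"center_failure:{type(exc).__name__}")
        return row
    row.update(center_x=circle.center[0], center_y=circle.center[1],
               circle_radius=circle.radius, circle_r2=circle.r_squared,
               k_selected=model.k_selected)
    if circle.r_squared <= config.circle_r2:
        row.update(passed=False, reason="circle_r2_below_threshold")
        return row
    profile = radial_profile(table, circle.center)
    try:
        fit = fit_radial(profile, model="best")
    except StormringError as exc:
        row.update(passed=False, reason=f"radial_fit_failure:{type(exc).__name__}")
        return row
    row.update(radius=fit.radius_mean, width=fit.width_sd,
               radial_r2=fit.r_squared, model=fit.model)
    if fit.r_squared < config.radial_r2:
        row.update(passed=False, reason="radial_r2_below_threshold")
        return row
    row.update(passed=True, _profile=profile, _fit=fit)
    return row


def run_top_view_cohort(tables: list[LocalizationTable], config: RunConfig,
                        label: str = "") -> CohortReport:
    """Analyse a cohort of top views and average the passing rings."""
    rows = []
    profiles, fits = [], []
    for i, t in enumerate(tables):
        row = analyze_ring(t, config, seed=config.seed + i)
        row["structure"] = i
        if row.get("passed"):
            profiles.append(row.pop("_profile"))
            fits.append(row.pop("_fit"))
        rows.append(row)
        log.info("ring %d: %s", i,
                 "pass" if row.get("passed") else row["reason"])
    df = pd.DataFrame(rows)
    attrition = (df.loc[~df["passed"].astype(bool), "reason"]
                 .value_counts().to_dict() if len(df) else {})
    averaged_fit = None
    mean = sem = None
    if profiles:
        avg = average_profiles(profiles)
        averaged_fit = fit_radial(avg, model="best")
        radii = [f.radius_mean for f in fits]
        mean, sem = float(np.mean(radii)), _sem(radii)
    return CohortReport(kind="top_view", label=label, per_structure=df,
                        n_input=len(tables), n_passing=len(profiles),
                        attrition=attrition, mean=mean, sem=sem,
                        averaged_fit=averaged_fit)


def run_side_view_cohort(tables: list[LocalizationTable], config: RunConfig,
                         label: str = "") -> CohortReport:
    """Analyse a cohort of side views and average the passing datasets."""
    rows, passing = [], []
    for i, t in enumerate(tables):
        row: dict = {"structure": i, "reason": ""}
        try:
            fit = analyze_side_view(t, seed=config.seed + i)
        except StormringError as exc:
            row.update(passed=False, reason=f"axial_failure:{type(exc).__name__}")
            rows.append(row)
            continue
        row.update(distance=fit.distance, axial_r2=fit.r_squared,
                   rotation=fit.rotation)
        if fit.r_squared < config.axial_r2 or not fit.passed_qc:
            row.update(passed=False, reason="axial_r2_below_threshold")
        else:
            row.update(passed=True)
            passing.append(fit)
        rows.append(row)
    df = pd.DataFrame(rows)
    attrition = (df.loc[~df["passed"].astype(bool), "reason"]
                 .value_counts().to_dict() if len(df) else {})
    mean = sem = None
    summary = None
    if passing:
        cohort = average_side_views(passing)
        summary = cohort.summary
        dists = [f.distance for f in passing]
        mean, sem = float(np.mean(dists)), _sem(dists)
    return CohortReport(kind="side_view", label=label, per_structure=df,
                        n_input=len(tables), n_passing=len(passing),
                        attrition=attrition, mean=mean, sem=sem,
                        averaged_fit=summary)


def simulate_cohort(kind: str, n: int, seed: int, **overrides
                    ) -> list[LocalizationTable]:
    """Generate n structures of the given kind with per-structure seeds."""
    tables = []
    for i in range(n):
        if kind == "top_view":
            cfg = TopViewConfig(seed=seed + i, **overrides)
            tables.append(generate_top_view(cfg)[0])
        elif kind == "side_view":
            cfg = SideViewConfig(seed=seed + i, **overrides)
            tables.append(generate_side_view(cfg)[0])
        else:
            raise ValidationError(f"unknown cohort kind {kind!r}", ["kind"])
    return tables


def run_pipeline(kind: str, config: RunConfig,
                 tables: list[LocalizationTable] | None = None,
                 n_simulated: int = 0, sim_overrides: dict | None = None,
                 label: str = "", out_dir=None) -> CohortReport:
    """One full cohort run with a reproducibility manifest.

    ``tables`` may be provided directly (loaded molecule lists) or
    simulated (``n_simulated`` structures with ``sim_overrides``).
    When ``out_dir`` is given, per-structure tables and the manifest are
    written there as delimited text / JSON.
    """
    if tables is None:
        if n_simulated <= 0:
            raise ValidationError("need input tables or n_simulated > 0",
                                  ["n_simulated"])
        tables = simulate_cohort(kind, n_simulated, config.seed,
                                 **(sim_overrides or {}))
    runner = run_top_view_cohort if kind == "top_view" else run_side_view_cohort
    report = runner(tables, config, label=label)
    cfg_dict = dataclasses.asdict(config)
    manifest = {
        "version": __version__,
        "kind": kind,
        "label": label,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "n_input": report.n_input,
        "n_passing": report.n_passing,
        "attrition": report.attrition,
    }
    report.manifest = manifest
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.per_structure.to_csv(out / f"{label or kind}_structures.tsv",
                                    sep="\t", index=False)
        (out / f"{label or kind}_manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
    return report


def load_cohort(paths, dialect: str = "auto") -> list[LocalizationTable]:
    """Read a list of molecule-list files into tables."""
    return [read_molecule_list(p, dialect=dialect) for p in paths]


def summarize_positions(reports: list[CohortReport],
                        geometry: LinkageConfig = LinkageConfig()
                        ) -> pd.DataFrame:
    """Tidy position table across cohorts, with linkage rows where possible.

    One row per cohort (protein × label mode × measurement axis) with
    mean, SEM and n; when a direct and an indirect cohort share a protein
    label (``"<protein>:direct"`` / ``"<protein>:indirect"``), a linkage
    row with the feasible epitope interval width is appended.
    """
    rows = []
    by_protein: dict[str, dict[str, CohortReport]] = {}
    for r in reports:
        protein, _, mode = r.label.partition(":")
        mode = mode or "direct"
        rows.append({
            "protein": protein, "label_mode": mode,
            "axis": "radial" if r.kind == "top_view" else "axial",
            "mean": r.mean, "sem": r.sem, "n": r.n_passing,
            "row_kind": "position",
        })
        by_protein.setdefault(protein, {})[mode] = r
    for protein, modes in by_protein.items():
        if {"direct", "indirect"} <= set(modes):
            d, i = modes["direct"], modes["indirect"]
            if d.mean is not None and i.mean is not None:
                est = estimate_linkage(i.mean - d.mean, geometry)
                rows.append({
                    "protein": protein, "label_mode": "direct+indirect",
                    "axis": "radial" if d.kind == "top_view" else "axial",
                    "mean": d.mean, "sem": d.sem, "n": d.n_passing,
                    "row_kind": "linkage",
                    "observed_offset": est.observed_offset,
                    "epitope_lo": est.epitope_offset_range[0],
                    "epitope_hi": est.epitope_offset_range[1],
                    "linkage_width": est.width,
                })
    return pd.DataFrame(rows)
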