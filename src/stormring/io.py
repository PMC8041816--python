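"""Reading, writing and cropping of SMLM molecule lists.

A *molecule list* is the tabular output of a single-molecule localization
reconstruction: one row per fluorophore blinking event with planar
coordinates and an event intensity (photon count).  This module isolates
all format concerns — delimiter dialects, vendor column names, pixel-unit
conversion — from the downstream geometry and statistics, which only ever
see an in-memory :class:`LocalizationTable` with coordinates in
nanometres.

Only delimited-text exports are supported.  Vendor binary molecule-list
formats are not parsed; reconstruction software exports text tables and
those are the interchange format here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, UsageError

#: Default physical pixel pitch of the camera, in nm, applied only when a
#: file's column names declare pixel units (e.g. ``"X [px]"``).
DEFAULT_PIXEL_SIZE_NM = 157.646

#: Column-name aliases, matched case-insensitively after stripping unit
#: suffixes.  First match wins; two distinct columns matching the same
#: field is an error.  User maps extend (and override) these.
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "x": ("x", "xc", "x [nm]", "x (nm)", "x_nm", "xnm", "x [px]", "x position"),
    "y": ("y", "yc", "y [nm]", "y (nm)", "y_nm", "ynm", "y [px]", "y position"),
    "intensity": ("intensity", "i", "photons", "photon count", "int",
                  "intensity [photon]", "amplitude", "signal"),
}

_PIXEL_UNIT_TOKENS = ("[px]", "(px)", "pixel", "pixels")


@dataclass
class LocalizationTable:
    """Drift-corrected blinking events for one cropped structure.

    Coordinates are nanometres in a fixed planar frame with y increasing
    upward; the origin is arbitrary (ROI crops record their offset in
    ``metadata`` so absolute positions stay recoverable).  Event order
    carries no meaning: every downstream result is invariant under row
    permutation.
    """

    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (self.x.shape == self.y.shape == self.intensity.shape):
            raise UsageError("x, y and intensity must have identical shapes")
        if self.x.ndim != 1:
            raise UsageError("event arrays must be one-dimensional")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise FormatError("non-finite coordinate in localization table")
        if not np.isfinite(self.intensity).all() or (self.intensity <= 0).any():
            bad = np.flatnonzero(~np.isfinite(self.intensity) | (self.intensity <= 0))
            raise FormatError(
                f"intensity must be strictly positive and finite; offending rows: {bad[:5].tolist()}"
            )

    def __len__(self) -> int:
        return self.x.size

    @property
    def xy(self) -> np.ndarray:
        """Events as an (n, 2) coordinate array."""
        return np.column_stack([self.x, self.y])

    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "intensity": self.intensity})

    def with_events(self, mask_or_index) -> "LocalizationTable":
        """A new table containing the selected events (metadata shared copy)."""
        return LocalizationTable(
            self.x[mask_or_index], self.y[mask_or_index],
            self.intensity[mask_or_index], dict(self.metadata),
        )

    def translated(self, dx: float, dy: float) -> "LocalizationTable":
        return LocalizationTable(self.x + dx, self.y + dy, self.intensity,
                                 dict(self.metadata))

    def rotated(self, angle: float) -> "LocalizationTable":
        """Rigidly rotate all events by ``angle`` radians about the origin."""
        c, s = np.cos(angle), np.sin(angle)
        return LocalizationTable(c * self.x - s * self.y,
                                 s * self.x + c * self.y,
                                 self.intensity, dict(self.metadata))


def _normalize(name: str) -> str:
    return name.strip().lower()


def _resolve_columns(columns: Iterable[str],
                     aliases: Mapping[str, Iterable[str]]) -> dict[str, str]:
    """Map the required fields x/y/intensity onto actual column names."""
    cols = list(columns)
    resolved: dict[str, str] = {}
    for fld, names in aliases.items():
        wanted = [_normalize(n) for n in names]
        matches = [c for c in cols if _normalize(c) in wanted]
        if len(matches) > 1:
            raise FormatError(
                f"ambiguous columns for field '{fld}': {matches}"
            )
        if matches:
            resolved[fld] = matches[0]
    for fld in ("x", "y", "intensity"):
        if fld not in resolved:
            raise FormatError(
                f"required column '{fld}' not found among {cols}"
            )
    return resolved


def _is_pixel_column(name: str) -> bool:
    n = _normalize(name)
    return any(tok in n for tok in _PIXEL_UNIT_TOKENS)


def read_molecule_list(path, dialect: str = "auto",
                       aliases: Mapping[str, Iterable[str]] | None = None,
                       pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
                       ) -> LocalizationTable:
    """Read a delimited-text molecule list into a :class:`LocalizationTable`.

    Parameters
    ----------
    path
        Text file with a header row and at least columns interpretable as
        x, y and intensity (see :data:`DEFAULT_ALIASES`).
    dialect
        ``"tab"``, ``"comma"`` or ``"auto"`` (sniff from the header line).
    aliases
        Extra column aliases merged over the defaults, e.g.
        ``{"x": ["Pos_X"]}``.
    pixel_size_nm
        Scale factor applied to coordinate columns whose *names* declare
        pixel units; nm columns pass through untouched.

    Leading ``#``-prefixed lines are treated as ``key=value`` metadata.
    Unknown extra columns (frame, z, width, ...) are recorded in
    ``metadata["extra_columns"]`` and otherwise ignored.
    """
    path = Path(path)
    if dialect not in ("auto", "tab", "comma"):
        raise UsageError(f"unknown dialect {dialect!r}")
    meta: dict = {"source": str(path)}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                k, _, v = stripped.partition("=")
                meta[k.strip()] = v.strip()
        else:
            break
    if body_start >= len(lines):
        raise EmptyInputError(f"{path}: no header row")
    header = lines[body_start]
    if dialect == "auto":
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header \
            else ","
        if "\t" not in header and "," not in header:
            sep = r"\s+"
    else:
        sep = "\t" if dialect == "tab" else ","
    try:
        if sep in ("\t", ","):
            df = pd.read_csv(path, sep=sep, comment="#",
                             float_precision="round_trip")
        else:
            df = pd.read_csv(path, sep=sep, comment="#", engine="python")
    except Exception as exc:  # noqa: BLE001 — surface as a format error
        raise FormatError(f"{path}: cannot parse as delimited text: {exc}") from exc
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: header present but zero data rows")

    full_aliases = {k: tuple(v) for k, v in DEFAULT_ALIASES.items()}
    if aliases:
        for k, v in aliases.items():
            full_aliases[k] = tuple(v) + full_aliases.get(k, ())
    resolved = _resolve_columns(df.columns, full_aliases)

    def _col(fld: str) -> np.ndarray:
        raw = pd.to_numeric(df[resolved[fld]], errors="coerce").to_numpy(float)
        if np.isnan(raw).any():
            row = int(np.flatnonzero(np.isnan(raw))[0])
            raise FormatError(
                f"{path}: column '{resolved[fld]}' unparseable at data row {row}"
            )
        return raw

    x, y, inten = _col("x"), _col("y"), _col("intensity")
    if _is_pixel_column(resolved["x"]) or _is_pixel_column(resolved["y"]):
        # column names declare pixel units -> convert to nm
        meta["applied_pixel_size_nm"] = pixel_size_nm
        x = x * pixel_size_nm
        y = y * pixel_size_nm
    bad = np.flatnonzero(~np.isfinite(inten) | (inten <= 0))
    if bad.size:
        raise FormatError(
            f"{path}: non-positive intensity at data row {int(bad[0])}"
        )
    extra = [c for c in df.columns if c not in resolved.values()]
    if extra:
        meta["extra_columns"] = extra
    return LocalizationTable(x, y, inten, meta)


def write_molecule_list(table: LocalizationTable, path) -> None:
    """Write a molecule list as tab-separated text with a metadata header.

    Numeric values use shortest round-trip ``repr`` so that
    ``read_molecule_list(write_molecule_list(t))`` reproduces x, y and
    intensity bit-exactly.
    """
    if len(table) == 0:
        raise EmptyInputError("refusing to write an empty molecule list")
    path = Path(path)
    scalar_meta = {k: v for k, v in table.metadata.items()
                   if isinstance(v, (str, int, float, bool))}
    try:
        with open(path, "w") as fh:
            for k, v in scalar_meta.items():
                fh.write(f"# {k}={v}\n")
            fh.write("x\ty\tintensity\n")
            for xi, yi, ii in zip(table.x, table.y, table.intensity):
                fh.write(f"{float(xi)!r}\t{float(yi)!r}\t{float(ii)!r}\n")
    except OSError as exc:
        raise OSError(f"cannot write molecule list to {path}: {exc}") from exc


def crop_roi(table: LocalizationTable, center: tuple[float, float],
             half_width: float) -> LocalizationTable:
    """Select events in the closed axis-aligned square ROI around ``center``.

    Events with ``|x - cx| <= half_width`` and ``|y - cy| <= half_width``
    (closed interval: boundary events are kept) are returned with the ROI
    offset recorded in metadata.
    """
    if half_width <= 0:
        raise UsageError("half_width must be positive")
    cx, cy = float(center[0]), float(center[1])
    mask = (np.abs(table.x - cx) <= half_width) & (np.abs(table.y - cy) <= half_width)
    if not mask.any():
        raise EmptyInputError("ROI contains no events")
    out = table.with_events(mask)
    out.metadata["roi_center_x"] = cx
    out.metadata["roi_center_y"] = cy
    out.metadata["roi_half_width"] = float(half_width)
    return out
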