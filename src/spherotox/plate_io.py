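"""Plate layouts, acquisition manifests, calibration and measurement tables.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)`` with the origin at the top-left;
* well labels are row-letter + 1-based column number (``"A1"`` .. ``"H12"`` on a
  standard 96-well plate);
* time is minutes since compound addition / magnet removal, with t = 0 at the
  first captured frame;
* image intensities are floats in [0, 1] (integer images are rescaled by their
  dtype maximum, RGB is converted to Rec. 709 luminance).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    LayoutError,
    ManifestError,
    ValidationError,
)

ROLES = frozenset(
    {"treatment", "vehicle", "positive_control", "negative_control", "empty"}
)

#: Rec. 709 luminance weights used to collapse RGB frames to grayscale.
LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])

LAYOUT_COLUMNS = ["well", "compound", "concentration_uM", "role", "replicate"]

MEASUREMENT_COLUMNS = [
    "well",
    "time_min",
    "area_px2",
    "area_mm2",
    "centroid_row",
    "centroid_col",
    "circularity",
    "qc_flags",
]


def well_name(row: int, col: int) -> str:
    """0-based grid indices -> well label, e.g. ``(1, 1)`` -> ``"B2"``."""
    if row < 0 or col < 0:
        raise ValidationError(f"negative grid index ({row}, {col})")
    letters = ""
    r = row
    while True:
        letters = chr(ord("A") + r % 26) + letters
        r = r // 26 - 1
        if r < 0:
            break
    return f"{letters}{col + 1}"


def parse_well(name: str) -> tuple[int, int]:
    """Well label -> 0-based ``(row, col)``, e.g. ``"B2"`` -> ``(1, 1)``."""
    s = name.strip().upper()
    i = 0
    while i < len(s) and s[i].isalpha():
        i += 1
    if i == 0 or i == len(s) or not s[i:].isdigit():
        raise ValidationError(f"cannot parse well name {name!r}")
    row = 0
    for ch in s[:i]:
        row = row * 26 + (ord(ch) - ord("A") + 1)
    return row - 1, int(s[i:]) - 1


@dataclass(frozen=True)
class WellSpec:
    """One well's assignment: compound, dose, role and replicate index."""

    name: str
    row: int
    col: int
    compound: str | None
    concentration_um: float
    role: str
    replicate: int
    solvent: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"well {self.name}: unknown role {self.role!r} (expected one of {sorted(ROLES)})"
            )
        if not np.isfinite(self.concentration_um) or self.concentration_um < 0:
            raise ValidationError(
                f"well {self.name}: concentration must be finite and >= 0, got {self.concentration_um}"
            )
        if self.role == "vehicle" and self.concentration_um != 0:
            raise ValidationError(
                f"well {self.name}: vehicle wells must have concentration 0, got {self.concentration_um}"
            )
        if self.role == "empty" and self.compound is not None:
            raise ValidationError(
                f"well {self.name}: empty wells must have no compound, got {self.compound!r}"
            )
        if (self.row, self.col) != parse_well(self.name):
            raise ValidationError(
                f"well {self.name}: grid indices ({self.row}, {self.col}) do not match the label"
            )


@dataclass(frozen=True)
class PlateLayout:
    """A validated well -> (compound, concentration, role, replicate) map."""

    wells: tuple[WellSpec, ...]
    n_rows: int = 8
    n_cols: int = 12

    def __post_init__(self) -> None:
        names = [w.name for w in self.wells]
        seen: set[str] = set()
        for n in names:
            if n in seen:
                raise LayoutError(f"duplicate well name {n!r}")
            seen.add(n)
        for w in self.wells:
            if not (0 <= w.row < self.n_rows and 0 <= w.col < self.n_cols):
                raise LayoutError(
                    f"well {w.name} at ({w.row}, {w.col}) outside the "
                    f"{self.n_rows}x{self.n_cols} grid"
                )

    def __len__(self) -> int:
        return len(self.wells)

    def well(self, name: str) -> WellSpec:
        for w in self.wells:
            if w.name == name:
                return w
        raise KeyError(name)

    def non_empty_wells(self) -> tuple[WellSpec, ...]:
        return tuple(w for w in self.wells if w.role != "empty")

    def vehicle_wells(self, solvent: str | None = ...) -> tuple[WellSpec, ...]:
        """Vehicle wells, optionally restricted to one solvent group.

        Passing ``solvent=None`` selects vehicles with no solvent annotation;
        the default (no argument) returns all vehicle wells.
        """
        wells = tuple(w for w in self.wells if w.role == "vehicle")
        if solvent is ...:
            return wells
        return tuple(w for w in wells if w.solvent == solvent)

    def compounds(self) -> tuple[str, ...]:
        """Distinct compound names over non-vehicle, non-empty wells, sorted."""
        return tuple(
            sorted(
                {
                    w.compound
                    for w in self.wells
                    if w.compound is not None and w.role not in ("vehicle", "empty")
                }
            )
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "well": w.name,
                "compound": w.compound if w.compound is not None else "",
                "concentration_uM": w.concentration_um,
                "role": w.role,
                "replicate": w.replicate,
                "solvent": w.solvent if w.solvent is not None else "",
            }
            for w in self.wells
        ]
        return pd.DataFrame(rows, columns=LAYOUT_COLUMNS + ["solvent"])


@dataclass(frozen=True)
class Calibration:
    """Pixel scale and well-grid geometry.

    ``grid_origin`` is the (row_px, col_px) center of well A1; ``grid_pitch``
    the spacing between adjacent well centers; ``well_radius_px`` the radius of
    the circular analysis region around each well center.
    """

    mm_per_px: float
    grid_origin: tuple[float, float]
    grid_pitch: tuple[float, float]
    well_radius_px: float

    def __post_init__(self) -> None:
        vals = (
            self.mm_per_px,
            *self.grid_origin,
            *self.grid_pitch,
            self.well_radius_px,
        )
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise ValidationError("all calibration values must be finite and > 0")

    def well_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.grid_origin[0] + row * self.grid_pitch[0],
            self.grid_origin[1] + col * self.grid_pitch[1],
        )

    def area_px2_to_mm2(self, area_px2: float) -> float:
        return area_px2 * self.mm_per_px**2


@dataclass
class ImageFrame:
    """A single grayscale plate image with its acquisition time."""

    pixels: np.ndarray
    time_min: float
    frame_id: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValidationError("frame pixels must be a 2D grayscale array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("frame pixels must be finite")
        if self.time_min < 0:
            raise ValidationError("frame time must be non-negative")


@dataclass(frozen=True)
class FrameRef:
    """Lazy reference to an on-disk frame; ``load()`` reads and normalizes it."""

    path: Path
    time_min: float
    frame_id: int

    def load(self) -> ImageFrame:
        return ImageFrame(read_image(self.path), self.time_min, self.frame_id)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as a float32 grayscale array in [0, 1].

    RGB(A) inputs are converted to luminance; integer images are rescaled by
    their dtype maximum.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / undecodable file
        raise OSError(f"cannot read image {path.name}: {exc}") from exc
    if arr.dtype.kind in "ui":
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ LUMA_WEIGHTS
    return np.clip(arr.astype(np.float32), 0.0, 1.0)


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image as 8-bit PNG/TIFF (by extension)."""
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# layout I/O


def _parse_optional(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def load_layout(path: str | Path) -> PlateLayout:
    """Read a plate-layout CSV.

    Required columns: ``well, compound, concentration_uM, role, replicate``;
    an optional ``solvent`` column assigns vehicle groups for per-solvent
    normalization. Roles are parsed case-insensitively.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise LayoutError(f"{path.name}: missing layout columns {missing}")
    wells = []
    for rec in df.to_dict("records"):
        name = str(rec["well"]).strip()
        row, col = parse_well(name)
        role = str(rec["role"]).strip().lower()
        conc = rec["concentration_uM"]
        conc = 0.0 if _parse_optional(conc) is None else float(conc)
        rep = rec["replicate"]
        wells.append(
            WellSpec(
                name=well_name(row, col),
                row=row,
                col=col,
                compound=_parse_optional(rec["compound"]),
                concentration_um=conc,
                role=role,
                replicate=1 if _parse_optional(rep) is None else int(rep),
                solvent=_parse_optional(rec.get("solvent")),
            )
        )
    return PlateLayout(wells=tuple(wells))


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    layout.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# manifest I/O


def load_manifest(path: str | Path, image_dir: str | Path) -> list[FrameRef]:
    """Read an acquisition manifest (CSV: ``filename,time_min``).

    Frames are returned sorted by acquisition time with sequential frame ids,
    independent of the row or filename order. Duplicate filenames, duplicate
    or negative times, and missing image files are rejected.
    """
    path = Path(path)
    image_dir = Path(image_dir)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("filename", "time_min"):
        if col not in df.columns:
            raise ManifestError(f"{path.name}: missing manifest column {col!r}")
    names = df["filename"].astype(str)
    if names.duplicated().any():
        dup = names[names.duplicated()].iloc[0]
        raise ManifestError(f"{path.name}: duplicate filename {dup!r}")
    times = df["time_min"].astype(float)
    if not np.all(np.isfinite(times)) or (times < 0).any():
        raise ManifestError(f"{path.name}: times must be finite and non-negative")
    if times.duplicated().any():
        t = float(times[times.duplicated()].iloc[0])
        raise ManifestError(
            f"{path.name}: non-monotone timestamps (time {t} min occurs twice)"
        )
    order = np.argsort(times.to_numpy(), kind="stable")
    refs = []
    for fid, idx in enumerate(order):
        fpath = image_dir / names.iloc[idx]
        if not fpath.is_file():
            raise OSError(f"manifest {path.name}: image file not found: {fpath}")
        refs.append(FrameRef(path=fpath, time_min=float(times.iloc[idx]), frame_id=fid))
    return refs


def write_manifest(entries: Iterable[tuple[str, float]], path: str | Path) -> None:
    """Write ``(filename, time_min)`` pairs as a manifest CSV."""
    df = pd.DataFrame(list(entries), columns=["filename", "time_min"])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# calibration I/O (TOML)


def load_calibration(path: str | Path) -> Calibration:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    try:
        return Calibration(
            mm_per_px=float(data["mm_per_px"]),
            grid_origin=(float(data["grid_origin_row_px"]), float(data["grid_origin_col_px"])),
            grid_pitch=(float(data["grid_pitch_row_px"]), float(data["grid_pitch_col_px"])),
            well_radius_px=float(data["well_radius_px"]),
        )
    except KeyError as exc:
        raise CalibrationError(f"calibration file missing key {exc}") from exc


def write_calibration(calib: Calibration, path: str | Path) -> None:
    text = (
        f"mm_per_px = {calib.mm_per_px!r}\n"
        f"grid_origin_row_px = {calib.grid_origin[0]!r}\n"
        f"grid_origin_col_px = {calib.grid_origin[1]!r}\n"
        f"grid_pitch_row_px = {calib.grid_pitch[0]!r}\n"
        f"grid_pitch_col_px = {calib.grid_pitch[1]!r}\n"
        f"well_radius_px = {calib.well_radius_px!r}\n"
    )
    Path(path).write_text(text)


# ---------------------------------------------------------------------------
# measurement tables


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-(well, frame) measurement table with the fixed header.

    Floats round-trip losslessly (written at full repr precision).
    """
    df = table.reindex(columns=MEASUREMENT_COLUMNS)
    df.to_csv(path, index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"well": str, "qc_flags": str},
        keep_default_na=True,
        float_precision="round_trip",
    )
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"measurement table missing columns {missing}")
    df["qc_flags"] = df["qc_flags"].fillna("")
    return df[MEASUREMENT_COLUMNS]
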