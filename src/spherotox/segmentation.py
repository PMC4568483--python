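"""Per-well spheroid segmentation and projected-area measurement.

Well regions are located purely geometrically from the calibration grid (the
plate is imaged whole and does not move); within each circular region of
interest (ROI) the dark spheroid is segmented by Otsu thresholding with a
contrast floor, cleaned by a radius-1 morphological opening and hole filling,
and the largest 8-connected component is reported as the spheroid.

Degenerate well content never raises: an empty or unreadably faint well
yields area 0 with ``no_object`` (plus ``low_contrast`` where thresholding
found only a weak class), so a single bad well cannot abort a plate run.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import perimeter as skimage_perimeter

from .errors import CalibrationError, InputError
from .plate_io import (
    Calibration,
    FrameRef,
    ImageFrame,
    PlateLayout,
    MEASUREMENT_COLUMNS,
)

QC_NO_OBJECT = "no_object"
QC_LOW_CONTRAST = "low_contrast"
QC_MULTI_OBJECT = "multi_object"
QC_TOUCHES_BOUNDARY = "touches_roi_boundary"

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity
_OPEN_FOOTPRINT = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)  # radius-1 disk


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the per-ROI segmentation.

    ``contrast_floor``: minimum (background − foreground-mean) intensity
    separation for a detection to be accepted; guards empty wells where Otsu
    would split noise. ``annulus_fraction``: outer fraction of the ROI radius
    used for background estimation. ``min_object_px``: components smaller than
    this are ignored when deciding ``multi_object``.
    """

    contrast_floor: float = 0.05
    annulus_fraction: float = 0.2
    opening_radius: int = 1
    min_object_px: int = 4


@dataclass(frozen=True)
class WellROI:
    """Circular analysis region of one well."""

    well: str
    center: tuple[float, float]
    radius_px: float


@dataclass(frozen=True)
class SpheroidMeasurement:
    """Projected-area measurement of one well in one frame."""

    well: str
    time_min: float
    area_px2: int
    area_mm2: float
    centroid: tuple[float, float] | None
    circularity: float | None
    qc_flags: frozenset[str]

    def to_row(self) -> dict:
        return {
            "well": self.well,
            "time_min": self.time_min,
            "area_px2": self.area_px2,
            "area_mm2": self.area_mm2,
            "centroid_row": self.centroid[0] if self.centroid else np.nan,
            "centroid_col": self.centroid[1] if self.centroid else np.nan,
            "circularity": self.circularity if self.circularity is not None else np.nan,
            "qc_flags": ";".join(sorted(self.qc_flags)),
        }


def locate_wells(
    frame_shape: tuple[int, int],
    layout: PlateLayout,
    calib: Calibration,
) -> list[WellROI]:
    """Geometric ROIs for every non-empty layout well.

    Raises :class:`CalibrationError` naming the first well whose ROI disk
    falls outside the frame.
    """
    rois = []
    for well in sorted(layout.non_empty_wells(), key=lambda w: (w.row, w.col)):
        cr, cc = calib.well_center(well.row, well.col)
        r = calib.well_radius_px
        if cr - r < 0 or cc - r < 0 or cr + r > frame_shape[0] - 1 or cc + r > frame_shape[1] - 1:
            raise CalibrationError(
                f"well {well.name}: ROI (center ({cr:.1f}, {cc:.1f}), radius {r}) "
                f"outside frame of shape {frame_shape}"
            )
        rois.append(WellROI(well=well.name, center=(cr, cc), radius_px=r))
    return rois


@lru_cache(maxsize=32)
def _roi_masks(radius_int: int, annulus_fraction: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disk mask, background annulus mask and boundary-ring mask for one radius."""
    n = radius_int
    rr, cc = np.mgrid[-n : n + 1, -n : n + 1]
    d2 = rr * rr + cc * cc
    disk = d2 <= n * n
    annulus = disk & (d2 >= ((1.0 - annulus_fraction) * n) ** 2)
    boundary = disk & (d2 >= (n - 1.5) ** 2)
    return disk, annulus, boundary


def segment_spheroid(
    frame: ImageFrame,
    roi: WellROI,
    cfg: SegmentationConfig | None = None,
    mm_per_px: float = 1.0,
) -> SpheroidMeasurement:
    """Segment the dark spheroid within one well ROI.

    Background is the median of the ROI's outer annulus (robust to smooth
    illumination gradients); candidate pixels are those below the Otsu
    threshold of the ROI-disk intensities, accepted only if their mean is at
    least ``contrast_floor`` darker than the background. Cleanup is a radius-1
    opening followed by hole filling; the largest 8-connected component is
    the spheroid (ties broken by darker mean intensity, then by smaller
    centroid row/col).
    """
    if cfg is None:
        cfg = SegmentationConfig()
    n = int(round(roi.radius_px))
    disk, annulus, boundary_ring = _roi_masks(n, cfg.annulus_fraction)
    cr, cc = int(round(roi.center[0])), int(round(roi.center[1]))
    patch = frame.pixels[cr - n : cr + n + 1, cc - n : cc + n + 1].astype(np.float64)

    def empty(flags: frozenset[str]) -> SpheroidMeasurement:
        return SpheroidMeasurement(
            well=roi.well,
            time_min=frame.time_min,
            area_px2=0,
            area_mm2=0.0,
            centroid=None,
            circularity=None,
            qc_flags=flags,
        )

    vals = patch[disk]
    background = float(np.median(patch[annulus]))
    if np.ptp(vals) == 0:  # uniform ROI: nothing to threshold
        return empty(frozenset({QC_NO_OBJECT}))
    thr = threshold_otsu(vals)
    fg = disk & (patch < thr)
    if not fg.any():
        return empty(frozenset({QC_NO_OBJECT}))
    if background - float(patch[fg].mean()) < cfg.contrast_floor:
        return empty(frozenset({QC_NO_OBJECT, QC_LOW_CONTRAST}))

    if cfg.opening_radius > 0:
        fg = ndimage.binary_opening(fg, structure=_OPEN_FOOTPRINT, iterations=cfg.opening_radius)
    fg = ndimage.binary_fill_holes(fg)
    labels, n_lab = ndimage.label(fg, structure=_STRUCT8)
    if n_lab == 0:
        return empty(frozenset({QC_NO_OBJECT}))

    sizes = np.bincount(labels.ravel())[1:]
    best = _pick_largest(labels, n_lab, sizes, patch)
    comp = labels == best

    flags = set()
    if np.count_nonzero(sizes >= cfg.min_object_px) > 1:
        flags.add(QC_MULTI_OBJECT)
    if (comp & boundary_ring).any():
        flags.add(QC_TOUCHES_BOUNDARY)

    area = int(comp.sum())
    rows, cols = np.nonzero(comp)
    centroid = (float(rows.mean()) + cr - n, float(cols.mean()) + cc - n)
    perim = skimage_perimeter(comp, neighborhood=4)
    circ = min(1.0, 4.0 * np.pi * area / perim**2) if perim > 0 else 1.0
    return SpheroidMeasurement(
        well=roi.well,
        time_min=frame.time_min,
        area_px2=area,
        area_mm2=area * mm_per_px**2,
        centroid=centroid,
        circularity=circ,
        qc_flags=frozenset(flags),
    )


def _pick_largest(
    labels: np.ndarray, n_lab: int, sizes: np.ndarray, patch: np.ndarray
) -> int:
    """Largest component label; ties → darker mean, then smaller centroid."""
    max_size = sizes.max()
    cands = [i + 1 for i in range(n_lab) if sizes[i] == max_size]
    if len(cands) == 1:
        return cands[0]

    def key(lab: int):
        mask = labels == lab
        rows, cols = np.nonzero(mask)
        return (float(patch[mask].mean()), float(rows.mean()), float(cols.mean()))

    return min(cands, key=key)


def measure_plate(
    frames: Iterable[ImageFrame | FrameRef],
    layout: PlateLayout,
    calib: Calibration,
    cfg: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Measure every (non-empty well, frame) pair of a plate sequence.

    Accepts loaded frames or lazy :class:`FrameRef` (loaded one at a time).
    The output table is ordered by (well, time) and is deterministic and
    independent of the input frame order.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    rows: list[dict] = []
    shape: tuple[int, int] | None = None
    rois: list[WellROI] | None = None
    for item in frames:
        frame = item.load() if isinstance(item, FrameRef) else item
        if shape is None:
            shape = frame.pixels.shape
            rois = locate_wells(shape, layout, calib)
        elif frame.pixels.shape != shape:
            raise InputError(
                f"frame {frame.frame_id} shape {frame.pixels.shape} differs from {shape}"
            )
        for roi in rois:
            rows.append(segment_spheroid(frame, roi, cfg, calib.mm_per_px).to_row())
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    well_order = [r.well for r in (rois or [])]
    df["well"] = pd.Categorical(df["well"], categories=well_order, ordered=True)
    df = df.sort_values(["well", "time_min"], kind="stable").reset_index(drop=True)
    df["well"] = df["well"].astype(str)
    return df
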