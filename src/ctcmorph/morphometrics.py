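"""Calibrated per-cell metrics: diameter, N/C ratio, nuclear-size QC, records.

Pixel areas become micrometer diameters through the equivalent-circle
convention d = 2*sqrt(A/pi) and a pixel-to-micrometer conversion factor
calibrated against reference diameters measured on a separate instrument
for the same cell population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import segmentation as seg
from .ellipse import (elongation_factor, fit_best_ellipse, fit_moments_ellipse,
                      preprocess_for_contour, trace_longest_contour)
from .errors import (CalibrationError, ContourError, DegenerateImageError,
                     EllipseFitError, InvalidGeometryError)
from .io import CellTile

QC_ACCEPTED = "accepted"
QC_REJECTED = "rejected"

#: Rejection reasons, in the order the rules are checked. A rejected record
#: carries exactly one primary reason: the first failing rule.
REASONS = ("none", "empty", "border_touch", "multi_particle",
           "nuclear_gt_95pct", "no_contour", "fit_failed")


@dataclass
class CalibrationFactor:
    """Micrometers per pixel plus the provenance of the reference."""

    um_per_px: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.um_per_px) and self.um_per_px > 0):
            raise CalibrationError(f"um_per_px must be finite and > 0, "
                                   f"got {self.um_per_px}")


def calibration_factor(ref_diameters_um: Iterable[float],
                       pixel_areas: Iterable[float],
                       source: str = "") -> CalibrationFactor:
    """Pixel-to-micrometer factor from reference diameters and pixel areas.

    The same cell population is measured twice: true diameters in
    micrometers on a reference instrument, and areas in px^2 on gallery
    images. The factor is the ratio of the mean reference diameter to the
    mean equivalent-circle diameter in pixels::

        um_per_px = mean(d_ref) / mean(2*sqrt(A/pi))
    """
    refs = np.asarray(list(ref_diameters_um), dtype=float)
    areas = np.asarray(list(pixel_areas), dtype=float)
    if refs.size == 0 or areas.size == 0:
        raise CalibrationError("calibration needs nonempty references and areas")
    if (refs <= 0).any() or (areas <= 0).any():
        raise CalibrationError("calibration inputs must be positive")
    mean_px_diameter = float(np.mean(2.0 * np.sqrt(areas / math.pi)))
    return CalibrationFactor(um_per_px=float(refs.mean()) / mean_px_diameter,
                             source=source)


def equivalent_diameter(area_px: float, cal: CalibrationFactor) -> float:
    """Equivalent-circle diameter in micrometers: d = k * 2*sqrt(A/pi)."""
    if area_px <= 0:
        raise InvalidGeometryError("equivalent diameter undefined for area <= 0")
    return cal.um_per_px * 2.0 * math.sqrt(area_px / math.pi)


def nc_ratio(a_nuc_px: float, a_cell_px: float) -> float:
    """Nuclear:cytoplasmic ratio A_N / (A_cell - A_N).

    The cytoplasmic area is the cell area excluding the nucleus, so the
    ratio legitimately exceeds 1 when the nucleus covers more than half the
    cell.
    """
    if not (0 < a_nuc_px < a_cell_px):
        raise InvalidGeometryError(
            f"need 0 < nuclear area < cell area, got {a_nuc_px} vs {a_cell_px}")
    return a_nuc_px / (a_cell_px - a_nuc_px)


def nuclear_size_qc(a_nuc_px: float, a_cell_px: float,
                    max_fraction: float = 0.95) -> bool:
    """True (pass) unless the nuclear area *exceeds* 95% of the cell area.

    The boundary case A_N == 0.95 * A_cell passes (strict inequality).
    """
    return not (a_nuc_px > max_fraction * a_cell_px)


@dataclass
class CellMorphology:
    """Per-cell morphology record; rejected cells keep NaN metric fields."""

    tile_id: str
    sample_id: str = ""
    group: str = "unknown"
    a_cell_px: int = 0
    a_nuc_px: int = 0
    diameter_um: float = math.nan
    nuc_diameter_um: float = math.nan
    nc_ratio: float = math.nan
    ef: float = math.nan
    qc_status: str = QC_REJECTED
    qc_reason: str = "none"
    timepoint_h: float | None = None
    flags: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "tile_id": self.tile_id, "sample_id": self.sample_id,
            "group": self.group, "a_cell_px": self.a_cell_px,
            "a_nuc_px": self.a_nuc_px, "diameter_um": self.diameter_um,
            "nuc_diameter_um": self.nuc_diameter_um, "nc_ratio": self.nc_ratio,
            "ef": self.ef, "qc_status": self.qc_status,
            "qc_reason": self.qc_reason, "timepoint_h": self.timepoint_h,
        }


def _primary_reason(flags: set[str]) -> str | None:
    """Map segmentation flags to the first failing QC rule (documented order)."""
    if seg.FLAG_EMPTY in flags or seg.FLAG_DEBRIS in flags:
        return "empty"
    if seg.FLAG_BORDER in flags:
        return "border_touch"
    if seg.FLAG_MULTI in flags:
        return "multi_particle"
    return None


def _measure_ef(tile: CellTile, cfg: dict) -> float:
    ecfg = cfg["ellipse"]
    mask = preprocess_for_contour(
        tile.channel("ck"), percentiles=tuple(ecfg["stretch_percentiles"]),
        smooth=ecfg["smooth_mask"], erosions=ecfg["smooth_erosions"],
        dilations=ecfg["smooth_dilations"])
    contour = trace_longest_contour(mask, min_points=ecfg["min_contour_points"])
    if ecfg["fit_method"] == "moments":
        lab = seg.label_particles(mask)
        sizes = lab.counts[1:]
        fit = fit_moments_ellipse(lab.particle_mask(int(np.argmax(sizes)) + 1))
    else:
        # traced boundary pixel centers sit ~0.5 px inside the true outline
        fit = fit_best_ellipse(contour, boundary_offset=0.5)
    return elongation_factor(fit)


def process_tile(tile: CellTile, cal: CalibrationFactor,
                 cfg: dict) -> CellMorphology:
    """Full per-tile measurement with ordered QC.

    QC rules are applied in a fixed order so the primary rejection reason is
    deterministic: empty -> border_touch -> multi_particle ->
    nuclear_gt_95pct -> no_contour/fit_failed. Per-tile quality failures
    never raise; only configuration errors do.
    """
    rec = CellMorphology(tile_id=tile.tile_id, sample_id=tile.sample_id,
                         group=tile.group, timepoint_h=tile.timepoint_h)
    sr = seg.segment_tile(tile, cfg)
    rec.a_cell_px = int(sr.a_cell_px)
    rec.a_nuc_px = int(sr.a_nuc_px)
    rec.flags = set(sr.flags)

    reason = _primary_reason(sr.flags)
    if reason is not None:
        rec.qc_reason = reason
        return rec

    if not nuclear_size_qc(rec.a_nuc_px, rec.a_cell_px,
                           cfg["qc"]["nuclear_max_fraction"]):
        rec.qc_reason = "nuclear_gt_95pct"
        return rec

    # areas are positive here (empty channels were flagged above)
    rec.diameter_um = equivalent_diameter(rec.a_cell_px, cal)
    rec.nuc_diameter_um = equivalent_diameter(rec.a_nuc_px, cal)
    rec.nc_ratio = nc_ratio(rec.a_nuc_px, rec.a_cell_px)

    try:
        rec.ef = _measure_ef(tile, cfg)
    except (ContourError, DegenerateImageError):
        rec.qc_reason = "no_contour"
        return rec
    except EllipseFitError:
        rec.qc_reason = "fit_failed"
        return rec

    rec.qc_status = QC_ACCEPTED
    rec.qc_reason = "none"
    return rec


def process_gallery(tiles: Sequence[CellTile], cal: CalibrationFactor,
                    cfg: dict) -> list[CellMorphology]:
    """Process tiles in order; per-tile QC failures become rejected records."""
    return [process_tile(t, cal, cfg) for t in tiles]


def records_to_frame(records: Sequence[CellMorphology]) -> pd.DataFrame:
    """Tabulate morphology records (column order of the results CSV)."""
    return pd.DataFrame([r.to_dict() for r in records])
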