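"""Gallery I/O: per-cell PNG tiles, channel manifests and result tables.

The enumeration platform exports each candidate cell as a small square PNG
(8-bit grayscale or 24-bit RGB). Which color plane holds which fluorescence
channel is not encoded in the file, so a CSV manifest carries the
channel-role assignment alongside sample metadata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .errors import FormatError, ManifestError

logger = logging.getLogger(__name__)

#: Recognized channel roles.
ROLES = ("brightfield", "dapi", "ck", "cd45")
#: Recognized group labels.
GROUPS = ("ctc", "cultured", "unknown")
#: Tile edge range typical of the platform's gallery export (descriptive only).
CONFORMANT_SIDE_RANGE = (80, 200)

#: Fixed column order of the per-cell results table.
RESULT_COLUMNS = (
    "tile_id", "sample_id", "group",
    "a_cell_px", "a_nuc_px",
    "diameter_um", "nuc_diameter_um", "nc_ratio", "ef",
    "qc_status", "qc_reason",
)

#: Manifest schema. Empty channel cells mean "channel absent".
MANIFEST_COLUMNS = (
    "path", "tile_id", "sample_id", "group",
    "br_ch", "dapi_ch", "ck_ch", "cd45_ch", "timepoint_h",
)
_CHANNEL_COLS = {"brightfield": "br_ch", "dapi": "dapi_ch",
                 "ck": "ck_ch", "cd45": "cd45_ch"}


@dataclass
class CellTile:
    """One square multi-channel gallery tile.

    ``pixels`` is an (H, W, C) uint8 array; ``roles`` maps a channel role
    (``dapi``, ``ck``, ...) to a plane index into the last axis.
    """

    tile_id: str
    pixels: np.ndarray
    roles: dict[str, int]
    sample_id: str = ""
    group: str = "unknown"
    timepoint_h: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3:
            raise FormatError(f"{self.tile_id}: pixels must be 2-D or (H, W, C)")
        if px.shape[0] != px.shape[1]:
            raise FormatError(
                f"{self.tile_id}: tile must be square, got {px.shape[0]}x{px.shape[1]}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise FormatError(f"{self.tile_id}: intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        for role, idx in self.roles.items():
            if role not in ROLES:
                raise ManifestError(f"{self.tile_id}: unknown channel role {role!r}")
            if not (0 <= int(idx) < px.shape[2]):
                raise ManifestError(
                    f"{self.tile_id}: role {role!r} -> channel {idx} but tile has "
                    f"{px.shape[2]} channel(s)")
        if self.group not in GROUPS:
            raise ManifestError(f"{self.tile_id}: unknown group {self.group!r}")
        if self.timepoint_h is not None and self.timepoint_h < 0:
            raise ManifestError(f"{self.tile_id}: timepoint_h must be non-negative")
        lo, hi = CONFORMANT_SIDE_RANGE
        if not (lo <= self.side_px <= hi):
            warnings.warn(
                f"tile {self.tile_id}: side {self.side_px} px outside the typical "
                f"gallery range {lo}-{hi} px", stacklevel=2)

    @property
    def side_px(self) -> int:
        return int(self.pixels.shape[0])

    def channel(self, role: str) -> np.ndarray:
        """Return the 2-D uint8 plane assigned to ``role``."""
        if role not in self.roles:
            raise ManifestError(f"{self.tile_id}: channel role {role!r} not assigned")
        return self.pixels[:, :, self.roles[role]]

    def has_channel(self, role: str) -> bool:
        return role in self.roles


def load_tile(path: str | Path, roles: Mapping[str, int], *,
              tile_id: str | None = None, sample_id: str = "",
              group: str = "unknown", timepoint_h: float | None = None) -> CellTile:
    """Load one PNG tile, splitting RGB composites into three planes.

    Intensities are preserved bit-exactly; no color-space conversion is
    applied (the pipelines operate per fluorescence channel).
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            if img.mode == "L":
                arr = np.asarray(img, dtype=np.uint8)[:, :, None]
            elif img.mode == "RGB":
                arr = np.asarray(img, dtype=np.uint8)
            else:
                raise FormatError(
                    f"{path}: unsupported image mode {img.mode!r} "
                    "(expected 8-bit grayscale or 24-bit RGB)")
    except (OSError, UnidentifiedImageError) as exc:
        raise OSError(f"cannot read tile {path}: {exc}") from exc
    return CellTile(
        tile_id=tile_id if tile_id is not None else path.stem,
        pixels=arr, roles=dict(roles), sample_id=sample_id, group=group,
        timepoint_h=timepoint_h)


@dataclass
class GalleryLoadResult:
    """Tiles loaded from a manifest plus the per-row load log."""

    tiles: list[CellTile]
    log: list[dict] = field(default_factory=list)

    @property
    def n_failures(self) -> int:
        return sum(1 for row in self.log if row["status"] != "ok")


def _row_roles(row: pd.Series) -> dict[str, int]:
    roles: dict[str, int] = {}
    for role, col in _CHANNEL_COLS.items():
        val = row.get(col)
        if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
            continue
        roles[role] = int(val)
    return roles


def load_gallery(manifest_path: str | Path) -> GalleryLoadResult:
    """Load every tile listed in a manifest CSV, in manifest order.

    A missing or unreadable tile is recorded as a load failure and
    processing continues; a duplicate tile_id aborts with ManifestError.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype={"tile_id": str, "sample_id": str})
    missing_cols = {"path", "tile_id"} - set(df.columns)
    if missing_cols:
        raise ManifestError(f"manifest missing required columns: {sorted(missing_cols)}")
    if df["tile_id"].duplicated().any():
        dups = df.loc[df["tile_id"].duplicated(), "tile_id"].tolist()
        raise ManifestError(f"duplicate tile_id(s) in manifest: {dups}")
    if len(df) == 0:
        warnings.warn(f"manifest {manifest_path} is empty", stacklevel=2)

    result = GalleryLoadResult(tiles=[])
    base = manifest_path.parent
    for _, row in df.iterrows():
        tile_path = Path(row["path"])
        if not tile_path.is_absolute():
            tile_path = base / tile_path
        tp = row.get("timepoint_h")
        timepoint = None if tp is None or (isinstance(tp, float) and np.isnan(tp)) else float(tp)
        group = row.get("group", "unknown")
        if not isinstance(group, str) or group == "":
            group = "unknown"
        try:
            tile = load_tile(
                tile_path, _row_roles(row), tile_id=str(row["tile_id"]),
                sample_id=str(row.get("sample_id", "")), group=group,
                timepoint_h=timepoint)
        except (OSError, FormatError, ManifestError) as exc:
            logger.warning("tile %s failed to load: %s", row["tile_id"], exc)
            result.log.append({"tile_id": str(row["tile_id"]),
                               "status": "error", "message": str(exc)})
            continue
        result.tiles.append(tile)
        result.log.append({"tile_id": tile.tile_id, "status": "ok", "message": ""})
    return result


def write_manifest(rows: Iterable[Mapping], path: str | Path) -> int:
    """Write a manifest CSV with the standard column order."""
    df = pd.DataFrame(list(rows))
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(MANIFEST_COLUMNS)]
    df.to_csv(path, index=False)
    return len(df)


def write_results(records: Sequence, path: str | Path) -> int:
    """Write per-cell morphology records as a delimited table.

    One row per cell; rejected cells are retained with ``qc_reason``
    populated and unmeasurable metric fields left empty. Numeric formatting
    round-trips to at least 6 significant digits.
    """
    rows = []
    for rec in records:
        rows.append(rec.to_dict() if hasattr(rec, "to_dict") else dict(rec))
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    df.to_csv(path, index=False, float_format="%.8g")
    return len(df)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results table written by :func:`write_results`."""
    return pd.read_csv(path, dtype={"tile_id": str, "sample_id": str})
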