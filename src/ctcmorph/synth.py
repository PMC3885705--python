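"""Synthetic gallery generator with exact ground truth.

Emulates the per-cell gallery tiles exported by the enumeration platform:
a bright cell body in the cytokeratin channel, a nucleus in the DAPI
channel, square tiles 80-200 px, plus the failure cases the QC filters
must catch (border-touching cells, doublets, apoptotic fragments with the
nucleus separated from the cytokeratin, blank tiles).

Rasterization uses a pixel-center inclusion rule on the 0-based integer
lattice, so every true area is an exact, oracle-checkable integer count.
The diameter-preserving elongation parameterization (semi-axes
a = d*sqrt(EF)/2, b = d/(2*sqrt(EF)), hence 2*sqrt(a*b) = d) lets size and
shape vary independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import ConfigError
from .io import CellTile, write_manifest

CASES = ("singlet", "border_touch", "doublet", "fragment", "blank")

#: Default case mixture: mostly clean singlets plus every failure mode.
DEFAULT_CASE_MIX = {"singlet": 0.70, "border_touch": 0.10, "doublet": 0.10,
                    "fragment": 0.05, "blank": 0.05}


@dataclass(frozen=True)
class EllipseSpec:
    """Analytic ellipse in tile coordinates: center (row, col), semi-axes,
    major-axis orientation in degrees from the column axis."""

    cy: float
    cx: float
    a: float  # semi-major, px
    b: float  # semi-minor, px
    theta_deg: float = 0.0

    def contains(self, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
        """Pixel-center inclusion test (<= 1 on the normalized quadratic)."""
        th = math.radians(self.theta_deg)
        dx = cc - self.cx
        dy = rr - self.cy
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0

    def rasterize(self, side: int) -> np.ndarray:
        rr, cc = np.mgrid[0:side, 0:side]
        return self.contains(rr, cc)

    @property
    def extent_rc(self) -> tuple[float, float]:
        """Half-extents along (rows, cols) of the bounding box."""
        th = math.radians(self.theta_deg)
        w = math.hypot(self.a * math.cos(th), self.b * math.sin(th))
        h = math.hypot(self.a * math.sin(th), self.b * math.cos(th))
        return h, w

    def scaled(self, k: float) -> "EllipseSpec":
        return replace(self, a=self.a * k, b=self.b * k)

    def moved(self, dr: float, dc: float) -> "EllipseSpec":
        return replace(self, cy=self.cy + dr, cx=self.cx + dc)


def lattice_area(ellipses: Sequence[EllipseSpec], side: int) -> int:
    """Exact pixel count of the union of rasterized ellipses."""
    if not ellipses:
        return 0
    mask = np.zeros((side, side), dtype=bool)
    for e in ellipses:
        mask |= e.rasterize(side)
    return int(mask.sum())


@dataclass(frozen=True)
class GalleryPreset:
    """Population parameters for one study group.

    Diameters are equivalent-circle diameters in micrometers; the EF and
    N/C distributions are lognormal around the given medians (EF is
    1 + lognormal so the circle EF = 1 is a hard floor).
    """

    d_mean_um: float
    d_sd_um: float
    ef_median: float
    nc_median: float
    d_min_um: float = 4.0
    ef_sigma: float = 0.40
    nc_sigma: float = 0.30
    ef_max: float = 2.8
    # intact malignant cells: nucleus at least ~30% of the cell area
    nc_range: tuple[float, float] = (0.4, 3.0)


#: Demo presets with the study groups' summary parameters (not fitted models).
PRESETS = {
    "ctc_like": GalleryPreset(d_mean_um=7.97, d_sd_um=1.81,
                              ef_median=1.27, nc_median=1.43),
    "cultured_like": GalleryPreset(d_mean_um=13.38, d_sd_um=2.54,
                                   ef_median=1.17, nc_median=1.12),
}


@dataclass
class GalleryConfig:
    """Fully seed-determined recipe for one synthetic gallery."""

    n_tiles: int = 200
    preset: GalleryPreset | str = "ctc_like"
    case_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CASE_MIX))
    tile_range: tuple[int, int] = (80, 200)
    um_per_px: float = 0.37
    fg_ck: float = 180.0
    fg_dapi: float = 200.0
    bg: float = 30.0
    noise_sd: float = 10.0
    blur_sigma: float = 0.0
    seed: int = 0
    group: str = "ctc"
    sample_id: str = "S1"
    timepoint_h: float | None = None

    def resolved_preset(self) -> GalleryPreset:
        if isinstance(self.preset, str):
            try:
                return PRESETS[self.preset]
            except KeyError:
                raise ConfigError(f"unknown preset {self.preset!r}") from None
        return self.preset

    def __post_init__(self) -> None:
        total = sum(self.case_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"case mixture must sum to 1, got {total}")
        for case in self.case_mix:
            if case not in CASES:
                raise ConfigError(f"unknown case {case!r}")


@dataclass
class CellTruth:
    """Exact ground truth for one synthetic tile."""

    tile_id: str
    case: str
    side_px: int
    cells: tuple[EllipseSpec, ...] = ()
    nuclei: tuple[EllipseSpec, ...] = ()
    true_area_cell_px: int = 0
    true_area_nuc_px: int = 0
    true_ef: float = math.nan
    true_nc: float = math.nan
    true_d_um: float = math.nan
    true_nuc_d_um: float = math.nan
    group: str = "ctc"
    sample_id: str = "S1"
    timepoint_h: float | None = None


def _finalize_truth(truth: CellTruth, um_per_px: float) -> CellTruth:
    """Fill in the lattice-count areas and derived exact metrics."""
    truth.true_area_cell_px = lattice_area(truth.cells, truth.side_px)
    truth.true_area_nuc_px = lattice_area(truth.nuclei, truth.side_px)
    if truth.cells:
        truth.true_ef = truth.cells[0].a / truth.cells[0].b
    if truth.true_area_cell_px > 0:
        truth.true_d_um = um_per_px * 2 * math.sqrt(truth.true_area_cell_px / math.pi)
    if truth.true_area_nuc_px > 0:
        truth.true_nuc_d_um = um_per_px * 2 * math.sqrt(truth.true_area_nuc_px / math.pi)
    if 0 < truth.true_area_nuc_px < truth.true_area_cell_px:
        truth.true_nc = truth.true_area_nuc_px / (
            truth.true_area_cell_px - truth.true_area_nuc_px)
    return truth


#: Smallest measurable feature sizes (semi-minor axes, px). Thinner
#: structures vanish under the two-iteration 3x3 erosion debris filter and
#: do not occur in intact cells at ~0.37 um/px.
_MIN_CELL_MINOR_PX = 3.5
_MIN_NUC_MINOR_PX = 3.2


@dataclass(frozen=True)
class _CellDraw:
    a: float
    b: float
    theta_deg: float
    n_a: float
    n_b: float

    @property
    def d_px(self) -> float:
        return 2.0 * math.sqrt(self.a * self.b)


def _draw_cell(rng: np.random.Generator, preset: GalleryPreset,
               um_per_px: float) -> _CellDraw:
    """Draw one cell: ellipse semi-axes, orientation and nucleus semi-axes.

    The nucleus is concentric and co-oriented with the cell, rounder than
    the cell body (its elongation is about the square root of the cell's),
    and always strictly contained in it with a physical minimum size.
    """
    while True:
        d_um = -math.inf
        while d_um < preset.d_min_um:
            d_um = rng.normal(preset.d_mean_um, preset.d_sd_um)
        if preset.ef_median > 1.0:
            ef = math.inf
            while ef > preset.ef_max:
                ef = 1.0 + rng.lognormal(math.log(preset.ef_median - 1.0),
                                         preset.ef_sigma)
        else:
            ef = 1.0
        d_px = d_um / um_per_px
        a = d_px * math.sqrt(ef) / 2.0
        b = d_px / (2.0 * math.sqrt(ef))
        if b >= _MIN_CELL_MINOR_PX:
            break
    lo, hi = preset.nc_range
    nc = -math.inf
    while not (lo <= nc <= hi):
        nc = rng.lognormal(math.log(preset.nc_median), preset.nc_sigma)
    frac = nc / (1.0 + nc)  # nuclear area fraction of the cell area

    r_n = math.sqrt(frac * a * b)  # nucleus equivalent-circle radius
    n_ef = math.sqrt(ef)
    # co-axial concentric containment requires n_a <= a and n_b <= b,
    # i.e. frac*ef <= n_ef <= ef/frac
    n_ef = min(max(n_ef, 1.0, 1.01 * frac * ef), 0.99 * ef / frac)
    n_a = 0.995 * r_n * math.sqrt(n_ef)
    n_b = 0.995 * r_n / math.sqrt(n_ef)
    if n_b < _MIN_NUC_MINOR_PX:
        n_a = min(n_a * _MIN_NUC_MINOR_PX / n_b, 0.99 * a)
        n_b = _MIN_NUC_MINOR_PX
    n_a = min(max(n_a, n_b), 0.99 * a)
    n_b = min(n_b, 0.99 * b)
    theta = rng.uniform(0.0, 180.0)
    return _CellDraw(a=a, b=b, theta_deg=theta, n_a=n_a, n_b=n_b)


def _tile_side(rng: np.random.Generator, cfg: GalleryConfig,
               min_side: int, cap: int | None = None) -> int:
    """Draw a tile edge length; the gallery export crops around the event,
    so the tile is never more than a few cell diameters across (``cap``)."""
    lo, hi = cfg.tile_range
    side = int(rng.integers(lo, hi + 1))
    if cap is not None:
        side = min(side, max(lo, cap))
    return max(side, min_side)


def _singlet_geometry(rng, cfg, preset) -> tuple[int, EllipseSpec, EllipseSpec]:
    draw = _draw_cell(rng, preset, cfg.um_per_px)
    probe = EllipseSpec(0, 0, draw.a, draw.b, draw.theta_deg)
    h, w = probe.extent_rc
    side = _tile_side(rng, cfg, int(math.ceil(2 * max(h, w))) + 10,
                      cap=int(math.ceil(8 * draw.d_px)))
    slack_r = side / 2 - h - 3
    slack_c = side / 2 - w - 3
    cy = (side - 1) / 2 + rng.uniform(-1, 1) * min(3.0, max(slack_r, 0.0))
    cx = (side - 1) / 2 + rng.uniform(-1, 1) * min(3.0, max(slack_c, 0.0))
    cell = EllipseSpec(cy, cx, draw.a, draw.b, draw.theta_deg)
    nucleus = EllipseSpec(cy, cx, draw.n_a, draw.n_b, draw.theta_deg)
    return side, cell, nucleus


def _make_singlet(rng, cfg, preset, tile_id) -> CellTruth:
    side, cell, nucleus = _singlet_geometry(rng, cfg, preset)
    return CellTruth(tile_id=tile_id, case="singlet", side_px=side,
                     cells=(cell,), nuclei=(nucleus,))


def _make_border(rng, cfg, preset, tile_id) -> CellTruth:
    side, cell, nucleus = _singlet_geometry(rng, cfg, preset)
    h, w = cell.extent_rc
    edge = rng.integers(0, 4)  # 0=left, 1=right, 2=top, 3=bottom
    off = rng.uniform(0.2, 0.5)
    if edge == 0:
        d = off * w - cell.cx
    elif edge == 1:
        d = (side - 1) - off * w - cell.cx
    elif edge == 2:
        d = off * h - cell.cy
    else:
        d = (side - 1) - off * h - cell.cy
    dr, dc = (0.0, d) if edge < 2 else (d, 0.0)
    cell = cell.moved(dr, dc)
    nucleus = nucleus.moved(dr, dc)
    # guarantee rasterized contact with the frame
    mask = cell.rasterize(side)
    guard = 0
    while mask.any() and not (mask[0, :].any() or mask[-1, :].any()
                              or mask[:, 0].any() or mask[:, -1].any()):
        step = (-1.0 if edge in (0, 2) else 1.0)
        sr, sc = (0.0, step) if edge < 2 else (step, 0.0)
        cell = cell.moved(sr, sc)
        nucleus = nucleus.moved(sr, sc)
        mask = cell.rasterize(side)
        guard += 1
        if guard > side:
            break
    return CellTruth(tile_id=tile_id, case="border_touch", side_px=side,
                     cells=(cell,), nuclei=(nucleus,))


def _make_doublet(rng, cfg, preset, tile_id) -> CellTruth:
    d1 = _draw_cell(rng, preset, cfg.um_per_px)
    d2 = _draw_cell(rng, preset, cfg.um_per_px)
    gap = 6.0
    sep = d1.a + d2.a + gap  # bounding circles disjoint by >= gap px
    ext = max(EllipseSpec(0, 0, d1.a, d1.b, d1.theta_deg).extent_rc
              + EllipseSpec(0, 0, d2.a, d2.b, d2.theta_deg).extent_rc)
    side = _tile_side(rng, cfg, int(math.ceil(sep + 2 * ext)) + 10,
                      cap=int(math.ceil(4 * (d1.d_px + d2.d_px))))
    phi = rng.uniform(0, 2 * math.pi)
    ur, uc = math.sin(phi), math.cos(phi)
    mid = (side - 1) / 2
    cells, nuclei = [], []
    for draw, sign in ((d1, -1.0), (d2, +1.0)):
        cy = mid + sign * ur * sep / 2
        cx = mid + sign * uc * sep / 2
        cells.append(EllipseSpec(cy, cx, draw.a, draw.b, draw.theta_deg))
        nuclei.append(EllipseSpec(cy, cx, draw.n_a, draw.n_b, draw.theta_deg))
    return CellTruth(tile_id=tile_id, case="doublet", side_px=side,
                     cells=tuple(cells), nuclei=tuple(nuclei))


def make_fragment(truth: CellTruth, *, overlap_fraction: float = 0.0,
                  gap_px: float = 4.0, ck_area_ratio: float = 0.5) -> CellTruth:
    """Turn a singlet truth into an apoptotic-fragment case.

    The cytokeratin ellipse is shrunk to a fragment (default: half the
    nuclear area, as in fragments shed by dying cells) and the nucleus is
    displaced along the major axis until it is disjoint from the fragment
    (``overlap_fraction=0``) or overlaps it by approximately the requested
    fraction of the nuclear area.
    """
    assert truth.case == "singlet" and len(truth.cells) == 1
    cell, nucleus = truth.cells[0], truth.nuclei[0]
    k = math.sqrt(ck_area_ratio * (nucleus.a * nucleus.b) / (cell.a * cell.b))
    frag = cell.scaled(k)
    th = math.radians(cell.theta_deg)
    ur, uc = math.sin(th), math.cos(th)
    side = truth.side_px

    def placed(dist: float) -> tuple[EllipseSpec, EllipseSpec]:
        f = frag.moved(-ur * dist / 2, -uc * dist / 2)
        n = EllipseSpec(frag.cy + ur * dist / 2, frag.cx + uc * dist / 2,
                        nucleus.a, nucleus.b, nucleus.theta_deg)
        return f, n

    if overlap_fraction <= 0:
        dist = frag.a + nucleus.a + gap_px
        f, n = placed(dist)
    else:
        lo, hi = 0.0, frag.a + nucleus.a + 2.0
        for _ in range(50):
            mid = (lo + hi) / 2
            f, n = placed(mid)
            fm = f.rasterize(side)
            nm = n.rasterize(side)
            frac = int((fm & nm).sum()) / max(int(nm.sum()), 1)
            if abs(frac - overlap_fraction) < 0.02:
                break
            if frac > overlap_fraction:
                lo = mid
            else:
                hi = mid
    new = CellTruth(tile_id=truth.tile_id, case="fragment", side_px=side,
                    cells=(f,), nuclei=(n,), group=truth.group,
                    sample_id=truth.sample_id, timepoint_h=truth.timepoint_h)
    return new


def _make_fragment_case(rng, cfg, preset, tile_id) -> CellTruth:
    base = _make_singlet(rng, cfg, preset, tile_id)
    # enlarge the canvas so both displaced pieces stay well inside
    cell = base.cells[0]
    need = int(math.ceil(4 * (cell.a + 6))) + 10
    if base.side_px < need:
        shift = (need - base.side_px) / 2
        base = CellTruth(
            tile_id=base.tile_id, case="singlet", side_px=need,
            cells=(base.cells[0].moved(shift, shift),),
            nuclei=(base.nuclei[0].moved(shift, shift),))
    return make_fragment(base)


def sample_truths(cfg: GalleryConfig,
                  rng: np.random.Generator | None = None) -> list[CellTruth]:
    """Draw per-tile ground truths from the gallery configuration.

    The per-tile case labels are the first draw from the seeded generator
    (a single vectorized categorical draw), so they can be reproduced
    independently.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    preset = cfg.resolved_preset()
    cases = list(cfg.case_mix.keys())
    probs = np.asarray([cfg.case_mix[c] for c in cases], dtype=float)
    drawn = rng.choice(cases, size=cfg.n_tiles, p=probs)
    truths: list[CellTruth] = []
    for i, case in enumerate(drawn):
        tile_id = f"{cfg.sample_id}_t{i:04d}"
        if case == "singlet":
            t = _make_singlet(rng, cfg, preset, tile_id)
        elif case == "border_touch":
            t = _make_border(rng, cfg, preset, tile_id)
        elif case == "doublet":
            t = _make_doublet(rng, cfg, preset, tile_id)
        elif case == "fragment":
            t = _make_fragment_case(rng, cfg, preset, tile_id)
        else:
            t = CellTruth(tile_id=tile_id, case="blank",
                          side_px=_tile_side(rng, cfg, cfg.tile_range[0]))
        t.group = cfg.group
        t.sample_id = cfg.sample_id
        t.timepoint_h = cfg.timepoint_h
        truths.append(_finalize_truth(t, cfg.um_per_px))
    return truths


def render_tile(truth: CellTruth, cfg: GalleryConfig,
                rng: np.random.Generator) -> CellTile:
    """Render one truth as a 3-plane RGB tile (CD45, CK, DAPI planes).

    Foreground pixels are exactly those whose centers satisfy the analytic
    ellipse inequality — the same rule that defines the truth areas — plus
    additive Gaussian noise clipped to [0, 255].
    """
    side = truth.side_px
    cell_mask = np.zeros((side, side), dtype=bool)
    for e in truth.cells:
        cell_mask |= e.rasterize(side)
    nuc_mask = np.zeros((side, side), dtype=bool)
    for e in truth.nuclei:
        nuc_mask |= e.rasterize(side)

    ck = np.where(cell_mask, cfg.fg_ck, cfg.bg).astype(np.float64)
    dapi = np.where(nuc_mask, cfg.fg_dapi, cfg.bg).astype(np.float64)
    cd45 = np.full((side, side), cfg.bg, dtype=np.float64)
    planes = [cd45, ck, dapi]
    if cfg.blur_sigma > 0:
        planes = [ndimage.gaussian_filter(p, cfg.blur_sigma) for p in planes]
    if cfg.noise_sd > 0:
        planes = [p + rng.normal(0.0, cfg.noise_sd, size=p.shape)
                  for p in planes]
    stack = np.stack([np.clip(np.rint(p), 0, 255).astype(np.uint8)
                      for p in planes], axis=-1)
    return CellTile(tile_id=truth.tile_id, pixels=stack,
                    roles={"cd45": 0, "ck": 1, "dapi": 2},
                    sample_id=truth.sample_id, group=truth.group,
                    timepoint_h=truth.timepoint_h)


def generate_tiles(cfg: GalleryConfig) -> list[tuple[CellTile, CellTruth]]:
    """In-memory gallery: seeded truths rendered to tiles, in order."""
    rng = np.random.default_rng(cfg.seed)
    truths = sample_truths(cfg, rng)
    return [(render_tile(t, cfg, rng), t) for t in truths]


def shrink_truths(truths: Sequence[CellTruth], *, cell_diam_factor: float = 0.94,
                  nuc_diam_factor: float = 0.90, um_per_px: float = 0.37,
                  timepoint_h: float = 48.0) -> list[CellTruth]:
    """Paired storage-shrinkage variant of a gallery.

    Every cell ellipse is scaled about its center by ``cell_diam_factor``
    and every nucleus by ``nuc_diam_factor`` (diameters scale linearly with
    the semi-axes), emulating cells re-imaged after fixative storage.
    """
    out = []
    for t in truths:
        new = CellTruth(
            tile_id=f"{t.tile_id}_t48", case=t.case, side_px=t.side_px,
            cells=tuple(c.scaled(cell_diam_factor) for c in t.cells),
            nuclei=tuple(n.scaled(nuc_diam_factor) for n in t.nuclei),
            group=t.group, sample_id=t.sample_id, timepoint_h=timepoint_h)
        out.append(_finalize_truth(new, um_per_px))
    return out


def truths_to_frame(truths: Sequence[CellTruth]) -> pd.DataFrame:
    """Truth table with first-ellipse geometry and exact areas."""
    rows = []
    for t in truths:
        cell = t.cells[0] if t.cells else None
        nuc = t.nuclei[0] if t.nuclei else None
        rows.append({
            "tile_id": t.tile_id, "case": t.case, "side_px": t.side_px,
            "n_cells": len(t.cells),
            "cell_cy": cell.cy if cell else math.nan,
            "cell_cx": cell.cx if cell else math.nan,
            "cell_a": cell.a if cell else math.nan,
            "cell_b": cell.b if cell else math.nan,
            "cell_theta_deg": cell.theta_deg if cell else math.nan,
            "nuc_a": nuc.a if nuc else math.nan,
            "nuc_b": nuc.b if nuc else math.nan,
            "true_area_cell_px": t.true_area_cell_px,
            "true_area_nuc_px": t.true_area_nuc_px,
            "true_ef": t.true_ef, "true_nc": t.true_nc,
            "true_d_um": t.true_d_um, "true_nuc_d_um": t.true_nuc_d_um,
            "group": t.group, "sample_id": t.sample_id,
            "timepoint_h": t.timepoint_h,
        })
    return pd.DataFrame(rows)


def generate_gallery(cfg: GalleryConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a gallery to disk: PNG tiles, manifest CSV and truth CSV.

    Fully reproducible: the same config (including seed) yields
    byte-identical outputs.
    """
    outdir = Path(outdir)
    tiledir = outdir / "tiles"
    tiledir.mkdir(parents=True, exist_ok=True)
    pairs = generate_tiles(cfg)
    manifest_rows = []
    for tile, truth in pairs:
        fname = f"{tile.tile_id}.png"
        Image.fromarray(tile.pixels, mode="RGB").save(tiledir / fname)
        manifest_rows.append({
            "path": f"tiles/{fname}", "tile_id": tile.tile_id,
            "sample_id": tile.sample_id, "group": tile.group,
            "br_ch": "", "dapi_ch": 2, "ck_ch": 1, "cd45_ch": 0,
            "timepoint_h": tile.timepoint_h,
        })
    manifest_path = outdir / "manifest.csv"
    write_manifest(manifest_rows, manifest_path)
    truth_path = outdir / "truth.csv"
    truths_to_frame([t for _, t in pairs]).to_csv(truth_path, index=False)
    return {"manifest": manifest_path, "truth": truth_path, "tiles": tiledir}
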