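"""Area pipeline: threshold, particle QC filters, above-threshold pixel counts.

Cell and nuclear areas are determined by counting above-threshold pixels in
the cytokeratin and DAPI channels after a chain of particle filters:

    cluster threshold -> connected components -> border rejection
    -> erosion debris filter -> multi-particle (watershed) detection

Tiles that fail a filter are flagged, never raised: a gallery run keeps
going and the flags become rejection reasons downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .errors import ConfigError, DegenerateImageError
from .io import CellTile

# QC flags attached by segment_tile
FLAG_BORDER = "border_touch"
FLAG_MULTI = "multi_particle"
FLAG_DEBRIS = "debris_only"
FLAG_EMPTY = "empty"

_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


def _connectivity_struct(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return _STRUCT_8
    if connectivity == 4:
        return _STRUCT_4
    raise ConfigError(f"connectivity must be 4 or 8, got {connectivity}")


def cluster_threshold(channel: np.ndarray) -> tuple[np.ndarray, int]:
    """Two-class histogram clustering of an 8-bit channel.

    Picks the integer cut ``t`` in [0, 254] that minimizes the pixel-weighted
    within-class intensity variance of the classes {intensity <= t} and
    {intensity > t} (equivalently maximizes the between-class variance; the
    classic two-means histogram criterion). Returns ``(mask, t)`` with the
    bright class as foreground: ``mask = channel > t``. Ties go to the lowest
    cut.

    Raises
    ------
    DegenerateImageError
        if the image is constant (no two clusters exist).
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise DegenerateImageError("empty channel")
    flat = channel.ravel().astype(np.int64)
    hist = np.bincount(flat, minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("constant image: no two intensity classes exist")

    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)[:-1]                      # class {<= t}, t = 0..254
    w1 = hist.sum() - w0
    s0 = np.cumsum(hist * levels)[:-1]
    mu0 = np.divide(s0, w0, out=np.zeros_like(s0), where=w0 > 0)
    mu1 = np.divide(hist @ levels - s0, w1, out=np.zeros_like(s0), where=w1 > 0)
    between = w0 * w1 * (mu1 - mu0) ** 2
    between[(w0 == 0) | (w1 == 0)] = -np.inf
    t = int(np.argmax(between))                    # first maximum = lowest cut
    return channel > t, t


def stabilized_threshold(channel: np.ndarray) -> tuple[np.ndarray, int]:
    """Bright-object threshold robust to small objects on large tiles.

    Plain two-class histogram clustering picks the wrong cut when the bright
    object covers a tiny fraction of the tile: splitting the background
    noise then yields a larger between-class variance than isolating the
    object. This variant stabilizes the selection numerically:

    1. the cut is first chosen by :func:`cluster_threshold` on a copy
       smoothed with a 3x3 boxcar (noise sd shrinks 3x, so the noise split
       loses to the object split);
    2. the cut is then refined to the intermeans fixed point of the *raw*
       histogram (t = midpoint of the two class means, iterated), which
       centers it in the intensity gap;
    3. the mask is taken from the raw intensities, so with exact foreground/
       background levels the mask equals the analytic rasterization.

    Returns ``(mask, threshold)`` like :func:`cluster_threshold` and raises
    :class:`DegenerateImageError` on constant images.
    """
    channel = np.asarray(channel)
    smooth = ndimage.uniform_filter(channel.astype(np.float64), size=3)
    smooth8 = np.clip(np.rint(smooth), 0, 255).astype(np.uint8)
    _, t0 = cluster_threshold(smooth8)  # raises on constant images
    flat = channel.ravel().astype(np.float64)
    thr = float(t0)
    for _ in range(50):
        lo = flat[flat <= thr]
        hi = flat[flat > thr]
        if lo.size == 0 or hi.size == 0:
            break
        new = (lo.mean() + hi.mean()) / 2.0
        if abs(new - thr) < 0.5:
            thr = new
            break
        thr = new
    t = int(np.floor(thr))
    return channel > t, t


@dataclass
class ParticleLabeling:
    """Labeled connected foreground regions of a binary mask.

    Labels are contiguous 1..K in raster order of each particle's first
    pixel; ``counts[k]`` is the pixel count of particle ``k`` (counts[0] is
    unused and set to 0).
    """

    labels: np.ndarray
    counts: np.ndarray

    @property
    def n(self) -> int:
        return int(len(self.counts) - 1)

    @property
    def foreground_px(self) -> int:
        return int(self.counts[1:].sum())

    def particle_mask(self, k: int) -> np.ndarray:
        return self.labels == k


def label_particles(mask: np.ndarray, connectivity: int = 8) -> ParticleLabeling:
    """Connected components of a binary mask (default 8-connectivity)."""
    labels, n = ndimage.label(np.asarray(mask, dtype=bool),
                              structure=_connectivity_struct(connectivity))
    counts = np.bincount(labels.ravel(), minlength=n + 1).astype(np.int64)
    counts[0] = 0
    return ParticleLabeling(labels=labels, counts=counts)


def _relabel(labels: np.ndarray, keep: np.ndarray) -> ParticleLabeling:
    """Drop labels not in ``keep``; renumber survivors 1..K' preserving order."""
    keep = np.asarray(sorted(set(int(k) for k in keep if k > 0)))
    mapping = np.zeros(labels.max() + 1 if labels.size else 1, dtype=labels.dtype)
    for new, old in enumerate(keep, start=1):
        mapping[old] = new
    new_labels = mapping[labels]
    counts = np.bincount(new_labels.ravel(), minlength=len(keep) + 1).astype(np.int64)
    counts[0] = 0
    return ParticleLabeling(labels=new_labels, counts=counts)


def reject_border_particles(labeling: ParticleLabeling) -> ParticleLabeling:
    """Delete every particle owning a pixel on the image frame.

    Cells incompletely bounded by the tile cannot be measured; any particle
    with a pixel in the first/last row or column is removed and survivors
    are relabeled 1..K' preserving their original order.
    """
    labels = labeling.labels
    if labeling.n == 0:
        return labeling
    edge = np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    border = set(int(k) for k in np.unique(edge) if k > 0)
    keep = [k for k in range(1, labeling.n + 1) if k not in border]
    return _relabel(labels, np.asarray(keep, dtype=labels.dtype))


def debris_filter(labeling: ParticleLabeling, *, erosions: int = 2,
                  measure_eroded: bool = False) -> ParticleLabeling:
    """Erosion-based debris rejection.

    Each particle is eroded ``erosions`` times with a full 3x3 structuring
    element; particles whose eroded mask is empty are deleted. By default
    survivors keep their ORIGINAL pixel sets (areas are counted on the
    un-eroded particles); ``measure_eroded=True`` keeps the eroded pixels
    instead.

    Disjoint 8-connected particles cannot share a 3x3 window, so eroding the
    whole mask at once equals per-particle erosion.
    """
    if labeling.n == 0 or erosions == 0:
        return labeling
    mask = labeling.labels > 0
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT_8,
                                    iterations=erosions, border_value=0)
    survivors = np.unique(labeling.labels[eroded])
    survivors = survivors[survivors > 0]
    if measure_eroded:
        kept = np.where(eroded, labeling.labels, 0)
        return _relabel(kept, survivors)
    return _relabel(labeling.labels, survivors)


def detect_multi_particle(labeling: ParticleLabeling, *, h_min: int = 4,
                          a_min: int = 30, h_depth: float = 1.0) -> bool:
    """True if the tile holds more than one object and must be eliminated.

    Two or more surviving particles is an immediate hit. A single particle
    is additionally probed for touching cells by watershed segmentation of
    its Euclidean distance transform: seeds are the regional maxima of the
    EDT (maxima closer than ``h_min`` px are merged) and the tile is a
    multi-particle image if at least two catchment basins each hold
    ``a_min`` px or more.

    Regional maxima are extracted with an h-maxima transform of depth
    ``h_depth``: the discrete EDT of a smooth convex particle carries
    shallow spurious maxima along its medial ridge (rasterization noise,
    depth well below 1 px), while genuinely touching cells are separated by
    a neck whose EDT saddle lies several pixels below the two body maxima.
    """
    if labeling.n >= 2:
        return True
    if labeling.n == 0:
        return False
    mask = labeling.particle_mask(1)
    dist = ndimage.distance_transform_edt(mask)
    seeds = h_maxima(dist, h_depth) if h_depth > 0 else dist == dist.max()
    # maxima closer than h_min px merge into one seed
    if h_min > 1:
        seeds = ndimage.binary_dilation(seeds, structure=_STRUCT_8,
                                        iterations=max(h_min // 2, 1))
        seeds &= mask
    markers, n_seeds = ndimage.label(seeds, structure=_STRUCT_8)
    if n_seeds < 2:
        return False
    basins = watershed(-dist, markers=markers, mask=mask)
    sizes = np.bincount(basins.ravel())[1:]
    return int((sizes >= a_min).sum()) >= 2


@dataclass
class SegmentationResult:
    """Above-threshold areas per channel plus aggregated QC flags."""

    a_cell_px: int
    a_nuc_px: int
    flags: set[str] = field(default_factory=set)
    threshold_ck: int | None = None
    threshold_dapi: int | None = None


def _segment_channel(channel: np.ndarray, cfg: dict) -> tuple[int, set[str], int | None]:
    """Run the filter chain on one channel; return (area_px, flags, threshold)."""
    seg = cfg["segmentation"]
    flags: set[str] = set()
    try:
        if seg.get("threshold_stabilize", True):
            mask, thr = stabilized_threshold(channel)
        else:
            mask, thr = cluster_threshold(channel)
    except DegenerateImageError:
        return 0, {FLAG_EMPTY}, None

    lab = label_particles(mask, connectivity=seg["connectivity"])
    if lab.n == 0:
        return 0, {FLAG_EMPTY}, thr

    lab = reject_border_particles(lab)
    if lab.n == 0:
        return 0, {FLAG_BORDER}, thr

    lab = debris_filter(lab, erosions=seg["debris_erosions"],
                        measure_eroded=seg["measure_eroded"])
    if lab.n == 0:
        return 0, {FLAG_DEBRIS}, thr

    if detect_multi_particle(lab, h_min=seg["watershed"]["h_min"],
                             a_min=seg["watershed"]["a_min"],
                             h_depth=seg["watershed"].get("h_depth", 1.0)):
        flags.add(FLAG_MULTI)
    return lab.foreground_px, flags, thr


def segment_tile(tile: CellTile, cfg: dict) -> SegmentationResult:
    """Measure cell (CK) and nuclear (DAPI) areas with full QC filtering.

    The filter chain runs independently on the cytokeratin and DAPI
    channels; flags are aggregated across both.
    """
    for role in ("ck", "dapi"):
        if not tile.has_channel(role):
            raise ConfigError(f"tile {tile.tile_id}: required channel {role!r} missing")
    a_cell, flags_ck, thr_ck = _segment_channel(tile.channel("ck"), cfg)
    a_nuc, flags_dapi, thr_dapi = _segment_channel(tile.channel("dapi"), cfg)
    return SegmentationResult(
        a_cell_px=a_cell, a_nuc_px=a_nuc, flags=flags_ck | flags_dapi,
        threshold_ck=thr_ck, threshold_dapi=thr_dapi)
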