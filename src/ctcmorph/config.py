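"""Pipeline configuration: defaults, YAML loading and deep merging.

Every tunable named in the module design notes lives here so that a single
YAML file (plus CLI overrides) fully determines a run.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

#: Full default configuration. Keys mirror the pipeline stages.
DEFAULT_CONFIG: dict[str, Any] = {
    "segmentation": {
        # 8-connectivity avoids splitting diagonal boundaries of rasterized ellipses
        "connectivity": 8,
        "debris_erosions": 2,
        # retain survivors' original pixels for area counting (not the eroded pixels)
        "measure_eroded": False,
        # stabilize threshold selection against tiny-object histograms
        "threshold_stabilize": True,
        "watershed": {
            # regional maxima of the EDT closer than h_min px are merged
            "h_min": 4,
            # a catchment basin must hold at least a_min px to count as a particle
            "a_min": 30,
            # h-maxima depth separating real body maxima from ridge noise
            "h_depth": 1.0,
        },
    },
    "ellipse": {
        "stretch_percentiles": [1.0, 99.0],
        "fit_method": "direct",  # "direct" (least-squares conic) or "moments"
        "min_contour_points": 5,
        # measure axes on the raw thresholded mask; the eroded/dilated smoothing
        # biases both axes by ~2 px which inflates EF at ~10 px cell radii
        "smooth_mask": False,
        "smooth_erosions": 3,
        "smooth_dilations": 1,
    },
    "qc": {
        "nuclear_max_fraction": 0.95,
    },
    "calibration": {
        "um_per_px": None,  # direct factor, or use the reference block
        "reference": None,  # {"ref_diameters_um": [...], "measured_gallery": path}
    },
    "debug": {
        "write_masks": False,
    },
}


def _deep_merge(base: dict, update: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in update.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> dict[str, Any]:
    """Build a run configuration: defaults <- YAML file <- overrides.

    Parameters
    ----------
    path : optional path to a YAML file holding a (partial) config tree.
    overrides : optional mapping merged last (e.g. CLI flags).
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        cfg = _deep_merge(cfg, loaded)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    _validate(cfg)
    return cfg


def _validate(cfg: Mapping) -> None:
    seg = cfg["segmentation"]
    if seg["connectivity"] not in (4, 8):
        raise ConfigError("segmentation.connectivity must be 4 or 8")
    if seg["debris_erosions"] < 0:
        raise ConfigError("segmentation.debris_erosions must be >= 0")
    lo, hi = cfg["ellipse"]["stretch_percentiles"]
    if not (0 <= lo < hi <= 100):
        raise ConfigError("ellipse.stretch_percentiles must satisfy 0 <= lo < hi <= 100")
    if cfg["ellipse"]["fit_method"] not in ("direct", "moments"):
        raise ConfigError("ellipse.fit_method must be 'direct' or 'moments'")
    frac = cfg["qc"]["nuclear_max_fraction"]
    if not (0 < frac <= 1):
        raise ConfigError("qc.nuclear_max_fraction must lie in (0, 1]")


def save_config(cfg: Mapping, path: str | Path) -> None:
    """Serialize a config snapshot next to run outputs (reproducibility)."""
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
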