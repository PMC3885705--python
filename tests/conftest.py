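"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ctcmorph.config import DEFAULT_CONFIG, load_config


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive; never share code with the
# implementation paths they check)

def exhaustive_otsu(image: np.ndarray) -> int:
    """Slow 255-point search minimizing pixel-weighted within-class variance.

    Classes are {intensity <= t} and {intensity > t}; ties go to the lowest
    cut.
    """
    flat = image.ravel().astype(np.float64)
    best_t, best_wcv = None, math.inf
    for t in range(255):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        wcv = lo.size * lo.var() + hi.size * hi.var()
        if wcv < best_wcv - 1e-9:
            best_wcv, best_t = wcv, t
    assert best_t is not None, "oracle needs a non-constant image"
    return best_t


def lattice_count(cy: float, cx: float, a: float, b: float, theta_deg: float,
                  side: int) -> int:
    """Exhaustive per-pixel ellipse inclusion count (python loop)."""
    th = math.radians(theta_deg)
    n = 0
    for r in range(side):
        for c in range(side):
            u = (c - cx) * math.cos(th) + (r - cy) * math.sin(th)
            v = -(c - cx) * math.sin(th) + (r - cy) * math.cos(th)
            if (u / a) ** 2 + (v / b) ** 2 <= 1.0:
                n += 1
    return n


def erode_3x3(mask: np.ndarray) -> np.ndarray:
    """Manual binary erosion with a full 3x3 element (loop oracle)."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            ok = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w and mask[rr, cc]):
                        ok = False
            out[r, c] = ok
    return out


def dilate_3x3(mask: np.ndarray) -> np.ndarray:
    """Manual binary dilation with a full 3x3 element (loop oracle)."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            hit = False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                        hit = True
            out[r, c] = hit
    return out


def raster_ellipse(cy, cx, a, b, theta_deg, side) -> np.ndarray:
    th = math.radians(theta_deg)
    rr, cc = np.mgrid[0:side, 0:side]
    u = (cc - cx) * math.cos(th) + (rr - cy) * math.sin(th)
    v = -(cc - cx) * math.sin(th) + (rr - cy) * math.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def cfg() -> dict:
    """Default pipeline configuration."""
    return load_config()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bimodal_image() -> np.ndarray:
    """64x64 two-Gaussian image (means 60/190, sd 10, fixed seed)."""
    g = np.random.default_rng(7)
    img = np.where(g.random((64, 64)) < 0.6,
                   g.normal(60, 10, (64, 64)), g.normal(190, 10, (64, 64)))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _default_cfg():
    return DEFAULT_CONFIG
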