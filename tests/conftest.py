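"""Shared fixtures and independent brute-force oracles.

Oracles here are deliberately naive (per-pixel loops, closed-form
arithmetic) so they stay independent of the vectorized implementation
paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

import fimid
from fimid.pipeline import RunConfig, quantify_stack

# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def enclosure_oracle(obj: np.ndarray, bnd: np.ndarray, reach: int) -> float:
    """Exhaustive perimeter-scan enclosure fraction (loops everywhere)."""
    H, W = obj.shape
    perim = []
    for r in range(H):
        for c in range(W):
            if not obj[r, c]:
                continue
            on_perim = False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < H and 0 <= cc < W) or not obj[rr, cc]:
                        on_perim = True
            if on_perim:
                perim.append((r, c))
    hits = 0
    for r, c in perim:
        found = False
        for rr in range(max(0, r - reach), min(H, r + reach + 1)):
            for cc in range(max(0, c - reach), min(W, c + reach + 1)):
                if bnd[rr, cc]:
                    found = True
        hits += found
    return hits / len(perim)


def windowed_threshold_oracle(img: np.ndarray, window: int, sens: float) -> np.ndarray:
    """Naive clipped-sliding-window adaptive threshold."""
    H, W = img.shape
    h = window // 2
    out = np.zeros((H, W), dtype=bool)
    for r in range(H):
        for c in range(W):
            block = img[max(0, r - h) : r + h + 1, max(0, c - h) : c + h + 1]
            mu = block.mean()
            sd = block.std()
            out[r, c] = sd > 0 and img[r, c] > mu + sens * sd
    return out


def bilinear_oracle(img: np.ndarray, tr: int, tc: int) -> np.ndarray:
    """Closed-form bilinear interpolation at half-pixel-aligned centers."""
    rows, cols = img.shape
    out = np.zeros((tr, tc))
    for i in range(tr):
        for j in range(tc):
            y = min(max((i + 0.5) * rows / tr - 0.5, 0), rows - 1)
            x = min(max((j + 0.5) * cols / tc - 0.5, 0), cols - 1)
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            y1, x1 = min(y0 + 1, rows - 1), min(x0 + 1, cols - 1)
            fy, fx = y - y0, x - x0
            out[i, j] = (
                img[y0, x0] * (1 - fy) * (1 - fx)
                + img[y0, x1] * (1 - fy) * fx
                + img[y1, x0] * fy * (1 - fx)
                + img[y1, x1] * fy * fx
            )
    return out


def shoelace(coords) -> float:
    """Polygon area by the shoelace formula."""
    xy = np.asarray(coords, dtype=np.float64)
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def random_mask_pair(rng: np.random.Generator, size: int):
    """A random blobby object plus a random partial boundary, disjoint."""
    obj = np.zeros((size, size), dtype=bool)
    r0, c0 = rng.integers(2, size - 2, 2)
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    radius = rng.integers(2, max(3, size // 3))
    obj[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = True
    if rng.random() < 0.5:  # sometimes a rectangle instead
        obj[:] = False
        h, w = rng.integers(2, size // 2, 2)
        obj[r0 % (size - h) : r0 % (size - h) + h, c0 % (size - w) : c0 % (size - w) + w] = True
    bnd = rng.random((size, size)) < rng.uniform(0.02, 0.3)
    bnd &= ~obj
    if not obj.any():
        obj[size // 2, size // 2] = True
        bnd[size // 2, size // 2] = False
    return obj, bnd


# ---------------------------------------------------------------------------
# Synthetic fixtures (small = fast; acceptance uses defaults)
# ---------------------------------------------------------------------------

SMALL = dict(n_myofibrils=60, fiber_radius_um=6.0)
CLEAN = dict(
    psf_sigma_px=0.0,
    defocus_step_px=0.0,
    noise_gain=0.0,
    read_noise_sd=0.0,
    n_planes=1,
)


@pytest.fixture(scope="session")
def small_spec():
    return fimid.SyntheticSpec(seed=7, **SMALL)


@pytest.fixture(scope="session")
def small_geometry(small_spec):
    return fimid.generate_geometry(small_spec)


@pytest.fixture(scope="session")
def small_render(small_spec, small_geometry):
    return fimid.render_stack(small_geometry, small_spec)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise- and blur-free small fiber with no boundary gaps."""
    return fimid.SyntheticSpec(seed=7, gap_fraction=0.0, **SMALL, **CLEAN)


@pytest.fixture(scope="session")
def clean_render(clean_spec):
    geom = fimid.generate_geometry(clean_spec)
    return fimid.render_stack(geom, clean_spec)


# ---------------------------------------------------------------------------
# Acceptance cohort: 20 fibers at generator defaults, quantified once
# ---------------------------------------------------------------------------

ACC_SEED = 123


@pytest.fixture(scope="session")
def acc_cohort():
    return fimid.simulate_cohort(n_fibers=20, seed=ACC_SEED)


@pytest.fixture(scope="session")
def acc_results(acc_cohort):
    """Per-fiber (measured row, ground truth) pairs at default config."""
    cfg = RunConfig()
    out = []
    for stack, gt in acc_cohort:
        rows, _ = quantify_stack(stack, cfg)
        assert len(rows) == 1
        out.append((rows[0], gt))
    return out
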