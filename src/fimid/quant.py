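"""Myofibril detection, filtering, and per-fiber quantification.

The measurement chain, per fiber:

1. the boundary (SERCA, optionally merged with autofluorescence) image is
   binarized with an adaptive local threshold;
2. connected components of non-boundary pixels inside the fiber are the
   candidate myofibril cross-sections (components touching the fiber border
   are discarded as geometrically truncated);
3. each candidate is scored for enclosure — the fraction of its outer
   perimeter pixels lying within a Chebyshev reach of boundary signal — and
   for shape (best-fit-ellipse aspect ratio, solidity, area);
4. candidates pass only if > 90% enclosed, aspect ratio <= 2.5, and
   circular/oval by the solidity proxy; rejected objects keep the first
   failing rule (size -> enclosure -> aspect -> shape) as their reason;
5. fiber-level outputs: mean myofibril CSA over accepted objects,
   intermyofibrillar area (boundary-positive area inside the fiber),
   occupied area = fiber CSA - intermyofibrillar area, and myofibril
   count = occupied area / mean myofibril CSA.

Occupied + intermyofibrillar area equals fiber CSA exactly (a one-step
re-subtraction makes the identity hold in floating point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops

__all__ = [
    "CandidateObject",
    "FiberQuantification",
    "UnquantifiableFiberError",
    "binarize_boundary",
    "detect_candidates",
    "enclosure_fraction",
    "filter_candidates",
    "intermyofibrillar_area",
    "quantify_fiber",
    "filter_rate_summary",
    "DEFAULT_FILTERS",
]

#: Default filter thresholds (recorded in the run manifest).
DEFAULT_FILTERS = {
    "enclosure_min": 0.90,
    "aspect_max": 2.5,
    "solidity_min": 0.90,
    "area_min_um2": 0.1,
    "area_max_um2": 20.0,
    "reach_px": 2,
}

STATUSES = (
    "accepted",
    "rejected:size",
    "rejected:enclosure",
    "rejected:aspect",
    "rejected:shape",
)


class UnquantifiableFiberError(RuntimeError):
    """No accepted myofibril objects: the fiber cannot be quantified."""


@dataclass
class CandidateObject:
    """One putative myofibril cross-section."""

    object_id: int
    area_um2: float
    major_axis_um: float
    minor_axis_um: float
    solidity: float
    enclosure_fraction: float
    centroid: tuple[float, float]  # (row, col) in image pixels
    status: str = "accepted"

    @property
    def aspect_ratio(self) -> float:
        if self.minor_axis_um <= 0:
            return float("inf")
        return self.major_axis_um / self.minor_axis_um


@dataclass
class FiberQuantification:
    fiber_id: int
    fiber_csa_um2: float
    n_candidates: int
    n_accepted: int
    filter_rate: float
    mean_myofibril_csa_um2: float
    intermyofibrillar_area_um2: float
    myofibril_occupied_area_um2: float
    myofibril_count: float


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

def _window_stats(img: np.ndarray, window_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Clipped-sliding-window mean and standard deviation at every pixel.

    Windows are truncated at the image border (statistics use only in-bounds
    pixels), matching a naive per-pixel loop.
    """
    n = window_px * window_px
    ones = np.ones_like(img)
    cnt = ndimage.uniform_filter(ones, window_px, mode="constant") * n
    s1 = ndimage.uniform_filter(img, window_px, mode="constant") * n
    s2 = ndimage.uniform_filter(img * img, window_px, mode="constant") * n
    mean = s1 / cnt
    var = np.clip(s2 / cnt - mean * mean, 0.0, None)
    return mean, np.sqrt(var)


def binarize_boundary(
    image: np.ndarray, window_px: int = 31, sensitivity: float = 0.5
) -> np.ndarray:
    """Adaptive local threshold for the boundary (SERCA) signal.

    A pixel is boundary-positive iff its intensity exceeds
    ``local_mean + sensitivity * local_std`` within the ``window_px`` sliding
    window (border-clipped) *and* the local window has non-zero contrast —
    so a uniform image yields an empty mask.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError(f"window_px must be odd and >= 3, got {window_px}")
    img = np.asarray(image, dtype=np.float64)
    mean, std = _window_stats(img, window_px)
    return (std > 0) & (img > mean + sensitivity * std)


# ---------------------------------------------------------------------------
# Candidate detection & enclosure
# ---------------------------------------------------------------------------

def _perimeter_pixels(obj: np.ndarray) -> np.ndarray:
    """Outer-perimeter pixels: object pixels with a non-object 8-neighbor
    (pixels beyond the image edge count as non-object)."""
    eroded = ndimage.binary_erosion(obj, structure=np.ones((3, 3)), border_value=0)
    return obj & ~eroded


def enclosure_fraction(
    object_mask: np.ndarray, boundary_mask: np.ndarray, reach_px: int = 2
) -> float:
    """Fraction of an object's outer-perimeter pixels with boundary signal
    within Chebyshev distance ``reach_px``."""
    object_mask = np.asarray(object_mask, dtype=bool)
    boundary_mask = np.asarray(boundary_mask, dtype=bool)
    if object_mask.shape != boundary_mask.shape:
        raise ValueError("mask dimensions differ")
    if reach_px < 1:
        raise ValueError("reach_px must be >= 1")
    if not object_mask.any():
        raise ValueError("object mask is empty")
    if (object_mask & boundary_mask).any():
        raise ValueError("object and boundary masks must be disjoint")
    size = 2 * reach_px + 1
    near_boundary = ndimage.binary_dilation(
        boundary_mask, structure=np.ones((size, size)), border_value=0
    )
    perim = _perimeter_pixels(object_mask)
    return float(near_boundary[perim].mean())


def detect_candidates(
    boundary_mask: np.ndarray,
    fiber_mask: np.ndarray,
    pixel_size_um: float,
    reach_px: int = 2,
) -> list[CandidateObject]:
    """Connected components (8-connectivity) of non-boundary pixels inside
    the fiber, with per-object morphology and enclosure.

    Components touching the fiber-mask border (or the image edge) are
    discarded: their geometry is truncated by the fiber outline rather than
    delimited by boundary signal.
    """
    boundary_mask = np.asarray(boundary_mask, dtype=bool)
    fiber_mask = np.asarray(fiber_mask, dtype=bool)
    if boundary_mask.shape != fiber_mask.shape:
        raise ValueError("mask dimensions differ")
    if not fiber_mask.any():
        raise ValueError("fiber mask is empty")
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be > 0")

    interior = fiber_mask & ~boundary_mask
    lbl = label(interior, connectivity=2)

    # Labels disqualified by touching the fiber border or image edge.
    # "Touching" is edge contact (4-adjacency): a pixel merely diagonal to
    # the outside is still fully delimited within the fiber.
    outside = ~fiber_mask
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    border_ring = fiber_mask & ndimage.binary_dilation(
        outside, structure=cross, border_value=1
    )
    bad = set(np.unique(lbl[border_ring])) | {0}
    for edge in (lbl[0, :], lbl[-1, :], lbl[:, 0], lbl[:, -1]):
        bad |= set(np.unique(edge))

    size = 2 * reach_px + 1
    near_boundary = ndimage.binary_dilation(
        boundary_mask, structure=np.ones((size, size)), border_value=0
    )

    objects: list[CandidateObject] = []
    oid = 0
    for p in regionprops(lbl):
        if p.label in bad:
            continue
        r0, c0, r1, c1 = p.bbox
        # pad by 1 so erosion sees the component's true outside
        sub = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
        sub[1:-1, 1:-1] = lbl[r0:r1, c0:c1] == p.label
        perim = _perimeter_pixels(sub)[1:-1, 1:-1]
        encl = float(near_boundary[r0:r1, c0:c1][perim].mean())
        objects.append(
            CandidateObject(
                object_id=oid,
                area_um2=float(p.area) * pixel_size_um**2,
                major_axis_um=float(p.axis_major_length) * pixel_size_um,
                minor_axis_um=float(p.axis_minor_length) * pixel_size_um,
                solidity=float(p.solidity),
                enclosure_fraction=encl,
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
            )
        )
        oid += 1
    return objects


# ---------------------------------------------------------------------------
# Filtering & quantification
# ---------------------------------------------------------------------------

def filter_candidates(
    objects: list[CandidateObject],
    enclosure_min: float = DEFAULT_FILTERS["enclosure_min"],
    aspect_max: float = DEFAULT_FILTERS["aspect_max"],
    solidity_min: float = DEFAULT_FILTERS["solidity_min"],
    area_min_um2: float = DEFAULT_FILTERS["area_min_um2"],
    area_max_um2: float = DEFAULT_FILTERS["area_max_um2"],
) -> list[CandidateObject]:
    """Set accept/reject status on every candidate.

    Acceptance requires enclosure_fraction strictly > ``enclosure_min``
    (">90% enclosed"), aspect_ratio <= ``aspect_max`` (inclusive at the
    "approximately 2.5:1" maximum), solidity >= ``solidity_min``
    (circular/oval proxy), and area within bounds. Rejected objects carry
    the first failing rule in the fixed order size -> enclosure -> aspect
    -> shape, so filter-rate decompositions are deterministic.
    """
    if not 0.0 < enclosure_min <= 1.0:
        raise ValueError("enclosure_min must be in (0, 1]")
    if min(aspect_max, solidity_min, area_min_um2, area_max_um2) <= 0:
        raise ValueError("filter thresholds must be positive")
    for obj in objects:
        if not area_min_um2 <= obj.area_um2 <= area_max_um2:
            obj.status = "rejected:size"
        elif not obj.enclosure_fraction > enclosure_min:
            obj.status = "rejected:enclosure"
        elif not obj.aspect_ratio <= aspect_max:
            obj.status = "rejected:aspect"
        elif not obj.solidity >= solidity_min:
            obj.status = "rejected:shape"
        else:
            obj.status = "accepted"
    return objects


def intermyofibrillar_area(
    merged_binary: np.ndarray, fiber_mask: np.ndarray, pixel_size_um: float
) -> float:
    """Area (µm²) of merged boundary-positive signal inside the fiber."""
    merged_binary = np.asarray(merged_binary, dtype=bool)
    fiber_mask = np.asarray(fiber_mask, dtype=bool)
    if merged_binary.shape != fiber_mask.shape:
        raise ValueError("mask dimensions differ")
    if not fiber_mask.any():
        raise ValueError("fiber mask is empty")
    return float(np.count_nonzero(merged_binary & fiber_mask)) * pixel_size_um**2


def quantify_fiber(
    fiber_id: int,
    fiber_csa_um2: float,
    accepted: list[CandidateObject],
    intermyofibrillar_area_um2: float,
    n_candidates: int | None = None,
) -> FiberQuantification:
    """Per-fiber myofibril size and number.

    ``mean myofibril CSA`` is the arithmetic mean over accepted objects;
    the occupied area is fiber CSA minus the intermyofibrillar area; the
    myofibril count is occupied area / mean CSA (an extrapolation — it can
    exceed the number of accepted objects). Raises
    :class:`UnquantifiableFiberError` when nothing was accepted, so callers
    must flag, not drop, such fibers.
    """
    accepted = [o for o in accepted if o.status == "accepted"]
    if not accepted:
        raise UnquantifiableFiberError(
            f"fiber {fiber_id}: no accepted myofibril objects"
        )
    if not 0.0 <= intermyofibrillar_area_um2 <= fiber_csa_um2:
        raise ValueError("intermyofibrillar area must be within [0, fiber CSA]")
    if n_candidates is None:
        n_candidates = len(accepted)
    if n_candidates < len(accepted):
        raise ValueError("n_candidates smaller than the accepted count")

    mean_csa = float(np.mean([o.area_um2 for o in accepted]))
    occupied = fiber_csa_um2 - intermyofibrillar_area_um2
    # Re-subtraction makes occupied + intermyofibrillar == fiber CSA exact
    # in round-to-nearest floating point (Sterbenz when the two halves are
    # comparable; sub-half-ulp rounding otherwise).
    intermyofibrillar_area_um2 = fiber_csa_um2 - occupied
    return FiberQuantification(
        fiber_id=fiber_id,
        fiber_csa_um2=fiber_csa_um2,
        n_candidates=int(n_candidates),
        n_accepted=len(accepted),
        filter_rate=(n_candidates - len(accepted)) / n_candidates,
        mean_myofibril_csa_um2=mean_csa,
        intermyofibrillar_area_um2=intermyofibrillar_area_um2,
        myofibril_occupied_area_um2=occupied,
        myofibril_count=occupied / mean_csa,
    )


def filter_rate_summary(quantifications: list[FiberQuantification]) -> float:
    """Pooled rejected/candidates fraction across fibers."""
    total = sum(q.n_candidates for q in quantifications)
    if total == 0:
        raise ValueError("no candidate objects in any fiber")
    rejected = sum(q.n_candidates - q.n_accepted for q in quantifications)
    return rejected / total
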