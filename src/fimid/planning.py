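"""Sample-size planning, sampling-sufficiency rules, and descriptive summaries.

Cochran's formula for estimating a mean to a relative margin of error e at
confidence level 1 - alpha, given a coefficient of variation CV:

    n = ceil( (z * CV / e)^2 )

where z is the two-sided standard-normal quantile for the confidence level.
Multiplying the per-fiber requirement by fibers/sample, samples/group, and
number of groups gives the manual-tracing workload that motivates
automation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

__all__ = [
    "cochran_sample_size",
    "tracing_workload",
    "sampling_sufficiency",
    "flag_outliers",
    "group_summary",
    "agreement",
]


def cochran_sample_size(
    cv: float, margin: float = 0.05, confidence: float = 0.95
) -> int:
    """Myofibrils to measure for a ``margin`` relative error on the mean CSA.

    Parameters
    ----------
    cv
        Coefficient of variation of myofibril CSA (SD / mean), >= 0.
    margin
        Relative margin of error, e.g. 0.05 for ±5%.
    confidence
        Two-sided confidence level in (0, 1).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if not margin > 0:
        raise ValueError("margin must be > 0")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return max(1, math.ceil((z * cv / margin) ** 2))


def tracing_workload(
    n_per_fiber: int,
    fibers_per_sample: int,
    samples_per_group: int,
    n_groups: int,
) -> int:
    """Total myofibrils to trace for a study design (pure product)."""
    factors = (n_per_fiber, fibers_per_sample, samples_per_group, n_groups)
    for f in factors:
        if not (isinstance(f, (int, np.integer)) and f >= 0):
            raise ValueError(f"all workload factors must be integers >= 0, got {f}")
    return int(np.prod(factors, dtype=np.int64))


def sampling_sufficiency(
    selected_csas, reference_mean_um2: float, tolerance: float = 0.10
) -> bool:
    """Has enough of the fiber population been sampled?

    True iff the mean CSA of the selected fibers lies within
    ``tolerance * reference`` of the whole-muscle reference mean
    (±10% for the mouse protocol, ±4% for the human one).
    """
    selected = np.asarray(selected_csas, dtype=np.float64)
    if selected.size == 0:
        raise ValueError("no fibers selected")
    if not reference_mean_um2 > 0:
        raise ValueError("reference mean must be > 0")
    if not tolerance > 0:
        raise ValueError("tolerance must be > 0")
    return bool(
        abs(selected.mean() - reference_mean_um2) <= tolerance * reference_mean_um2
    )


def flag_outliers(values, k: float = 3.0, mode: str = "sd") -> np.ndarray:
    """Flag values deviating more than ``k`` times from the group mean.

    ``mode='sd'`` (default): flagged iff |v - mean| > k * population SD.
    ``mode='fold'``: flagged iff v > k * mean or v < mean / k (requires a
    positive mean); provided because "deviated more than three times from
    the mean" admits both readings.

    Groups of fewer than 3 values flag nothing.
    """
    if not k > 0:
        raise ValueError("k must be > 0")
    values = np.asarray(values, dtype=np.float64)
    flags = np.zeros(values.shape, dtype=bool)
    if values.size < 3:
        return flags
    mean = values.mean()
    if mode == "sd":
        sd = values.std(ddof=0)
        if sd > 0:
            flags = np.abs(values - mean) > k * sd
    elif mode == "fold":
        if not mean > 0:
            raise ValueError("fold mode requires a positive group mean")
        flags = (values > k * mean) | (values < mean / k)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return flags


def group_summary(group_a, group_b) -> dict:
    """Descriptive two-group comparison: means, SDs, n, percent change."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.mean() == 0:
        raise ValueError("group A mean is zero; percent change undefined")
    return {
        "n_a": int(a.size),
        "n_b": int(b.size),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)) if a.size > 1 else 0.0,
        "sd_b": float(b.std(ddof=1)) if b.size > 1 else 0.0,
        "percent_change": float(100.0 * (b.mean() - a.mean()) / a.mean()),
    }


def agreement(auto, manual) -> float:
    """Pearson correlation between automated and manual measurements."""
    auto = np.asarray(auto, dtype=np.float64)
    manual = np.asarray(manual, dtype=np.float64)
    if auto.shape != manual.shape or auto.ndim != 1:
        raise ValueError("inputs must be 1-D and of equal length")
    if auto.size < 3:
        raise ValueError("need at least 3 paired values")
    if auto.std() == 0 or manual.std() == 0:
        raise ValueError("degenerate (zero-variance) input")
    return float(stats.pearsonr(auto, manual)[0])
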