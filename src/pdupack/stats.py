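"""Small statistical helpers: calibration checks and summary statistics."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


def binomial_se_pct(p_pct: float, n: int) -> float:
    """Standard error (in percentage points) of a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be > 0")
    p = p_pct / 100.0
    return 100.0 * math.sqrt(max(p * (1.0 - p), 0.0) / n)


def uniform_start_pvalue(starts: np.ndarray, length: int, bin_size: int = 1000) -> float:
    """Chi-square p-value for uniformity of read starts along a replicon.

    Starts are binned into `bin_size`-bp bins (a trailing partial bin is
    dropped) and tested against the equal-occupancy multinomial.  Read
    starts, not per-base coverage, are binned because adjacent coverage
    values are correlated while start counts are independent.
    """
    n_bins = length // bin_size
    if n_bins < 2:
        raise ValueError("replicon too short for the requested bin size")
    starts = np.asarray(starts)
    starts = starts[starts < n_bins * bin_size]
    if starts.size == 0:
        raise ValueError("no read starts to test")
    counts = np.bincount(starts // bin_size, minlength=n_bins)
    return float(sps.chisquare(counts).pvalue)


def kish_effective_n(weights: Sequence[float]) -> float:
    """Kish effective sample size of a weighted (clustered) sample.

    Reads drawn repeatedly from the same surviving fragment are not
    independent; weighting each distinct fragment by its read count gives
    the effective number of independent sampling units.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0 or (w < 0).any():
        raise ValueError("weights must be non-empty and non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("weights sum to zero")
    return float(total * total / np.square(w).sum())


@dataclass(frozen=True)
class DiameterSummary:
    """Mean/SD of particle diameters and of the largest top fraction."""

    n: int
    mean: float
    sd: float
    top_fraction: float
    top_n: int
    top_mean: float
    top_sd: float


def summarize_diameters(values: Sequence[float], top_fraction: float = 0.1) -> DiameterSummary:
    """Sample mean/SD (n-1 denominator) of diameters and of the largest decile.

    The top set holds the ceil(top_fraction * n) largest values; ties at the
    boundary are all included, so the top set may exceed that size.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no diameters given")
    if (arr <= 0).any():
        raise ValueError("diameters must be positive")
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    k = math.ceil(top_fraction * arr.size)
    srt = np.sort(arr)
    threshold = srt[-k]
    top = arr[arr >= threshold]

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    return DiameterSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=_sd(arr),
        top_fraction=top_fraction,
        top_n=int(top.size),
        top_mean=float(top.mean()),
        top_sd=_sd(top),
    )
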