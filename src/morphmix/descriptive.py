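"""Pre-mixture screening: kernel-density bimodality checks and
mean-standardized variance comparisons between traits.

A strongly bimodal trait distribution in one sex, alongside a unimodal one
in the other, is the first line of evidence for a discrete male dimorphism;
the mixture model then does the inference.  Variances are compared after
standardizing by the trait mean (var/mean), which makes traits of different
absolute size commensurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "KdeEstimate", "VarianceComparison",
    "kde", "count_modes", "silverman_bandwidth",
    "standardized_variance", "variance_ratio",
]

GRID_SIZE = 512
DEFAULT_PROMINENCE = 0.05   # fraction of peak height; suppresses grid ripple


def silverman_bandwidth(xs: np.ndarray) -> float:
    """Rule-of-thumb bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5)."""
    xs = np.asarray(xs, dtype=float)
    sd = float(np.std(xs, ddof=1))
    q75, q25 = np.percentile(xs, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * xs.size ** (-0.2)


@dataclass
class KdeEstimate:
    """Gaussian kernel density on a fixed grid, with mode bookkeeping."""

    bandwidth: float
    grid: np.ndarray
    density: np.ndarray
    n: int
    mode_count: int
    mode_locations: np.ndarray

    def to_dict(self) -> dict:
        return {"bandwidth": self.bandwidth, "n": self.n,
                "mode_count": self.mode_count,
                "mode_locations": [float(v) for v in self.mode_locations]}


def kde(xs: Sequence[float], bandwidth: Optional[float] = None,
        min_prominence: float = DEFAULT_PROMINENCE) -> KdeEstimate:
    """Gaussian KDE on a 512-point grid spanning the data ± 3 bandwidths.

    ``bandwidth=None`` selects the Silverman rule of thumb.  Needs n ≥ 3 and
    nonzero spread.
    """
    xs = np.asarray(xs, dtype=float)
    if xs.size < 3:
        raise ValueError(f"KDE needs at least 3 values, got {xs.size}")
    if np.std(xs) == 0:
        raise ValueError("degenerate sample: zero variance")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(xs)
    if not bandwidth > 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")

    grid = np.linspace(xs.min() - 3 * bandwidth, xs.max() + 3 * bandwidth, GRID_SIZE)
    z = (grid[:, None] - xs[None, :]) / bandwidth
    density = np.exp(-0.5 * z * z).sum(axis=1) / (
        xs.size * bandwidth * np.sqrt(2 * np.pi))

    est = KdeEstimate(bandwidth=float(bandwidth), grid=grid, density=density,
                      n=int(xs.size), mode_count=0, mode_locations=np.empty(0))
    est.mode_count = count_modes(est, min_prominence)
    return est


def count_modes(est: KdeEstimate, min_prominence: float = DEFAULT_PROMINENCE) -> int:
    """Strict local maxima with prominence ≥ min_prominence·max(density).

    Plateaus count once.  Updates ``est.mode_locations`` as a side effect.
    """
    peaks, _ = find_peaks(est.density,
                          prominence=min_prominence * float(est.density.max()))
    # an endpoint maximum (monotone density) is a mode find_peaks cannot see
    if est.density.size >= 2:
        interior_max = est.density[peaks].max() if peaks.size else -np.inf
        for idx in (0, est.density.size - 1):
            neighbor = est.density[1] if idx == 0 else est.density[-2]
            if est.density[idx] > neighbor and est.density[idx] > interior_max:
                peaks = np.sort(np.append(peaks, idx))
    est.mode_locations = est.grid[peaks]
    return int(peaks.size)


def standardized_variance(xs: Sequence[float], squared: bool = False) -> float:
    """Sample variance over sample mean (mm); ``squared=True`` gives the
    squared coefficient of variation var/mean² instead."""
    xs = np.asarray(xs, dtype=float)
    if xs.size < 2:
        raise ValueError("standardized variance needs n >= 2")
    mean = float(np.mean(xs))
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    var = float(np.var(xs, ddof=1))
    return var / mean ** 2 if squared else var / mean


@dataclass
class VarianceComparison:
    trait_a: str
    trait_b: str
    standardized_variance_a: float
    standardized_variance_b: float
    ratio: float

    def to_dict(self) -> dict:
        return {"trait_a": self.trait_a, "trait_b": self.trait_b,
                "standardized_variance_a": self.standardized_variance_a,
                "standardized_variance_b": self.standardized_variance_b,
                "ratio": self.ratio}


def variance_ratio(trait_xs: Sequence[float], size_xs: Sequence[float],
                   trait_name: str = "patella", size_name: str = "prosoma",
                   squared: bool = False) -> VarianceComparison:
    """Mean-standardized variance of the trait over that of body size."""
    sv_a = standardized_variance(trait_xs, squared=squared)
    sv_b = standardized_variance(size_xs, squared=squared)
    return VarianceComparison(trait_name, size_name, sv_a, sv_b, sv_a / sv_b)
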