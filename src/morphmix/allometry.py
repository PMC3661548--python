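"""Standardized major axis (model II) regression for static allometry.

When both the trait and the body-size proxy carry measurement and biological
error, ordinary least squares underestimates the scaling slope; SMA (also
called reduced major axis) fits the line whose slope is

    b = sign(r) · sd(y) / sd(x),      a = ȳ − b·x̄,

with the classical confidence interval built from
B = F(1−α; 1, n−2)·(1−r²)/(n−2):  CI = b·(√(B+1) ± √B).  Intercept limits
are propagated from the slope limits through the centroid.  Fits here are on
the natural (untransformed) mm scale by default; log-log is available via a
flag for conventional allometric exponents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .facing_gamma import ClassificationResult
from .io import MeasurementTable, Sex

__all__ = ["SmaFit", "SlopeComparison", "sma_fit", "compare_slopes",
           "allometry_by_group", "GroupAllometry"]


@dataclass(frozen=True)
class SmaFit:
    """One group's SMA line with 95% (by default) confidence intervals."""

    group: str
    n: int
    slope: float
    intercept: float
    r: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {"group": self.group, "n": self.n, "slope": self.slope,
                "intercept": self.intercept, "r": self.r,
                "slope_ci": list(self.slope_ci),
                "intercept_ci": list(self.intercept_ci), "alpha": self.alpha}


def sma_fit(x: Sequence[float], y: Sequence[float], *, group: str = "",
            alpha: float = 0.05, log_scale: bool = False) -> SmaFit:
    """Standardized major axis fit of y on x.

    Requires n ≥ 3 and nonzero variance in both variables.  With
    ``log_scale`` both variables are log-transformed first (slope is then
    the allometric exponent).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"SMA needs at least 3 pairs, got {n}")
    if log_scale:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log-scale SMA requires strictly positive data")
        x, y = np.log(x), np.log(y)

    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0 or sy == 0:
        raise ValueError("degenerate data: zero variance in x or y")

    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * sy / sx
    xbar, ybar = float(np.mean(x)), float(np.mean(y))
    intercept = ybar - slope * xbar

    f_crit = float(stats.f.ppf(1.0 - alpha, 1, n - 2))
    B = f_crit * (1.0 - r * r) / (n - 2)
    lo = slope * (np.sqrt(B + 1.0) - np.sqrt(B))
    hi = slope * (np.sqrt(B + 1.0) + np.sqrt(B))
    slope_ci = (min(lo, hi), max(lo, hi))
    # intercept limits through the centroid: a = ȳ − b·x̄ at the slope limits
    ints = sorted((ybar - slope_ci[0] * xbar, ybar - slope_ci[1] * xbar))
    return SmaFit(group=group, n=n, slope=slope, intercept=intercept, r=r,
                  slope_ci=slope_ci, intercept_ci=(ints[0], ints[1]), alpha=alpha)


@dataclass(frozen=True)
class SlopeComparison:
    """CI-overlap verdict between two groups' SMA slopes."""

    group_a: str
    group_b: str
    overlap: bool
    verdict: str     # "a_steeper" | "b_steeper" | "indistinguishable"

    def to_dict(self) -> dict:
        return {"group_a": self.group_a, "group_b": self.group_b,
                "overlap": self.overlap, "verdict": self.verdict}


def compare_slopes(a: SmaFit, b: SmaFit) -> SlopeComparison:
    """Declare a slope steeper only when its whole CI clears the other's."""
    if a.slope_ci[0] > b.slope_ci[1]:
        return SlopeComparison(a.group, b.group, overlap=False, verdict="a_steeper")
    if b.slope_ci[0] > a.slope_ci[1]:
        return SlopeComparison(a.group, b.group, overlap=False, verdict="b_steeper")
    return SlopeComparison(a.group, b.group, overlap=True, verdict="indistinguishable")


@dataclass
class GroupAllometry:
    fits: dict[str, SmaFit] = field(default_factory=dict)
    comparisons: list[SlopeComparison] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"fits": {k: v.to_dict() for k, v in self.fits.items()},
                "comparisons": [c.to_dict() for c in self.comparisons],
                "warnings": list(self.warnings)}


GROUPS = ("heteromorphic males", "homeomorphic males", "females")


def allometry_by_group(table: MeasurementTable,
                       classification: Optional[ClassificationResult],
                       alpha: float = 0.05,
                       log_scale: bool = False) -> GroupAllometry:
    """Per-group SMA fits: heteromorphic males, homeomorphic males, females.

    Juveniles and records missing either length are excluded.  Males the
    classification left unassigned enter neither male fit.  Groups with
    fewer than 3 usable pairs are skipped with a warning and omitted from
    comparisons.
    """
    out = GroupAllometry()
    adults = table.adults()
    males = [r for r in adults if r.sex is Sex.MALE and r.usable]
    females = [r for r in adults if r.sex is Sex.FEMALE and r.usable]

    groups: dict[str, list] = {g: [] for g in GROUPS}
    if classification is not None and males:
        # classification.values were the male patella lengths, in table order
        if len(classification.labels) != len(males):
            raise ValueError(
                "classification does not match the male records in the table")
        for rec, lab in zip(males, classification.labels):
            if lab == "heteromorphic":
                groups["heteromorphic males"].append(rec)
            elif lab == "homeomorphic":
                groups["homeomorphic males"].append(rec)
    elif males:
        out.warnings.append(
            "no classification supplied: male morph fits skipped")
    groups["females"] = females

    for name in GROUPS:
        recs = groups[name]
        if len(recs) < 3:
            out.warnings.append(
                f"group '{name}' has {len(recs)} usable pairs (< 3): fit skipped")
            continue
        x = [r.prosoma_length for r in recs]
        y = [r.patella_length for r in recs]
        try:
            out.fits[name] = sma_fit(x, y, group=name, alpha=alpha,
                                     log_scale=log_scale)
        except ValueError as exc:
            out.warnings.append(f"group '{name}': {exc}")

    names = [g for g in GROUPS if g in out.fits]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out.comparisons.append(compare_slopes(out.fits[a], out.fits[b]))
    return out


def fits_to_tsv(fits: dict[str, SmaFit]) -> str:
    """Serialize fits in the published coefficient-table layout."""
    lines = ["group\tintercept\tintercept_ci_low\tintercept_ci_high"
             "\tslope\tslope_ci_low\tslope_ci_high\tn"]
    for name in GROUPS:
        if name not in fits:
            continue
        f = fits[name]
        lines.append("\t".join([
            name,
            f"{f.intercept:.3f}", f"{f.intercept_ci[0]:.3f}", f"{f.intercept_ci[1]:.3f}",
            f"{f.slope:.3f}", f"{f.slope_ci[0]:.3f}", f"{f.slope_ci[1]:.3f}",
            str(f.n)]))
    return "\n".join(lines) + "\n"
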