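"""Facing-gamma mixture model for a dimorphic male trait.

The trait distribution of a male-dimorphic population is modelled as a
two-component mixture of "facing" gamma densities: a lower-bounded gamma
skewed toward higher values for the minor (homeomorphic) morph, and its
mirror image — an upper-bounded gamma skewed toward lower values — for the
major (heteromorphic) morph.  Writing G(x; λ, θ) for the ordinary gamma
density with shape λ and scale θ,

    f_homeo(x)  = G(x − L; λ₁, θ₁)    for x ≥ L   (right-facing),
    f_hetero(x) = G(U − x; λ₂, θ₂)    for x ≤ U   (left-facing),
    f(x)        = π f_homeo(x) + (1 − π) f_hetero(x).

Morph membership is latent; the seven parameters (π, λ₁, θ₁, L, λ₂, θ₂, U)
are estimated by direct maximization of the observed-data log-likelihood.
Classification proceeds either from component quantiles (a male below the
heteromorphic component's 0.05 quantile is homeomorphic with ≥95%
within-component confidence, and symmetrically above the homeomorphic
0.95 quantile) or from posterior membership probabilities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "Orientation",
    "FacingGammaComponent",
    "MixtureModel",
    "FitConfig",
    "ClassificationResult",
    "ComparisonReport",
    "fit_mixture",
    "fit_single_gamma",
    "model_compare",
    "classification_cutoffs",
    "classify",
]


class Orientation(str, Enum):
    RIGHT_FACING = "right_facing"   # lower-bounded, skew toward higher values
    LEFT_FACING = "left_facing"     # upper-bounded, skew toward lower values


@dataclass(frozen=True)
class FacingGammaComponent:
    """A bound-shifted gamma density facing right (from L up) or left (from U down)."""

    orientation: Orientation
    shape: float            # λ, dimensionless
    scale: float            # θ, mm
    bound: float            # L (right-facing) or U (left-facing), mm

    def __post_init__(self) -> None:
        if not self.shape > 0:
            raise ValueError(f"shape must be > 0, got {self.shape}")
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")

    @property
    def mean(self) -> float:
        """L + λθ (right-facing) or U − λθ (left-facing)."""
        if self.orientation is Orientation.RIGHT_FACING:
            return self.bound + self.shape * self.scale
        return self.bound - self.shape * self.scale

    @property
    def variance(self) -> float:
        return self.shape * self.scale ** 2

    def _z(self, x):
        """Distance into the support, ≥ 0 inside."""
        x = np.asarray(x, dtype=float)
        if self.orientation is Orientation.RIGHT_FACING:
            return x - self.bound
        return self.bound - x

    def pdf(self, x):
        """Density per mm; zero outside the support."""
        z = self._z(x)
        out = np.where(z >= 0, stats.gamma.pdf(np.clip(z, 0, None),
                                               self.shape, scale=self.scale), 0.0)
        return out if out.ndim else float(out)

    def logpdf(self, x):
        z = self._z(x)
        out = np.where(z >= 0, stats.gamma.logpdf(np.clip(z, 0, None),
                                                  self.shape, scale=self.scale), -np.inf)
        return out if out.ndim else float(out)

    def cdf(self, x):
        """P(X ≤ x); a left-facing component is the survival function of its mirror."""
        z = self._z(x)
        g = special.gammainc(self.shape, np.clip(z, 0, None) / self.scale)
        if self.orientation is Orientation.RIGHT_FACING:
            out = np.where(z >= 0, g, 0.0)
        else:
            out = np.where(z >= 0, 1.0 - g, 1.0)
        return out if out.ndim else float(out)

    def quantile(self, p: float) -> float:
        """Inverse CDF in mm; exact inverse of :meth:`cdf` to 1e-9."""
        if not 0.0 < p < 1.0:
            raise ValueError(f"p must lie in (0, 1), got {p}")
        if self.orientation is Orientation.RIGHT_FACING:
            return self.bound + stats.gamma.ppf(p, self.shape, scale=self.scale)
        return self.bound - stats.gamma.ppf(1.0 - p, self.shape, scale=self.scale)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        g = rng.gamma(self.shape, self.scale, size=n)
        if self.orientation is Orientation.RIGHT_FACING:
            return self.bound + g
        return self.bound - g

    def to_dict(self) -> dict:
        key = "lower_bound" if self.orientation is Orientation.RIGHT_FACING else "upper_bound"
        return {"shape": self.shape, "scale": self.scale, key: self.bound}


def right_facing(shape: float, scale: float, lower_bound: float) -> FacingGammaComponent:
    return FacingGammaComponent(Orientation.RIGHT_FACING, shape, scale, lower_bound)


def left_facing(shape: float, scale: float, upper_bound: float) -> FacingGammaComponent:
    return FacingGammaComponent(Orientation.LEFT_FACING, shape, scale, upper_bound)


@dataclass(frozen=True)
class MixtureModel:
    """Two facing gamma components plus a mixing weight.

    ``weight_homeo`` is the proportion π of the right-facing (homeomorphic)
    component.  Identity is fixed by orientation, not by mean, which removes
    label switching: the lower-bounded component is always "homeo".
    """

    weight_homeo: float
    homeo: FacingGammaComponent
    hetero: FacingGammaComponent
    n: Optional[int] = None
    loglik: Optional[float] = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.weight_homeo < 1.0:
            raise ValueError("weight_homeo must lie strictly in (0, 1)")
        if self.homeo.orientation is not Orientation.RIGHT_FACING:
            raise ValueError("homeo component must be right-facing")
        if self.hetero.orientation is not Orientation.LEFT_FACING:
            raise ValueError("hetero component must be left-facing")
        if not self.homeo.bound < self.hetero.bound:
            raise ValueError("lower bound L must lie below upper bound U")

    def pdf(self, x):
        p = self.weight_homeo
        out = p * self.homeo.pdf(x) + (1.0 - p) * self.hetero.pdf(x)
        return out

    def logpdf(self, x):
        p = self.weight_homeo
        a = np.log(p) + self.homeo.logpdf(x)
        b = np.log1p(-p) + self.hetero.logpdf(x)
        return np.logaddexp(a, b)

    def log_likelihood(self, xs) -> float:
        xs = np.asarray(xs, dtype=float)
        if xs.size == 0:
            raise ValueError("log-likelihood of an empty sample is undefined")
        return float(np.sum(self.logpdf(xs)))

    def posterior_hetero(self, x):
        """P(heteromorphic | trait value x) ∈ [0, 1].

        1 below the homeo lower bound, 0 above the hetero upper bound.
        """
        x = np.asarray(x, dtype=float)
        la = np.log(self.weight_homeo) + self.homeo.logpdf(x)
        lb = np.log1p(-self.weight_homeo) + self.hetero.logpdf(x)
        with np.errstate(invalid="ignore", over="ignore"):
            post = np.where(
                np.isneginf(la) & np.isneginf(lb), np.nan,
                np.where(np.isneginf(lb), 0.0,
                         np.where(np.isneginf(la), 1.0,
                                  1.0 / (1.0 + np.exp(np.clip(la - lb, -745, 745))))))
        return post if post.ndim else float(post)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n trait values from the mixture.

        The left-facing component's lower tail extends below zero with
        negligible mass; nonpositive draws (impossible lengths) are redrawn.
        """
        comp = rng.random(n) < self.weight_homeo
        out = np.where(comp, self.homeo.sample(n, rng), self.hetero.sample(n, rng))
        bad = out <= 0
        while bad.any():
            k = int(bad.sum())
            c = rng.random(k) < self.weight_homeo
            out[bad] = np.where(c, self.homeo.sample(k, rng),
                                self.hetero.sample(k, rng))
            bad = out <= 0
        return out

    @property
    def parameters(self) -> dict:
        return {
            "weight_homeo": self.weight_homeo,
            "homeo_shape": self.homeo.shape, "homeo_scale": self.homeo.scale,
            "lower_bound": self.homeo.bound,
            "hetero_shape": self.hetero.shape, "hetero_scale": self.hetero.scale,
            "upper_bound": self.hetero.bound,
        }

    def to_dict(self) -> dict:
        return {
            "weight_homeo": self.weight_homeo,
            "homeo": self.homeo.to_dict(),
            "hetero": self.hetero.to_dict(),
            "n": self.n,
            "loglik": self.loglik,
            "fit": dict(self.meta),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        return cls(
            weight_homeo=d["weight_homeo"],
            homeo=right_facing(d["homeo"]["shape"], d["homeo"]["scale"],
                               d["homeo"]["lower_bound"]),
            hetero=left_facing(d["hetero"]["shape"], d["hetero"]["scale"],
                               d["hetero"]["upper_bound"]),
            n=d.get("n"), loglik=d.get("loglik"), meta=d.get("fit", {}),
        )

    @classmethod
    def from_json(cls, s: str) -> "MixtureModel":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Controls for mixture estimation.

    Estimation maximizes the log-likelihood over an unconstrained
    reparameterization: logit π; log(λ − 1) so shapes stay ≥ 1 (no density
    spikes exactly at a bound); log θ; the bounds L and U enter directly,
    constrained only by L < U.  The supports [L, ∞) and (−∞, U] jointly
    cover every observation whenever L < U, so neither bound needs to clear
    the data range — an extreme lower-tail draw from the upper-bounded
    component may legitimately fall below L.  Scale floors (θ ≥ 1e-3 of the
    data span) keep the optimizer away from the classical one-point
    likelihood degeneracy of location-scale mixtures.  ``starts``
    deterministic initializations are built from data quantile splits.
    """

    starts: int = 8
    min_n: int = 10
    tol: float = 1e-8
    max_iter: int = 4000
    seed: int = 0


class FitError(RuntimeError):
    """Optimizer failed to converge from every start; carries diagnostics."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


def _softplus(a: float) -> float:
    return float(np.logaddexp(0.0, a))


def _inv_softplus(y: float) -> float:
    # inverse of log(1+e^a); y > 0
    return float(y + np.log(-np.expm1(-y))) if y > 1e-10 else float(np.log(np.expm1(y)))


def _unpack(params: np.ndarray):
    t, s1, r1, L, s2, r2, U = params
    pi = 1.0 / (1.0 + math.exp(-min(max(t, -700), 700)))
    lam1 = 1.0 + math.exp(s1)
    th1 = math.exp(r1)
    lam2 = 1.0 + math.exp(s2)
    th2 = math.exp(r2)
    return pi, lam1, th1, float(L), lam2, th2, float(U)


def _neg_loglik(params: np.ndarray, xs: np.ndarray, span: float) -> float:
    pi, lam1, th1, L, lam2, th2, U = _unpack(params)
    if not (L < U) or lam1 > 1e4 or lam2 > 1e4:
        return 1e12
    if th1 < 1e-3 * span or th2 < 1e-3 * span:   # degeneracy guard
        return 1e12
    if not (0.0 < pi < 1.0):
        return 1e12
    z1 = xs - L
    z2 = U - xs
    with np.errstate(divide="ignore", invalid="ignore"):
        la = np.where(z1 > 0,
                      math.log(pi) + (lam1 - 1) * np.log(np.where(z1 > 0, z1, 1.0))
                      - z1 / th1 - special.gammaln(lam1) - lam1 * math.log(th1),
                      -np.inf)
        lb = np.where(z2 > 0,
                      math.log1p(-pi) + (lam2 - 1) * np.log(np.where(z2 > 0, z2, 1.0))
                      - z2 / th2 - special.gammaln(lam2) - lam2 * math.log(th2),
                      -np.inf)
    ll = np.logaddexp(la, lb).sum()
    if not np.isfinite(ll):
        return 1e12
    return -float(ll)


def _moment_start(xs: np.ndarray, split_q: float, pad: float) -> np.ndarray:
    """Initial unconstrained parameter vector from a quantile split.

    Data below the ``split_q`` quantile seed the right-facing component
    (moment-matched gamma above the group minimum − pad), the rest seed the
    left-facing one below the group maximum + pad.
    """
    cut = np.quantile(xs, split_q)
    left = xs[xs <= cut]
    right = xs[xs > cut]
    if left.size < 2 or right.size < 2:
        left, right = xs, xs

    def gamma_moments(z: np.ndarray):
        m, v = float(np.mean(z)), float(np.var(z)) + 1e-8
        lam = max(m * m / v, 1.05)
        th = max(m / lam, 1e-4)
        return lam, th

    L0 = float(left.min()) - pad
    U0 = float(right.max()) + pad
    lam1, th1 = gamma_moments(left - L0)
    lam2, th2 = gamma_moments(U0 - right)
    pi0 = left.size / xs.size
    pi0 = min(max(pi0, 0.05), 0.95)
    return np.array([
        math.log(pi0 / (1 - pi0)),
        math.log(lam1 - 1.0), math.log(th1), L0,
        math.log(lam2 - 1.0), math.log(th2), U0,
    ])


def fit_mixture(xs: Sequence[float], config: FitConfig = FitConfig()) -> MixtureModel:
    """Fit the seven-parameter facing-gamma mixture by maximum likelihood.

    Deterministic given ``config``: the multi-start schedule is a fixed set
    of data-quantile splits plus small seeded jitters.  Raises
    :class:`FitError` when no start converges and ``ValueError`` for samples
    below ``config.min_n``.
    """
    xs = np.asarray(xs, dtype=float)
    if xs.size < config.min_n:
        raise ValueError(
            f"mixture fitting needs at least {config.min_n} values, got {xs.size}")
    if np.any(xs <= 0):
        raise ValueError("trait values must be positive")
    lo, hi = float(xs.min()), float(xs.max())
    span = hi - lo
    if span <= 0:
        raise ValueError("degenerate sample: zero range")

    rng = np.random.default_rng(config.seed)
    splits = np.linspace(0.25, 0.75, config.starts)
    pads = [0.02 * span, 0.1 * span]
    best = None
    n_converged = 0
    for k, q in enumerate(splits):
        x0 = _moment_start(xs, float(q), pads[k % len(pads)])
        if k >= 2:  # jitter later starts to escape identical seeds
            x0 = x0 + rng.normal(0.0, 0.15, size=7)
        res = optimize.minimize(
            _neg_loglik, x0, args=(xs, span), method="Nelder-Mead",
            options={"maxiter": config.max_iter, "fatol": config.tol,
                     "xatol": 1e-8, "adaptive": True})
        # gradient polish from the simplex optimum
        res2 = optimize.minimize(_neg_loglik, res.x, args=(xs, span),
                                 method="L-BFGS-B",
                                 options={"maxiter": config.max_iter})
        if res2.fun < res.fun:
            res = res2
        if np.isfinite(res.fun) and res.fun < 1e11:
            n_converged += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None or best.fun >= 1e11:
        raise FitError("mixture fit failed to converge from every start", best=best)

    pi, lam1, th1, L, lam2, th2, U = _unpack(best.x)
    return MixtureModel(
        weight_homeo=pi,
        homeo=right_facing(lam1, th1, L),
        hetero=left_facing(lam2, th2, U),
        n=int(xs.size),
        loglik=-float(best.fun),
        meta={"starts": config.starts, "seed": config.seed,
              "converged": bool(n_converged > 0), "n_converged": int(n_converged)},
    )


def fit_single_gamma(xs: Sequence[float], config: FitConfig = FitConfig()
                     ) -> FacingGammaComponent:
    """MLE of a single right-facing (lower-bounded) gamma, bound estimated.

    The three-parameter baseline used for model comparison against the
    two-component mixture.
    """
    xs = np.asarray(xs, dtype=float)
    if xs.size < 3:
        raise ValueError("single-gamma fit needs at least 3 values")
    lo = float(xs.min())
    span = float(xs.max() - lo) or 1.0

    def nll(params):
        s, r, a = params
        lam = 1.0 + math.exp(s)
        th = math.exp(r)
        L = lo - _softplus(a)
        if lam > 1e4:
            return 1e12
        z = xs - L
        ll = ((lam - 1) * np.log(z) - z / th
              - special.gammaln(lam) - lam * math.log(th)).sum()
        return -float(ll) if np.isfinite(ll) else 1e12

    best = None
    for pad in (0.02 * span, 0.1 * span, 0.5 * span):
        L0 = lo - pad
        z = xs - L0
        m, v = float(np.mean(z)), float(np.var(z)) + 1e-8
        lam0 = max(m * m / v, 1.05)
        th0 = max(m / lam0, 1e-4)
        x0 = np.array([math.log(lam0 - 1.0), math.log(th0), _inv_softplus(pad)])
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 2000, "fatol": config.tol,
                                         "xatol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    s, r, a = best.x
    comp = right_facing(1.0 + math.exp(s), math.exp(r), lo - _softplus(a))
    return comp


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

class ClassificationRule(str, Enum):
    COMPONENT_QUANTILE = "component_quantile"
    POSTERIOR = "posterior"


def classification_cutoffs(m: MixtureModel, level: float = 0.95
                           ) -> tuple[float, float]:
    """Trait cutoffs asserting morph membership at ``level`` confidence.

    ``cutoff_low`` is the heteromorphic component's (1 − level) quantile:
    below it, at most (1 − level) of heteromorphic males occur, so a male
    there is homeomorphic at the stated level.  ``cutoff_high`` is the
    homeomorphic component's ``level`` quantile, symmetrically.  When
    cutoff_low > cutoff_high the two assertion regions cross — a band of
    trait values is claimed by both morphs at the stated level — and
    classification leaves that band unassigned; check
    :func:`cutoffs_overlap`.
    """
    if not 0.5 < level < 1.0:
        raise ValueError(f"level must lie in (0.5, 1), got {level}")
    cutoff_low = float(m.hetero.quantile(1.0 - level))
    cutoff_high = float(m.homeo.quantile(level))
    return cutoff_low, cutoff_high


def cutoffs_overlap(m: MixtureModel, level: float = 0.95) -> bool:
    """True when the two morphs' assertion regions cross."""
    lo, hi = classification_cutoffs(m, level)
    return lo > hi


@dataclass
class ClassificationResult:
    """Per-male morph assignment at a confidence level.

    ``labels[i]`` ∈ {"homeomorphic", "heteromorphic", "unassigned"};
    ``posterior[i]`` is P(heteromorphic | xᵢ).  Ties at a cutoff are left
    unassigned (strict inequalities).
    """

    level: float
    rule: ClassificationRule
    cutoff_low: float
    cutoff_high: float
    overlapping: bool
    values: np.ndarray
    posterior: np.ndarray
    labels: list[str]

    def counts(self) -> dict[str, int]:
        out = {"homeomorphic": 0, "heteromorphic": 0, "unassigned": 0}
        for lab in self.labels:
            out[lab] += 1
        return out

    def to_dict(self) -> dict:
        return {
            "level": self.level, "rule": self.rule.value,
            "cutoff_low": self.cutoff_low, "cutoff_high": self.cutoff_high,
            "overlapping": self.overlapping,
            "counts": self.counts(),
            "values": [float(v) for v in self.values],
            "posterior_hetero": [float(p) for p in self.posterior],
            "labels": list(self.labels),
        }


def classify(m: MixtureModel, xs: Sequence[float], level: float = 0.95,
             rule: ClassificationRule | str = ClassificationRule.COMPONENT_QUANTILE,
             ) -> ClassificationResult:
    """Label each trait value homeomorphic / heteromorphic / unassigned.

    ``component_quantile`` labels by position relative to the 95% cutoffs
    (the rule that reproduces printed cutoff values exactly from component
    parameters); ``posterior`` labels by thresholding the posterior morph
    probability at ``level``, which additionally depends on the mixing
    weight π.
    """
    rule = ClassificationRule(rule)
    xs = np.asarray(xs, dtype=float)
    cutoff_low, cutoff_high = classification_cutoffs(m, level)
    post = np.atleast_1d(m.posterior_hetero(xs))

    labels: list[str] = []
    for x, p in zip(xs, post):
        if rule is ClassificationRule.COMPONENT_QUANTILE:
            if x < cutoff_low and x < cutoff_high:
                labels.append("homeomorphic")
            elif x > cutoff_high and x > cutoff_low:
                labels.append("heteromorphic")
            else:
                labels.append("unassigned")
        else:
            if p >= level:
                labels.append("heteromorphic")
            elif p <= 1.0 - level:
                labels.append("homeomorphic")
            else:
                labels.append("unassigned")
    return ClassificationResult(
        level=level, rule=rule,
        cutoff_low=cutoff_low, cutoff_high=cutoff_high,
        overlapping=bool(cutoff_low > cutoff_high),
        values=xs, posterior=post, labels=labels,
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

@dataclass
class CandidateFit:
    name: str
    loglik: float
    k: int                      # number of free parameters
    aic: float
    aicc: float
    model: object
    error: Optional[str] = None

    def to_dict(self) -> dict:
        return {"name": self.name, "loglik": self.loglik, "k": self.k,
                "aic": self.aic, "aicc": self.aicc, "error": self.error}


@dataclass
class ComparisonReport:
    candidates: list[CandidateFit]
    preferred: Optional[str]    # None on an exact tie
    criterion: str

    def to_dict(self) -> dict:
        return {"criterion": self.criterion, "preferred": self.preferred,
                "candidates": [c.to_dict() for c in self.candidates]}


def _score(loglik: float, k: int, n: int) -> tuple[float, float]:
    aic = 2 * k - 2 * loglik
    denom = n - k - 1
    aicc = aic + (2 * k * (k + 1) / denom if denom > 0 else math.inf)
    return aic, aicc


def model_compare(xs: Sequence[float], config: FitConfig = FitConfig(),
                  criterion: str = "aic") -> ComparisonReport:
    """Fit a one-component lower-bounded gamma and the two-component facing
    mixture; rank them by AIC (or AICc via ``criterion="aicc"``).

    Per-candidate fit failures are recorded, not fatal, as long as one
    candidate converges.
    """
    if criterion not in ("aic", "aicc"):
        raise ValueError("criterion must be 'aic' or 'aicc'")
    xs = np.asarray(xs, dtype=float)
    n = int(xs.size)
    candidates: list[CandidateFit] = []

    try:
        single = fit_single_gamma(xs, config)
        ll = float(np.sum(single.logpdf(xs)))
        aic, aicc = _score(ll, 3, n)
        candidates.append(CandidateFit("single_gamma", ll, 3, aic, aicc, single))
    except Exception as exc:  # noqa: BLE001 — recorded, not fatal
        candidates.append(CandidateFit("single_gamma", math.nan, 3, math.inf,
                                       math.inf, None, error=str(exc)))
    try:
        mix = fit_mixture(xs, config)
        aic, aicc = _score(mix.loglik, 7, n)
        candidates.append(CandidateFit("facing_mixture", mix.loglik, 7, aic, aicc, mix))
    except Exception as exc:  # noqa: BLE001
        candidates.append(CandidateFit("facing_mixture", math.nan, 7, math.inf,
                                       math.inf, None, error=str(exc)))

    ok = [c for c in candidates if c.error is None]
    if not ok:
        raise FitError("no candidate model converged")
    key = (lambda c: c.aic) if criterion == "aic" else (lambda c: c.aicc)
    scores = sorted(ok, key=key)
    preferred = scores[0].name
    if len(scores) > 1 and math.isclose(key(scores[0]), key(scores[1]),
                                        rel_tol=0.0, abs_tol=1e-12):
        preferred = None  # exact tie: no preference
    return ComparisonReport(candidates, preferred, criterion)
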