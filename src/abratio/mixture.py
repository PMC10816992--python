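"""Unsupervised positivity threshold from a two-component Gaussian mixture.

The plasma A-beta 42/40 ratio of a mixed cohort (amyloid-positive and
-negative individuals) is bimodal, with the amyloid-positive component
shifted toward lower ratios. The unsupervised cutoff is obtained by

1. removing outliers with a Tukey fence (1.5 IQR beyond the quartiles),
2. fitting a two-component, unequal-variance univariate Gaussian mixture
   by expectation-maximisation, and
3. taking the intersection of the two fitted component curves, which is
   available in closed form as the root of a quadratic in the log-density
   difference.

Values at or below the threshold are classified plasmatic A-beta-positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "MixtureFit",
    "ThresholdMethod",
    "ThresholdResult",
    "BOUNDARY_RULE",
    "DegenerateFitError",
    "NoIntersectionError",
    "iqr_fences",
    "remove_outliers_iqr",
    "fit_gmm_em",
    "gaussian_intersection",
    "classify_plasmatic",
]

#: Classification convention at the cutoff (ties are called positive).
BOUNDARY_RULE = "value <= threshold => plasmatic Abeta+"

_VAR_FLOOR = 1e-12
# Hathaway-style constraint: reject solutions whose component scales differ
# by more than a factor 1/_SCALE_RATIO_MIN (guards the unbounded likelihood)
_SCALE_RATIO_MIN = 0.05


class ThresholdMethod(str, Enum):
    GMM = "gmm"
    STUMP = "stump"
    YOUDEN = "youden"


@dataclass(frozen=True)
class ThresholdResult:
    """A positivity cutoff on the 42/40 ratio scale.

    The boundary convention is shared by all three derivation methods:
    ratios less than or equal to the cutoff are plasmatic A-beta-positive.
    """

    value: float
    method: ThresholdMethod
    boundary_rule: str = BOUNDARY_RULE


@dataclass(frozen=True)
class MixtureFit:
    """Parameters of a fitted two-component univariate Gaussian mixture.

    Components are ordered so that ``means[0] < means[1]``; component 0 is
    the (lower-ratio) plasmatic A-beta-positive component.
    """

    weights: Tuple[float, float]
    means: Tuple[float, float]
    sds: Tuple[float, float]
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: Tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if abs(self.weights[0] + self.weights[1] - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        if not self.means[0] < self.means[1]:
            raise ValueError("components must be ordered with means[0] < means[1]")
        if min(self.sds) <= 0:
            raise ValueError("component standard deviations must be positive")

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return self.weights[0] * norm.pdf(x, self.means[0], self.sds[0]) + self.weights[
            1
        ] * norm.pdf(x, self.means[1], self.sds[1])


class DegenerateFitError(RuntimeError):
    """All EM restarts collapsed onto singular components."""


class NoIntersectionError(RuntimeError):
    """No density crossing exists between the two component means.

    Carries both roots of the log-density quadratic (attribute ``roots``)
    for inspection; this can happen with extremely unbalanced weights.
    """

    def __init__(self, msg: str, roots: Sequence[float]):
        super().__init__(msg)
        self.roots = tuple(roots)


def iqr_fences(values: Sequence[float]) -> Tuple[float, float]:
    """Tukey fences ``(q25 - 1.5 IQR, q75 + 1.5 IQR)``.

    Quartiles use linear interpolation between order statistics, the
    common statistical-software default.
    """
    v = np.asarray(values, dtype=float)
    q25, q75 = np.quantile(v, [0.25, 0.75])
    iqr = q75 - q25
    return q25 - 1.5 * iqr, q75 + 1.5 * iqr


def remove_outliers_iqr(values: Sequence[float]):
    """Split ``values`` into (kept, removed) by the interquartile criterion.

    The fences are computed once from the full input, not iteratively.
    Order within each part follows the input. Requires at least 4 finite
    values so that the quartiles are meaningful.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 4 or not np.all(np.isfinite(v)):
        raise ValueError("need at least 4 finite values to apply the IQR criterion")
    lo, hi = iqr_fences(v)
    keep = (v >= lo) & (v <= hi)
    return v[keep], v[~keep]


def _em_once(v: np.ndarray, mu: np.ndarray, sd: np.ndarray, w: np.ndarray,
             tol: float, max_iter: int):
    """Run EM from one starting point. Returns None on degenerate collapse."""
    n = v.size
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: log responsibilities
        logcomp = (
            np.log(w)[:, None]
            - 0.5 * math.log(2 * math.pi)
            - np.log(sd)[:, None]
            - 0.5 * ((v[None, :] - mu[:, None]) / sd[:, None]) ** 2
        )
        lognorm = logsumexp(logcomp, axis=0)
        loglik = float(lognorm.sum())
        trace.append(loglik)
        resp = np.exp(logcomp - lognorm[None, :])
        if abs(loglik - prev) < tol:
            converged = True
            break
        prev = loglik
        # M-step
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-10):
            return None
        w = nk / n
        mu = (resp @ v) / nk
        var = (resp @ (v**2)) / nk - mu**2
        var = np.maximum(var, _VAR_FLOOR)
        if np.any(var <= _VAR_FLOOR):
            # a component collapsed onto (nearly) a single point
            return None
        sd = np.sqrt(var)
    if sd.min() / sd.max() < _SCALE_RATIO_MIN:
        # spike component: the unequal-variance likelihood is unbounded, so
        # near-singular solutions are spurious maxima, not fits
        return None
    return w, mu, sd, trace, it, converged


def fit_gmm_em(
    values: Sequence[float],
    k: int = 2,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_starts: int = 10,
    seed: Optional[int] = None,
) -> MixtureFit:
    """Fit a two-component unequal-variance Gaussian mixture by EM.

    The log-likelihood is non-decreasing across EM iterations; convergence
    is declared when its successive change falls below ``tol``. The best of
    ``n_starts`` seeded restarts is returned, with components reordered so
    the lower-mean (amyloid-positive) component comes first. The first
    start splits the sorted sample at the median; subsequent starts jitter
    the component means. Collapsed (singular) restarts are discarded; if
    every restart collapses a :class:`DegenerateFitError` is raised.
    """
    if k != 2:
        raise NotImplementedError("only the two-component mixture is supported")
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 10 or not np.all(np.isfinite(v)):
        raise ValueError("need at least 10 finite values to fit the mixture")
    rng = np.random.default_rng(seed)
    s = np.sort(v)
    lower, upper = s[: v.size // 2], s[v.size // 2 :]
    mu0 = np.array([lower.mean(), upper.mean()])
    sd0 = np.array([max(lower.std(), 1e-6 * abs(mu0[0]) + 1e-12),
                    max(upper.std(), 1e-6 * abs(mu0[1]) + 1e-12)])
    spread = max(s[-1] - s[0], 1e-12)

    best = None
    for start in range(n_starts):
        if start == 0:
            mu, sd = mu0.copy(), sd0.copy()
        else:
            mu = mu0 + rng.normal(0.0, 0.25 * spread, size=2)
            sd = sd0 * rng.uniform(0.5, 2.0, size=2)
        out = _em_once(v, mu, sd, np.array([0.5, 0.5]), tol, max_iter)
        if out is None:
            continue
        if best is None or out[3][-1] > best[3][-1]:
            best = out
    if best is None:
        raise DegenerateFitError("every EM restart collapsed onto a singular component")
    w, mu, sd, trace, it, converged = best
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    # renormalise exactly so the stored weights sum to 1 to machine precision
    w = w / w.sum()
    return MixtureFit(
        weights=(float(w[0]), float(1.0 - w[0])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        loglik=float(trace[-1]),
        n_iter=it,
        converged=converged,
        loglik_trace=tuple(trace),
    )


def gaussian_intersection(fit: MixtureFit, weighted: bool = True) -> ThresholdResult:
    """Cutoff at the crossing of the two fitted Gaussian curves.

    With ``weighted=True`` (default) the weight-multiplied component
    densities are equated -- i.e. the posterior-probability-0.5 decision
    boundary of the fitted mixture. ``weighted=False`` equates the raw
    component densities instead. Equating log-densities gives a quadratic
    in x (linear when the variances are equal); the root lying strictly
    between the two means is the threshold. If no root falls in that
    interval a :class:`NoIntersectionError` is raised carrying both roots.
    """
    (m1, m2), (s1, s2) = fit.means, fit.sds
    (p1, p2) = fit.weights if weighted else (0.5, 0.5)
    logk = math.log(p1 / p2) + math.log(s2 / s1)
    if s1 == s2:
        # linear case: (m2-m1)/s^2 * x = (m2^2-m1^2)/(2 s^2) - logk... solve directly
        x = (m1 + m2) / 2.0 + s1 * s1 * logk / (m2 - m1)
        roots = [x]
    else:
        a = 1.0 / (2 * s2 * s2) - 1.0 / (2 * s1 * s1)
        b = m1 / (s1 * s1) - m2 / (s2 * s2)
        c = m2 * m2 / (2 * s2 * s2) - m1 * m1 / (2 * s1 * s1) + logk
        disc = b * b - 4 * a * c
        if disc < 0:
            raise NoIntersectionError("log-density quadratic has no real roots", [])
        sq = math.sqrt(disc)
        # numerically stable quadratic roots
        q = -0.5 * (b + math.copysign(sq, b))
        roots = sorted({q / a, c / q if q != 0 else -b / (2 * a)})
    inside = [r for r in roots if m1 < r < m2]
    if not inside:
        raise NoIntersectionError(
            f"no density crossing between the component means ({m1:.6g}, {m2:.6g})",
            roots,
        )
    return ThresholdResult(value=float(inside[0]), method=ThresholdMethod.GMM)


def classify_plasmatic(values: Sequence[float], thr: ThresholdResult) -> np.ndarray:
    """Label each ratio ``positive`` (<= threshold) or ``negative`` (>)."""
    v = np.asarray(values, dtype=float)
    return np.where(v <= thr.value, "positive", "negative")
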