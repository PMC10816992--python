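"""ROC curve, AUC with 95% CI, and the Youden-index threshold.

Positivity direction is fixed a priori: a LOW plasma 42/40 ratio indicates
brain amyloidosis, so a value is called positive when it is at or below
the cutoff. The curve therefore traces (1-Sp, Sn) as the cutoff sweeps
from below the smallest to above the largest observed value. The
trapezoidal AUC equals the Mann-Whitney probability
``P(x+ < x-) + 0.5 P(x+ = x-)``. Confidence intervals come from DeLong's
placement-value variance (default) or a stratified percentile bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .mixture import ThresholdMethod, ThresholdResult
from .stump import SingleClassError, _coerce

__all__ = ["RocCurve", "roc_curve", "auc_ci", "youden_threshold", "plot_roc"]


@dataclass(frozen=True)
class RocCurve:
    """Operating points of the ratio test over all cutoffs.

    ``thresholds`` contains one entry per distinct observed value plus the
    two trivial endpoints ``-inf`` (nothing called positive: Sn=0, Sp=1)
    and ``+inf`` (everything positive: Sn=1, Sp=0). Sensitivity is
    non-decreasing in the threshold because positivity means
    ``value <= threshold``.
    """

    thresholds: Tuple[float, ...]
    sensitivity: Tuple[float, ...]
    specificity: Tuple[float, ...]
    auc: float
    auc_ci: Optional[Tuple[float, float]] = None

    @property
    def points(self):
        return list(zip(self.thresholds, self.sensitivity, self.specificity))

    def youden(self) -> Tuple[float, ...]:
        """J = Sn + Sp - 1 at every operating point."""
        return tuple(sn + sp - 1.0 for sn, sp in zip(self.sensitivity, self.specificity))


def _split_classes(values, truth):
    v, t = _coerce(values, truth)
    if t.all() or not t.any():
        raise SingleClassError("ROC analysis requires both classes")
    return v[t], v[~t]


def roc_curve(values, truth=None) -> RocCurve:
    """ROC curve of the ratio against CSF/PET amyloid status.

    Accepts ``LabeledSample`` pairs or separate value/truth sequences.
    """
    pos, neg = _split_classes(values, truth)
    cuts = np.unique(np.concatenate([pos, neg]))
    # value <= cut is called positive
    sn = np.searchsorted(np.sort(pos), cuts, side="right") / pos.size
    fpr = np.searchsorted(np.sort(neg), cuts, side="right") / neg.size
    thresholds = np.concatenate([[-np.inf], cuts, [np.inf]])
    sn = np.concatenate([[0.0], sn, [1.0]])
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    auc = float(np.trapezoid(sn, fpr))
    return RocCurve(
        thresholds=tuple(float(t) for t in thresholds),
        sensitivity=tuple(float(x) for x in sn),
        specificity=tuple(float(1.0 - x) for x in fpr),
        auc=auc,
    )


def _placements(pos: np.ndarray, neg: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """DeLong placement values under the low-value-positive orientation.

    ``v10[i]`` is the fraction of negatives ranked below positive i
    (ties half-weighted); ``v01[j]`` symmetric for negatives.
    """
    # low ratio = positive: a positive is correctly ranked against a
    # negative when it is SMALLER, so count negatives above each positive
    ns = np.sort(neg)
    left = np.searchsorted(ns, pos, side="left")
    right = np.searchsorted(ns, pos, side="right")
    v10 = ((neg.size - right) + 0.5 * (right - left)) / neg.size
    ps = np.sort(pos)
    left = np.searchsorted(ps, neg, side="left")
    right = np.searchsorted(ps, neg, side="right")
    v01 = (left + 0.5 * (right - left)) / pos.size
    return v10, v01


def auc_ci(
    values,
    truth=None,
    method: str = "delong",
    level: float = 0.95,
    seed: Optional[int] = None,
    n_boot: int = 2000,
) -> Tuple[float, float]:
    """Confidence interval for the AUC, clipped to [0, 1].

    ``method="delong"`` uses the asymptotic placement-value variance;
    ``method="bootstrap"`` a stratified percentile bootstrap with
    ``n_boot`` resamples (seeded). With every observed value identical the
    variance degenerates and an error is raised.
    """
    pos, neg = _split_classes(values, truth)
    if np.unique(np.concatenate([pos, neg])).size == 1:
        raise ValueError("all values tied: AUC variance degenerates to 0")
    if method == "delong":
        v10, v01 = _placements(pos, neg)
        auc = float(v10.mean())
        var = 0.0
        if pos.size > 1:
            var += v10.var(ddof=1) / pos.size
        if neg.size > 1:
            var += v01.var(ddof=1) / neg.size
        z = norm.ppf(0.5 + level / 2)
        half = z * math.sqrt(var)
        lo, hi = auc - half, auc + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos, size=pos.size, replace=True)
            bn = rng.choice(neg, size=neg.size, replace=True)
            v10, _ = _placements(bp, bn)
            aucs[b] = v10.mean()
        alpha = 1 - level
        lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(max(0.0, lo)), float(min(1.0, hi))


def youden_threshold(roc: RocCurve) -> ThresholdResult:
    """Observed cutoff maximising J = Sn + Sp - 1.

    Only finite (observed) cutoffs compete. Ties are broken toward the
    higher-specificity (smaller) cutoff, favouring fewer false positives
    in a screening-then-confirmation chain.
    """
    best = None
    for t, sn, sp in roc.points:
        if not math.isfinite(t):
            continue
        j = sn + sp - 1.0
        if best is None or j > best[0] + 1e-15 or (abs(j - best[0]) <= 1e-15 and sp > best[1]):
            best = (j, sp, t)
    if best is None:
        raise ValueError("degenerate ROC curve: no finite operating point")
    return ThresholdResult(value=float(best[2]), method=ThresholdMethod.YOUDEN)


def plot_roc(roc: RocCurve, annotations: Optional[dict] = None, path=None):
    """Plot the ROC curve, optionally annotating named cutoffs.

    ``annotations`` maps a label (e.g. ``"gmm"``) to a threshold value;
    the nearest operating point is marked. Saves to ``path`` when given,
    otherwise returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = [1 - sp for sp in roc.specificity]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(fpr, roc.sensitivity, drawstyle="steps-post", color="C0", lw=1.5)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    if annotations:
        thr = np.asarray(roc.thresholds)
        for name, value in annotations.items():
            i = int(np.argmin(np.abs(np.where(np.isfinite(thr), thr, np.inf) - value)))
            ax.plot(1 - roc.specificity[i], roc.sensitivity[i], "o", ms=5)
            ax.annotate(
                f"{name}: {value:.4f}",
                (1 - roc.specificity[i], roc.sensitivity[i]),
                textcoords="offset points",
                xytext=(8, -4),
                fontsize=8,
            )
    ci = f" (95% CI {roc.auc_ci[0]:.3f}-{roc.auc_ci[1]:.3f})" if roc.auc_ci else ""
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc.auc:.3f}{ci}", fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
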