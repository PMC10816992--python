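"""Supervised threshold from a depth-one decision tree (Gini stump).

Given ratios paired with CSF/PET amyloid status, the stump scans every
midpoint between consecutive distinct sorted values and keeps the cut that
minimises the size-weighted Gini impurity of the two leaves. The left
branch (ratio <= cut) predicts amyloid-positive; this direction is fixed a
priori because brain amyloidosis lowers the plasma 42/40 ratio. Training
uses all labelled data: no cross-validation, no pruning, no class weights.
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np

from .diagnostics import DiagnosticPerformance, evaluate_threshold
from .mixture import ThresholdMethod, ThresholdResult

__all__ = ["LabeledSample", "SingleClassError", "fit_stump", "split_details", "stump_performance"]


class LabeledSample(NamedTuple):
    """A ratio paired with its ground-truth amyloid status."""

    value: float
    truth: str  # "positive" or "negative"


class SingleClassError(ValueError):
    """The labelled input contains only one class (or no valid split)."""


def _coerce(samples, truth) -> Tuple[np.ndarray, np.ndarray]:
    if truth is None:
        pairs = list(samples)
        values = np.array([s[0] for s in pairs], dtype=float)
        truth = [s[1] for s in pairs]
    else:
        values = np.asarray(samples, dtype=float)
    t = np.asarray(truth)
    if t.dtype != bool:
        t = np.asarray(
            [
                bool(x) if isinstance(x, (bool, np.bool_, int, np.integer))
                else str(getattr(x, "value", x)).lower() == "positive"
                for x in truth
            ],
            dtype=bool,
        )
    if values.shape != t.shape or values.ndim != 1:
        raise ValueError("values and truth labels must be 1-d and of equal length")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    return values, t


def fit_stump(samples: Union[Sequence[LabeledSample], Sequence[float]],
              truth: Optional[Sequence] = None) -> ThresholdResult:
    """Exhaustive one-split Gini stump.

    Accepts either a sequence of :class:`LabeledSample` or separate
    ``values``/``truth`` sequences. Candidate cutpoints are the midpoints
    between consecutive distinct sorted values; the returned cut minimises

    ``n_L/n * G(L) + n_R/n * G(R)``, with ``G = 1 - sum_c p_c^2``.

    When several cuts tie, the smallest is returned (deterministic).
    Raises :class:`SingleClassError` when only one class is present or all
    values are identical (no valid split).
    """
    v, t = _coerce(samples, truth)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 labelled samples")
    if t.all() or not t.any():
        raise SingleClassError("both classes must be present to fit a stump")
    order = np.argsort(v, kind="stable")
    vs, ts = v[order], t[order]
    boundary = np.nonzero(np.diff(vs) > 0)[0]  # split after index i
    if boundary.size == 0:
        raise SingleClassError("all values identical: no valid split exists")
    pos_left = np.cumsum(ts)[boundary].astype(float)
    n_left = (boundary + 1).astype(float)
    n_pos = float(ts.sum())
    pos_right = n_pos - pos_left
    n_right = n - n_left

    def gini(pos, tot):
        p = pos / tot
        return 1.0 - p * p - (1.0 - p) * (1.0 - p)

    impurity = (n_left / n) * gini(pos_left, n_left) + (n_right / n) * gini(pos_right, n_right)
    # smallest cut among (numerical) ties on the minimal impurity
    best = int(np.nonzero(impurity <= impurity.min() + 1e-12)[0][0])
    i = boundary[best]
    cut = 0.5 * (vs[i] + vs[i + 1])
    return ThresholdResult(value=float(cut), method=ThresholdMethod.STUMP)


def split_details(samples, truth=None, thr: Optional[ThresholdResult] = None) -> dict:
    """Leaf composition and impurities of a (fitted) stump, for reporting."""
    v, t = _coerce(samples, truth)
    if thr is None:
        thr = fit_stump(v, t)
    left = v <= thr.value
    out = {"threshold": thr.value, "leaves": {}}
    n = v.size
    total = 0.0
    for name, mask in (("left_le", left), ("right_gt", ~left)):
        npos = int(t[mask].sum())
        nn = int(mask.sum())
        gini = 0.0
        if nn:
            p = npos / nn
            gini = 1.0 - p * p - (1 - p) * (1 - p)
        total += (nn / n) * gini
        out["leaves"][name] = {"n": nn, "n_positive": npos, "n_negative": nn - npos, "gini": gini}
    out["weighted_gini"] = total
    return out


def stump_performance(samples, truth=None, thr: Optional[ThresholdResult] = None) -> DiagnosticPerformance:
    """Sensitivity/specificity of a stump cutoff on labelled samples.

    Uses the shared boundary rule (ratio <= cut is called positive). When
    ``thr`` is omitted the stump is fitted on the same samples first, which
    mirrors an apparent-performance evaluation on the training data.
    """
    v, t = _coerce(samples, truth)
    if thr is None:
        thr = fit_stump(v, t)
    return evaluate_threshold(v, t, thr.value)
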