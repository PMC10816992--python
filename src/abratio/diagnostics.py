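"""Confusion-matrix metrics, likelihood ratios, and posttest probabilities.

The screening calculus: a cutoff's sensitivity Sn and specificity Sp give
likelihood ratios LR+ = Sn/(1-Sp) and LR- = (1-Sn)/Sp. For a person with
pretest (prevalence-based) probability p of brain amyloidosis, the pretest
odds p/(1-p) multiplied by the likelihood ratio of the observed test
result yield the posttest odds, hence the posttest probability. All
arithmetic is carried out on exact fractions of counts; rounding is a
presentation concern (see :func:`round_half_up`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "DiagnosticPerformance",
    "PosttestResult",
    "confusion",
    "sens_spec",
    "likelihood_ratios",
    "posttest",
    "evaluate_threshold",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), as tables are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _as_bool(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return np.asarray(
        [
            bool(x) if isinstance(x, (bool, np.bool_, int, np.integer))
            else str(getattr(x, "value", x)).lower() == "positive"
            for x in labels
        ],
        dtype=bool,
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of plasmatic calls against CSF/PET amyloid status."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_positive(self) -> int:
        """Number of truly amyloid-positive participants."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Sensitivity/specificity of a cutoff with its likelihood ratios."""

    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float
    cm: ConfusionMatrix


@dataclass(frozen=True)
class PosttestResult:
    """Pretest and posttest odds/probabilities at one prevalence."""

    prevalence: float
    pretest_odds: float
    posttest_odds_pos: float
    posttest_odds_neg: float
    posttest_prob_pos: float
    posttest_prob_neg: float


def confusion(pred: Sequence, truth: Sequence) -> ConfusionMatrix:
    """Cross-tabulate predicted plasmatic calls against amyloid status.

    Labels may be booleans or the strings ``positive``/``negative``.
    """
    p = _as_bool(pred)
    t = _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.size} predictions vs {t.size} truths")
    return ConfusionMatrix(
        tp=int(np.sum(p & t)),
        fn=int(np.sum(~p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
    )


def sens_spec(cm: ConfusionMatrix) -> Tuple[float, float]:
    """``(tp/(tp+fn), tn/(fp+tn))``; raises on an empty truth margin."""
    if cm.n_positive == 0 or cm.n_negative == 0:
        raise ValueError("sensitivity/specificity undefined: a truth margin is empty")
    return cm.tp / cm.n_positive, cm.tn / cm.n_negative


def likelihood_ratios(sensitivity: float, specificity: float) -> Tuple[float, float]:
    """``(Sn/(1-Sp), (1-Sn)/Sp)``.

    A perfectly specific test has an infinite positive likelihood ratio
    (returned as ``math.inf``); zero specificity leaves LR- undefined and
    raises.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if specificity == 0:
        raise ValueError("LR- undefined at specificity 0")
    lr_pos = math.inf if specificity == 1 else sensitivity / (1 - specificity)
    lr_neg = (1 - sensitivity) / specificity
    return lr_pos, lr_neg


def posttest(prevalence: float, sensitivity: float, specificity: float) -> PosttestResult:
    """Posttest probabilities of amyloidosis after a positive/negative test.

    ``prevalence`` is the pretest probability in the target population
    (e.g. 15.8% among clinically normal 60-year-olds, 32.6% at 80).
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    lr_pos, lr_neg = likelihood_ratios(sensitivity, specificity)
    pre = prevalence / (1 - prevalence)
    odds_pos = pre * lr_pos
    odds_neg = pre * lr_neg
    return PosttestResult(
        prevalence=prevalence,
        pretest_odds=pre,
        posttest_odds_pos=odds_pos,
        posttest_odds_neg=odds_neg,
        posttest_prob_pos=1.0 if math.isinf(odds_pos) else odds_pos / (1 + odds_pos),
        posttest_prob_neg=odds_neg / (1 + odds_neg),
    )


def evaluate_threshold(values: Sequence[float], truth: Sequence, threshold: float) -> DiagnosticPerformance:
    """Apparent performance of a cutoff on labelled ratios (<= is positive)."""
    v = np.asarray(values, dtype=float)
    pred = v <= threshold
    cm = confusion(pred.tolist(), truth)
    sn, sp = sens_spec(cm)
    if sp == 0:
        lr_pos, lr_neg = math.inf, math.nan
    else:
        lr_pos, lr_neg = likelihood_ratios(sn, sp)
    return DiagnosticPerformance(sensitivity=sn, specificity=sp, lr_pos=lr_pos, lr_neg=lr_neg, cm=cm)
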