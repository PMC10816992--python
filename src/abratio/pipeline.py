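"""End-to-end analysis: eligibility filter, three thresholds, performance
tables, and posttest probabilities.

The flow mirrors how the three cutoffs differ in the population they see:

* the Gaussian-mixture cutoff is fitted on ALL participants with a plasma
  ratio -- labelled or not -- after IQR outlier removal (this asymmetry is
  deliberate and enforced: the unsupervised method is exactly the one
  that can exploit unlabelled ratios);
* the Gini stump is trained on the eligible labelled subset;
* the ROC/Youden cutoff uses only eligible labelled participants WITHOUT
  dementia, the screening population of interest.

Each cutoff is then evaluated on both labelled subgroups, and the
non-demented sensitivity/specificity feed the posttest-probability grid.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from . import __version__
from .cohort import (
    AmyloidStatus,
    Cohort,
    DEFAULT_WINDOW_DAYS,
    call_amyloid,
    has_dementia,
    is_eligible,
    read_cohort,
)
from .diagnostics import DiagnosticPerformance, PosttestResult, posttest, round_half_up
from .mixture import (
    MixtureFit,
    ThresholdResult,
    fit_gmm_em,
    gaussian_intersection,
    iqr_fences,
    remove_outliers_iqr,
)
from .roc import RocCurve, auc_ci, roc_curve, youden_threshold
from .stump import SingleClassError, fit_stump, split_details
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["AnalysisReport", "run_pipeline", "render_report"]

log = logging.getLogger(__name__)

#: Default pretest prevalences of amyloid positivity among clinically
#: normal adults, by age.
DEFAULT_PREVALENCES = {"age_60": 0.158, "age_80": 0.326}


@dataclass
class AnalysisReport:
    """Everything the pipeline computed, JSON-serialisable via ``to_dict``."""

    thresholds: Dict[str, ThresholdResult]
    mixture_fit: Optional[MixtureFit]
    outlier_ids: List[str]
    stump_details: Optional[dict]
    roc: Optional[RocCurve]
    performance: Dict[str, Dict[str, DiagnosticPerformance]]  # method -> subgroup -> perf
    posttest: Dict[str, Dict[str, PosttestResult]]  # method -> prevalence label -> result
    counts: Dict[str, int]
    warnings: List[str]
    provenance: Dict[str, str]

    def to_dict(self) -> dict:
        def num(x):
            if x is None or (isinstance(x, float) and math.isnan(x)):
                return None
            if isinstance(x, float) and math.isinf(x):
                return "inf" if x > 0 else "-inf"
            return x

        out: dict = {
            "thresholds": {
                m: {"value": t.value, "method": t.method.value, "boundary_rule": t.boundary_rule}
                for m, t in self.thresholds.items()
            },
            "counts": dict(sorted(self.counts.items())),
            "warnings": list(self.warnings),
            "provenance": dict(sorted(self.provenance.items())),
            "outlier_ids": list(self.outlier_ids),
        }
        if self.mixture_fit is not None:
            f = self.mixture_fit
            out["mixture_fit"] = {
                "weights": list(f.weights),
                "means": list(f.means),
                "sds": list(f.sds),
                "loglik": f.loglik,
                "n_iter": f.n_iter,
                "converged": f.converged,
            }
        if self.stump_details is not None:
            out["stump"] = self.stump_details
        if self.roc is not None:
            out["roc"] = {
                "auc": self.roc.auc,
                "auc_ci": None if self.roc.auc_ci is None else list(self.roc.auc_ci),
                "n_points": len(self.roc.thresholds),
            }
        out["performance"] = {
            m: {
                sub: {
                    "sensitivity": p.sensitivity,
                    "specificity": p.specificity,
                    "lr_pos": num(p.lr_pos),
                    "lr_neg": num(p.lr_neg),
                    "confusion": {"tp": p.cm.tp, "fn": p.cm.fn, "fp": p.cm.fp, "tn": p.cm.tn},
                }
                for sub, p in subs.items()
            }
            for m, subs in self.performance.items()
        }
        out["posttest"] = {
            m: {
                label: {
                    "prevalence": r.prevalence,
                    "pretest_odds": r.pretest_odds,
                    "posttest_odds_pos": num(r.posttest_odds_pos),
                    "posttest_odds_neg": num(r.posttest_odds_neg),
                    "posttest_prob_pos": r.posttest_prob_pos,
                    "posttest_prob_neg": r.posttest_prob_neg,
                }
                for label, r in results.items()
            }
            for m, results in self.posttest.items()
        }
        return out


def _config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    cohort: Optional[Cohort] = None,
    cohort_path=None,
    generator_config: Optional[GeneratorConfig] = None,
    window_days: int = DEFAULT_WINDOW_DAYS,
    prevalences: Optional[Dict[str, float]] = None,
    ci_method: str = "delong",
    weighted_intersection: bool = True,
    csf_precedence: bool = True,
    seed: int = 0,
) -> AnalysisReport:
    """Run the full threshold analysis on a cohort.

    Exactly one of ``cohort``, ``cohort_path`` or ``generator_config``
    must be provided. ``seed`` drives the EM restarts and any bootstrap;
    with a generator config the cohort itself is reproducible from the
    config's own seed. Supervised stages are skipped (with a recorded
    warning) when the labelled subset is empty or single-class; the
    mixture threshold always runs.
    """
    sources = [cohort is not None, cohort_path is not None, generator_config is not None]
    if sum(sources) != 1:
        raise ValueError("provide exactly one of cohort, cohort_path, generator_config")
    provenance = {"version": __version__, "seed": str(seed), "window_days": str(window_days)}
    if cohort_path is not None:
        cohort = read_cohort(cohort_path)
        provenance["source"] = f"file:{cohort_path}"
    elif generator_config is not None:
        cohort = generate_cohort(generator_config)
        provenance["source"] = "synthetic"
        provenance["config_hash"] = _config_hash(generator_config.to_dict())
    else:
        provenance["source"] = "in-memory"
    prevalences = dict(prevalences or DEFAULT_PREVALENCES)
    warnings: List[str] = []
    counts: Dict[str, int] = {"cohort": len(cohort)}

    # ---- eligibility and subgroups -------------------------------------
    with_ratio = [p for p in cohort if p.ratio is not None]
    counts["with_ratio"] = len(with_ratio)
    labeled = []
    for p in cohort:
        call = call_amyloid(p, csf_precedence=csf_precedence)
        if call.status is AmyloidStatus.UNKNOWN:
            continue
        if p.ratio is None:
            continue
        if is_eligible(p, window_days=window_days, csf_precedence=csf_precedence):
            labeled.append((p, call.status is AmyloidStatus.POSITIVE))
    n_measured = sum(
        1 for p in cohort if call_amyloid(p, csf_precedence=csf_precedence).status is not AmyloidStatus.UNKNOWN
    )
    counts["amyloid_measured"] = n_measured
    counts["eligible_labeled"] = len(labeled)
    counts["excluded_by_window"] = n_measured - len(labeled)
    nondem = [(p, t) for p, t in labeled if p.mmse is not None and not has_dementia(p)]
    counts["eligible_labeled_nondemented"] = len(nondem)
    log.info(
        "cohort %d | with ratio %d | amyloid measured %d | eligible labelled %d | non-demented %d",
        counts["cohort"], counts["with_ratio"], n_measured, len(labeled), len(nondem),
    )

    thresholds: Dict[str, ThresholdResult] = {}
    performance: Dict[str, Dict[str, DiagnosticPerformance]] = {}
    posttest_grid: Dict[str, Dict[str, PosttestResult]] = {}

    # ---- mixture threshold on ALL ratios (labelled and unlabelled) -----
    ratios = np.array([p.ratio for p in with_ratio], dtype=float)
    kept, _removed = remove_outliers_iqr(ratios)
    lo, hi = iqr_fences(ratios)
    outlier_ids = [p.id for p in with_ratio if not lo <= p.ratio <= hi]
    counts["outliers_removed"] = len(outlier_ids)
    log.info("IQR outlier filter removed %d of %d ratios", len(outlier_ids), ratios.size)
    fit = fit_gmm_em(kept, seed=seed)
    thresholds["gmm"] = gaussian_intersection(fit, weighted=weighted_intersection)

    # ---- supervised stages ---------------------------------------------
    stump_dets = None
    roc = None
    lv = np.array([p.ratio for p, _ in labeled], dtype=float)
    lt = [t for _, t in labeled]
    try:
        if not labeled:
            raise SingleClassError("no eligible labelled participants")
        thresholds["stump"] = fit_stump(lv, lt)
        stump_dets = split_details(lv, lt, thresholds["stump"])
    except SingleClassError as exc:
        warnings.append(f"stump stage skipped: {exc}")
        log.warning("stump stage skipped: %s", exc)
    try:
        if not nondem:
            raise SingleClassError("no eligible labelled non-demented participants")
        nv = np.array([p.ratio for p, _ in nondem], dtype=float)
        nt = [t for _, t in nondem]
        curve = roc_curve(nv, nt)
        ci = auc_ci(nv, nt, method=ci_method, seed=seed)
        roc = RocCurve(curve.thresholds, curve.sensitivity, curve.specificity, curve.auc, ci)
        thresholds["youden"] = youden_threshold(roc)
    except (SingleClassError, ValueError) as exc:
        warnings.append(f"ROC stage skipped: {exc}")
        log.warning("ROC stage skipped: %s", exc)

    # ---- performance tables and posttest grid --------------------------
    from .diagnostics import evaluate_threshold  # local import avoids cycle at module load

    subgroups = {"all": (lv, lt), "non_demented": ([p.ratio for p, _ in nondem], [t for _, t in nondem])}
    for method, thr in thresholds.items():
        by_subgroup = {}
        for name, (vals, tru) in subgroups.items():
            vals = np.asarray(vals, dtype=float)
            if vals.size and any(tru) and not all(tru):
                by_subgroup[name] = evaluate_threshold(vals, tru, thr.value)
        if by_subgroup:
            performance[method] = by_subgroup
        perf = by_subgroup.get("non_demented")
        if perf is not None and 0 < perf.specificity:
            posttest_grid[method] = {
                label: posttest(prev, perf.sensitivity, perf.specificity)
                for label, prev in sorted(prevalences.items())
            }

    return AnalysisReport(
        thresholds=thresholds,
        mixture_fit=fit,
        outlier_ids=outlier_ids,
        stump_details=stump_dets,
        roc=roc,
        performance=performance,
        posttest=posttest_grid,
        counts=counts,
        warnings=warnings,
        provenance=provenance,
    )


def _pct(x: float) -> str:
    return f"{round_half_up(100 * x, 1):.1f}%"


def render_report(report: AnalysisReport, format: str = "json") -> str:
    """Serialise a report as canonical JSON or a markdown summary.

    Identical reports render to identical bytes (keys sorted, floats via
    ``repr``), so re-running with the same seed and config is bit-stable.
    """
    if format == "json":
        return json.dumps(report.to_dict(), sort_keys=True, indent=2) + "\n"
    if format != "markdown":
        raise ValueError(f"unknown report format {format!r}")

    lines = ["# Plasma A-beta 42/40 threshold analysis", ""]
    c = report.counts
    lines += [
        f"Cohort: {c.get('cohort', 0)} participants; {c.get('amyloid_measured', 0)} with a CSF/PET "
        f"amyloid measurement; {c.get('eligible_labeled', 0)} eligible labelled "
        f"({c.get('eligible_labeled_nondemented', 0)} without dementia); "
        f"{c.get('outliers_removed', 0)} ratio outliers removed before the mixture fit.",
        "",
        "## Thresholds",
        "",
        "| method | threshold | rule |",
        "|---|---|---|",
    ]
    for m, t in sorted(report.thresholds.items()):
        lines.append(f"| {m} | {t.value:.4f} | {t.boundary_rule} |")
    skipped = [w for w in report.warnings]
    if skipped:
        lines += ["", "## Skipped stages", ""] + [f"- {w}" for w in skipped]
    if report.roc is not None:
        ci = report.roc.auc_ci
        ci_txt = f" (95% CI {ci[0]:.3f}-{ci[1]:.3f})" if ci else ""
        lines += ["", f"AUC (non-demented labelled subset): {report.roc.auc:.3f}{ci_txt}"]
    for m, subs in sorted(report.performance.items()):
        for sub, p in sorted(subs.items()):
            pop = "All individuals" if sub == "all" else "Non-demented individuals"
            lines += [
                "",
                f"## {pop} -- {m} threshold {report.thresholds[m].value:.4f}",
                "",
                f"| {pop} | CSF/PET A-beta+ | CSF/PET A-beta- |",
                "|---|---|---|",
                f"| Plasmatic A-beta+ | {p.cm.tp} | {p.cm.fp} |",
                f"| Plasmatic A-beta- | {p.cm.fn} | {p.cm.tn} |",
                "",
                f"Sensitivity {_pct(p.sensitivity)}, specificity {_pct(p.specificity)}.",
            ]
    if report.posttest:
        lines += ["", "## Posttest probabilities (non-demented Sn/Sp)", "",
                  "| method | prevalence | P(A-beta+ | test+) | P(A-beta+ | test-) |",
                  "|---|---|---|---|"]
        for m, grid in sorted(report.posttest.items()):
            for label, r in sorted(grid.items()):
                lines.append(
                    f"| {m} | {label}: {_pct(r.prevalence)} | {_pct(r.posttest_prob_pos)} "
                    f"| {_pct(r.posttest_prob_neg)} |"
                )
    lines += ["", f"Provenance: {json.dumps(report.provenance, sort_keys=True)}", ""]
    return "\n".join(lines)
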