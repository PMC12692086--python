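"""Diagnostic evaluation of score positivity against the bleeding outcome.

Implements confusion-matrix metrics as exact rationals (sensitivity,
specificity, positivity rate), the empirical ROC AUC with the midrank
tie convention, and Youden-index cut-off selection for continuous
markers.  Published contingency tables for the original score and two
modifications, stratified by AML subgroup, ship as a packaged CSV and
can be expanded back into per-patient prediction/outcome pairs so the
whole metric pipeline is exercised end to end.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort, Subgroup
from .scoring import ScoreId, score_all

__all__ = [
    "ConfusionMatrix",
    "MarkerDirection",
    "UndefinedMetricError",
    "confusion",
    "sensitivity",
    "specificity",
    "positivity_rate",
    "percent",
    "empirical_auc",
    "YoudenResult",
    "youden_cutoff",
    "expand_contingency",
    "MARKER_DIRECTIONS",
    "StratumScoreReport",
    "MarkerReport",
    "EvaluationReport",
    "evaluate_cohort",
    "load_reference_contingency",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero (e.g. no bleeders in the stratum)."""


class MarkerDirection(str, enum.Enum):
    """Which tail of a marker indicates bleeding risk."""

    HIGH_RISK = "high_risk"  # larger values -> bleeding (LDH, D-dimer, PT, INR)
    LOW_RISK = "low_risk"    # smaller values -> bleeding (fibrinogen, platelets, Hgb)


#: Risk direction of each continuous marker; explicit configuration,
#: never inferred from data (silent flipping could fabricate AUC > 0.5).
MARKER_DIRECTIONS: dict[str, MarkerDirection] = {
    "pt_seconds": MarkerDirection.HIGH_RISK,
    "d_dimer_ng_ml": MarkerDirection.HIGH_RISK,
    "fibrinogen_mg_dl": MarkerDirection.LOW_RISK,
    "platelet_1e9_l": MarkerDirection.LOW_RISK,
    "ldh": MarkerDirection.HIGH_RISK,
    "hemoglobin_g_dl": MarkerDirection.LOW_RISK,
    "inr": MarkerDirection.HIGH_RISK,
}


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of score positivity against the true bleeding outcome."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive_outcome(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative_outcome(self) -> int:
        return self.fp + self.tn


def confusion(predictions: Sequence[bool], outcomes: Sequence[bool]) -> ConfusionMatrix:
    """Tabulate binary predictions against binary outcomes."""
    if len(predictions) != len(outcomes):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(outcomes)} outcomes"
        )
    if len(predictions) == 0:
        raise ValueError("empty input")
    p = np.asarray(predictions, dtype=bool)
    o = np.asarray(outcomes, dtype=bool)
    return ConfusionMatrix(
        tp=int(np.sum(p & o)),
        fp=int(np.sum(p & ~o)),
        fn=int(np.sum(~p & o)),
        tn=int(np.sum(~p & ~o)),
    )


def sensitivity(cm: ConfusionMatrix) -> Fraction:
    """TP / (TP + FN), exact."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive outcomes")
    return Fraction(cm.tp, cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> Fraction:
    """TN / (TN + FP), exact."""
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative outcomes")
    return Fraction(cm.tn, cm.tn + cm.fp)


def positivity_rate(cm: ConfusionMatrix) -> Fraction:
    """(TP + FP) / N: fraction of the stratum flagged score-positive."""
    if cm.n == 0:
        raise UndefinedMetricError("positivity rate undefined: empty stratum")
    return Fraction(cm.tp + cm.fp, cm.n)


def percent(value: Fraction | float, decimals: int = 1) -> float:
    """Proportion -> percent, rounded half-up to the given decimals.

    Rounding happens only at report time; internal metrics stay exact.
    """
    if isinstance(value, Fraction):
        d = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        d = Decimal(repr(float(value)))
    q = Decimal(1).scaleb(-decimals)
    return float((d * 100).quantize(q, rounding=ROUND_HALF_UP))


def empirical_auc(scores: Sequence[float], outcomes: Sequence[bool]) -> float:
    """Empirical ROC area of a numeric score against a binary outcome.

    Equals the tie-corrected rank statistic
    ``P(score_case > score_control) + 0.5 * P(equal)`` computed via
    midranks (the Mann-Whitney convention).  Requires both outcome
    classes to be present.
    """
    s = np.asarray(scores, dtype=float)
    o = np.asarray(outcomes, dtype=bool)
    if s.shape != o.shape:
        raise ValueError("scores and outcomes must have equal length")
    n1 = int(o.sum())
    n0 = int((~o).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present to compute an AUC")
    ranks = rankdata(s)  # midranks for ties
    u = ranks[o].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclasses.dataclass(frozen=True)
class YoudenResult:
    cutoff: float
    sensitivity: Fraction
    specificity: Fraction

    @property
    def youden_index(self) -> float:
        return float(self.sensitivity + self.specificity - 1)


def _predict(values: np.ndarray, cutoff: float, direction: MarkerDirection) -> np.ndarray:
    if direction == MarkerDirection.HIGH_RISK:
        return values > cutoff
    return values < cutoff


def youden_cutoff(
    marker: Sequence[float],
    outcomes: Sequence[bool],
    direction: MarkerDirection,
) -> YoudenResult:
    """Select the cut-off maximizing the Youden index (sens + spec - 1).

    Candidate thresholds are midpoints between adjacent distinct observed
    values plus -inf/+inf sentinels; a patient is called positive when the
    marker lies beyond the cut-off in the declared risk direction.  Ties in
    the Youden index are broken toward higher specificity, then toward the
    lower cut-off value, so the result is deterministic.
    """
    direction = MarkerDirection(direction)
    v = np.asarray(marker, dtype=float)
    o = np.asarray(outcomes, dtype=bool)
    if v.shape != o.shape:
        raise ValueError("marker and outcomes must have equal length")
    if o.all() or not o.any():
        raise ValueError("both outcome classes must be present")

    distinct = np.unique(v)
    candidates = [-math.inf, math.inf]
    candidates.extend((distinct[:-1] + distinct[1:]) / 2.0)

    best: Optional[tuple] = None
    for c in candidates:
        cm = confusion(_predict(v, c, direction), o)
        se, sp = sensitivity(cm), specificity(cm)
        key = (se + sp - 1, sp, -c if not math.isinf(c) else -c)
        # maximize J, then specificity, then prefer the smaller cutoff
        if best is None or key > best[0]:
            best = (key, YoudenResult(float(c), se, sp))
    return best[1]


def expand_contingency(tp: int, fp: int, fn: int, tn: int) -> tuple[list[bool], list[bool]]:
    """Expand contingency counts into (predictions, outcomes) lists whose
    :func:`confusion` reproduces the counts exactly."""
    cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)  # validates nonnegativity
    predictions = [True] * (cm.tp + cm.fp) + [False] * (cm.fn + cm.tn)
    outcomes = [True] * cm.tp + [False] * cm.fp + [True] * cm.fn + [False] * cm.tn
    return predictions, outcomes


def load_reference_contingency() -> pd.DataFrame:
    """Published score-vs-bleeding contingency tables (original score and
    modifications 3 and 7, each stratified by M3 / non-M3 subgroup)."""
    with resources.files("dicscore.data").joinpath("reference_contingency.csv").open() as fh:
        return pd.read_csv(fh)


def _wilson(k: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


@dataclasses.dataclass
class StratumScoreReport:
    """Metrics of one scoring system within one stratum."""

    score_id: ScoreId
    stratum: str
    cm: ConfusionMatrix
    sensitivity: Optional[Fraction]
    specificity: Optional[Fraction]
    positivity_rate: Fraction
    auc: Optional[float]  # AUC of the integer total as a rank score
    sensitivity_ci: Optional[tuple[float, float]] = None
    specificity_ci: Optional[tuple[float, float]] = None
    undefined: tuple[str, ...] = ()


@dataclasses.dataclass
class MarkerReport:
    """Univariate discrimination of one continuous marker in one stratum."""

    marker: str
    stratum: str
    direction: MarkerDirection
    n_used: int
    auc: Optional[float]  # direction-oriented (risk-increasing) AUC
    youden: Optional[YoudenResult]
    undefined: tuple[str, ...] = ()


@dataclasses.dataclass
class EvaluationReport:
    scores: list[StratumScoreReport]
    markers: list[MarkerReport]
    n_by_stratum: dict[str, int]

    def to_json_dict(self) -> dict:
        out: dict = {"n_by_stratum": self.n_by_stratum, "scores": [], "markers": []}
        for s in self.scores:
            out["scores"].append(
                {
                    "score_id": s.score_id.value,
                    "stratum": s.stratum,
                    "tp": s.cm.tp, "fp": s.cm.fp, "fn": s.cm.fn, "tn": s.cm.tn,
                    "sensitivity": None if s.sensitivity is None else
                        [s.sensitivity.numerator, s.sensitivity.denominator],
                    "sensitivity_percent": None if s.sensitivity is None else percent(s.sensitivity),
                    "specificity": None if s.specificity is None else
                        [s.specificity.numerator, s.specificity.denominator],
                    "specificity_percent": None if s.specificity is None else percent(s.specificity),
                    "positivity_rate": [s.positivity_rate.numerator, s.positivity_rate.denominator],
                    "positivity_rate_percent": percent(s.positivity_rate),
                    "auc": s.auc,
                    "sensitivity_ci95": s.sensitivity_ci,
                    "specificity_ci95": s.specificity_ci,
                    "undefined": list(s.undefined),
                }
            )
        for m in self.markers:
            out["markers"].append(
                {
                    "marker": m.marker,
                    "stratum": m.stratum,
                    "direction": m.direction.value,
                    "n_used": m.n_used,
                    "auc": m.auc,
                    "youden_cutoff": None if m.youden is None else m.youden.cutoff,
                    "youden_sensitivity": None if m.youden is None else float(m.youden.sensitivity),
                    "youden_specificity": None if m.youden is None else float(m.youden.specificity),
                    "undefined": list(m.undefined),
                }
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per score x stratum x metric."""
        rows = []
        for s in self.scores:
            base = dict(kind="score", name=s.score_id.value, stratum=s.stratum)
            rows.append({**base, "metric": "sensitivity_percent",
                         "value": None if s.sensitivity is None else percent(s.sensitivity)})
            rows.append({**base, "metric": "specificity_percent",
                         "value": None if s.specificity is None else percent(s.specificity)})
            rows.append({**base, "metric": "positivity_rate_percent",
                         "value": percent(s.positivity_rate)})
            rows.append({**base, "metric": "auc", "value": s.auc})
        for m in self.markers:
            base = dict(kind="marker", name=m.marker, stratum=m.stratum)
            rows.append({**base, "metric": "auc", "value": m.auc})
            rows.append({**base, "metric": "youden_cutoff",
                         "value": None if m.youden is None else m.youden.cutoff})
        return pd.DataFrame(rows, columns=["kind", "name", "stratum", "metric", "value"])


def _oriented(values: np.ndarray, direction: MarkerDirection) -> np.ndarray:
    return values if direction == MarkerDirection.HIGH_RISK else -values


def evaluate_cohort(
    cohort: Cohort,
    score_ids: Sequence[ScoreId],
    stratify_by_subgroup: bool = True,
    markers: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Full diagnostic report: per (score, stratum) confusion metrics and
    rank AUC of the integer total, plus per-marker univariate AUC and
    Youden cut-off.

    Strata lacking one outcome class are reported with the affected
    metrics flagged undefined rather than as numbers.  Records that
    cannot be scored by a particular system (missing component) are
    excluded from that system's confusion matrix; they remain visible
    through :func:`dicscore.scoring.score_all` failures.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if markers is None:
        markers = list(MARKER_DIRECTIONS)

    if stratify_by_subgroup:
        strata = [(sg.value, cohort.subset(sg)) for sg in Subgroup
                  if len(cohort.subset(sg))]
    else:
        strata = [("all", cohort)]

    score_reports: list[StratumScoreReport] = []
    marker_reports: list[MarkerReport] = []
    n_by_stratum = {name: len(sub) for name, sub in strata}

    for name, sub in strata:
        outcome_by_id = {r.patient_id: r.bleeding for r in sub.records}
        table = score_all(sub, list(score_ids))
        by_score: dict[ScoreId, list] = {ScoreId(s): [] for s in score_ids}
        for res in table.results:
            by_score[res.score_id].append(res)
        for sid, results in by_score.items():
            preds = [r.positive for r in results]
            outs = [outcome_by_id[r.patient_id] for r in results]
            totals = [r.total for r in results]
            cm = confusion(preds, outs) if preds else ConfusionMatrix(0, 0, 0, 0)
            undefined = []
            se = sp = auc = se_ci = sp_ci = None
            try:
                se = sensitivity(cm)
                se_ci = _wilson(cm.tp, cm.tp + cm.fn)
            except UndefinedMetricError:
                undefined.append("sensitivity")
            try:
                sp = specificity(cm)
                sp_ci = _wilson(cm.tn, cm.tn + cm.fp)
            except UndefinedMetricError:
                undefined.append("specificity")
            try:
                auc = empirical_auc(totals, outs)
            except ValueError:
                undefined.append("auc")
            score_reports.append(
                StratumScoreReport(
                    score_id=sid, stratum=name, cm=cm,
                    sensitivity=se, specificity=sp,
                    positivity_rate=positivity_rate(cm),
                    auc=auc, sensitivity_ci=se_ci, specificity_ci=sp_ci,
                    undefined=tuple(undefined),
                )
            )
        for marker in markers:
            direction = MARKER_DIRECTIONS[marker]
            pairs = [(getattr(r, marker), r.bleeding) for r in sub.records
                     if getattr(r, marker) is not None]
            vals = np.array([p[0] for p in pairs], dtype=float)
            outs_m = np.array([p[1] for p in pairs], dtype=bool)
            undefined_m: list[str] = []
            auc_m = None
            yr = None
            if len(pairs) == 0 or outs_m.all() or not outs_m.any():
                undefined_m = ["auc", "youden"]
            else:
                auc_m = empirical_auc(_oriented(vals, direction), outs_m)
                yr = youden_cutoff(vals, outs_m, direction)
            marker_reports.append(
                MarkerReport(marker=marker, stratum=name, direction=direction,
                             n_used=len(pairs), auc=auc_m, youden=yr,
                             undefined=tuple(undefined_m))
            )

    return EvaluationReport(scores=score_reports, markers=marker_reports,
                            n_by_stratum=n_by_stratum)
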