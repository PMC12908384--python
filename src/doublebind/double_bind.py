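"""Evolutionary double-bind diagnostics from fitted parameters.

Three quantities summarise whether radiotherapy plus NK-cell therapy forms a
double bind:

* the **double-bind score** lambda_RN - lambda_SN: positive when NK killing
  preferentially removes radiation-resistant cells, the defining criterion;
* the **cost of resistance** r_S - r_R: negative when resistance confers an
  intrinsic growth-rate benefit rather than a cost;
* the **interaction class** of the competition coefficients (alpha_SR,
  alpha_RS).  In this model a positive alpha inside (· + alpha ·)/K is
  suppressive, so both coefficients above tolerance means mutual competition,
  both below -tol means mutual facilitation (mutualism), and one-sided
  suppression is antagonism named after the suppressed population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .model_core import Condition, ParameterSet
from .fitting import FitSummary

__all__ = [
    "InteractionClass",
    "DoubleBindReport",
    "double_bind_score",
    "cost_of_resistance",
    "classify_interaction",
    "analyze_summary",
]

#: Default dead zone around zero for interaction classification.
DEFAULT_TOL = 0.05


class InteractionClass(str, Enum):
    MUTUALISM = "mutualism"
    COMPETITION = "competition"
    SENSITIVE_ANTAGONISM = "sensitive_antagonism"
    RESISTANT_ANTAGONISM = "resistant_antagonism"
    NEUTRAL = "neutral"


def double_bind_score(params: ParameterSet) -> float:
    """lambda_RN - lambda_SN; positive means a true double bind.

    For parameter sets from no-NK arms (both kill rates fixed at zero) the
    score is vacuously zero and a warning is issued.
    """
    if params.lambda_SN == 0 and params.lambda_RN == 0:
        warnings.warn(
            "both NK kill rates are zero (no-NK arm); double-bind score is "
            "not informative",
            stacklevel=2,
        )
        return 0.0
    return params.lambda_RN - params.lambda_SN


def cost_of_resistance(params: ParameterSet) -> float:
    """r_S - r_R; negative indicates an intrinsic growth benefit to resistance."""
    return params.r_S - params.r_R


def classify_interaction(
    alpha_SR: float, alpha_RS: float, tol: float = DEFAULT_TOL
) -> InteractionClass:
    """Quadrant classification of the competition coefficients.

    ``tol`` is a dead zone: coefficients within ±tol count as absent.
    """
    if tol < 0:
        raise ValueError("tolerance must be nonnegative")
    s_suppressed = alpha_SR > tol      # R suppresses S
    r_suppressed = alpha_RS > tol      # S suppresses R
    s_helped = alpha_SR < -tol
    r_helped = alpha_RS < -tol
    if s_suppressed and r_suppressed:
        return InteractionClass.COMPETITION
    if s_helped and r_helped:
        return InteractionClass.MUTUALISM
    if s_suppressed:
        return InteractionClass.SENSITIVE_ANTAGONISM
    if r_suppressed:
        return InteractionClass.RESISTANT_ANTAGONISM
    return InteractionClass.NEUTRAL


@dataclass
class DoubleBindReport:
    """Per-arm diagnostics plus the overall double-bind verdict."""

    per_condition: dict
    double_bind: bool
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_condition": self.per_condition,
            "double_bind": self.double_bind,
            "notes": list(self.notes),
        }

    def to_text(self) -> str:
        lines = [
            f"{'arm':<6} {'score':>10} {'score sem':>10} {'cost r_S-r_R':>13} "
            f"{'interaction':>22} {'double bind':>12}"
        ]
        for cond, d in self.per_condition.items():
            score = "—" if d["double_bind_score"] is None \
                else f"{d['double_bind_score']:.4g}"
            sem = "—" if d.get("score_sem") is None else f"{d['score_sem']:.2g}"
            flag = {True: "yes", False: "no", None: "n/a"}[d["double_bind"]]
            lines.append(
                f"{cond:<6} {score:>10} {sem:>10} "
                f"{d['cost_of_resistance']:>13.4g} "
                f"{d['interaction_class']:>22} {flag:>12}"
            )
        verdict = "present" if self.double_bind else "absent"
        lines.append(f"overall: evolutionary double bind {verdict}")
        lines.extend(self.notes)
        return "\n".join(lines)


def analyze_summary(summary: FitSummary, tol: float = DEFAULT_TOL) -> DoubleBindReport:
    """Double-bind diagnostics for every arm in a fit summary.

    The double-bind score and its dispersion are computed per replicate and
    then summarised when per-replicate estimates are available; NK-free arms
    are reported but marked not applicable.
    """
    per_condition: dict[str, dict] = {}
    notes: list[str] = []
    nk_flags: list[bool] = []
    for cond in summary.conditions:
        has_nk = cond.has_nk
        entry: dict = {}
        reps = summary.replicate_values.get(cond.value, {})
        if has_nk:
            if reps.get("lambda_RN") and reps.get("lambda_SN"):
                scores = np.asarray(reps["lambda_RN"]) - np.asarray(reps["lambda_SN"])
                score = float(np.mean(scores))
                sem = float(np.std(scores, ddof=1) / np.sqrt(scores.size)) \
                    if scores.size > 1 else 0.0
            else:
                score = summary.value(cond, "lambda_RN") \
                    - summary.value(cond, "lambda_SN")
                sem = None
            entry["double_bind_score"] = score
            entry["score_sem"] = sem
            entry["double_bind"] = bool(score > 0)
            nk_flags.append(score > 0)
        else:
            entry["double_bind_score"] = None
            entry["score_sem"] = None
            entry["double_bind"] = None
        entry["cost_of_resistance"] = summary.value(cond, "r_S") \
            - summary.value(cond, "r_R")
        entry["interaction_class"] = classify_interaction(
            summary.value(cond, "alpha_SR"), summary.value(cond, "alpha_RS"), tol
        ).value
        per_condition[cond.value] = entry
    if not nk_flags:
        notes.append(
            "no NK-containing arm in summary: double-bind criterion not applicable"
        )
    overall = bool(nk_flags) and all(nk_flags)
    return DoubleBindReport(
        per_condition=per_condition, double_bind=overall, notes=notes
    )
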