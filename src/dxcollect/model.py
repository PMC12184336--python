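"""Model/results facade over weight learning and cross-validated evaluation.

``EnsembleModel`` is built from cases plus concept-linked responses and an
ensemble specification; ``fit()`` learns the WMVE weights and runs the
repeated cross-validation, returning an ``EnsembleResults`` with the weight
estimates, per-outcome out-of-sample metrics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .aggregation import Differential, WeightTable
from .evaluation import Case
from .experiment import CVPlan, CVSummary, EnsembleSpec, run_configuration
from .weighting import GROUP_CAP, LearnReport, learn_weights

__all__ = ["EnsembleModel", "EnsembleResults"]


class EnsembleModel:
    """A diagnostic-ensemble model: members, weighting rule, CV design.

    Parameters
    ----------
    cases : sequence of Case
        Cases with gold-standard concept ids.
    responses : sequence of Differential
        Concept-linked ranked lists, any mix of humans and LLMs.
    ensemble : EnsembleSpec
        Which LLMs and how many humans to combine, weighting rule, and the
        metric that drives weight learning.
    plan : CVPlan, optional
        Cross-validation design (default: 10-times repeated five-fold).
    """

    def __init__(self, cases: Sequence[Case],
                 responses: Sequence[Differential],
                 ensemble: EnsembleSpec,
                 plan: CVPlan | None = None,
                 group_cap: int = GROUP_CAP):
        if not cases:
            raise ValueError("no cases")
        self.cases = list(cases)
        self.responses = list(responses)
        self.ensemble = ensemble
        self.plan = plan or CVPlan()
        self.group_cap = group_cap
        self._by_case: dict[str, list[Differential]] = {}
        for d in self.responses:
            self._by_case.setdefault(d.case_id, []).append(d)

    @classmethod
    def from_dataframes(cls, cases_df: pd.DataFrame,
                        responses_df: pd.DataFrame,
                        ensemble: EnsembleSpec,
                        plan: CVPlan | None = None) -> "EnsembleModel":
        """Build from tidy frames.

        ``cases_df`` needs columns ``case_id`` and ``correct_ids`` (iterable
        per row); ``responses_df`` needs ``case_id``, ``diagnostician_id``,
        ``kind`` and ``entries`` (ordered iterable per row).
        """
        cases = [Case(str(r.case_id), frozenset(map(str, r.correct_ids)))
                 for r in cases_df.itertuples()]
        responses = [Differential(str(r.case_id), str(r.diagnostician_id),
                                  tuple(map(str, r.entries)), str(r.kind))
                     for r in responses_df.itertuples()]
        return cls(cases, responses, ensemble, plan)

    def fit(self) -> "EnsembleResults":
        """Learn weights (full data) and cross-validate out-of-sample."""
        cv = run_configuration(self.cases, self._by_case, self.ensemble,
                               self.plan, cap=self.group_cap)
        if self.ensemble.weighting == "equal":
            weights, report = WeightTable(), LearnReport(0, 0, ())
        else:
            weights, report = learn_weights(
                self.cases, self._by_case, self.ensemble.llm_ids,
                self.ensemble.n_humans, metric=self.ensemble.metric,
                seed=self.plan.seed, cap=self.group_cap)
        return EnsembleResults(self, weights, report, cv)


@dataclass
class EnsembleResults:
    """Fitted weights plus cross-validated performance."""

    model: EnsembleModel
    weights: WeightTable
    learn_report: LearnReport
    cv: CVSummary

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.weights.weights, name="weight").sort_index()

    @property
    def metrics(self) -> dict[str, float]:
        return self.cv.means

    @property
    def per_outcome(self) -> pd.DataFrame:
        return self.cv.per_outcome

    def summary(self) -> str:
        spec, plan = self.model.ensemble, self.model.plan
        per = self.cv.per_outcome
        lines = [
            "Diagnostic Ensemble Results",
            "=" * 46,
            f"Members:     {len(spec.llm_ids)} LLM(s) + {spec.n_humans} human(s)",
            f"Weighting:   {spec.weighting} (metric: {spec.metric})",
            f"CV design:   {plan.n_repeats}x repeated {plan.n_folds}-fold "
            f"({plan.n_outcomes} outcomes), seed {plan.seed}",
            f"Cases:       {self.cv.n_eligible_cases} eligible, "
            f"{self.cv.n_filtered_cases} filtered",
            "-" * 46,
            "Out-of-sample mean (sd) over outcomes:",
        ]
        for m in ("top1", "top3", "top5", "mrr"):
            lines.append(f"  {m:<6} {per[m].mean():7.4f}  ({per[m].std():.4f})")
        if self.weights.weights:
            lines.append("-" * 46)
            lines.append("Learned weights (full data):")
            for k, v in sorted(self.weights.weights.items()):
                lines.append(f"  {k:<16} {v:10.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)
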