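"""Repeated cross-validation of diagnostic ensembles and error-complementarity
analytics.

The validation design is 10-times repeated five-fold cross-validation: per
repeat, cases are partitioned into five near-equal folds; each fold in turn
serves as the *training* fold on which member weights are learned, and the
remaining four folds are scored out-of-sample.  Metrics are averaged across
the fifty outcomes (mean of per-outcome means, not pooled ranks).

Human-containing configurations are evaluated per case by averaging over
physician groups (all groups of ``n_humans``, or 100 seeded samples when
more exist); cases with fewer physicians than the configuration needs are
filtered out, mirroring the minimum-five-physicians eligibility rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import Differential, WeightTable, aggregate
from .evaluation import Case, RANK_CUTOFF, rank_of_first_correct
from .weighting import (GROUP_CAP, METRICS, case_rng, learn_weights,
                        sample_groups)

__all__ = ["EnsembleSpec", "CVPlan", "CVSummary", "AgreementMatrix",
           "make_folds", "build_human_groups", "run_configuration",
           "evaluate_spec_on_cases", "complementarity", "rank1_agreement",
           "fraction_outperformed"]


@dataclass(frozen=True)
class EnsembleSpec:
    """Which diagnosticians are combined, and how."""

    llm_ids: tuple[str, ...] = ()
    n_humans: int = 0
    weighting: str = "wmve"  # "wmve" | "equal"
    metric: str = "top5"     # metric driving weight learning

    def __post_init__(self) -> None:
        object.__setattr__(self, "llm_ids", tuple(self.llm_ids))
        if not self.llm_ids and self.n_humans == 0:
            raise ValueError("ensemble needs at least one member")
        if self.weighting not in ("wmve", "equal"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.n_humans < 0:
            raise ValueError("n_humans must be >= 0")


@dataclass(frozen=True)
class CVPlan:
    """Repeated k-fold plan; 10 x 5 = 50 outcomes by default."""

    n_folds: int = 5
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ValueError("need n_folds >= 2 and n_repeats >= 1")

    @property
    def n_outcomes(self) -> int:
        return self.n_folds * self.n_repeats


def make_folds(case_ids: Sequence[str], plan: CVPlan) -> list[dict[str, int]]:
    """Seeded uniform partition into near-equal folds, one dict per repeat."""
    ids = sorted(case_ids)
    if len(ids) < plan.n_folds:
        raise ValueError(f"need at least {plan.n_folds} cases, got {len(ids)}")
    rng = np.random.default_rng(plan.seed)
    assignments = []
    for _ in range(plan.n_repeats):
        perm = rng.permutation(len(ids))
        folds = np.array_split(perm, plan.n_folds)
        a: dict[str, int] = {}
        for f, idx in enumerate(folds):
            for i in idx:
                a[ids[i]] = f
        assignments.append(a)
    return assignments


def build_human_groups(case_diffs: Sequence[Differential], n_humans: int,
                       cap: int = GROUP_CAP,
                       rng: np.random.Generator | None = None
                       ) -> list[tuple[str, ...]]:
    """Physician groups available for one case (all, or ``cap`` samples)."""
    human_ids = sorted({d.diagnostician_id for d in case_diffs
                        if d.kind == "human"})
    return sample_groups(human_ids, n_humans, cap=cap, rng=rng)


def _case_group_metrics(case: Case, llm_diffs: Sequence[Differential],
                        human_diffs: Sequence[Differential],
                        spec: EnsembleSpec, weights: WeightTable,
                        cap: int, rng: np.random.Generator,
                        cutoff: int = RANK_CUTOFF) -> dict[str, float]:
    """Mean metrics over physician groups for one case; also the collective
    rank and top concept of the first group (used by complementarity)."""
    if spec.n_humans == 0:
        groups: list[tuple[str, ...]] = [()]
    else:
        groups = build_human_groups(human_diffs, spec.n_humans, cap=cap, rng=rng)
    by_human = {d.diagnostician_id: d for d in human_diffs}
    acc = {m: 0.0 for m in ("top1", "top3", "top5", "mrr")}
    first_rank = math.inf
    first_top = None
    for gi, group in enumerate(groups):
        members = list(llm_diffs) + [by_human[h] for h in group]
        coll = aggregate(members, weights)
        r = rank_of_first_correct(coll.concepts, case.correct_ids, cutoff=cutoff)
        if gi == 0:
            first_rank = r
            first_top = coll.concepts[0] if coll.concepts else None
        acc["top1"] += 1.0 if r <= 1 else 0.0
        acc["top3"] += 1.0 if r <= 3 else 0.0
        acc["top5"] += 1.0 if r <= cutoff else 0.0
        acc["mrr"] += (1.0 / r) if r <= cutoff else 0.0
    g = len(groups)
    out = {m: v / g for m, v in acc.items()}
    out["_first_rank"] = first_rank
    out["_first_top"] = first_top
    return out


def _eligible(case: Case, diffs: Sequence[Differential],
              spec: EnsembleSpec) -> tuple[list[Differential],
                                           list[Differential]] | None:
    llm_by_id = {d.diagnostician_id: d for d in diffs if d.kind == "llm"}
    humans = [d for d in diffs if d.kind == "human"]
    if any(j not in llm_by_id for j in spec.llm_ids):
        return None
    if len(humans) < spec.n_humans:
        return None
    return [llm_by_id[j] for j in spec.llm_ids], humans


@dataclass
class CVSummary:
    """Result of one cross-validated configuration run."""

    spec: EnsembleSpec
    plan: CVPlan
    per_outcome: pd.DataFrame  # columns: repeat, fold, C, top1, top3, top5, mrr
    n_eligible_cases: int
    n_filtered_cases: int

    @property
    def means(self) -> dict[str, float]:
        return {m: float(self.per_outcome[m].mean())
                for m in ("top1", "top3", "top5", "mrr")}

    def __repr__(self) -> str:
        m = self.means
        return (f"CVSummary(outcomes={len(self.per_outcome)}, "
                f"top1={m['top1']:.3f}, top3={m['top3']:.3f}, "
                f"top5={m['top5']:.3f}, mrr={m['mrr']:.3f})")


def evaluate_spec_on_cases(cases: Sequence[Case],
                           responses: Mapping[str, Sequence[Differential]],
                           spec: EnsembleSpec, weights: WeightTable,
                           cap: int = GROUP_CAP, seed: int = 0,
                           ) -> pd.DataFrame:
    """Per-case group-averaged metrics for a fixed weight table."""
    rows = []
    for case in sorted(cases, key=lambda c: c.case_id):
        got = _eligible(case, responses.get(case.case_id, ()), spec)
        if got is None:
            continue
        llm_diffs, human_diffs = got
        rng = case_rng(seed, case.case_id, salt="eval")
        m = _case_group_metrics(case, llm_diffs, human_diffs, spec, weights,
                                cap, rng)
        rows.append({"case_id": case.case_id, **{k: v for k, v in m.items()
                                                 if not k.startswith("_")},
                     "first_rank": m["_first_rank"],
                     "first_top": m["_first_top"]})
    return pd.DataFrame(rows)


def run_configuration(cases: Sequence[Case],
                      responses: Mapping[str, Sequence[Differential]],
                      spec: EnsembleSpec, plan: CVPlan,
                      cap: int = GROUP_CAP) -> CVSummary:
    """Cross-validate one ensemble configuration.

    Weights are learned on each outcome's training fold only (or fixed to 1
    for equal weighting); the other folds are scored out-of-sample, averaging
    over physician groups per case; the summary reports per-outcome metrics
    and their mean across all ``n_repeats * n_folds`` outcomes.
    """
    eligible = [c for c in cases
                if _eligible(c, responses.get(c.case_id, ()), spec) is not None]
    n_filtered = len(cases) - len(eligible)
    if not eligible:
        raise ValueError("no eligible case for this configuration")
    assignments = make_folds([c.case_id for c in eligible], plan)
    by_id = {c.case_id: c for c in eligible}

    rows = []
    for rep, assign in enumerate(assignments):
        for train_fold in range(plan.n_folds):
            train = [by_id[cid] for cid, f in assign.items() if f == train_fold]
            test = [by_id[cid] for cid, f in assign.items() if f != train_fold]
            if spec.weighting == "equal" or not train:
                weights = WeightTable()
            else:
                weights, _ = learn_weights(
                    train, responses, spec.llm_ids, spec.n_humans,
                    metric=spec.metric, cap=cap,
                    seed=plan.seed * 1000 + rep * plan.n_folds + train_fold)
            df = evaluate_spec_on_cases(test, responses, spec, weights,
                                        cap=cap, seed=plan.seed)
            rows.append({"repeat": rep, "fold": train_fold, "C": len(df),
                         **{m: float(df[m].mean())
                            for m in ("top1", "top3", "top5", "mrr")}})
    return CVSummary(spec, plan, pd.DataFrame(rows),
                     n_eligible_cases=len(eligible),
                     n_filtered_cases=n_filtered)


# ---------------------------------------------------------------------------
# Complementarity analytics
# ---------------------------------------------------------------------------

RANK_BINS = ("1", "2", "3", "4", "5", "not_ranked")


@dataclass(frozen=True)
class AgreementMatrix:
    """6x6 percentage matrix of rank co-occurrence between two sources."""

    cells: np.ndarray  # shape (6, 6), rows = source A, cols = source B
    condition: str = "all"
    n_cases: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=list(RANK_BINS),
                            columns=list(RANK_BINS))

    @property
    def diagonal_share(self) -> float:
        return float(np.trace(self.cells))


def _rank_bin(r: float, cutoff: int = RANK_CUTOFF) -> int:
    return int(r) - 1 if r <= cutoff else len(RANK_BINS) - 1


def complementarity(ranks_a: Sequence[float], ranks_b: Sequence[float],
                    condition: str = "all") -> AgreementMatrix:
    """Tabulate where two sources place the correct diagnosis.

    Cell (i, j) is the percentage of cases where source A assigned the
    correct diagnosis rank i+1 (or did not rank it, last bin) and source B
    rank j+1.  ``condition="both_wrong"`` restricts to cases where neither
    source placed a correct diagnosis at rank 1.
    """
    if len(ranks_a) != len(ranks_b):
        raise ValueError("rank lists must be paired")
    if condition not in ("all", "both_wrong"):
        raise ValueError(f"unknown condition {condition!r}")
    pairs = list(zip(ranks_a, ranks_b))
    if condition == "both_wrong":
        pairs = [(a, b) for a, b in pairs if a != 1 and b != 1]
    cells = np.zeros((6, 6))
    for a, b in pairs:
        cells[_rank_bin(a), _rank_bin(b)] += 1
    if pairs:
        cells = cells * (100.0 / len(pairs))
    return AgreementMatrix(cells, condition=condition, n_cases=len(pairs))


def rank1_agreement(top_a: Sequence[str | None], top_b: Sequence[str | None],
                    ranks_a: Sequence[float] | None = None,
                    ranks_b: Sequence[float] | None = None,
                    both_wrong: bool = False) -> float:
    """Percentage of cases where two sources share the same top-ranked concept.

    With ``both_wrong=True`` only cases where neither source has the correct
    diagnosis at rank 1 are considered (requires the rank lists).
    """
    if len(top_a) != len(top_b):
        raise ValueError("top-concept lists must be paired")
    idx = range(len(top_a))
    if both_wrong:
        if ranks_a is None or ranks_b is None:
            raise ValueError("both_wrong needs the rank lists")
        idx = [i for i in idx if ranks_a[i] != 1 and ranks_b[i] != 1]
    if not idx:
        return float("nan")
    agree = sum(1 for i in idx
                if top_a[i] is not None and top_a[i] == top_b[i])
    return 100.0 * agree / len(idx)


def fraction_outperformed(individual_scores: Mapping[str, Mapping[str, float]],
                          reference_scores: Mapping[str, float],
                          ) -> dict[str, float]:
    """Share of humans a reference strictly outperforms (and ties with).

    ``individual_scores``: per human, per-case metric values on the cases
    that human solved.  Each human is compared with the reference's mean on
    the *same* case subset.  Humans with no overlapping cases are excluded.
    """
    strict = tied = n = 0
    for human, per_case in individual_scores.items():
        shared = [cid for cid in per_case if cid in reference_scores]
        if not shared:
            continue
        n += 1
        h_mean = float(np.mean([per_case[c] for c in shared]))
        r_mean = float(np.mean([reference_scores[c] for c in shared]))
        if h_mean < r_mean:
            strict += 1
        elif h_mean == r_mean:
            tied += 1
    if n == 0:
        raise ValueError("no comparable humans")
    return {"strict": 100.0 * strict / n,
            "strict_or_tied": 100.0 * (strict + tied) / n,
            "n_humans": n}
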