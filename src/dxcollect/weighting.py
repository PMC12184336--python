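"""Weighted majority voting ensemble (WMVE) weight learning.

Every diagnostician starts at weight 1.  For each training case the weight
of diagnostician ``j`` grows by

    alpha_j = s_j * (n - sum_k s_k) / n

where ``s_j`` in [0, 1] is j's per-case score under the chosen metric
(top-k: 0/1 indicator; reciprocal rank: 1/r up to rank 5, else 0) and ``n``
is the ensemble size.  A correct answer therefore earns more when the rest
of the ensemble does poorly.  Increments are non-negative, so weights are
monotone non-decreasing and the final weight ``1 + sum_i alpha_{j,i}`` does
not depend on the order in which training cases are visited.

Physicians rarely cover enough cases for individual weights, so all humans
share a single weight: for each training case, every group of ``n_humans``
physicians (capped at 100 sampled groups) is embedded in the full ensemble,
alpha values are computed per group, and the per-case increment to the
shared weight is the average over group members and groups.  LLM members'
increments are likewise averaged over the sampled groups.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .aggregation import HUMAN_SHARED, Differential, WeightTable
from .evaluation import Case, RANK_CUTOFF, rank_of_first_correct

__all__ = ["METRICS", "WMVEState", "member_score", "wmve_update",
           "learn_weights", "shared_human_weight", "sample_groups",
           "case_rng"]

METRICS = ("top1", "top3", "top5", "rr")

#: Default cap on the number of physician groups enumerated per case.
GROUP_CAP = 100


def member_score(d: Differential, correct: Iterable[str], metric: str,
                 cutoff: int = RANK_CUTOFF) -> float:
    """Per-case score s in [0, 1] of one diagnostician under ``metric``."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    r = rank_of_first_correct(d.entries, correct, cutoff=cutoff)
    if metric == "rr":
        return 0.0 if math.isinf(r) else 1.0 / r
    k = int(metric[3:])
    return 1.0 if r <= k else 0.0


@dataclass(frozen=True)
class WMVEState:
    """Current ensemble weights during sequential learning."""

    n: int
    w: Mapping[str, float]
    metric: str = "top5"
    history: tuple[Mapping[str, float], ...] = ()

    @classmethod
    def initial(cls, member_ids: Sequence[str], metric: str = "top5") -> "WMVEState":
        if not member_ids:
            raise ValueError("ensemble needs at least one member")
        if len(set(member_ids)) != len(member_ids):
            raise ValueError("duplicate member ids")
        return cls(n=len(member_ids), w={m: 1.0 for m in member_ids}, metric=metric)


def wmve_update(state: WMVEState, scores: Mapping[str, float]) -> WMVEState:
    """One sequential update: w_j += s_j * (n - sum(s)) / n."""
    if set(scores) != set(state.w):
        raise ValueError("scores must cover exactly the ensemble members")
    for j, s in scores.items():
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"score of {j} outside [0, 1]: {s}")
    total = sum(scores.values())
    alpha = {j: s * (state.n - total) / state.n for j, s in scores.items()}
    new_w = {j: state.w[j] + alpha[j] for j in state.w}
    return replace(state, w=new_w, history=state.history + (alpha,))


def case_rng(seed: int, case_id: str, salt: str = "groups") -> np.random.Generator:
    """RNG keyed by (seed, case_id): reproducible and order-independent."""
    digest = hashlib.sha256(f"{seed}:{salt}:{case_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


def sample_groups(member_ids: Sequence[str], n_humans: int, cap: int = GROUP_CAP,
                  rng: np.random.Generator | None = None
                  ) -> list[tuple[str, ...]]:
    """All C(m, n) physician groups, or ``cap`` unique seeded samples.

    Sampling without replacement over the enumerable group space when it is
    small enough to list; otherwise rejection-samples distinct combinations.
    """
    m = len(member_ids)
    if n_humans > m:
        raise ValueError(f"cannot form groups of {n_humans} from {m} physicians")
    ids = sorted(member_ids)
    n_total = math.comb(m, n_humans)
    if n_total <= cap:
        return list(combinations(ids, n_humans))
    if rng is None:
        raise ValueError("sampling beyond the cap requires an rng")
    if n_total <= 20 * cap:
        all_groups = list(combinations(ids, n_humans))
        idx = rng.choice(n_total, size=cap, replace=False)
        return [all_groups[i] for i in sorted(idx)]
    chosen: set[tuple[str, ...]] = set()
    while len(chosen) < cap:
        pick = tuple(sorted(rng.choice(ids, size=n_humans, replace=False)))
        chosen.add(pick)
    return sorted(chosen)


def _case_alphas(llm_diffs: Mapping[str, Differential],
                 human_diffs: Sequence[Differential],
                 n_humans: int, correct: frozenset[str], metric: str,
                 cap: int, rng: np.random.Generator,
                 ) -> tuple[dict[str, float], float | None, int]:
    """Group-averaged alpha increments for one training case.

    Returns (per-LLM alpha, shared-human alpha or None, number of groups).
    """
    llm_ids = sorted(llm_diffs)
    llm_scores = {j: member_score(llm_diffs[j], correct, metric) for j in llm_ids}
    if n_humans == 0:
        n = len(llm_ids)
        total = sum(llm_scores.values())
        return ({j: s * (n - total) / n for j, s in llm_scores.items()}, None, 1)

    by_human = {d.diagnostician_id: d for d in human_diffs}
    groups = sample_groups(list(by_human), n_humans, cap=cap, rng=rng)
    n = len(llm_ids) + n_humans
    llm_alpha = {j: 0.0 for j in llm_ids}
    human_alpha = 0.0
    for group in groups:
        h_scores = [member_score(by_human[h], correct, metric) for h in group]
        total = sum(llm_scores.values()) + sum(h_scores)
        for j in llm_ids:
            llm_alpha[j] += llm_scores[j] * (n - total) / n
        human_alpha += float(np.mean([s * (n - total) / n for s in h_scores]))
    g = len(groups)
    return ({j: a / g for j, a in llm_alpha.items()}, human_alpha / g, g)


def shared_human_weight(human_diffs: Sequence[Differential], n_humans: int,
                        fixed_members: Mapping[str, Differential],
                        correct: Iterable[str], metric: str,
                        cap: int = GROUP_CAP,
                        rng: np.random.Generator | None = None) -> float:
    """Per-case increment to the shared physician weight.

    Enumerates (or samples up to ``cap``) groups of ``n_humans`` physicians,
    computes each group member's alpha inside the full ensemble (group plus
    the fixed LLM members), and averages over members and groups.
    """
    if len(human_diffs) < n_humans:
        raise ValueError(
            f"case has {len(human_diffs)} physicians, needs {n_humans}")
    if rng is None:
        rng = np.random.default_rng(0)
    _, h_alpha, _ = _case_alphas(dict(fixed_members), human_diffs, n_humans,
                                 frozenset(correct), metric, cap, rng)
    assert h_alpha is not None
    return h_alpha


@dataclass(frozen=True)
class LearnReport:
    """Bookkeeping from one weight-learning pass."""

    n_cases_used: int
    n_cases_skipped: int
    skipped_case_ids: tuple[str, ...]


def learn_weights(train_cases: Sequence[Case],
                  responses: Mapping[str, Sequence[Differential]],
                  llm_ids: Sequence[str], n_humans: int,
                  metric: str = "top5", seed: int = 0,
                  cap: int = GROUP_CAP, equal: bool = False,
                  per_group: bool = False,
                  ) -> tuple[WeightTable, LearnReport]:
    """Learn a WeightTable from training cases by sequential WMVE updates.

    ``responses`` maps case_id to all differentials recorded for that case.
    LLM members get individual weights; all physicians share one weight under
    the ``"human_shared"`` key.  Cases missing any LLM response or with fewer
    than ``n_humans`` physician responses are skipped and reported.  With
    ``equal=True`` learning is bypassed and every weight is 1.  With
    ``per_group=True`` the update is applied once per sampled group instead
    of once per case (increments summed over groups rather than averaged).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    llm_ids = sorted(set(llm_ids))
    if not llm_ids and n_humans == 0:
        raise ValueError("ensemble has no members")
    member_keys = list(llm_ids) + ([HUMAN_SHARED] if n_humans > 0 else [])
    weights = {m: 1.0 for m in member_keys}
    if equal:
        return WeightTable(weights), LearnReport(0, 0, ())

    used, skipped = 0, []
    for case in sorted(train_cases, key=lambda c: c.case_id):
        diffs = responses.get(case.case_id, ())
        llm_diffs = {d.diagnostician_id: d for d in diffs
                     if d.kind == "llm" and d.diagnostician_id in llm_ids}
        human_diffs = [d for d in diffs if d.kind == "human"]
        if len(llm_diffs) < len(llm_ids) or len(human_diffs) < n_humans:
            skipped.append(case.case_id)
            continue
        rng = case_rng(seed, case.case_id)
        if per_group and n_humans > 0:
            by_human = {d.diagnostician_id: d for d in human_diffs}
            groups = sample_groups(list(by_human), n_humans, cap=cap, rng=rng)
            n = len(llm_ids) + n_humans
            llm_scores = {j: member_score(llm_diffs[j], case.correct_ids, metric)
                          for j in llm_ids}
            for group in groups:
                h_scores = [member_score(by_human[h], case.correct_ids, metric)
                            for h in group]
                total = sum(llm_scores.values()) + sum(h_scores)
                for j in llm_ids:
                    weights[j] += llm_scores[j] * (n - total) / n
                weights[HUMAN_SHARED] += float(
                    np.mean([s * (n - total) / n for s in h_scores]))
        else:
            llm_alpha, h_alpha, _ = _case_alphas(
                llm_diffs, human_diffs, n_humans, case.correct_ids, metric,
                cap, rng)
            for j, a in llm_alpha.items():
                weights[j] += a
            if h_alpha is not None:
                weights[HUMAN_SHARED] += h_alpha
        used += 1
    if used == 0:
        raise ValueError("no eligible training case")
    return WeightTable(weights), LearnReport(used, len(skipped), tuple(skipped))
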