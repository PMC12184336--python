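"""Top-k accuracy and mean reciprocal rank against multi-answer gold standards.

A nominated diagnosis is correct if it matches *any* of a case's correct
concept ids (roughly a third of real case collections carry more than one
acceptable answer).  The rank of the first correct hit, ``r_i``, drives all
metrics; hits beyond rank 5 — and misses — are assigned ``r_i = inf`` so
they contribute nothing:

    MRR = (1/C) * sum_i 1/r_i          top-k = #{i : r_i <= k} / C
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = ["Case", "EvalResult", "rank_of_first_correct", "summarize",
           "RANK_CUTOFF"]

#: Default rank beyond which a correct diagnosis no longer counts.
RANK_CUTOFF = 5


@dataclass(frozen=True)
class Case:
    """A diagnostic case: id, gold-standard concept ids, optional metadata."""

    case_id: str
    correct_ids: frozenset[str]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = frozenset(self.correct_ids)
        if not ids:
            raise ValueError(f"case {self.case_id} has no correct ids")
        object.__setattr__(self, "correct_ids", ids)

    @property
    def multi_answer(self) -> bool:
        return len(self.correct_ids) > 1


def rank_of_first_correct(ranked: Sequence[str], correct: Iterable[str],
                          cutoff: int = RANK_CUTOFF) -> float:
    """1-based rank of the first correct concept, or ``inf``.

    Positions beyond ``cutoff`` and outright absence both yield ``inf``.
    """
    correct = set(correct)
    if not correct:
        raise ValueError("empty gold-standard set")
    for pos, cid in enumerate(ranked[:cutoff], start=1):
        if cid in correct:
            return float(pos)
    return math.inf


@dataclass(frozen=True)
class EvalResult:
    """Summary metrics over a list of first-correct ranks."""

    C: int
    ranks: tuple[float, ...]
    top1: float
    top3: float
    top5: float
    mrr: float

    def as_dict(self) -> dict[str, float]:
        return {"C": self.C, "top1": self.top1, "top3": self.top3,
                "top5": self.top5, "mrr": self.mrr}


def summarize(ranks: Sequence[float], cutoff: int = RANK_CUTOFF) -> EvalResult:
    """Compute top-1/3/5 and MRR from per-case first-correct ranks."""
    if len(ranks) == 0:
        raise ValueError("no evaluable cases")
    ranks = tuple(float(r) for r in ranks)
    if any(r < 1 for r in ranks):
        raise ValueError("ranks are 1-based")
    C = len(ranks)

    def topk(k: int) -> float:
        return sum(1 for r in ranks if r <= k) / C

    mrr = sum((1.0 / r) if r <= cutoff else 0.0 for r in ranks) / C
    return EvalResult(C=C, ranks=ranks, top1=topk(1), top3=topk(3),
                      top5=topk(cutoff), mrr=mrr)
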