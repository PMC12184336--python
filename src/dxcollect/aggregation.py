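"""Rank-discounted, weighted aggregation of ranked differentials.

Each diagnostician contributes a ranked list of concept-linked diagnoses.
A diagnosis at rank ``r`` in diagnostician ``j``'s list earns the partial
score ``w_j / r`` (the inverse-rank rule); partial scores are summed over
all diagnosticians and the collective differential is the list of nominated
concepts sorted by decreasing total score.  Positive rescaling of all
weights leaves the collective ordering unchanged, so weights need no
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = ["Differential", "WeightTable", "CollectiveDifferential",
           "partial_scores", "aggregate"]


@dataclass(frozen=True)
class Differential:
    """One diagnostician's ordered diagnosis list for one case.

    ``entries`` holds concept ids, most probable first (rank 1).  The raw
    free-text strings the ids were linked from may be kept alongside for
    audit.  Duplicate concepts are allowed in raw form; scoring collapses
    them to their best (smallest) rank.
    """

    case_id: str
    diagnostician_id: str
    entries: tuple[str, ...]
    kind: str = "human"  # "human" | "llm"
    raw_entries: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("a differential must contain at least one entry")
        if self.kind not in ("human", "llm"):
            raise ValueError(f"unknown diagnostician kind {self.kind!r}")
        object.__setattr__(self, "entries", tuple(self.entries))
        object.__setattr__(self, "raw_entries", tuple(self.raw_entries))


#: Key under which the shared physician weight is stored in a WeightTable.
HUMAN_SHARED = "human_shared"


@dataclass
class WeightTable:
    """Per-diagnostician non-negative weights; absent ids default to 1.

    Human diagnosticians without an individual entry fall back to the shared
    physician weight (key ``"human_shared"``) when one is present, mirroring
    the single collective weight learned for physicians.
    """

    weights: dict[str, float] = field(default_factory=dict)
    default: float = 1.0

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.weights.items() if v < 0}
        if bad or self.default < 0:
            raise ValueError(f"weights must be non-negative, got {bad or self.default}")

    def weight_for(self, diagnostician_id: str, kind: str = "human") -> float:
        if diagnostician_id in self.weights:
            return self.weights[diagnostician_id]
        if kind == "human" and HUMAN_SHARED in self.weights:
            return self.weights[HUMAN_SHARED]
        return self.default

    def scaled(self, c: float) -> "WeightTable":
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return WeightTable({k: v * c for k, v in self.weights.items()}, self.default * c)


@dataclass(frozen=True)
class CollectiveDifferential:
    """Aggregated ranking for one case with per-concept provenance."""

    case_id: str
    ranked: tuple[tuple[str, float], ...]  # (concept_id, total score), score desc
    provenance: Mapping[str, tuple[tuple[str, int], ...]]  # concept -> (dx_id, rank)

    @property
    def concepts(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.ranked)

    def top(self, k: int = 5) -> tuple[str, ...]:
        return self.concepts[:k]


def partial_scores(d: Differential, w: float, max_input_rank: int | None = None
                   ) -> dict[str, float]:
    """Inverse-rank partial scores ``w / r`` for one differential.

    A concept appearing more than once contributes only from its best
    (smallest) rank.  ``max_input_rank`` optionally truncates the input list
    before scoring (default: score every rank).
    """
    if w < 0:
        raise ValueError("weight must be non-negative")
    scores: dict[str, float] = {}
    entries = d.entries if max_input_rank is None else d.entries[:max_input_rank]
    for pos, cid in enumerate(entries, start=1):
        if cid not in scores:  # first occurrence = best rank
            scores[cid] = w / pos
    return scores


def aggregate(ds: Sequence[Differential],
              w: WeightTable | Mapping[str, float] | None = None,
              max_input_rank: int | None = None) -> CollectiveDifferential:
    """Sum weighted partial scores over diagnosticians and sort.

    Ties in total score are broken by the best supporting individual rank
    (ascending), then by concept_id — the ordering is fully deterministic
    and invariant to the order of ``ds``.
    """
    if not ds:
        raise ValueError("no differentials to aggregate")
    case_ids = {d.case_id for d in ds}
    if len(case_ids) != 1:
        raise ValueError(f"differentials span multiple cases: {sorted(case_ids)}")
    if w is None:
        w = WeightTable()
    elif not isinstance(w, WeightTable):
        w = WeightTable(dict(w))

    totals: dict[str, float] = {}
    best_rank: dict[str, int] = {}
    prov: dict[str, list[tuple[str, int]]] = {}
    for d in sorted(ds, key=lambda d: d.diagnostician_id):
        wd = w.weight_for(d.diagnostician_id, d.kind)
        seen: set[str] = set()
        entries = d.entries if max_input_rank is None else d.entries[:max_input_rank]
        for pos, cid in enumerate(entries, start=1):
            if cid in seen:
                continue
            seen.add(cid)
            totals[cid] = totals.get(cid, 0.0) + wd / pos
            best_rank[cid] = min(best_rank.get(cid, pos), pos)
            prov.setdefault(cid, []).append((d.diagnostician_id, pos))

    order = sorted(totals, key=lambda cid: (-totals[cid], best_rank[cid], cid))
    return CollectiveDifferential(
        case_id=next(iter(case_ids)),
        ranked=tuple((cid, totals[cid]) for cid in order),
        provenance={cid: tuple(pairs) for cid, pairs in prov.items()},
    )
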