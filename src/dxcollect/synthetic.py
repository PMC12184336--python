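"""Synthetic terminologies, case cohorts and diagnostician responses.

Real case collections of this kind are controlled-access, and the clinical
terminology they link into is licensed, so every other module is exercised
against generated worlds with the same statistical structure:

* a terminology of uniquely-named concepts, each with several synonym
  spellings (word-order permutation, plural and British-spelling variants);
* cases with one or (with probability ``multi_answer_prob``, default 0.34)
  two gold-standard concepts;
* diagnosticians (humans or LLMs) of heterogeneous accuracy: each lists the
  correct concept with probability ``p_correct``, placing it at a
  truncated-geometric rank, and fills the remaining slots with wrong
  concepts drawn as a ``rho``-mixture of a per-case shared "attractive wrong
  answer" pool (correlated errors within an ``error_pool`` label) and
  idiosyncratic uniform draws;
* free-text rendering of every entry through synonym choice plus plural /
  British / word-order / typo corruption, with the intended concept recorded
  as ground truth for matcher testing.

Everything is driven by a single seed; identical configurations reproduce
byte-identical worlds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .aggregation import Differential
from .evaluation import Case
from .terminology import Concept, NormalizationDialect, Terminology

__all__ = ["DiagnosticianProfile", "WorldConfig", "GroundTruth", "World",
           "generate_world", "generate_terminology", "render_text",
           "default_profiles"]

# Word stock for concept names.  The "category" words include British-
# mappable and pluralizable forms so corruption ops have material to act on.
_CATEGORY_WORDS = (
    "infection", "tumor", "edema", "anemia", "hemorrhage", "syndrome",
    "fracture", "lesion", "fever", "injury", "stenosis", "ischemia",
    "ulcer", "cyst", "leukemia", "goiter",
)
_SYLLABLES = ("ba", "co", "de", "fi", "ga", "hu", "ki", "lo", "me", "na",
              "po", "qua", "ri", "so", "tu", "ve", "xa", "zo", "bri", "cle")

#: Reverse of the default dialect's British->US table, for corruption.
_US_TO_BRITISH = {v: k for k, v in
                  NormalizationDialect.default().british_to_us.items()}


@dataclass(frozen=True)
class DiagnosticianProfile:
    """Behavioural parameters of one simulated diagnostician.

    ``p_correct``: probability a case's correct concept appears in the list.
    ``rank_geom_p``: success parameter of the truncated geometric placing the
    correct concept (larger = more mass on rank 1).
    ``rho``: probability an error is drawn from the case's shared wrong-answer
    pool for this profile's ``error_pool`` label (1 = fully correlated errors
    within the pool, 0 = fully idiosyncratic).
    """

    diagnostician_id: str
    kind: str = "human"  # "human" | "llm"
    p_correct: float = 0.5
    rank_geom_p: float = 0.6
    rho: float = 0.0
    list_length: int = 5
    error_pool: str = "shared"
    coverage: float = 1.0  # probability of responding to a given case

    def __post_init__(self) -> None:
        for name in ("p_correct", "rho", "coverage"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.rank_geom_p <= 1.0):
            raise ValueError("rank_geom_p must lie in (0, 1]")
        if self.list_length < 1:
            raise ValueError("list_length must be >= 1")
        if self.kind not in ("human", "llm"):
            raise ValueError(f"unknown kind {self.kind!r}")


def default_profiles(n_humans: int = 5, n_llms: int = 2,
                     human_p: float = 0.45, llm_p: float = 0.6,
                     rho: float = 0.5) -> list[DiagnosticianProfile]:
    """A plausible mixed cohort: humans and LLMs with separate error pools."""
    hs = [DiagnosticianProfile(f"H{i:03d}", "human", human_p, 0.6, rho,
                               error_pool="human")
          for i in range(n_humans)]
    ls = [DiagnosticianProfile(f"LLM{i}", "llm", llm_p, 0.7, rho,
                               error_pool="llm")
          for i in range(n_llms)]
    return hs + ls


@dataclass(frozen=True)
class WorldConfig:
    """Full recipe for one synthetic world (seed mandatory)."""

    seed: int
    n_concepts: int = 500
    synonyms_per_concept: int = 3
    tag_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"disorder": 0.7, "finding": 0.2,
                                 "morphologic abnormality": 0.1})
    n_cases: int = 200
    multi_answer_prob: float = 0.34
    profiles: tuple[DiagnosticianProfile, ...] = ()
    corruption: Mapping[str, float] = field(
        default_factory=lambda: {"plural": 0.10, "british": 0.05,
                                 "word_order": 0.10, "typo": 0.02,
                                 "synonym_swap": 0.20})
    shared_pool_size: int = 5

    def __post_init__(self) -> None:
        profiles = tuple(self.profiles) or tuple(default_profiles())
        object.__setattr__(self, "profiles", profiles)
        max_len = max(p.list_length for p in profiles)
        if self.n_concepts < 10 * max_len:
            raise ValueError("n_concepts must be >= 10x the longest list")
        for k, v in {**self.corruption,
                     "multi_answer_prob": self.multi_answer_prob}.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"probability {k}={v} outside [0, 1]")
        ids = [p.diagnostician_id for p in profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate diagnostician ids in profiles")


@dataclass
class GroundTruth:
    """Oracle mapping for matcher and pipeline tests.

    ``intended``: per (case_id, diagnostician_id), the concept id behind each
    rendered raw string, aligned with the differential's entries.
    """

    correct_ids: dict[str, frozenset[str]]
    intended: dict[tuple[str, str], tuple[tuple[str, str], ...]]  # (raw, cid)


@dataclass
class World:
    config: WorldConfig
    terminology: Terminology
    cases: list[Case]
    responses: list[Differential]
    ground_truth: GroundTruth

    def responses_by_case(self) -> dict[str, list[Differential]]:
        out: dict[str, list[Differential]] = {}
        for d in self.responses:
            out.setdefault(d.case_id, []).append(d)
        return out


def _make_word(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        k = int(rng.integers(2, 4))
        w = "".join(rng.choice(_SYLLABLES) for _ in range(k))
        if w not in used:
            used.add(w)
            return w


def generate_terminology(n_concepts: int, synonyms_per_concept: int,
                         tag_distribution: Mapping[str, float],
                         rng: np.random.Generator) -> Terminology:
    """Concepts named ``"<unique pseudo-word> <category word>"``.

    The unique first word guarantees distinct normalized token sets across
    concepts; synonyms are word-order, plural and British variants that all
    normalize back to the preferred term's token set.
    """
    tags = sorted(tag_distribution)
    probs = np.array([tag_distribution[t] for t in tags], dtype=float)
    probs = probs / probs.sum()
    used: set[str] = set()
    concepts = []
    for i in range(n_concepts):
        head = _make_word(rng, used)
        cat = str(rng.choice(_CATEGORY_WORDS))
        preferred = f"{head} {cat}"
        variants = {preferred}
        # word-order variant
        variants.add(f"{cat} {head}")
        # plural variant of the category word
        variants.add(f"{head} {cat}s")
        # British-spelling variant where one exists
        if cat in _US_TO_BRITISH:
            variants.add(f"{head} {_US_TO_BRITISH[cat]}")
        syns = [preferred] + sorted(variants - {preferred})
        tag = str(rng.choice(tags, p=probs))
        concepts.append(Concept(
            concept_id=f"C{i:06d}",
            preferred_term=preferred,
            synonyms=tuple(syns[:max(1, synonyms_per_concept)]),
            semantic_tag=tag,
        ))
    return Terminology.from_concepts(concepts)


def _pluralize(tok: str) -> str:
    if tok.endswith(("s", "x", "z", "ch", "sh")) or len(tok) <= 3:
        return tok
    return tok + "s"


def _typo(tok: str, rng: np.random.Generator) -> str:
    if len(tok) < 4:
        return tok
    i = int(rng.integers(0, len(tok)))
    if rng.random() < 0.5:
        return tok[:i] + tok[i + 1:]  # deletion
    c = chr(ord("a") + int(rng.integers(0, 26)))
    return tok[:i] + c + tok[i + 1:]  # substitution


def render_text(concept: Concept, corruption: Mapping[str, float],
                rng: np.random.Generator) -> str:
    """Render a concept as corrupted free text (the intended id is the oracle)."""
    syn = concept.preferred_term
    if rng.random() < corruption.get("synonym_swap", 0.0):
        syn = str(rng.choice(concept.synonyms))
    tokens = syn.split()
    if rng.random() < corruption.get("word_order", 0.0) and len(tokens) > 1:
        rng.shuffle(tokens)
    if rng.random() < corruption.get("plural", 0.0):
        i = int(rng.integers(0, len(tokens)))
        tokens[i] = _pluralize(tokens[i])
    if rng.random() < corruption.get("british", 0.0):
        tokens = [_US_TO_BRITISH.get(t, t) for t in tokens]
    if rng.random() < corruption.get("typo", 0.0):
        i = int(rng.integers(0, len(tokens)))
        tokens[i] = _typo(tokens[i], rng)
    return " ".join(t for t in tokens if t)


def _truncated_geometric(p: float, kmax: int, rng: np.random.Generator) -> int:
    """Rank in 1..kmax with P(r) proportional to (1-p)^(r-1) * p."""
    pmf = np.array([(1 - p) ** (r - 1) * p for r in range(1, kmax + 1)])
    pmf = pmf / pmf.sum()
    return int(rng.choice(np.arange(1, kmax + 1), p=pmf))


def generate_world(cfg: WorldConfig) -> World:
    """Generate terminology, cases, free-text responses and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    term = generate_terminology(cfg.n_concepts, cfg.synonyms_per_concept,
                                cfg.tag_distribution, rng)
    concept_ids = sorted(term.concepts)
    pool_labels = sorted({p.error_pool for p in cfg.profiles})

    cases: list[Case] = []
    pools: dict[tuple[str, str], list[str]] = {}  # (case_id, label) -> pool
    for i in range(cfg.n_cases):
        case_id = f"case{i:05d}"
        n_correct = 2 if rng.random() < cfg.multi_answer_prob else 1
        correct = rng.choice(concept_ids, size=n_correct, replace=False)
        correct_set = frozenset(str(c) for c in correct)
        cases.append(Case(case_id, correct_set))
        remaining = [c for c in concept_ids if c not in correct_set]
        for label in pool_labels:
            pool = rng.choice(remaining, size=cfg.shared_pool_size,
                              replace=False)
            pools[(case_id, label)] = [str(c) for c in pool]

    responses: list[Differential] = []
    intended: dict[tuple[str, str], tuple[tuple[str, str], ...]] = {}
    for case in cases:
        correct_list = sorted(case.correct_ids)
        for prof in cfg.profiles:
            if rng.random() >= prof.coverage:
                continue
            entries = _simulate_entries(prof, case, correct_list,
                                        pools[(case.case_id, prof.error_pool)],
                                        concept_ids, rng)
            rendered = tuple(
                (render_text(term.concepts[cid], cfg.corruption, rng), cid)
                for cid in entries)
            responses.append(Differential(
                case_id=case.case_id,
                diagnostician_id=prof.diagnostician_id,
                entries=tuple(entries),
                kind=prof.kind,
                raw_entries=tuple(r for r, _ in rendered),
            ))
            intended[(case.case_id, prof.diagnostician_id)] = rendered

    gt = GroundTruth(
        correct_ids={c.case_id: c.correct_ids for c in cases},
        intended=intended,
    )
    return World(cfg, term, cases, responses, gt)


def _simulate_entries(prof: DiagnosticianProfile, case: Case,
                      correct_list: list[str], pool: list[str],
                      concept_ids: list[str],
                      rng: np.random.Generator) -> list[str]:
    L = prof.list_length
    slots: list[str | None] = [None] * L
    if rng.random() < prof.p_correct:
        r = _truncated_geometric(prof.rank_geom_p, L, rng)
        slots[r - 1] = str(rng.choice(correct_list))
    used = set(case.correct_ids)
    pool_remaining = [c for c in pool if c not in used]
    for i in range(L):
        if slots[i] is not None:
            continue
        cid = None
        if pool_remaining and rng.random() < prof.rho:
            j = int(rng.integers(0, len(pool_remaining)))
            cid = pool_remaining.pop(j)
        else:
            while cid is None or cid in used:
                cid = str(rng.choice(concept_ids))
        slots[i] = cid
        used.add(cid)
    return [s for s in slots if s is not None]
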