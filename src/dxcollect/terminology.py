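"""Clinical terminology store and free-text diagnosis linking.

Diagnoses arrive as free text ("Chlamydia infections", "Tumour of lung") and
must be mapped to unique concept identifiers in a SNOMED-CT-like terminology
before any aggregation can happen.  Linking is two-stage:

1. *Exact* token-set matching: both the query and every stored synonym are
   normalized (case folding, punctuation stripping, stop-word removal,
   British->US spelling, acronym expansion, plural->singular rewriting) and
   collapsed to word sets; a hit requires set equality, i.e. a Jaccard
   similarity of exactly 1.  When several concepts share a token set the
   semantic tag decides (disorder > finding > morphologic abnormality >
   body structure > person > organism > specimen > other).
2. *Fallback* similarity matching for everything the exact stage misses:
   the query is embedded with a deterministic character-trigram TF-IDF
   vectorizer fitted on the terminology's synonym corpus, and the concept
   holding the most cosine-similar synonym wins.  Any vectorizer exposing
   ``fit``/``transform`` over raw strings can be plugged in instead.

The normalization behaviour is defined entirely by a versioned
:class:`NormalizationDialect` (shipped as ``data/dialect_default.json``), so
results are reproducible without any external lexical tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics.pairwise import linear_kernel

__all__ = [
    "SEMANTIC_TAGS",
    "TAG_PREFERENCE",
    "Concept",
    "NormalizationDialect",
    "MatchResult",
    "Terminology",
    "TrigramVectorizer",
    "normalize",
    "match_exact",
    "match_fallback",
    "match",
    "match_audit",
]

#: Closed enumeration of semantic tags, in disambiguation-preference order.
TAG_PREFERENCE: tuple[str, ...] = (
    "disorder",
    "finding",
    "morphologic abnormality",
    "body structure",
    "person",
    "organism",
    "specimen",
    "other",
)
SEMANTIC_TAGS = frozenset(TAG_PREFERENCE)

_TAG_RANK = {t: i for i, t in enumerate(TAG_PREFERENCE)}

# Guard endings for the bare "s" -> "" plural rule: words like "virus",
# "diabetes insipidus", "psoriasis", "abscess" must not be clipped.
_S_RULE_GUARD = ("ss", "us", "is")


@dataclass(frozen=True)
class Concept:
    """One terminology entry: a unique ID, its synonyms and a semantic tag."""

    concept_id: str
    preferred_term: str
    synonyms: tuple[str, ...]
    semantic_tag: str = "other"

    def __post_init__(self) -> None:
        if self.semantic_tag not in SEMANTIC_TAGS:
            raise ValueError(
                f"unknown semantic tag {self.semantic_tag!r} for {self.concept_id}"
            )
        syns = tuple(self.synonyms)
        if self.preferred_term not in syns:
            syns = (self.preferred_term, *syns)
        if not syns:
            raise ValueError(f"concept {self.concept_id} has no synonyms")
        object.__setattr__(self, "synonyms", syns)


@dataclass(frozen=True)
class NormalizationDialect:
    """Versioned, self-contained normalization rules.

    Applying the dialect is idempotent: every rewrite produces tokens that no
    rule fires on again, so ``normalize(normalize(x)) == normalize(x)``.
    """

    stop_words: frozenset[str]
    british_to_us: Mapping[str, str]
    acronym_map: Mapping[str, str]
    plural_rules: tuple[tuple[str, str], ...]
    case_folding: bool = True
    punctuation_strip: bool = True
    version: str = "unversioned"

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormalizationDialect":
        return cls(
            stop_words=frozenset(d.get("stop_words", ())),
            british_to_us=dict(d.get("british_to_us", {})),
            acronym_map=dict(d.get("acronym_map", {})),
            plural_rules=tuple((a, b) for a, b in d.get("plural_rules", ())),
            case_folding=bool(d.get("case_folding", True)),
            punctuation_strip=bool(d.get("punctuation_strip", True)),
            version=str(d.get("version", "unversioned")),
        )

    @classmethod
    def from_json(cls, path) -> "NormalizationDialect":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "NormalizationDialect":
        text = (
            resources.files("dxcollect.data")
            .joinpath("dialect_default.json")
            .read_text(encoding="utf-8")
        )
        return cls.from_dict(json.loads(text))

    # -- token-level rules -------------------------------------------------
    def singularize(self, token: str) -> str:
        for suffix, repl in self.plural_rules:
            if not token.endswith(suffix) or len(token) <= len(suffix):
                continue
            if suffix == "s" and (token.endswith(_S_RULE_GUARD) or len(token) <= 3):
                continue
            return token[: -len(suffix)] + repl
        return token


def _tokenize(raw: str, dialect: NormalizationDialect) -> list[str]:
    s = raw.lower() if dialect.case_folding else raw
    if dialect.punctuation_strip:
        s = "".join(c if c.isalnum() else " " for c in s)
    return s.split()


def normalize(raw: str, dialect: NormalizationDialect | None = None) -> frozenset[str]:
    """Normalize free text to an order-free token set.

    Pipeline: case folding, punctuation stripping, acronym expansion,
    British->US mapping, plural->singular rewriting, stop-word removal,
    multiset collapse to a set.  An empty result marks the input as
    unmatchable (e.g. text consisting only of stop words), which callers
    treat as a valid no-match rather than an error.
    """
    if dialect is None:
        dialect = NormalizationDialect.default()
    tokens: list[str] = []
    for tok in _tokenize(raw, dialect):
        expansion = dialect.acronym_map.get(tok)
        tokens.extend(expansion.split() if expansion else [tok])
    out: set[str] = set()
    for tok in tokens:
        tok = dialect.british_to_us.get(tok, tok)
        tok = dialect.singularize(tok)
        if tok and tok not in dialect.stop_words:
            out.add(tok)
    return frozenset(out)


def _strip_semantic_tag(term: str) -> str:
    """Drop a trailing parenthesized semantic tag, e.g. ``"X (disorder)"``."""
    t = term.rstrip()
    if t.endswith(")") and "(" in t:
        head, _, tail = t.rpartition("(")
        if tail[:-1].strip().lower() in SEMANTIC_TAGS:
            return head.rstrip()
    return t


@dataclass(frozen=True)
class MatchResult:
    """Outcome of linking one raw string to the terminology."""

    concept_id: str | None
    method: str  # "exact" | "fallback" | "unmatched"
    similarity: float
    candidates: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.method == "exact" and self.similarity != 1.0:
            raise ValueError("exact matches have similarity 1")
        if self.method == "unmatched" and self.concept_id is not None:
            raise ValueError("unmatched results carry no concept_id")


_UNMATCHED = MatchResult(None, "unmatched", 0.0)


class TrigramVectorizer:
    """Deterministic character-trigram TF-IDF embedding of short strings.

    Fitted once on the terminology's normalized synonym corpus; queries are
    normalized with the same dialect and rendered as a sorted token string,
    so the embedding is invariant to word order and to the surface variation
    the dialect absorbs, while trigrams keep it robust to typos.
    """

    def __init__(self, dialect: NormalizationDialect | None = None):
        self.dialect = dialect or NormalizationDialect.default()
        self._tfidf = TfidfVectorizer(analyzer="char_wb", ngram_range=(3, 3))
        self._fitted = False

    def _canon(self, raw: str) -> str:
        toks = normalize(raw, self.dialect)
        return " ".join(sorted(toks)) if toks else raw.lower().strip()

    def fit(self, corpus: Iterable[str]) -> "TrigramVectorizer":
        self._tfidf.fit([self._canon(s) for s in corpus])
        self._fitted = True
        return self

    def transform(self, texts: Sequence[str]):
        if not self._fitted:
            raise RuntimeError("vectorizer used before fit()")
        return self._tfidf.transform([self._canon(s) for s in texts])


@dataclass
class Terminology:
    """A collection of concepts plus the normalized-synonym lookup index."""

    concepts: dict[str, Concept] = field(default_factory=dict)
    dialect: NormalizationDialect = field(default_factory=NormalizationDialect.default)
    norm_index: dict[frozenset[str], list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = list(self.concepts)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate concept_id in terminology")
        self.rebuild_index()
        self._vectorizer: TrigramVectorizer | None = None
        self._syn_matrix = None
        self._syn_concept_ids: list[str] = []

    @classmethod
    def from_concepts(
        cls, concepts: Iterable[Concept], dialect: NormalizationDialect | None = None
    ) -> "Terminology":
        return cls(
            concepts={c.concept_id: c for c in concepts},
            dialect=dialect or NormalizationDialect.default(),
        )

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self):
        return iter(self.concepts.values())

    def rebuild_index(self) -> None:
        index: dict[frozenset[str], set[str]] = {}
        for c in self.concepts.values():
            for syn in c.synonyms:
                key = normalize(_strip_semantic_tag(syn), self.dialect)
                if key:
                    index.setdefault(key, set()).add(c.concept_id)
        self.norm_index = {k: sorted(v) for k, v in index.items()}

    # -- fallback machinery -------------------------------------------------
    def synonym_corpus(self) -> tuple[list[str], list[str]]:
        """All stored synonym strings (tag-stripped) and their concept ids."""
        strings, ids = [], []
        for cid in sorted(self.concepts):
            for syn in self.concepts[cid].synonyms:
                strings.append(_strip_semantic_tag(syn))
                ids.append(cid)
        return strings, ids

    def default_vectorizer(self) -> TrigramVectorizer:
        """Trigram TF-IDF vectorizer fitted on this terminology (cached)."""
        if self._vectorizer is None:
            strings, ids = self.synonym_corpus()
            vec = TrigramVectorizer(self.dialect).fit(strings)
            self._vectorizer = vec
            self._syn_matrix = vec.transform(strings)
            self._syn_concept_ids = ids
        return self._vectorizer

    def _synonym_embeddings(self, vec) -> tuple[object, list[str]]:
        if vec is self.default_vectorizer():
            return self._syn_matrix, self._syn_concept_ids
        strings, ids = self.synonym_corpus()
        return vec.transform(strings), ids


def match_exact(raw: str, term: Terminology) -> MatchResult:
    """Token-set equality (Jaccard = 1) lookup with semantic-tag preference."""
    key = normalize(_strip_semantic_tag(raw), term.dialect)
    if not key:
        return _UNMATCHED
    hits = term.norm_index.get(key)
    if not hits:
        return _UNMATCHED
    best = min(
        hits, key=lambda cid: (_TAG_RANK[term.concepts[cid].semantic_tag], cid)
    )
    cands = tuple((cid, 1.0) for cid in hits)
    return MatchResult(best, "exact", 1.0, cands)


def match_fallback(
    raw: str,
    term: Terminology,
    vec: TrigramVectorizer | None = None,
    min_similarity: float = 0.0,
    n_candidates: int = 5,
) -> MatchResult:
    """Nearest-synonym cosine-similarity match.

    Always returns a concept (the one holding the most similar synonym,
    ties broken by smallest concept_id) unless ``min_similarity`` > 0 demotes
    a weak hit to unmatched.
    """
    if not term.concepts:
        raise ValueError("cannot match against an empty terminology")
    if vec is None:
        vec = term.default_vectorizer()
    q = vec.transform([raw])
    if q.nnz == 0 or float(q.multiply(q).sum()) == 0.0:
        raise ValueError(f"query {raw!r} produced a zero-norm vector")
    syn_matrix, syn_ids = term._synonym_embeddings(vec)
    sims = linear_kernel(q, syn_matrix).ravel()
    best_per_concept: dict[str, float] = {}
    for cid, s in zip(syn_ids, sims):
        if s > best_per_concept.get(cid, -1.0):
            best_per_concept[cid] = float(s)
    ranked = sorted(best_per_concept.items(), key=lambda kv: (-kv[1], kv[0]))
    best_id, best_sim = ranked[0]
    best_sim = min(best_sim, 1.0)  # clip fp overshoot
    cands = tuple((cid, min(s, 1.0)) for cid, s in ranked[:n_candidates])
    if best_sim < min_similarity:
        return MatchResult(None, "unmatched", 0.0, cands)
    return MatchResult(best_id, "fallback", best_sim, cands)


def match(
    raw: str,
    term: Terminology,
    vec: TrigramVectorizer | None = None,
    min_similarity: float = 0.0,
) -> MatchResult:
    """Two-stage linking: exact token-set match, then similarity fallback."""
    res = match_exact(raw, term)
    if res.method == "exact":
        return res
    return match_fallback(raw, term, vec, min_similarity=min_similarity)


def match_audit(term: Terminology, vec: TrigramVectorizer | None = None) -> dict:
    """Run both matchers over every stored synonym and compare.

    Returns the exact/fallback agreement rate over synonyms where the exact
    stage succeeds, plus any cross-concept normalized-synonym collisions
    (same token set indexed under more than one concept).
    """
    strings, ids = term.synonym_corpus()
    n_exact = n_agree = 0
    disagreements: list[tuple[str, str, str]] = []
    for s, cid in zip(strings, ids):
        ex = match_exact(s, term)
        if ex.method != "exact":
            continue
        n_exact += 1
        fb = match_fallback(s, term, vec)
        if fb.concept_id == ex.concept_id:
            n_agree += 1
        else:
            disagreements.append((s, ex.concept_id, fb.concept_id))
    collisions = {
        tuple(sorted(k)): v for k, v in term.norm_index.items() if len(v) > 1
    }
    return {
        "n_synonyms": len(strings),
        "n_exact": n_exact,
        "n_agree": n_agree,
        "agreement_rate": (n_agree / n_exact) if n_exact else float("nan"),
        "disagreements": disagreements,
        "collisions": collisions,
    }
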