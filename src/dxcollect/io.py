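"""File formats, raw LLM-response cleanup and run manifests.

Formats (all plain text):

* terminology JSON — ``[{"id", "preferred", "synonyms", "tag"}, ...]``
* cases JSON — ``[{"case_id", "correct_ids", "metadata"?}, ...]``
* responses JSONL — one ``{"case_id", "diagnostician_id", "kind",
  "entries", "raw_entries"?}`` object per line
* weights JSON — ``{diagnostician_id_or_"human_shared": weight}``
* results CSV — via pandas

Ranks are 1-based everywhere; an absent rank is serialized as ``null``,
never 0.  Schema violations are reported with their record location.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from typing import Iterable, Sequence

from .aggregation import Differential, WeightTable
from .evaluation import Case
from .terminology import Concept, NormalizationDialect, Terminology

__all__ = ["FormatError", "strip_llm_preamble", "RunManifest",
           "read_terminology", "write_terminology", "read_cases",
           "write_cases", "read_responses", "write_responses",
           "read_weights", "write_weights"]


class FormatError(ValueError):
    """Schema violation, annotated with the offending record's location."""


def _load_cleanup_rules() -> dict:
    text = (resources.files("dxcollect.data").joinpath("llm_cleanup.json")
            .read_text(encoding="utf-8"))
    return json.loads(text)


_CLEANUP = _load_cleanup_rules()
_NUMBERING = [re.compile(p) for p in _CLEANUP["numbering_patterns"]]


def strip_llm_preamble(raw: str,
                       preamble_prefixes: Sequence[str] | None = None,
                       ) -> list[str]:
    """Clean a verbose raw LLM response into ordered diagnosis strings.

    If the response starts with a known conversational preamble ("Sure,...",
    "Here are...", "Based on...", ...) everything up to the first line break
    is dropped; list numbering ("1.", "2)", "(3)", "iv.", "-", ...) is then
    stripped from each line.  Raises if nothing usable remains.
    """
    if not raw.strip():
        raise FormatError("empty LLM response")
    prefixes = (list(preamble_prefixes) if preamble_prefixes is not None
                else _CLEANUP["preamble_prefixes"])
    text = raw.strip()
    first_line = text.splitlines()[0].strip().lower()
    if any(first_line.startswith(p) for p in prefixes):
        _, sep, rest = text.partition("\n")
        text = rest if sep else ""
    lines = []
    for line in text.splitlines():
        for pat in _NUMBERING:
            line = pat.sub("", line)
        line = line.strip()
        if line:
            lines.append(line)
    if not lines:
        raise FormatError("LLM response contained no diagnoses after cleanup")
    return lines


# ---------------------------------------------------------------------------
# Terminology
# ---------------------------------------------------------------------------

def read_terminology(path, dialect: NormalizationDialect | None = None
                     ) -> Terminology:
    with open(path, encoding="utf-8") as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise FormatError(f"{path}: expected a JSON list of concepts")
    concepts = []
    for i, rec in enumerate(records):
        try:
            concepts.append(Concept(
                concept_id=str(rec["id"]),
                preferred_term=str(rec["preferred"]),
                synonyms=tuple(rec.get("synonyms", ())),
                semantic_tag=str(rec.get("tag", "other")),
            ))
        except (KeyError, TypeError, ValueError) as e:
            raise FormatError(f"{path}: concept record {i}: {e}") from e
    return Terminology.from_concepts(concepts, dialect)


def write_terminology(term: Terminology, path) -> None:
    records = [{"id": c.concept_id, "preferred": c.preferred_term,
                "synonyms": list(c.synonyms), "tag": c.semantic_tag}
               for c in sorted(term, key=lambda c: c.concept_id)]
    _dump_json(records, path)


# ---------------------------------------------------------------------------
# Cases / responses / weights
# ---------------------------------------------------------------------------

def read_cases(path) -> list[Case]:
    with open(path, encoding="utf-8") as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise FormatError(f"{path}: expected a JSON list of cases")
    cases = []
    for i, rec in enumerate(records):
        try:
            cases.append(Case(
                case_id=str(rec["case_id"]),
                correct_ids=frozenset(str(c) for c in rec["correct_ids"]),
                metadata=dict(rec.get("metadata", {})),
            ))
        except (KeyError, TypeError, ValueError) as e:
            raise FormatError(f"{path}: case record {i}: {e}") from e
    return cases


def write_cases(cases: Iterable[Case], path) -> None:
    records = [{"case_id": c.case_id, "correct_ids": sorted(c.correct_ids),
                "metadata": dict(c.metadata)}
               for c in sorted(cases, key=lambda c: c.case_id)]
    _dump_json(records, path)


def read_responses(path) -> list[Differential]:
    diffs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                diffs.append(Differential(
                    case_id=str(rec["case_id"]),
                    diagnostician_id=str(rec["diagnostician_id"]),
                    entries=tuple(str(e) for e in rec["entries"]),
                    kind=str(rec.get("kind", "human")),
                    raw_entries=tuple(rec.get("raw_entries", ())),
                ))
            except (KeyError, TypeError, ValueError,
                    json.JSONDecodeError) as e:
                raise FormatError(f"{path}: line {lineno}: {e}") from e
    return diffs


def write_responses(diffs: Iterable[Differential], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in diffs:
            rec = {"case_id": d.case_id,
                   "diagnostician_id": d.diagnostician_id,
                   "kind": d.kind, "entries": list(d.entries)}
            if d.raw_entries:
                rec["raw_entries"] = list(d.raw_entries)
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_weights(path) -> WeightTable:
    with open(path, encoding="utf-8") as fh:
        rec = json.load(fh)
    if not isinstance(rec, dict):
        raise FormatError(f"{path}: expected a JSON object of weights")
    try:
        return WeightTable({str(k): float(v) for k, v in rec.items()})
    except (TypeError, ValueError) as e:
        raise FormatError(f"{path}: {e}") from e


def write_weights(w: WeightTable, path) -> None:
    _dump_json(dict(sorted(w.weights.items())), path)


def _dump_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-identically."""

    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    record_counts: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def write(self, path) -> None:
        _dump_json(self.__dict__, path)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))
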