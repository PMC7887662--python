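"""Health-reference detection, categorisation and engagement scoring.

The rubric recognises ten categories of health reference — combinations of a
thematic group (impact, adaptation, mitigation, co-benefit, trade-off,
background) and a specificity level (general, specific, detailed) — each
carrying an entry score of 1–3. A document's health engagement score (HES)
runs from 0 (no reference) to 5: any mention enters at its category's entry
score and engagement across several thematic groups amends the score upward,
capped at 5.

Detection is sentence-unitised: a sentence containing a core health term is a
candidate, cue lexicons assign exactly one category per candidate, and a
fixed precedence order (trade-off > co-benefit > adaptation > mitigation >
impact > background) resolves sentences matching several groups, with the
most specific level winning inside a group. A candidate matching no cue falls
back to impact/general — the minimal "any mention" reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .corpus_io import TokenizedDocument, normalize_term

__all__ = [
    "VALID_CATEGORIES",
    "ENTRY_SCORES",
    "GROUP_PRECEDENCE",
    "ReferenceCategory",
    "HealthReference",
    "EngagementScores",
    "HealthLexicon",
    "find_health_references",
    "classify_reference",
    "aggregate_hes",
    "health_term_count",
    "score_document",
    "score_corpus",
    "summarize_categories",
    "scores_to_frame",
]

#: The ten valid (group, level) category pairs.
VALID_CATEGORIES: tuple[tuple[str, str], ...] = (
    ("impact", "general"),
    ("impact", "specific"),
    ("adaptation", "general"),
    ("adaptation", "specific"),
    ("adaptation", "detailed"),
    ("mitigation", "general"),
    ("co_benefit", "general"),
    ("co_benefit", "specific"),
    ("trade_off", "general"),
    ("background", "general"),
)

#: Entry score contributed by the first reference of each category.
ENTRY_SCORES: dict[tuple[str, str], int] = {
    ("impact", "general"): 1,
    ("impact", "specific"): 3,
    ("adaptation", "general"): 2,
    ("adaptation", "specific"): 3,
    ("adaptation", "detailed"): 3,
    ("mitigation", "general"): 2,
    ("co_benefit", "general"): 2,
    ("co_benefit", "specific"): 3,
    ("trade_off", "general"): 2,
    ("background", "general"): 1,
}

#: Rarer, more informative groups win over generic ones when cues collide.
GROUP_PRECEDENCE: tuple[str, ...] = (
    "trade_off", "co_benefit", "adaptation", "mitigation", "impact", "background",
)

_LEVEL_ORDER = {"detailed": 2, "specific": 1, "general": 0}


@dataclass(frozen=True)
class ReferenceCategory:
    group: str
    level: str

    def __post_init__(self) -> None:
        if (self.group, self.level) not in ENTRY_SCORES:
            raise ValueError(f"invalid category {self.group}/{self.level}")

    @property
    def entry_score(self) -> int:
        return ENTRY_SCORES[(self.group, self.level)]

    def __str__(self) -> str:  # used as a column label
        return f"{self.group}/{self.level}"


@dataclass(frozen=True)
class CandidateSpan:
    """A sentence containing at least one core health term."""

    doc_id: str
    sentence_index: int
    tokens: tuple[str, ...]
    matched_terms: tuple[str, ...]


@dataclass(frozen=True)
class HealthReference:
    doc_id: str
    category: ReferenceCategory
    sentence_index: int
    matched_terms: tuple[str, ...]

    @property
    def entry_score(self) -> int:
        return self.category.entry_score


@dataclass
class EngagementScores:
    """Per-document engagement measures; ``htp`` is filled by the topic model."""

    doc_id: str
    any_mention: bool
    hes: int
    health_term_count: int
    categories: tuple[ReferenceCategory, ...] = ()
    htp: float | None = None


def _phrase_positions(tokens: Sequence[str], phrase: tuple[str, ...]) -> list[int]:
    n = len(phrase)
    return [
        i for i in range(len(tokens) - n + 1)
        if tuple(tokens[i:i + n]) == phrase
    ]


class HealthLexicon:
    """Core health terms plus per-(group, level) cue lists.

    Terms are stored normalized (same rules as corpus text) as token tuples,
    so multiword cues match as contiguous phrases.
    """

    def __init__(self, core_terms: Iterable[str], cues: Mapping[str, Iterable[str]]):
        self.core_terms: list[tuple[str, ...]] = sorted(
            {tuple(normalize_term(t).split()) for t in core_terms if normalize_term(t)}
        )
        if not self.core_terms:
            raise ValueError("core_terms must be non-empty")
        self.cues: dict[tuple[str, str], list[tuple[str, ...]]] = {}
        for key, terms in cues.items():
            group, _, level = key.partition("/")
            if (group, level) not in ENTRY_SCORES:
                raise ValueError(f"cue list for unknown category {key!r}")
            self.cues[(group, level)] = sorted(
                {tuple(normalize_term(t).split()) for t in terms if normalize_term(t)}
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HealthLexicon":
        payload = yaml.safe_load(Path(path).read_text("utf-8"))
        return cls(payload["core_terms"], payload.get("cues", {}))

    @classmethod
    def default(cls) -> "HealthLexicon":
        text = resources.files("ndchealth.data").joinpath("health_lexicon.yaml").read_text("utf-8")
        payload = yaml.safe_load(text)
        return cls(payload["core_terms"], payload.get("cues", {}))

    def cue_terms(self, group: str, level: str) -> list[tuple[str, ...]]:
        return self.cues.get((group, level), [])


def find_health_references(
    doc: TokenizedDocument, lexicon: HealthLexicon
) -> list[CandidateSpan]:
    """Every sentence containing >= 1 core health term, with matches recorded."""
    spans: list[CandidateSpan] = []
    for idx, sent in enumerate(doc.sentences):
        matched = [
            " ".join(term) for term in lexicon.core_terms
            if _phrase_positions(sent, term)
        ]
        if matched:
            spans.append(CandidateSpan(doc.doc_id, idx, tuple(sent), tuple(matched)))
    return spans


def classify_reference(span: CandidateSpan, lexicon: HealthLexicon) -> HealthReference:
    """Assign exactly one category to a candidate sentence.

    The first group in precedence order with a matching cue wins; within the
    group the most specific level whose cue also matches wins. With no cue
    match at all the sentence is read as a bare mention: impact/general.
    """
    tokens = span.tokens
    chosen: ReferenceCategory | None = None
    for group in GROUP_PRECEDENCE:
        levels = sorted(
            (lvl for (g, lvl) in ENTRY_SCORES if g == group),
            key=lambda l: _LEVEL_ORDER[l],
        )
        if not any(
            _phrase_positions(tokens, cue)
            for cue in lexicon.cue_terms(group, "general")
        ):
            continue
        level = "general"
        for lvl in sorted(levels, key=lambda l: -_LEVEL_ORDER[l]):
            if lvl == "general":
                break
            if any(
                _phrase_positions(tokens, cue)
                for cue in lexicon.cue_terms(group, lvl)
            ):
                level = lvl
                break
        chosen = ReferenceCategory(group, level)
        break
    if chosen is None:
        chosen = ReferenceCategory("impact", "general")
    return HealthReference(span.doc_id, chosen, span.sentence_index, span.matched_terms)


def aggregate_hes(references: Sequence[HealthReference]) -> int:
    """Document HES: 0 with no reference, else the maximum entry score plus a
    breadth bonus of one point per additional thematic group engaged, capped
    at 5."""
    if not references:
        return 0
    max_entry = max(r.entry_score for r in references)
    groups = {r.category.group for r in references}
    return min(5, max_entry + (len(groups) - 1))


def health_term_count(doc: TokenizedDocument, lexicon: HealthLexicon) -> int:
    """Total occurrences of core health terms across all sentences."""
    total = 0
    for sent in doc.sentences:
        for term in lexicon.core_terms:
            total += len(_phrase_positions(sent, term))
    return total


def score_document(
    doc: TokenizedDocument, lexicon: HealthLexicon
) -> tuple[EngagementScores, list[HealthReference]]:
    """Detect, classify and aggregate for one document."""
    refs = [classify_reference(s, lexicon) for s in find_health_references(doc, lexicon)]
    hes = aggregate_hes(refs)
    cats = sorted({(r.category.group, r.category.level) for r in refs})
    scores = EngagementScores(
        doc_id=doc.doc_id,
        any_mention=hes >= 1,
        hes=hes,
        health_term_count=health_term_count(doc, lexicon),
        categories=tuple(ReferenceCategory(g, l) for g, l in cats),
    )
    return scores, refs


def score_corpus(
    docs: Sequence[TokenizedDocument], lexicon: HealthLexicon | None = None
) -> list[EngagementScores]:
    lexicon = lexicon or HealthLexicon.default()
    return [score_document(d, lexicon)[0] for d in docs]


def summarize_categories(scores: Sequence[EngagementScores]) -> pd.Series:
    """Fraction of documents containing each category, plus any-mention.

    Indexed by ``group/level`` labels and ``any_mention``.
    """
    if not scores:
        raise ValueError("cannot summarise an empty corpus")
    n = len(scores)
    out = {}
    for group, level in VALID_CATEGORIES:
        out[f"{group}/{level}"] = sum(
            any(c.group == group and c.level == level for c in s.categories)
            for s in scores
        ) / n
    out["any_mention"] = sum(s.any_mention for s in scores) / n
    return pd.Series(out, name="proportion")


def scores_to_frame(scores: Sequence[EngagementScores]) -> pd.DataFrame:
    """Per-document scores as a flat table (one boolean column per category)."""
    rows = []
    for s in scores:
        row: dict[str, object] = {
            "doc_id": s.doc_id,
            "any_mention": s.any_mention,
            "hes": s.hes,
            "health_term_count": s.health_term_count,
        }
        if s.htp is not None:
            row["htp"] = s.htp
        for group, level in VALID_CATEGORIES:
            row[f"{group}/{level}"] = any(
                c.group == group and c.level == level for c in s.categories
            )
        rows.append(row)
    return pd.DataFrame(rows)
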