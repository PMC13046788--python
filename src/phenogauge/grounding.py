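"""Grounding free-text diagnosis mentions to Mondo disease terms.

Each candidate string from a differential diagnosis is mapped in two
stages. Stage 1 is an exact match of the normalized string against the
normalized labels and synonyms of all non-obsolete disease terms; a hit is
definitive (score 1.0) and stage 2 is never consulted. Stage 2 assigns the
highest-scoring term under a pluggable string-similarity scorer and accepts
it only at or above a configurable threshold; below the threshold the item
remains ungrounded.

The default scorer is a composite normalized edit similarity: the larger of
the plain similarity ``1 - levenshtein / max(len)`` and its token-sort
variant (tokens sorted and re-joined before comparison, so word order does
not matter). Taking the max keeps word-reordered mentions close without
letting a first-letter typo — which changes the token sort order — destroy
the score. Any callable with the same signature can be registered under a
scorer id, e.g. an embedding-based matcher; the pipeline treats the scorer
as interchangeable.

Ties — one string being the label/synonym of several terms, or equal
stage-2 scores — resolve to the lexicographically smallest CURIE and are
recorded on the result.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import Callable, Sequence

import edlib

from .ontology import OntologyGraph
from .pheno_io import Differential

__all__ = [
    "GroundedItem",
    "GroundingConfig",
    "normalize",
    "register_scorer",
    "get_scorer",
    "edit_similarity",
    "token_sort_edit_similarity",
    "lexical_similarity",
    "build_lexical_index",
    "ground_item",
    "ground_differential",
    "grounding_coverage",
]

_DASHES = dict.fromkeys(map(ord, "‐‑‒–—―"), "-")
_APOSTROPHES = dict.fromkeys(map(ord, "‘’ʼ"), "'")
_EDGE_PUNCT = " \t\n\"'.,;:!?()[]{}"
_PAREN_SUFFIX = re.compile(r"\s*\([^()]*\)\s*$")
_WS = re.compile(r"\s+")


def normalize(text: str) -> str:
    """Canonical matching form of a disease mention.

    Case-folded, Unicode-normalized (NFKC), dashes and apostrophes unified,
    surrounding punctuation stripped, internal whitespace collapsed, and a
    trailing parenthetical qualifier (typically an acronym, "… (BBS)")
    removed — for matching only; the raw text is preserved elsewhere.
    """
    text = unicodedata.normalize("NFKC", text)
    text = text.translate(_DASHES).translate(_APOSTROPHES)
    text = text.casefold()
    text = _PAREN_SUFFIX.sub("", text)
    text = text.strip(_EDGE_PUNCT)
    return _WS.sub(" ", text)


# ---------------------------------------------------------------------------
# scorers

Scorer = Callable[[str, str], float]
_SCORERS: dict[str, Scorer] = {}


def register_scorer(scorer_id: str) -> Callable[[Scorer], Scorer]:
    def deco(fn: Scorer) -> Scorer:
        _SCORERS[scorer_id] = fn
        return fn

    return deco


def get_scorer(scorer_id: str) -> Scorer:
    try:
        return _SCORERS[scorer_id]
    except KeyError:
        raise KeyError(
            f"unknown scorer {scorer_id!r}; registered: {sorted(_SCORERS)}"
        ) from None


def _token_sort(text: str) -> str:
    return " ".join(sorted(text.split()))


def _edit_sim(a: str, b: str) -> float:
    if a == b:
        return 1.0 if a else 0.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b)["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


@register_scorer("edit")
def edit_similarity(a: str, b: str) -> float:
    """Plain normalized edit similarity, in [0, 1]."""
    return _edit_sim(a, b)


@register_scorer("token_sort_edit")
def token_sort_edit_similarity(a: str, b: str) -> float:
    """Normalized edit similarity on token-sorted strings, in [0, 1]."""
    return _edit_sim(_token_sort(a), _token_sort(b))


@register_scorer("lexical")
def lexical_similarity(a: str, b: str) -> float:
    """Default scorer: max of plain and token-sort edit similarity."""
    return max(_edit_sim(a, b), token_sort_edit_similarity(a, b))


@dataclass(frozen=True)
class GroundingConfig:
    """Knobs for the two-stage matcher.

    ``threshold`` gates stage-2 similarity matches; 0.80 by default — high
    enough to admit single-typo variants of multi-word disease names while
    rejecting unrelated strings.
    """

    threshold: float = 0.80
    normalizer: str = "default"
    scorer_id: str = "lexical"

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.normalizer != "default":
            raise ValueError(f"unknown normalizer {self.normalizer!r}")


@dataclass(frozen=True)
class GroundedItem:
    """Result of grounding one differential item."""

    raw_text: str
    mondo_id: str | None
    match_kind: str  # exact | similarity | none
    score: float
    tie: bool = False


def build_lexical_index(graph: OntologyGraph) -> dict[str, list[str]]:
    """Normalized label/synonym → sorted CURIEs, excluding obsolete terms.

    Cached on the graph instance; all grounding for a graph shares it.
    """
    if graph._lexical_index is None:
        index: dict[str, list[str]] = {}
        for curie in graph.terms():
            if curie in graph.obsolete:
                continue
            term = graph.nodes[curie]
            for name in (term.label, *term.synonyms):
                key = normalize(name)
                if key:
                    index.setdefault(key, []).append(curie)
        for key in index:
            index[key] = sorted(set(index[key]))
        graph._lexical_index = index
    return graph._lexical_index


def ground_item(
    raw_text: str,
    graph: OntologyGraph,
    config: GroundingConfig | None = None,
    scorer: Scorer | None = None,
) -> GroundedItem:
    """Ground one free-text mention to a Mondo term, or leave it ungrounded.

    Stage 1 (exact lexical match) takes precedence; only when it fails is
    the similarity scorer consulted, and its best candidate is accepted
    only at ``config.threshold`` or above.
    """
    config = config or GroundingConfig()
    index = build_lexical_index(graph)
    key = normalize(raw_text)
    if not key:
        return GroundedItem(raw_text, None, "none", 0.0)

    hits = index.get(key)
    if hits:
        return GroundedItem(raw_text, hits[0], "exact", 1.0, tie=len(hits) > 1)

    scorer = scorer or get_scorer(config.scorer_id)
    best_score = -1.0
    best_terms: list[str] = []
    for entry, curies in index.items():
        score = scorer(key, entry)
        if score > best_score:
            best_score, best_terms = score, list(curies)
        elif score == best_score:
            best_terms.extend(curies)
    if best_score >= config.threshold and best_terms:
        best_terms = sorted(set(best_terms))
        return GroundedItem(
            raw_text, best_terms[0], "similarity", best_score,
            tie=len(best_terms) > 1,
        )
    return GroundedItem(raw_text, None, "none", 0.0)


def ground_differential(
    diff: Differential,
    graph: OntologyGraph,
    config: GroundingConfig | None = None,
) -> list[GroundedItem]:
    """Ground every item of a differential, preserving rank slots.

    Ungrounded items keep their position; they are never compacted away,
    because rank positions are the method's asserted ordering.
    """
    config = config or GroundingConfig()
    scorer = get_scorer(config.scorer_id)
    out = []
    for item in diff.items:
        text = item if isinstance(item, str) else getattr(item, "label", str(item))
        out.append(ground_item(text, graph, config, scorer=scorer))
    return out


def grounding_coverage(items: Sequence[GroundedItem]) -> float | None:
    """Fraction of items assigned a Mondo term; ``None`` for an empty list."""
    if not items:
        return None
    return sum(1 for it in items if it.match_kind != "none") / len(items)
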