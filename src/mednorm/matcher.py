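"""Cascaded concept matching.

One raw reported name is resolved through a fixed cascade:

1. cache check (previously resolved names, including negative results);
2. curated special-case mapping, resolved against the primary tier;
3. approximate best match on the primary vocabulary tier — a returned
   candidate is accepted without further evaluation;
4. on failure, approximate best match on the extended fallback tier;
5. the fallback candidate's preferred name is re-matched against the
   primary tier (secondary query), anchoring international or
   non-marketed names to a primary-tier concept.

A name unresolved after all steps is UNMATCHED — deliberately so for
non-drug inputs (devices, garbled text), since over-matching is the
costlier error in pharmacovigilance.

The local similarity scorer blends token-set overlap with normalized
character edit distance in equal halves; the acceptance threshold is a
tunable (default 0.40) chosen so that a single-character misspelling of
a one-token drug name scores above it while unrelated multi-word
device names score well below.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import edlib

from .cache import CacheSet
from .preprocess import NormalizedName, RuleSet, apply_special_case, normalize
from .vocab import (
    Concept,
    VocabularyStore,
    candidates_by_token,
    lookup_exact,
)

__all__ = [
    "MatchStatus",
    "MatchStage",
    "ScoredCandidate",
    "MatchResult",
    "similarity",
    "best_match",
    "match_cascade",
    "match_batch",
    "BatchSummary",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.40


class MatchStatus(str, Enum):
    MATCHED = "MATCHED"
    UNMATCHED = "UNMATCHED"


class MatchStage(str, Enum):
    CACHE = "CACHE"
    SPECIAL_CASE = "SPECIAL_CASE"
    PRIMARY = "PRIMARY"
    FALLBACK_SECONDARY = "FALLBACK_SECONDARY"
    NONE = "NONE"


@dataclass(frozen=True)
class ScoredCandidate:
    concept: Concept
    matched_name: str
    score: float


@dataclass(frozen=True)
class MatchResult:
    raw_name: str
    normalized: str
    status: MatchStatus
    stage: MatchStage
    concept_id: str | None = None
    standardized_name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if (self.status is MatchStatus.MATCHED) != (self.concept_id is not None):
            raise ValueError("status MATCHED iff concept_id present")
        if (self.stage is MatchStage.NONE) != (
            self.status is MatchStatus.UNMATCHED
        ):
            raise ValueError("stage NONE iff status UNMATCHED")


def similarity(a: str, b: str) -> float:
    """Blend of token-set Jaccard and normalized Levenshtein similarity.

    ``0.5 * |tokens(a) & tokens(b)| / |tokens(a) | tokens(b)|
    + 0.5 * (1 - lev(a, b) / max(|a|, |b|))``

    Both inputs must be normalized.  Symmetric, bounded in [0, 1],
    equals 1 iff the strings are equal; two empty strings score 0.
    """
    if not a and not b:
        return 0.0
    ta, tb = set(a.split()), set(b.split())
    union = ta | tb
    token_score = len(ta & tb) / len(union) if union else 0.0
    if a == b:
        char_score = 1.0
    else:
        dist = edlib.align(a, b)["editDistance"]
        char_score = 1.0 - dist / max(len(a), len(b))
    return 0.5 * token_score + 0.5 * char_score


def best_match(
    store: VocabularyStore,
    name: NormalizedName | str,
    threshold: float = DEFAULT_THRESHOLD,
) -> ScoredCandidate | None:
    """Single best concept for a normalized name, or ``None``.

    An exact hit on any indexed name short-circuits with score 1.0.
    Otherwise every candidate generated by token overlap (exact or
    edit-distance-1) is scored against each of its names and the
    highest-scoring pair is returned if it reaches *threshold*.  Ties:
    higher score, then shorter matched name, then lower concept_id.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    text = name.text if isinstance(name, NormalizedName) else name
    if not text:
        return None

    exact = lookup_exact(store, text)
    if exact:
        return ScoredCandidate(concept=exact[0], matched_name=text, score=1.0)

    tokens = set(text.split())
    best: tuple[float, int, str, Concept, str] | None = None
    for concept in candidates_by_token(store, tokens):
        for cand_name in store.names[concept.concept_id]:
            score = similarity(text, cand_name)
            key = (-score, len(cand_name), concept.concept_id)
            if best is None or key < (-best[0], best[1], best[2]):
                best = (score, len(cand_name), concept.concept_id,
                        concept, cand_name)
    if best is None or best[0] < threshold:
        return None
    return ScoredCandidate(concept=best[3], matched_name=best[4],
                           score=best[0])


def _resolve_target(
    store: VocabularyStore, target: str, rules: RuleSet
) -> Concept | None:
    """Resolve a special-case target (concept id or name) in *store*."""
    if target in store.concepts:
        return store.concepts[target]
    hits = lookup_exact(store, normalize(target, rules).text)
    return hits[0] if hits else None


def _result_payload(result: MatchResult) -> dict:
    return {
        "normalized": result.normalized,
        "status": result.status.value,
        "stage": result.stage.value,
        "concept_id": result.concept_id,
        "standardized_name": result.standardized_name,
        "score": result.score,
    }


def _result_from_payload(raw: str, payload: dict) -> MatchResult:
    status = MatchStatus(payload["status"])
    stage = (
        MatchStage.NONE if status is MatchStatus.UNMATCHED else MatchStage.CACHE
    )
    return MatchResult(
        raw_name=raw,
        normalized=payload["normalized"],
        status=status,
        stage=stage,
        concept_id=payload["concept_id"],
        standardized_name=payload["standardized_name"],
        score=payload["score"],
    )


def match_cascade(
    raw: str,
    primary: VocabularyStore,
    extended: VocabularyStore | None = None,
    cache: CacheSet | None = None,
    rules: RuleSet | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> MatchResult:
    """Resolve one raw name through the full matching cascade.

    The result (matched or not) is written to the match cache before
    returning, so reprocessing the same raw string is a cache hit.
    Matching itself never raises on ordinary strings; cache I/O errors
    propagate as :class:`mednorm.cache.CacheError`.
    """
    rules = rules if rules is not None else RuleSet.empty()

    if cache is not None:
        payload = cache.get("match", raw)
        if payload is not None:
            return _result_from_payload(raw, payload)

    norm = normalize(raw, rules)

    result: MatchResult | None = None

    target = apply_special_case(norm, rules, raw=raw)
    if target is not None:
        concept = _resolve_target(primary, target, rules)
        if concept is not None:
            # the curated file's target name is authoritative for display;
            # a bare concept-id target falls back to the preferred name
            shown = concept.preferred_name if target in primary.concepts else target
            result = MatchResult(
                raw_name=raw,
                normalized=norm.text,
                status=MatchStatus.MATCHED,
                stage=MatchStage.SPECIAL_CASE,
                concept_id=concept.concept_id,
                standardized_name=shown,
                score=1.0,
            )

    if result is None:
        hit = best_match(primary, norm, threshold)
        if hit is not None:
            result = MatchResult(
                raw_name=raw,
                normalized=norm.text,
                status=MatchStatus.MATCHED,
                stage=MatchStage.PRIMARY,
                concept_id=hit.concept.concept_id,
                standardized_name=hit.concept.preferred_name,
                score=hit.score,
            )

    if result is None and extended is not None:
        fallback = best_match(extended, norm, threshold)
        if fallback is not None:
            # secondary query: anchor the fallback's preferred name
            alt = normalize(fallback.concept.preferred_name, rules)
            secondary = best_match(primary, alt, threshold)
            if secondary is not None:
                result = MatchResult(
                    raw_name=raw,
                    normalized=norm.text,
                    status=MatchStatus.MATCHED,
                    stage=MatchStage.FALLBACK_SECONDARY,
                    concept_id=secondary.concept.concept_id,
                    standardized_name=secondary.concept.preferred_name,
                    score=secondary.score,
                )

    if result is None:
        result = MatchResult(
            raw_name=raw,
            normalized=norm.text,
            status=MatchStatus.UNMATCHED,
            stage=MatchStage.NONE,
        )

    if cache is not None:
        cache.put("match", raw, _result_payload(result))
        cache.flush()
    return result


@dataclass(frozen=True)
class BatchSummary:
    """Distinct-name match statistics for one batch run."""

    total: int
    distinct: int
    matched_distinct: int
    match_rate: float | None  # percentage over distinct names; None if empty
    stage_counts: dict[str, int]

    @property
    def match_rate_display(self) -> str:
        if self.match_rate is None:
            return "n/a"
        return f"{self.match_rate:.1f}%"


def match_batch(
    names: list[str],
    primary: VocabularyStore,
    extended: VocabularyStore | None = None,
    cache: CacheSet | None = None,
    rules: RuleSet | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[MatchResult], BatchSummary]:
    """Match a list of raw names, order-preserving, with a run summary.

    The match rate is reported over distinct names (the standard way a
    mapping coverage figure is quoted).  With a warm cache a second
    invocation reproduces the same concepts and scores without touching
    the vocabulary stores.
    """
    results = [
        match_cascade(raw, primary, extended, cache, rules, threshold)
        for raw in names
    ]
    by_name: dict[str, MatchResult] = {}
    for res in results:
        by_name.setdefault(res.raw_name, res)
    distinct = len(by_name)
    matched = sum(
        1 for r in by_name.values() if r.status is MatchStatus.MATCHED
    )
    stage_counts: dict[str, int] = {}
    for res in results:
        stage_counts[res.stage.value] = stage_counts.get(res.stage.value, 0) + 1
    rate = 100.0 * matched / distinct if distinct else None
    return results, BatchSummary(
        total=len(names),
        distinct=distinct,
        matched_distinct=matched,
        match_rate=rate,
        stage_counts=stage_counts,
    )
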