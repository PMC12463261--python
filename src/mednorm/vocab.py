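"""Local two-tier drug vocabulary store.

The store is an offline analogue of the reference terminologies a
standardization pipeline queries remotely: a PRIMARY tier playing the
role of the core drug nomenclature (concepts carry an opaque identifier
comparable to an RxCUI) and an EXTENDED tier playing the role of a
broader fallback vocabulary holding international or non-marketed names.

Each concept's preferred name and synonyms are normalized at load time
with the same preprocessing rules used at query time, so lookups operate
under a single normalization contract.  Candidate generation for
approximate matching uses a token inverted index with edit-distance-1
token bridging (a reproducible local stand-in for lexical variant
generation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import edlib
import pandas as pd

from .preprocess import RuleSet, normalize

__all__ = [
    "Tier",
    "TermType",
    "RelationKind",
    "Concept",
    "Relation",
    "VocabularyStore",
    "VocabularyError",
    "load_vocabulary",
    "lookup_exact",
    "candidates_by_token",
    "relations_of",
]


class Tier(str, Enum):
    PRIMARY = "primary"
    EXTENDED = "extended"


class TermType(str, Enum):
    INGREDIENT = "INGREDIENT"
    BRAND = "BRAND"
    CLINICAL_DRUG = "CLINICAL_DRUG"
    MULTI_INGREDIENT = "MULTI_INGREDIENT"


class RelationKind(str, Enum):
    HAS_INGREDIENT = "HAS_INGREDIENT"
    HAS_ATC = "HAS_ATC"
    HAS_CLASS = "HAS_CLASS"
    HAS_GENERIC_NAME = "HAS_GENERIC_NAME"


# WHO ATC notation: letter, 2 digits, 2 letters, optional 2 digits
_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}(\d{2})?$")


class VocabularyError(ValueError):
    """Raised for missing files, duplicate ids or dangling relations."""


@dataclass(frozen=True)
class Concept:
    concept_id: str
    preferred_name: str
    term_type: TermType
    synonyms: frozenset[str] = frozenset()  # normalized forms

    def __post_init__(self) -> None:
        if not self.preferred_name:
            raise ValueError("preferred_name must be non-empty")


@dataclass(frozen=True)
class Relation:
    source_id: str
    kind: RelationKind
    target: str
    label: str = ""


@dataclass
class VocabularyStore:
    """Concepts, relations and a token inverted index for one tier."""

    tier: Tier
    concepts: dict[str, Concept] = field(default_factory=dict)
    relations: list[Relation] = field(default_factory=list)
    # normalized token -> set of concept ids indexed under it
    token_index: dict[str, set[str]] = field(default_factory=dict)
    # concept id -> normalized names (preferred + synonyms)
    names: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts


def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise VocabularyError(f"vocabulary file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise VocabularyError(f"{path.name}: missing columns {missing}")
    return df


def load_vocabulary(
    path: str | Path,
    tier: Tier | str,
    rules: RuleSet | None = None,
) -> VocabularyStore:
    """Load one tier of the vocabulary file set from directory *path*.

    Expects ``concepts.tsv`` (concept_id, preferred_name, term_type,
    tier), ``synonyms.tsv`` (concept_id, synonym, language) and
    ``relations.tsv`` (source_id, kind, target, label).  Rows whose
    ``tier`` column does not equal *tier* are ignored, so one file set
    can carry both tiers.  Names are normalized with *rules* at load
    time and the token index is built over every normalized name.

    Loading is deterministic given file contents.  Raises
    :class:`VocabularyError` on a missing file, a duplicate concept_id,
    a relation whose source is unknown, or a malformed ATC code.
    """
    tier = Tier(tier)
    rules = rules if rules is not None else RuleSet.empty()
    path = Path(path)

    concepts_df = _read_tsv(
        path / "concepts.tsv",
        ["concept_id", "preferred_name", "term_type", "tier"],
    )
    synonyms_df = _read_tsv(path / "synonyms.tsv", ["concept_id", "synonym"])
    relations_df = _read_tsv(
        path / "relations.tsv", ["source_id", "kind", "target"]
    )

    all_tier_ids = set(concepts_df["concept_id"])
    concepts_df = concepts_df[concepts_df["tier"] == tier.value]
    store = VocabularyStore(tier=tier)

    syn_by_id: dict[str, list[str]] = {}
    for row in synonyms_df.itertuples(index=False):
        syn_by_id.setdefault(row.concept_id, []).append(row.synonym)

    for row in concepts_df.itertuples(index=False):
        cid = row.concept_id
        if cid in store.concepts:
            raise VocabularyError(f"duplicate concept_id: {cid}")
        normalized_syns = frozenset(
            n.text
            for n in (normalize(s, rules) for s in syn_by_id.get(cid, []))
            if n.text
        )
        concept = Concept(
            concept_id=cid,
            preferred_name=row.preferred_name,
            term_type=TermType(row.term_type),
            synonyms=normalized_syns,
        )
        store.concepts[cid] = concept

        all_names = sorted(
            {normalize(row.preferred_name, rules).text} | normalized_syns
        )
        all_names = [n for n in all_names if n]
        store.names[cid] = tuple(all_names)
        for name in all_names:
            for tok in name.split():
                store.token_index.setdefault(tok, set()).add(cid)

    for row in relations_df.itertuples(index=False):
        if row.source_id not in store.concepts:
            # relations of the other tier's concepts are not an error
            if row.source_id in all_tier_ids:
                continue
            raise VocabularyError(
                f"relation references unknown source concept: {row.source_id}"
            )
        kind = RelationKind(row.kind)
        label = getattr(row, "label", "")
        if kind is RelationKind.HAS_ATC and not _ATC_RE.match(row.target):
            raise VocabularyError(
                f"malformed ATC code {row.target!r} on {row.source_id}"
            )
        store.relations.append(
            Relation(row.source_id, kind, row.target, label)
        )

    return store


def lookup_exact(store: VocabularyStore, term: str) -> list[Concept]:
    """All concepts whose preferred name or any synonym equals *term*.

    *term* must already be normalized.  Deterministic order
    (concept_id ascending); empty list for no hit.
    """
    if not term:
        return []
    hits = [
        cid for cid, names in store.names.items() if term in names
    ]
    return [store.concepts[cid] for cid in sorted(hits)]


def _tokens_within_one_edit(store: VocabularyStore, token: str) -> set[str]:
    out = set()
    for indexed in store.token_index:
        if abs(len(indexed) - len(token)) > 1:
            continue
        if edlib.align(token, indexed, k=1)["editDistance"] in (0, 1):
            out.add(indexed)
    return out


def candidates_by_token(
    store: VocabularyStore, tokens: set[str] | frozenset[str]
) -> list[Concept]:
    """Union of concepts sharing >=1 token with the query, exactly or at
    edit distance 1 (token bridging recovers single-typo tokens).

    Returns concepts in concept_id order; raises ``ValueError`` on an
    empty token set.
    """
    if not tokens:
        raise ValueError("token set must be non-empty")
    ids: set[str] = set()
    for tok in tokens:
        for bridged in _tokens_within_one_edit(store, tok):
            ids |= store.token_index[bridged]
    return [store.concepts[cid] for cid in sorted(ids)]


def relations_of(
    store: VocabularyStore, concept_id: str, kind: RelationKind | str
) -> list[tuple[str, str]]:
    """All (target, label) pairs of the given relation kind, in stable
    (target, label) order.  Raises ``KeyError`` for an unknown concept.
    """
    if concept_id not in store.concepts:
        raise KeyError(f"unknown concept_id: {concept_id}")
    kind = RelationKind(kind)
    pairs = [
        (r.target, r.label)
        for r in store.relations
        if r.source_id == concept_id and r.kind is kind
    ]
    return sorted(pairs)
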