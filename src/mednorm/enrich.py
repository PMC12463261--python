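"""Attach ingredients, generic name, ATC codes and drug classes to a
matched concept, mirroring the metadata retrieval a standardization
pipeline performs against a drug-terminology service.

The generic name of a branded or combination product is the name(s) of
its active ingredient(s); multi-ingredient names are joined with " / "
in alphabetical order.  ATC codes (4th level by default in the shipped
vocabularies) are taken from the product concept when present and
otherwise looked up on its ingredient concept(s) — the level at which
ATC is typically linked.  Missing metadata yields empty fields, never
errors: enrichment-success rates are themselves reported statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

from .vocab import (
    RelationKind,
    TermType,
    VocabularyStore,
    relations_of,
)

__all__ = ["EnrichedRecord", "enrich", "enrichment_summary"]


@dataclass(frozen=True)
class EnrichedRecord:
    concept_id: str
    ingredients: tuple[tuple[str, str], ...] = ()  # (ingredient_id, name)
    generic_name: str = ""
    atc_codes: tuple[tuple[str, str], ...] = ()  # (code, class_name)
    drug_classes: tuple[str, ...] = ()

    @property
    def has_ingredient(self) -> bool:
        return bool(self.ingredients)

    @property
    def has_atc(self) -> bool:
        return bool(self.atc_codes)


def enrich(store: VocabularyStore, concept_id: str) -> EnrichedRecord:
    """Build the :class:`EnrichedRecord` for a matched concept.

    Pure function of the store: repeat calls give identical records.
    Raises ``KeyError`` for a concept absent from the store.
    """
    if concept_id not in store.concepts:
        raise KeyError(f"unknown concept_id: {concept_id}")
    concept = store.concepts[concept_id]

    ing_pairs = relations_of(store, concept_id, RelationKind.HAS_INGREDIENT)
    ingredients = tuple(
        (target, label or _name_of(store, target)) for target, label in ing_pairs
    )
    if not ingredients and concept.term_type is TermType.INGREDIENT:
        # an ingredient concept is its own ingredient link
        ingredients = ((concept_id, concept.preferred_name),)

    if concept.term_type is TermType.INGREDIENT:
        generic = concept.preferred_name
    elif ingredients:
        generic = " / ".join(sorted(name for _, name in ingredients))
    else:
        explicit = relations_of(store, concept_id, RelationKind.HAS_GENERIC_NAME)
        generic = explicit[0][1] or explicit[0][0] if explicit else ""

    atc = relations_of(store, concept_id, RelationKind.HAS_ATC)
    if not atc:
        # fall back to the ingredient concept(s); never overrides a
        # product-level ATC
        seen: set[tuple[str, str]] = set()
        for ing_id, _ in ingredients:
            if ing_id in store.concepts:
                seen.update(relations_of(store, ing_id, RelationKind.HAS_ATC))
        atc = sorted(seen)

    classes = relations_of(store, concept_id, RelationKind.HAS_CLASS)
    class_names = tuple(sorted(label or target for target, label in classes))

    return EnrichedRecord(
        concept_id=concept_id,
        ingredients=ingredients,
        generic_name=generic,
        atc_codes=tuple(atc),
        drug_classes=class_names,
    )


def _name_of(store: VocabularyStore, concept_id: str) -> str:
    c = store.concepts.get(concept_id)
    return c.preferred_name if c is not None else concept_id


def enrichment_summary(
    records: list[EnrichedRecord],
) -> tuple[float | None, float | None]:
    """(ingredient_rate, atc_rate) as percentages over matched records;
    ``(None, None)`` for empty input (displayed as "n/a")."""
    if not records:
        return None, None
    n = len(records)
    ing = 100.0 * sum(r.has_ingredient for r in records) / n
    atc = 100.0 * sum(r.has_atc for r in records) / n
    return ing, atc
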