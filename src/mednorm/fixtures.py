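"""Synthetic test-data generation.

Everything the pipeline consumes can be generated offline and
deterministically from a seed: two-tier demo vocabularies, raw name
variants corrupted by a configurable noise model (the error classes
seen in spontaneous-report drug fields: misspellings, case noise, dose
strengths, dose-form words, French terms, combination joins), and
spontaneous-report tables with an injected drug-event association
optionally fragmented across several name variants.

The corrupted names retain their ground truth, and generated report
tables emit the exact aggregated 2x2 contingency table they encode, so
matcher recovery and signal statistics can be asserted end to end
without any external data.
"""

from __future__ import annotations

import random
import string
import zlib
from dataclasses import dataclass, replace
from pathlib import Path

from .signals import ContingencyTable, ReportRecord

__all__ = [
    "NoiseModel",
    "SignalSpec",
    "CorruptedName",
    "gen_vocabulary",
    "corrupt_name",
    "gen_reports",
    "write_reports_csv",
    "DATA_DIR",
]

# packaged demo vocabulary + curated rule files
DATA_DIR = Path(__file__).parent / "data"

_DOSE_MENU = ("500 mg", "50/12.5", "10 ml", "250mg", "5%")
_FORM_MENU = ("tablet", "caplets", "injection", "capsule")
_FRENCH_MENU = ("comprimé", "gouttes", "sirop")

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class NoiseModel:
    """Per-class corruption probabilities; reproducible from the seed."""

    p_typo: float = 0.0
    p_case: float = 0.0
    p_dose_suffix: float = 0.0
    p_form_word: float = 0.0
    p_french: float = 0.0
    p_combo_join: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_typo", "p_case", "p_dose_suffix",
            "p_form_word", "p_french", "p_combo_join",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")


@dataclass(frozen=True)
class SignalSpec:
    """Design of one injected drug-event association."""

    drug_key: str
    event_key: str
    n_reports: int
    target_a: int
    drug_margin: int
    event_margin: int
    n_variants: int = 1

    def __post_init__(self) -> None:
        if self.target_a > min(self.drug_margin, self.event_margin):
            raise ValueError("target_a exceeds a margin")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.drug_margin + self.event_margin - self.target_a > self.n_reports:
            raise ValueError("margins exceed the report count")


@dataclass(frozen=True)
class CorruptedName:
    raw: str
    clean: str
    applied: tuple[str, ...]


def _name_rng(model: NoiseModel, clean: str) -> random.Random:
    # per-name stream: same (seed, name) pair always corrupts identically
    return random.Random((model.rng_seed << 32) ^ zlib.crc32(clean.encode()))


def _one_edit(text: str, rng: random.Random) -> str:
    """One random character edit (substitute, delete or insert a letter),
    never touching spaces so token structure is preserved."""
    positions = [i for i, ch in enumerate(text) if ch != " "]
    if not positions:
        return text
    op = rng.choice(["sub", "del", "ins"])
    i = rng.choice(positions)
    letter = rng.choice(string.ascii_lowercase)
    if op == "sub":
        while letter == text[i].lower():
            letter = rng.choice(string.ascii_lowercase)
        return text[:i] + letter + text[i + 1:]
    if op == "del" and len(text.replace(" ", "")) > 2:
        return text[:i] + text[i + 1:]
    return text[:i] + letter + text[i:]


def corrupt_name(clean: str, model: NoiseModel) -> CorruptedName:
    """Apply each noise class by an independent coin flip, in a fixed
    order, recording which classes fired.  All probabilities zero
    returns the clean string unchanged."""
    rng = _name_rng(model, clean)
    raw = clean
    applied: list[str] = []
    if rng.random() < model.p_typo:
        raw = _one_edit(raw, rng)
        applied.append("typo")
    if rng.random() < model.p_combo_join and " " in raw:
        raw = raw.replace(" ", "/")
        applied.append("combo_join")
    if rng.random() < model.p_case:
        raw = raw.upper()
        applied.append("case")
    if rng.random() < model.p_dose_suffix:
        raw = f"{raw} {rng.choice(_DOSE_MENU)}"
        applied.append("dose_suffix")
    if rng.random() < model.p_form_word:
        raw = f"{raw} {rng.choice(_FORM_MENU)}"
        applied.append("form_word")
    if rng.random() < model.p_french:
        raw = f"{raw} {rng.choice(_FRENCH_MENU)}"
        applied.append("french")
    return CorruptedName(raw=raw, clean=clean, applied=tuple(applied))


def _make_word(rng: random.Random, n_syllables: int = 3) -> str:
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
        for _ in range(n_syllables)
    )


def _unique_words(rng: random.Random, count: int, n_syllables: int = 3) -> list[str]:
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < count:
        w = _make_word(rng, n_syllables)
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def gen_vocabulary(
    seed: int,
    n_ingredients: int,
    n_brands: int,
    n_combos: int,
    french_fraction: float = 0.0,
    out_dir: str | Path | None = None,
) -> tuple[list[str], list[str], list[str]]:
    """Generate a loadable two-tier vocabulary file set.

    Ingredient names are pronounceable 6-letter strings; every brand is
    linked to at least one ingredient and every combo to two.  A
    ``french_fraction`` of concepts receive an accented synonym.  Output
    is byte-identical per seed.  Returns the three file contents
    (concepts, synonyms, relations) as line lists; when *out_dir* is
    given they are also written as ``concepts.tsv``, ``synonyms.tsv``
    and ``relations.tsv``.
    """
    rng = random.Random(seed)
    words = _unique_words(rng, n_ingredients + n_brands)
    ing_names = words[:n_ingredients]
    brand_names = words[n_ingredients:]

    concepts = ["concept_id\tpreferred_name\tterm_type\ttier"]
    synonyms = ["concept_id\tsynonym\tlanguage"]
    relations = ["source_id\tkind\ttarget\tlabel"]

    ing_ids: list[str] = []
    for i, name in enumerate(ing_names):
        cid = f"I{i + 1:04d}"
        ing_ids.append(cid)
        concepts.append(f"{cid}\t{name}\tINGREDIENT\tprimary")
        atc = (
            rng.choice("ACDGJLNR")
            + f"{rng.randrange(100):02d}"
            + rng.choice(string.ascii_uppercase)
            + rng.choice(string.ascii_uppercase)
        )
        relations.append(f"{cid}\tHAS_ATC\t{atc}\tclass of {name}")
        if rng.random() < french_fraction:
            synonyms.append(f"{cid}\t{name}é\tfr")

    for i, name in enumerate(brand_names):
        cid = f"B{i + 1:04d}"
        ing = rng.choice(ing_ids) if ing_ids else None
        concepts.append(f"{cid}\t{name.capitalize()}\tBRAND\tprimary")
        if ing is not None:
            relations.append(f"{cid}\tHAS_INGREDIENT\t{ing}\t")
        if rng.random() < french_fraction:
            synonyms.append(f"{cid}\t{name}é\tfr")

    for i in range(n_combos):
        cid = f"M{i + 1:04d}"
        if len(ing_ids) < 2:
            break
        pair = rng.sample(range(len(ing_ids)), 2)
        name = f"{ing_names[pair[0]]} / {ing_names[pair[1]]}"
        concepts.append(f"{cid}\t{name}\tMULTI_INGREDIENT\tprimary")
        for j in pair:
            relations.append(f"{cid}\tHAS_INGREDIENT\t{ing_ids[j]}\t")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for fname, lines in (
            ("concepts.tsv", concepts),
            ("synonyms.tsv", synonyms),
            ("relations.tsv", relations),
        ):
            (out_dir / fname).write_text("\n".join(lines) + "\n", "utf-8")
    return concepts, synonyms, relations


def _distinct_variants(
    canonical: str, n_variants: int, model: NoiseModel
) -> list[str]:
    if n_variants == 1:
        return [canonical]
    variants: list[str] = []
    seen = {canonical}
    attempt = 0
    while len(variants) < n_variants:
        sub_model = replace(
            model,
            p_typo=max(model.p_typo, 0.999),  # variants must differ
            rng_seed=(model.rng_seed * 1009 + attempt) % (2**31),
        )
        raw = corrupt_name(canonical, sub_model).raw
        if raw not in seen:
            seen.add(raw)
            variants.append(raw)
        attempt += 1
        if attempt > 100 * n_variants:  # degenerate noise model
            raw = f"{canonical} v{len(variants) + 1}"
            seen.add(raw)
            variants.append(raw)
    return variants


def gen_reports(
    spec: SignalSpec, model: NoiseModel
) -> tuple[list[ReportRecord], dict[str, str], ContingencyTable, list[str]]:
    """Generate a report table realizing *spec* exactly.

    Exactly ``target_a`` reports contain both the drug and the event;
    margins match the spec.  Drug mentions are distributed round-robin
    across ``n_variants`` corrupted name variants (in report order), so
    per-variant counts are deterministic: when ``target_a`` and
    ``drug_margin`` divide evenly by ``n_variants`` every variant gets
    ``target_a / n_variants`` co-occurrence reports.

    Returns ``(reports, variant_map, expected_aggregated_table,
    variants)`` where the table is the exact aggregated contingency the
    reports encode.
    """
    variants = _distinct_variants(spec.drug_key, spec.n_variants, model)
    variant_map = {v: spec.drug_key for v in variants}

    a = spec.target_a
    b = spec.drug_margin - a
    c = spec.event_margin - a
    d = spec.n_reports - a - b - c
    expected = ContingencyTable(a=a, b=b, c=c, d=d)

    reports: list[ReportRecord] = []
    drug_counter = 0

    def next_variant() -> str:
        nonlocal drug_counter
        v = variants[drug_counter % len(variants)]
        drug_counter += 1
        return v

    idx = 0
    for _ in range(a):
        reports.append(
            ReportRecord(
                report_id=f"r{idx:07d}",
                drugs=frozenset({next_variant()}),
                events=frozenset({spec.event_key}),
            )
        )
        idx += 1
    for _ in range(b):
        reports.append(
            ReportRecord(
                report_id=f"r{idx:07d}",
                drugs=frozenset({next_variant()}),
            )
        )
        idx += 1
    for _ in range(c):
        reports.append(
            ReportRecord(
                report_id=f"r{idx:07d}",
                events=frozenset({spec.event_key}),
            )
        )
        idx += 1
    for _ in range(d):
        reports.append(ReportRecord(report_id=f"r{idx:07d}"))
        idx += 1

    return reports, variant_map, expected, variants


def write_reports_csv(reports: list[ReportRecord], path: str | Path) -> None:
    """Long-format report table: one row per (report, drug) x event
    combination; drug-less or event-less reports keep an empty cell."""
    lines = ["report_id,drug,event"]
    for rep in reports:
        drugs = sorted(rep.drugs) or [""]
        events = sorted(rep.events) or [""]
        for drg in drugs:
            for evt in events:
                lines.append(f"{rep.report_id},{drg},{evt}")
    Path(path).write_text("\n".join(lines) + "\n", "utf-8")
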