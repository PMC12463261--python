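"""Normalization of raw reported medication names.

Spontaneous-report drug fields mix case, punctuation, dose strengths,
dose forms, routes, French terms and free-text noise around the core
pharmacological name ("TYLENOL 500 MG CAPLETS", "Losartan/HCTZ 50/12.5").
This module reduces such strings to a canonical lowercase token form that
both the vocabulary index and the matcher operate on, applying a fixed
rule pipeline plus three editable curated rule files:

* an unwanted-terms list (dose forms, units, routes, filler words,
  including French equivalents such as "comprime"),
* an abbreviation map (e.g. ``hcl`` -> ``hydrochloride``),
* a special-cases map of verbatim terms to a standardized target name
  (e.g. ``doliprane`` -> ``Paracetamol``), consulted before any
  vocabulary matching.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "RuleSet",
    "NormalizedName",
    "load_rules",
    "normalize",
    "apply_special_case",
    "fold_accents",
]

# characters treated as token separators before punctuation stripping
DELIMITERS = frozenset("/\\-+,")

# closed list of unit suffixes recognised in number+unit tokens ("500mg")
_UNITS = ("mcg", "mg", "ml", "g", "ui", "iu", "%")

_NUMBER_RE = re.compile(r"^\d+(?:\.\d+)?$")
_NUMBER_UNIT_RE = re.compile(
    r"^\d+(?:\.\d+)?(?:" + "|".join(re.escape(u) for u in _UNITS) + r")$"
)
_PAREN_RE = re.compile(r"\([^)]*\)|\[[^\]]*\]|\{[^}]*\}")
_KEEP_RE = re.compile(r"[^a-z0-9. ]")


def fold_accents(text: str) -> str:
    """Strip diacritics: NFD-decompose and drop combining marks (é -> e).

    Canonical (not compatibility) decomposition, so spacing modifier
    characters never introduce new whitespace into the string.
    """
    decomposed = unicodedata.normalize("NFD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


@dataclass(frozen=True)
class RuleSet:
    """Curated preprocessing rules, all entries stored in normalized form.

    ``unwanted_terms`` and special-case keys are lowercase and
    accent-folded; abbreviation expansion is applied once per token
    (non-recursive).
    """

    unwanted_terms: frozenset[str] = frozenset()
    abbreviations: dict[str, str] = field(default_factory=dict)
    special_cases: dict[str, str] = field(default_factory=dict)
    delimiters: frozenset[str] = DELIMITERS

    @staticmethod
    def empty() -> "RuleSet":
        return RuleSet()


@dataclass(frozen=True)
class NormalizedName:
    """A normalized name: canonical text, its tokens and the rule trace."""

    text: str
    tokens: tuple[str, ...]
    trace: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.text != " ".join(self.tokens):
            raise ValueError("text must equal tokens joined by single spaces")

    @property
    def is_empty(self) -> bool:
        return not self.tokens


class RuleParseError(ValueError):
    """A rule file row that cannot be parsed (reported with line number)."""


def _iter_rule_lines(path: Path):
    for lineno, line in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def _fold_key(term: str) -> str:
    return fold_accents(term.strip().lower())


def load_rules(
    unwanted_path: str | Path,
    abbrev_path: str | Path,
    special_path: str | Path,
) -> RuleSet:
    """Load the three curated rule files into a :class:`RuleSet`.

    Formats (UTF-8, ``#`` comments and blank lines skipped):

    * unwanted terms: one term per line;
    * abbreviations: two tab-separated columns (short form, expansion);
    * special cases: two tab-separated columns (verbatim raw term,
      target standardized name or concept id).

    Raises :class:`RuleParseError` naming the offending line for rows
    that do not have exactly two columns.
    """
    unwanted_path = Path(unwanted_path)
    abbrev_path = Path(abbrev_path)
    special_path = Path(special_path)

    unwanted = frozenset(
        _fold_key(line) for _, line in _iter_rule_lines(unwanted_path)
    )

    abbreviations: dict[str, str] = {}
    for lineno, line in _iter_rule_lines(abbrev_path):
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != 2 or not all(parts):
            raise RuleParseError(
                f"{abbrev_path.name}:{lineno}: expected 2 tab-separated columns"
            )
        abbreviations[_fold_key(parts[0])] = _fold_key(parts[1])

    special_cases: dict[str, str] = {}
    for lineno, line in _iter_rule_lines(special_path):
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != 2 or not all(parts):
            raise RuleParseError(
                f"{special_path.name}:{lineno}: expected 2 tab-separated columns"
            )
        special_cases[_fold_key(parts[0])] = parts[1]

    return RuleSet(
        unwanted_terms=unwanted,
        abbreviations=abbreviations,
        special_cases=special_cases,
    )


def normalize(raw: str, rules: RuleSet | None = None) -> NormalizedName:
    """Normalize a raw reported name through the fixed rule pipeline.

    Steps, in order: lowercase; accent folding; removal of parenthesized
    or bracketed segments (reporter annotations); delimiter characters
    (``/ \\ - + ,``) to spaces; strip remaining punctuation; tokenize;
    drop pure-number and number+unit tokens ("500", "12.5", "500mg");
    expand abbreviations (once per token); drop unwanted terms; collapse
    whitespace.  The trace records which steps changed the string.

    Idempotent: ``normalize(normalize(x).text) == normalize(x)`` up to
    the trace.  A name reduced to zero tokens yields empty text.
    """
    if rules is None:
        rules = RuleSet.empty()
    trace: list[str] = []

    text = raw.lower()
    if text != raw:
        trace.append("lowercase")

    folded = fold_accents(text)
    if folded != text:
        trace.append("accent_fold")
    text = folded

    deparen = _PAREN_RE.sub(" ", text)
    if deparen != text:
        trace.append("strip_parenthetical")
    text = deparen

    delim = "".join(" " if ch in rules.delimiters else ch for ch in text)
    if delim != text:
        trace.append("delimiters_to_space")
    text = delim

    depunct = _KEEP_RE.sub("", text)
    if depunct != text:
        trace.append("strip_punctuation")
    text = depunct

    tokens: list[str] = []
    dropped_number = False
    for tok in text.split():
        if _NUMBER_RE.match(tok) or _NUMBER_UNIT_RE.match(tok):
            dropped_number = True
            continue
        tok = tok.strip(".").replace(".", "")
        if tok:
            tokens.append(tok)
    if dropped_number:
        trace.append("drop_number_tokens")

    expanded: list[str] = []
    did_expand = False
    for tok in tokens:
        if tok in rules.abbreviations:
            expanded.extend(rules.abbreviations[tok].split())
            did_expand = True
        else:
            expanded.append(tok)
    if did_expand:
        trace.append("expand_abbreviations")

    kept = [t for t in expanded if t not in rules.unwanted_terms]
    if len(kept) != len(expanded):
        trace.append("drop_unwanted_terms")

    return NormalizedName(
        text=" ".join(kept), tokens=tuple(kept), trace=tuple(trace)
    )


def apply_special_case(
    name: NormalizedName, rules: RuleSet, raw: str | None = None
) -> str | None:
    """Return the special-case target for *name*, if one is defined.

    Both the verbatim raw string (lowercased, accent-folded) and the
    normalized text are honoured as keys; the raw key takes precedence.
    Returns the target standardized name (or concept id) or ``None``.
    """
    if raw is not None:
        hit = rules.special_cases.get(_fold_key(raw))
        if hit is not None:
            return hit
    return rules.special_cases.get(name.text)
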