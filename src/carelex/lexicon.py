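"""Categorized term dictionaries (gazetteers) that drive all matching.

The classifier is entirely lexicon-driven: facility names, caregiver terms,
patient-referring terms, patient-agency verbs and negation cues all live in a
single two-column table (``term,category``) so that institution-specific
dictionaries can be swapped in at run time without touching code.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable


class Category(str, enum.Enum):
    """Role a dictionary term plays in the rule engine."""

    INSTITUTION = "INSTITUTION"
    FORMAL = "FORMAL"
    INFORMAL = "INFORMAL"
    PATIENT_TERM = "PATIENT_TERM"
    PATIENT_VERB = "PATIENT_VERB"
    INSTITUTION_NEGATION = "INSTITUTION_NEGATION"
    REMOVAL_PHRASE = "REMOVAL_PHRASE"
    VISIT_VARIANT = "VISIT_VARIANT"


# The patient-referring surface forms the home self-care rule inspects.
CANONICAL_PATIENT_TERMS = frozenset({"patient", "pt", "patient's"})

MAX_TERM_TOKENS = 6


@dataclass(frozen=True, order=True)
class Term:
    """A lowercase 1..6-token surface form with its dictionary category."""

    surface: str
    category: Category

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(self.surface.split())


@dataclass
class Lexicon:
    """A validated set of categorized terms.

    Duplicate (surface, category) pairs are collapsed by construction; use
    :func:`validate_lexicon` to audit invariants on hand-built instances.
    """

    terms: set[Term] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)

    def by_category(self, category: Category) -> list[Term]:
        return sorted(t for t in self.terms if t.category is category)

    def surfaces(self, category: Category) -> set[str]:
        return {t.surface for t in self.terms if t.category is category}

    def add(self, surface: str, category: Category) -> None:
        self.terms.add(Term(surface=surface, category=category))

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, item: tuple[str, Category] | Term) -> bool:
        if isinstance(item, Term):
            return item in self.terms
        surface, category = item
        return Term(surface=surface, category=Category(category)) in self.terms


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon from a two-column delimited file (``term,category``).

    Surfaces are normalized to lowercase. Rows with an unknown category or an
    empty term are rejected with the offending row number in the message.
    """
    path = Path(path)
    lex = Lexicon(provenance={"source": str(path)})
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"term", "category"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected header columns 'term,category'")
        for lineno, row in enumerate(reader, start=2):
            raw_term = (row.get("term") or "").strip()
            raw_cat = (row.get("category") or "").strip()
            if not raw_term:
                raise ValueError(f"{path}:{lineno}: empty term")
            try:
                category = Category(raw_cat)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: unknown category {raw_cat!r} for term {raw_term!r}"
                ) from None
            surface = " ".join(raw_term.lower().split())
            lex.add(surface, category)
    issues = validate_lexicon(lex)
    if issues:
        raise ValueError(f"{path}: invalid lexicon: " + "; ".join(issues))
    return lex


def save_lexicon(lex: Lexicon, path: str | Path) -> None:
    """Serialize to the same two-column format :func:`load_lexicon` reads."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["term", "category"])
        for term in sorted(lex.terms, key=lambda t: (t.category.value, t.surface)):
            writer.writerow([term.surface, term.category.value])


def validate_lexicon(lex: Lexicon | Iterable[Term]) -> list[str]:
    """Report invariant violations; returns an empty list iff the lexicon is valid.

    Validation never raises: each issue string names the term, its category
    and the violated rule.
    """
    terms = list(lex.terms) if isinstance(lex, Lexicon) else list(lex)
    issues: list[str] = []
    seen: set[tuple[str, Category]] = set()
    for term in terms:
        key = (term.surface, term.category)
        if key in seen:
            issues.append(
                f"duplicate term {term.surface!r} in category {term.category.value}"
            )
        seen.add(key)
        if not term.surface:
            issues.append(f"empty surface in category {term.category.value}")
            continue
        if term.surface != term.surface.lower():
            issues.append(
                f"term {term.surface!r} ({term.category.value}) contains uppercase characters"
            )
        if term.surface != " ".join(term.surface.split()):
            issues.append(
                f"term {term.surface!r} ({term.category.value}) has irregular whitespace"
            )
        if not 1 <= len(term.tokens) <= MAX_TERM_TOKENS:
            issues.append(
                f"term {term.surface!r} ({term.category.value}) must be 1..{MAX_TERM_TOKENS} tokens"
            )
    # The home self-care rule matches exactly these patient-referring forms,
    # so a lexicon that defines the category at all must define it in full.
    patient_terms = {t.surface for t in terms if t.category is Category.PATIENT_TERM}
    if patient_terms and patient_terms != set(CANONICAL_PATIENT_TERMS):
        issues.append(
            "PATIENT_TERM category must contain exactly "
            f"{sorted(CANONICAL_PATIENT_TERMS)}, got {sorted(patient_terms)}"
        )
    return issues


def bundled_fixture_lexicon() -> Lexicon:
    """The packaged starter dictionary.

    A minimal reconstruction covering facility names, formal/informal
    caregiver terms, patient terms and verbs, institution-negation cues and
    visiting variants; real deployments swap in a site-specific dictionary
    (e.g. a state skilled-nursing-facility registry) via :func:`load_lexicon`.
    """
    ref = resources.files("carelex.data").joinpath("fixture_lexicon.csv")
    with resources.as_file(ref) as path:
        lex = load_lexicon(path)
    lex.provenance["source"] = "bundled fixture"
    return lex
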