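"""Sentence segmentation, tokenization, n-gram gazetteer matching and the
word-window / negation-neighborhood primitives the classifier is built on.

All matching is verbatim token n-gram matching on lowercase text — no
stemming beyond a closed inflectional variant expansion for negation cues and
"visiting", and no fuzzy matching (unlisted or misspelled facility names are
an acknowledged miss class).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .lexicon import Category, Lexicon, Term


@dataclass(frozen=True)
class Sentence:
    index: int
    tokens: tuple[str, ...]
    char_span: tuple[int, int]


@dataclass(frozen=True)
class TermMatch:
    term: Term
    sentence_index: int
    token_span: tuple[int, int]  # half-open, within sentence


@dataclass(frozen=True)
class WindowConfig:
    """Word-window size for proximity rules; 4 gave the best training accuracy."""

    k: int = 4

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("window size k must be >= 0")


_SENTENCE_BOUNDARY = re.compile(r"[.!?\n]")
# Tokens are runs of letters/digits; internal apostrophes are kept so
# "patient's" stays one token. All other punctuation is discarded.
_TOKEN = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)*")


def tokenize(sentence_text: str) -> list[str]:
    """Split into lowercase word tokens, preserving internal apostrophes."""
    return _TOKEN.findall(sentence_text)


def segment_sentences(cleaned_text: str) -> list[Sentence]:
    """Split cleaned text at ``.!?`` and newlines; empty sentences are dropped.

    Telephone notes are line-structured, so a newline is a hard boundary.
    Character spans are half-open intervals into ``cleaned_text``.
    """
    sentences: list[Sentence] = []
    start = 0
    for m in _SENTENCE_BOUNDARY.finditer(cleaned_text):
        piece = cleaned_text[start : m.start()]
        tokens = tokenize(piece)
        if tokens:
            sentences.append(
                Sentence(index=len(sentences), tokens=tuple(tokens), char_span=(start, m.start()))
            )
        start = m.end()
    tail = cleaned_text[start:]
    if tokenize(tail):
        sentences.append(
            Sentence(index=len(sentences), tokens=tuple(tokenize(tail)), char_span=(start, len(cleaned_text)))
        )
    return sentences


def match_terms(
    sentences: Sequence[Sentence],
    lexicon: Lexicon,
    category: Category,
) -> list[TermMatch]:
    """Find every occurrence of the category's terms as contiguous token n-grams.

    At each token position the longest matching term wins and consumes its
    tokens; shorter matches overlapping a longer one are suppressed. Matches
    are returned ordered by (sentence, start position).
    """
    terms = lexicon.by_category(category)
    if not terms:
        return []
    by_first: dict[str, list[Term]] = {}
    for term in terms:
        by_first.setdefault(term.tokens[0], []).append(term)
    for cands in by_first.values():
        cands.sort(key=lambda t: len(t.tokens), reverse=True)

    matches: list[TermMatch] = []
    for sent in sentences:
        i = 0
        n = len(sent.tokens)
        while i < n:
            hit = None
            for term in by_first.get(sent.tokens[i], ()):
                width = len(term.tokens)
                if sent.tokens[i : i + width] == term.tokens:
                    hit = TermMatch(term=term, sentence_index=sent.index, token_span=(i, i + width))
                    break  # candidates sorted longest-first
            if hit is not None:
                matches.append(hit)
                i = hit.token_span[1]
            else:
                i += 1
    return matches


def within_word_window(
    sentence: Sentence,
    span_a: tuple[int, int],
    span_b: tuple[int, int],
    cfg: WindowConfig = WindowConfig(),
) -> bool:
    """True iff the token gap between the nearest ends of the spans is <= k.

    Symmetric in the two spans; spans in different sentences never qualify
    (callers enforce that both spans index into ``sentence``). Overlapping
    spans have gap zero.
    """
    (a0, a1), (b0, b1) = span_a, span_b
    if a0 >= b1:
        gap = a0 - b1
    elif b0 >= a1:
        gap = b0 - a1
    else:
        gap = 0
    return gap <= cfg.k


_SPECIAL_VARIANTS: dict[str, set[str]] = {
    "waiting list": {"wait list", "waitlist"},
    "rehab": {"rehabilitation"},
    "rehabilitation": {"rehab"},
}


def _inflect(base: str) -> set[str]:
    forms = {base, base + "s"}
    if base.endswith("e"):
        forms |= {base + "d", base[:-1] + "ing"}
    else:
        forms |= {base + "ed", base + "ing"}
        if base.endswith("l"):  # cancelled / cancelling doublings
            forms |= {base + "led", base + "ling"}
    return forms


def expand_variants(stem: str) -> set[str]:
    """Closed set of inflectional variants of a (possibly multi-token) stem.

    Suffixes {s, ed, ing, d} are applied to the stem's head verb, with the
    head de-inflected first when it already carries -ed/-ing ("discharged
    from" also yields "discharges from", "discharging from"). A few
    lexicalized pairs (rehab/rehabilitation, waiting list/waitlist) are
    special-cased. Deterministic.
    """
    head, *rest = stem.lower().split()
    bases = {head}
    if head.endswith("ing") and len(head) > 4:
        bases.add(head[:-3])
    elif head.endswith("ed") and len(head) > 3:
        bases.add(head[:-1] if head[:-1].endswith("e") else head[:-2])
    forms: set[str] = {head}
    for base in bases:
        forms |= _inflect(base)
    suffix = (" " + " ".join(rest)) if rest else ""
    out = {f + suffix for f in forms}
    out.add(stem.lower())
    out |= _SPECIAL_VARIANTS.get(stem.lower(), set())
    return out


_VISIT_VARIANTS = frozenset(expand_variants("visit"))


def detect_visiting_nurse(
    sentences: Sequence[Sentence],
    visit_variants: Iterable[str] | None = None,
) -> bool:
    """Detect formal-caregiver evidence of the form "visit(ing) ... nurse".

    For each sentence containing the token ``nurse``: true if a visiting
    variant occurs before the nurse token in the same sentence, or after it
    in the same sentence or anywhere in the immediately following sentence.
    """
    variants = frozenset(visit_variants) if visit_variants is not None else _VISIT_VARIANTS
    for sent in sentences:
        positions = [i for i, tok in enumerate(sent.tokens) if tok == "nurse"]
        if not positions:
            continue
        for pos in positions:
            if any(tok in variants for tok in sent.tokens[:pos]):
                return True
            if any(tok in variants for tok in sent.tokens[pos + 1 :]):
                return True
            nxt = next((s for s in sentences if s.index == sent.index + 1), None)
            if nxt is not None and any(tok in variants for tok in nxt.tokens):
                return True
    return False


def _contains_ngram(tokens: Sequence[str], phrase_tokens: tuple[str, ...]) -> bool:
    width = len(phrase_tokens)
    return any(
        tuple(tokens[i : i + width]) == phrase_tokens
        for i in range(len(tokens) - width + 1)
    )


def non_negated_institution_matches(
    sentences: Sequence[Sentence],
    lexicon: Lexicon,
) -> list[TermMatch]:
    """Institution matches surviving the negation-neighborhood rule.

    A facility mention co-occurring in a sentence with a negation cue
    ("waiting list for", "discharged from", "declined", "rehab", ...) refers
    to a potential, past or unapproved placement, not the current residence;
    in that case ALL mentions of that facility in the note are disregarded.
    """
    all_matches = match_terms(sentences, lexicon, Category.INSTITUTION)
    if not all_matches:
        return []
    negation_phrases = {
        tuple(variant.split())
        for stem in lexicon.surfaces(Category.INSTITUTION_NEGATION)
        for variant in expand_variants(stem)
    }
    sent_by_index = {s.index: s for s in sentences}
    negated_terms: set[Term] = set()
    for m in all_matches:
        tokens = sent_by_index[m.sentence_index].tokens
        if any(_contains_ngram(tokens, phrase) for phrase in negation_phrases):
            negated_terms.add(m.term)
    return [m for m in all_matches if m.term not in negated_terms]


_SUPPRESSED_UNIGRAMS = ("patient", "pt", "caregiver", "guardian")
_SUPPRESSED_BIGRAM = ("care", "giver")


def suppress_patient_terms_in_institution_sentences(
    sentences: Sequence[Sentence],
    surviving_institution_matches: Sequence[TermMatch],
) -> list[Sentence]:
    """Remove patient/caregiver tokens from sentences naming an institution.

    In a sentence that mentions the patient's facility, "patient", "pt",
    "care giver", "caregiver" and "guardian" describe institutional care, not
    independent home care or a separate hired caregiver, so they are dropped
    before caregiver-term matching. Other sentences are untouched.
    """
    flagged = {m.sentence_index for m in surviving_institution_matches}
    out: list[Sentence] = []
    for sent in sentences:
        if sent.index not in flagged:
            out.append(sent)
            continue
        kept: list[str] = []
        i = 0
        while i < len(sent.tokens):
            if tuple(sent.tokens[i : i + 2]) == _SUPPRESSED_BIGRAM:
                i += 2
                continue
            if sent.tokens[i] in _SUPPRESSED_UNIGRAMS:
                i += 1
                continue
            kept.append(sent.tokens[i])
            i += 1
        out.append(replace(sent, tokens=tuple(kept)))
    return out
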