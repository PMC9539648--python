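"""Note-level classification into four binary flags.

Each note is labelled independently, on its own text only, for:

* ``home`` — evidence the patient resides at home and self-manages care,
* ``institution`` — evidence the patient resides in a care facility,
* ``formal`` — a paid/professional caregiver (agency, visiting nurse, or
  institutional staff),
* ``informal`` — an unpaid family member or friend providing care.

Flags are not mutually exclusive, except for two hard implications: a patient
residing in an institution is by definition under formal (staff) care, and is
not residing at home. A note with no evidence gets all zeros — absence of
information and explicit negation are not distinguished.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .lexicon import Category, Lexicon, bundled_fixture_lexicon
from .preprocess import preprocess
from .textmatch import (
    Sentence,
    TermMatch,
    WindowConfig,
    detect_visiting_nurse,
    match_terms,
    non_negated_institution_matches,
    segment_sentences,
    suppress_patient_terms_in_institution_sentences,
    within_word_window,
)

FLAGS = ("home", "institution", "formal", "informal")


@dataclass(frozen=True)
class NoteLabels:
    """The four binary note-level flags."""

    home: int = 0
    institution: int = 0
    formal: int = 0
    informal: int = 0

    def __post_init__(self) -> None:
        for flag in FLAGS:
            if getattr(self, flag) not in (0, 1):
                raise ValueError(f"{flag} must be 0 or 1")
        if self.institution and not self.formal:
            raise ValueError("institution=1 implies formal=1")
        if self.institution and self.home:
            raise ValueError("institution=1 implies home=0")

    def as_dict(self) -> dict[str, int]:
        return {flag: getattr(self, flag) for flag in FLAGS}

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.home, self.institution, self.formal, self.informal)


@dataclass(frozen=True)
class Evidence:
    """One triggering rule or matched term behind a flag."""

    source: str  # rule name or dictionary term
    sentence_index: int  # -1 for note-level patterns
    text: str


@dataclass
class EvidenceTrace:
    """Per-flag evidence lists; a flag is 1 iff its list is non-empty."""

    home: list[Evidence] = field(default_factory=list)
    institution: list[Evidence] = field(default_factory=list)
    formal: list[Evidence] = field(default_factory=list)
    informal: list[Evidence] = field(default_factory=list)

    def for_flag(self, flag: str) -> list[Evidence]:
        return getattr(self, flag)


@dataclass(frozen=True)
class ClassifierConfig:
    """Lexicon plus proximity-window size (4 words by default)."""

    lexicon: Lexicon
    window: WindowConfig = WindowConfig(k=4)

    @classmethod
    def default(cls) -> "ClassifierConfig":
        return cls(lexicon=bundled_fixture_lexicon())


# Rule 13, second clause: an answered "relationship to patient" template field
# naming the patient themself is home self-care evidence. The unanswered
# variant was already deleted during preprocessing.
_RELATIONSHIP_SELF = re.compile(r"relationship to patient\s*:\s*(?:patient|pt|self)\b")


def _mask_spans(sentences: Sequence[Sentence], matches: Sequence[TermMatch]) -> list[Sentence]:
    """Replace tokens consumed by institution n-grams with an unmatchable sentinel."""
    spans_by_sentence: dict[int, list[tuple[int, int]]] = {}
    for m in matches:
        spans_by_sentence.setdefault(m.sentence_index, []).append(m.token_span)
    out: list[Sentence] = []
    for sent in sentences:
        spans = spans_by_sentence.get(sent.index)
        if not spans:
            out.append(sent)
            continue
        tokens = list(sent.tokens)
        for start, end in spans:
            for i in range(start, end):
                tokens[i] = "\x00"
        out.append(replace(sent, tokens=tuple(tokens)))
    return out


def _snippet(sent: Sentence, span: tuple[int, int]) -> str:
    return " ".join(sent.tokens[span[0] : span[1]])


@dataclass(frozen=True)
class NoteSignals:
    """Raw per-category evidence before the implication guards.

    ``home`` here means home-self-care evidence was found, regardless of
    whether an institution mention later vetoes the flag; the coverage report
    needs this ungated view.
    """

    institution: tuple[Evidence, ...]
    visiting_nurse: tuple[Evidence, ...]
    formal_terms: tuple[Evidence, ...]
    informal_terms: tuple[Evidence, ...]
    home: tuple[Evidence, ...]


def extract_signals(raw_text: str, cfg: ClassifierConfig, note_id: str = "") -> NoteSignals:
    """Run the full rule pipeline and collect raw evidence per category."""
    lex = cfg.lexicon
    cleaned = preprocess(raw_text, note_id).cleaned_text
    sentences = segment_sentences(cleaned)
    sent_by_index = {s.index: s for s in sentences}

    inst_matches = non_negated_institution_matches(sentences, lex)
    institution_ev = tuple(
        Evidence(m.term.surface, m.sentence_index, _snippet(sent_by_index[m.sentence_index], m.token_span))
        for m in inst_matches
    )

    # Caregiver matching runs on the "unconsumed view": tokens claimed by a
    # surviving institution n-gram are masked, then patient/caregiver tokens
    # are suppressed in institution sentences.
    masked = _mask_spans(sentences, inst_matches)
    working = suppress_patient_terms_in_institution_sentences(masked, inst_matches)

    visit_variants = lex.surfaces(Category.VISIT_VARIANT) or None
    visiting_ev: tuple[Evidence, ...] = ()
    if detect_visiting_nurse(working, visit_variants):
        visiting_ev = (Evidence("visiting-nurse-rule", -1, "visit variant near 'nurse'"),)

    work_by_index = {s.index: s for s in working}

    def term_evidence(category: Category) -> tuple[Evidence, ...]:
        return tuple(
            Evidence(m.term.surface, m.sentence_index, _snippet(work_by_index[m.sentence_index], m.token_span))
            for m in match_terms(working, lex, category)
        )

    formal_ev = term_evidence(Category.FORMAL)
    informal_ev = term_evidence(Category.INFORMAL)

    home_ev: list[Evidence] = []
    patient_terms = match_terms(working, lex, Category.PATIENT_TERM)
    patient_verbs = match_terms(working, lex, Category.PATIENT_VERB)
    verbs_by_sentence: dict[int, list[TermMatch]] = {}
    for v in patient_verbs:
        verbs_by_sentence.setdefault(v.sentence_index, []).append(v)
    evidenced_sentences: set[int] = set()
    for p in patient_terms:
        if p.sentence_index in evidenced_sentences:  # one evidence line per sentence
            continue
        sent = work_by_index[p.sentence_index]
        for v in verbs_by_sentence.get(p.sentence_index, ()):
            if within_word_window(sent, p.token_span, v.token_span, cfg.window):
                home_ev.append(
                    Evidence(
                        "patient-verb-window",
                        p.sentence_index,
                        f"{_snippet(sent, p.token_span)} ~ {_snippet(sent, v.token_span)}",
                    )
                )
                evidenced_sentences.add(p.sentence_index)
                break
    m = _RELATIONSHIP_SELF.search(cleaned)
    if m:
        home_ev.append(Evidence("relationship-to-patient", -1, m.group(0)))

    return NoteSignals(
        institution=institution_ev,
        visiting_nurse=visiting_ev,
        formal_terms=formal_ev,
        informal_terms=informal_ev,
        home=tuple(home_ev),
    )


def classify_note(
    raw_text: str,
    note_id: str = "",
    cfg: ClassifierConfig | None = None,
) -> tuple[NoteLabels, EvidenceTrace]:
    """Classify one note; deterministic, never raises on malformed text."""
    if cfg is None:
        cfg = ClassifierConfig.default()
    sig = extract_signals(raw_text, cfg, note_id)

    trace = EvidenceTrace()
    trace.institution.extend(sig.institution)

    trace.formal.extend(sig.formal_terms)
    trace.formal.extend(sig.visiting_nurse)
    for ev in sig.institution:
        trace.formal.append(
            Evidence("institution-implies-formal", ev.sentence_index, ev.text)
        )

    trace.informal.extend(sig.informal_terms)

    # Home self-care is only assessed when no institutional residence is found.
    if not sig.institution:
        trace.home.extend(sig.home)

    labels = NoteLabels(
        home=int(bool(trace.home)),
        institution=int(bool(trace.institution)),
        formal=int(bool(trace.formal)),
        informal=int(bool(trace.informal)),
    )
    return labels, trace


def classify_corpus(
    notes: Iterable[tuple[str, str, str]],
    cfg: ClassifierConfig | None = None,
):
    """Classify (note_id, patient_id, text) records independently.

    Returns a pandas DataFrame with one row per note, in input order, columns
    ``note_id, patient_id, home, institution, formal, informal``. Duplicate
    note ids are rejected.
    """
    import pandas as pd

    if cfg is None:
        cfg = ClassifierConfig.default()
    rows = []
    seen: set[str] = set()
    for note_id, patient_id, text in notes:
        if note_id in seen:
            raise ValueError(f"duplicate note_id {note_id!r}")
        seen.add(note_id)
        labels, _ = classify_note(text, note_id, cfg)
        rows.append({"note_id": note_id, "patient_id": patient_id, **labels.as_dict()})
    return pd.DataFrame(rows, columns=["note_id", "patient_id", *FLAGS])


def explain(trace: EvidenceTrace) -> str:
    """Human-readable per-flag evidence report."""
    lines: list[str] = []
    for flag in FLAGS:
        evidence = trace.for_flag(flag)
        if not evidence:
            lines.append(f"{flag}: no evidence (default 0)")
            continue
        lines.append(f"{flag}: 1")
        for ev in evidence:
            where = f"sentence {ev.sentence_index}" if ev.sentence_index >= 0 else "note-level"
            lines.append(f"  - {ev.source} ({where}): {ev.text!r}")
    return "\n".join(lines)
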