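"""Ordered text normalization applied to every note before any matching.

Telephone-encounter notes mix clinical abbreviations ("PT" the discipline vs
"pt" the patient), template boilerplate ("patient portal", "family history:"
sections) and device collocations ("hearing aid") that would otherwise fire
false caregiver or residence evidence. Nine substitution rules, applied in a
fixed order, neutralize these patterns. The exact phrase lists live in this
one module so they can be audited in a single place.

Order matters: rule 1 disambiguates uppercase "PT" (physical therapy) and must
run before rule 2 lowercases the note and erases the case signal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ProcessedNote:
    """A note after normalization, with a per-rule application trace."""

    note_id: str
    original_text: str
    cleaned_text: str
    trace: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def rule_count(self, rule_id: int) -> int:
        for rid, count in self.trace:
            if rid == rule_id:
                return count
        raise KeyError(rule_id)


# Rule 1: standalone uppercase "PT" is the physical-therapy discipline, never
# the patient. Bounded by non-letters so acronyms like "CPT" are untouched.
_UPPER_PT = re.compile(r"(?<![A-Za-z])PT(?![A-Za-z])")


def expand_uppercase_pt(text: str) -> str:
    """Replace standalone uppercase ``PT`` with ``physical therapy`` (rule 1)."""
    return _UPPER_PT.sub("physical therapy", text)


# Smart quotes normalized alongside lowercasing so dictionary terms like
# "patient's" match regardless of the EHR editor's apostrophe style.
_QUOTE_MAP = str.maketrans({"’": "'", "‘": "'", "“": '"', "”": '"'})


def lowercase(text: str) -> str:
    """Lowercase the note and normalize curly quotes to ASCII (rule 2)."""
    return text.lower().translate(_QUOTE_MAP)


# Rule 3: boilerplate phrases that raise false positives for "patient",
# "family", "nurse" or "caregiver". Deleted verbatim from the lowercase text.
FALSE_POSITIVE_PHRASES: tuple[str, ...] = (
    "nurse navigator",
    "navigator nurse",
    "patient portal",
    "patient name",
    "e.g., visiting nurse",
    "patient & caregiver",
    "patient or caregiver",
    "patient &/or caregiver",
    "family medicine",
    "family practice",
    "family doctor",
    "family physician",
    "alone with family",
    "verbalizes understanding",
    "verbalized understanding",
)

# An unfilled "relationship to patient" template field: the phrase, an
# optional colon, then nothing but blanks up to end-of-line. An answered
# field survives and is inspected later by the home self-care rule.
_UNANSWERED_RELATIONSHIP = re.compile(r"relationship to patient:?[ \t]*(?=\r?\n|$)")


def remove_false_positive_phrases(text: str) -> tuple[str, int]:
    """Delete the rule-3 boilerplate phrases from lowercase text."""
    count = 0
    for phrase in FALSE_POSITIVE_PHRASES:
        count += text.count(phrase)
        text = text.replace(phrase, "")
    text, n = _UNANSWERED_RELATIONSHIP.subn("", text)
    return text, count + n


# Rule 4: "family history" sections list relatives who are not caregivers.
_FAMILY_HISTORY = re.compile(r"family history[^\n\r]*")


def strip_family_history(text: str) -> str:
    """Remove ``family history`` and everything up to the next newline (rule 4)."""
    return _FAMILY_HISTORY.sub("", text)


# Rule 5: device collocations. If any appears in the note, every standalone
# "aid"/"aids" token is removed note-wide ("aid" could otherwise be read as a
# caregiver aide elsewhere in the same note).
_AID_TRIGGER = re.compile(r"\b(?:sleeping|sleep|hearing|hear) aids?\b")
_AID_TOKEN = re.compile(r"\baids?\b")


def strip_device_aid_terms(text: str) -> str:
    """Remove ``aid``/``aids`` tokens when a device collocation is present (rule 5)."""
    if _AID_TRIGGER.search(text):
        return _AID_TOKEN.sub("", text)
    return text


# Rule 6: "want(s/ing) (the) patient/pt" collapses to "patient" so the verb
# "want" is not read as patient agency.
_WANT_PATIENT = re.compile(r"\bwant(?:s|ing)? (?:the (?:patient|pt)|pt)\b")


def neutralize_want_patient(text: str) -> str:
    """Collapse ``want(s|ing) (the) patient|pt`` to ``patient`` (rule 6)."""
    return _WANT_PATIENT.sub("patient", text)


# Rule 7: therapy-referral collocations where "pt" is the discipline.
_PT_OT = re.compile(r"\bpt (?:or|and) ot\b|\bpt/ot\b")


def expand_pt_ot(text: str) -> str:
    """Rewrite ``pt or/and ot`` and ``pt/ot`` to ``physical therapy and ot`` (rule 7)."""
    return _PT_OT.sub("physical therapy and ot", text)


def normalize_email(text: str) -> str:
    """Rewrite ``e-mail`` to ``email`` so tokenization keeps it whole (rule 8)."""
    return text.replace("e-mail", "email")


# Rule 9: possessive/plural/line-broken variants of "patient partner"
# collapse to the canonical bigram.
_PATIENT_PARTNER = re.compile(r"\bpatient(?:'s|s|\ns)\s+partner\b")


def normalize_patient_partner(text: str) -> str:
    """Canonicalize variants of ``patient partner`` (rule 9)."""
    return _PATIENT_PARTNER.sub("patient partner", text)


def preprocess(raw_text: str, note_id: str = "") -> ProcessedNote:
    """Apply the nine normalization rules in order and record a trace.

    Deterministic; never raises. Trace counts are the number of pattern
    applications for substitution rules, or 0/1 changed-flags for rules whose
    application count is not meaningful (lowercasing).
    """
    text = raw_text
    trace: list[tuple[int, int]] = []

    n1 = len(_UPPER_PT.findall(text))
    text = expand_uppercase_pt(text)
    trace.append((1, n1))

    lowered = lowercase(text)
    trace.append((2, int(lowered != text)))
    text = lowered

    text, n3 = remove_false_positive_phrases(text)
    trace.append((3, n3))

    n4 = len(_FAMILY_HISTORY.findall(text))
    text = strip_family_history(text)
    trace.append((4, n4))

    n5 = len(_AID_TOKEN.findall(text)) if _AID_TRIGGER.search(text) else 0
    text = strip_device_aid_terms(text)
    trace.append((5, n5))

    text, n6 = _WANT_PATIENT.subn("patient", text)
    trace.append((6, n6))

    text, n7 = _PT_OT.subn("physical therapy and ot", text)
    trace.append((7, n7))

    n8 = text.count("e-mail")
    text = normalize_email(text)
    trace.append((8, n8))

    text, n9 = _PATIENT_PARTNER.subn("patient partner", text)
    trace.append((9, n9))

    return ProcessedNote(
        note_id=note_id,
        original_text=raw_text,
        cleaned_text=text,
        trace=tuple(trace),
    )
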