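"""Seeded generator of telephone-encounter-style notes with known gold flags.

The real study corpus is private EHR data, so every other module is exercised
against synthetic notes instead. Notes are assembled from short evidence
templates (informal relation mentioned, agency care arranged, facility
residence, negated facility mention, patient self-care) plus neutral filler,
with gold flags set from the evidence actually inserted.

Noise classes emulate the documented misclassification causes — misspelled or
unlisted facility names, uncommon relation abbreviations ("dtr" for
daughter), irregular template headers, false-positive bait phrases, and
uncertain/undecided phrasing. Noise perturbs only the text, never the gold
labels: it models truth a human annotator still resolves but the rule engine
may miss.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field, replace

from .classify import NoteLabels
from .lexicon import Category, Lexicon, bundled_fixture_lexicon, validate_lexicon

NOISE_CLASSES = (
    "facility_misspelling",
    "uncommon_abbreviation",
    "template_injection",
    "distractor_injection",
    "uncertainty_phrasing",
)


@dataclass(frozen=True)
class Prevalence:
    """Per-flag gold prevalence targets.

    Defaults follow the observed feature rates in telephone-encounter notes:
    about two-thirds of notes carry home-residence evidence, a fifth name a
    facility, a third a formal caregiver and four-fifths an informal one.
    """

    home: float = 0.663
    institution: float = 0.213
    formal: float = 0.352
    informal: float = 0.806


@dataclass(frozen=True)
class NoiseRates:
    facility_misspelling: float = 0.1
    uncommon_abbreviation: float = 0.1
    template_injection: float = 0.1
    distractor_injection: float = 0.1
    uncertainty_phrasing: float = 0.1

    def rate(self, noise_class: str) -> float:
        return getattr(self, noise_class)

    @classmethod
    def none(cls) -> "NoiseRates":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SyntheticConfig:
    n_notes: int = 100
    notes_per_patient: tuple[int, int] = (1, 5)
    prevalence: Prevalence = field(default_factory=Prevalence)
    noise_rates: NoiseRates = field(default_factory=NoiseRates)
    seed: int = 0


@dataclass(frozen=True)
class LabeledNote:
    note_id: str
    patient_id: str
    text: str
    gold: NoteLabels
    noise_tags: frozenset[str] = frozenset()


# Facilities intentionally absent from the bundled dictionary, emulating the
# unlisted-facility miss class; only used under facility_misspelling noise.
HELD_OUT_FACILITIES = ("maple grove commons", "cedar brook manor", "willow point estates")

# Relation abbreviations annotators read but the dictionary does not list.
_ABBREVIATIONS = {
    "sister": "sis",
    "husband": "husb",
    "wife": "wf",
    "spouse": "sp",
    "daughter": "dtr",
    "son": "sn",
    "mother": "mom",
    "father": "dad",
    "friend": "frnd",
    "family": "fam",
}

_FILLER = (
    "medication refill sent to pharmacy.",
    "voicemail left regarding upcoming appointment.",
    "reviewed current medication list with no changes.",
    "no new concerns at this time.",
    "will follow up by phone next week.",
)

_DISTRACTORS = (
    "family history: mother dm, sister htn",
    "msg sent via patient portal",
    "uses a hearing aid at night",
    "referred to pt/ot for evaluation",
    "PT evaluated gait today",
    "seen in family medicine clinic",
)

_TEMPLATE_HEADERS = (
    "patient name: john doe",
    "relationship to patient:",
)


def inject_distractors(text: str, rng: random.Random) -> str:
    """Append label-neutral false-positive bait that preprocessing must defuse."""
    picks = rng.sample(_DISTRACTORS, k=rng.randint(1, 2))
    parts = [text] if text else []
    return "\n".join(parts + picks)


def _corrupt_facility(facility: str, rng: random.Random) -> str:
    mode = rng.randrange(3)
    if mode == 0:  # drop an interior character
        i = rng.randrange(1, len(facility) - 1)
        return facility[:i] + facility[i + 1 :]
    if mode == 1:  # truncate to the first word
        return facility.split()[0]
    return rng.choice(HELD_OUT_FACILITIES)  # unlisted facility


def inject_noise(note: LabeledNote, cfg: SyntheticConfig, rng: random.Random) -> LabeledNote:
    """Apply configured noise classes to the text; gold labels never change."""
    text = note.text
    tags = set(note.noise_tags)
    rates = cfg.noise_rates

    if rng.random() < rates.uncertainty_phrasing:
        m = re.search(r"pt now residing at ([a-z' ]+)\.", text)
        if m:
            facility = m.group(1)
            wrapped = (
                f"her final choice is {facility}."
                if rng.random() < 0.5
                else f"pt declined {facility} placement."
            )
            text = text[: m.start()] + wrapped + text[m.end() :]
            tags.add("uncertainty_phrasing")

    if rng.random() < rates.facility_misspelling:
        m = _FACILITY_MENTION.search(text)
        if m:
            target = m.group(1)
            text = text.replace(target, _corrupt_facility(target, rng))
            tags.add("facility_misspelling")

    if rng.random() < rates.uncommon_abbreviation:
        new_text = text
        for relation, abbrev in _ABBREVIATIONS.items():
            new_text = re.sub(rf"\b{relation}\b", abbrev, new_text)
        if new_text != text:
            text = new_text
            tags.add("uncommon_abbreviation")

    if rng.random() < rates.template_injection:
        header = "\n".join(rng.sample(_TEMPLATE_HEADERS, k=rng.randint(1, 2)))
        text = header + "\n" + text
        tags.add("template_injection")

    if rng.random() < rates.distractor_injection:
        text = inject_distractors(text, rng)
        tags.add("distractor_injection")

    return replace(note, text=text, noise_tags=frozenset(tags))


# Facility names only ever appear inside these sentence templates, so noise
# can locate them without consulting the lexicon.
_FACILITY_MENTION = re.compile(
    r"(?:residing at|waiting list for|final choice is|declined) ([a-z' ]+?)(?: placement)?\."
)


def _sample_gold(prev: Prevalence, rng: random.Random) -> NoteLabels:
    institution = int(rng.random() < prev.institution)
    if institution:
        return NoteLabels(
            home=0,
            institution=1,
            formal=1,
            informal=int(rng.random() < prev.informal),
        )
    # Conditional rates so the marginal prevalences hit their targets even
    # though institution notes force home=0 and formal=1.
    p_home = prev.home / (1 - prev.institution)
    p_formal = (prev.formal - prev.institution) / (1 - prev.institution)
    return NoteLabels(
        home=int(rng.random() < p_home),
        institution=0,
        formal=int(rng.random() < p_formal),
        informal=int(rng.random() < prev.informal),
    )


def _build_text(gold: NoteLabels, lex: Lexicon, rng: random.Random) -> str:
    relations = sorted(lex.surfaces(Category.INFORMAL))
    agencies = sorted(lex.surfaces(Category.FORMAL))
    facilities = sorted(lex.surfaces(Category.INSTITUTION))
    verbs = sorted(lex.surfaces(Category.PATIENT_VERB))

    lines = ["telephone encounter note"]
    if gold.institution:
        lines.append(f"pt now residing at {rng.choice(facilities)}.")
    elif rng.random() < 0.2:  # negated facility mention, exercises the negation rule
        lines.append(f"pt is on the waiting list for {rng.choice(facilities)}.")
    if gold.formal and not gold.institution:
        lines.append(f"{rng.choice(agencies)} will see pt weekly.")
    if gold.informal:
        lines.append(f"spoke with pt's {rng.choice(relations)} about plan of care.")
    if gold.home:
        lines.append(f"pt {rng.choice(verbs)} to call back with updates.")
    lines.append(rng.choice(_FILLER))
    mid = lines[1:]
    rng.shuffle(mid)
    return "\n".join(lines[:1] + mid)


def generate_corpus(cfg: SyntheticConfig, lexicon: Lexicon | None = None) -> list[LabeledNote]:
    """Generate a labelled synthetic corpus; byte-identical for a given config."""
    lex = lexicon if lexicon is not None else bundled_fixture_lexicon()
    issues = validate_lexicon(lex)
    if issues:
        raise ValueError("invalid lexicon: " + "; ".join(issues))
    prev = cfg.prevalence
    for name in ("home", "institution", "formal", "informal"):
        p = getattr(prev, name)
        if not 0 <= p <= 1:
            raise ValueError(f"prevalence.{name} must be in [0, 1]")
    if prev.home + prev.institution > 1:
        raise ValueError(
            "unachievable prevalence: home + institution > 1 "
            "(a note cannot be both at home and in an institution)"
        )
    if prev.formal < prev.institution:
        raise ValueError(
            "unachievable prevalence: formal < institution "
            "(institutional residence implies formal care)"
        )
    if cfg.n_notes < 1:
        raise ValueError("n_notes must be >= 1")
    lo, hi = cfg.notes_per_patient
    if not 1 <= lo <= hi:
        raise ValueError("notes_per_patient must be a positive (min, max) range")

    rng = random.Random(cfg.seed)
    notes: list[LabeledNote] = []
    patient_idx = 0
    while len(notes) < cfg.n_notes:
        patient_idx += 1
        pid = f"p{patient_idx:04d}"
        for _ in range(min(rng.randint(lo, hi), cfg.n_notes - len(notes))):
            gold = _sample_gold(prev, rng)
            text = _build_text(gold, lex, rng)
            note = LabeledNote(
                note_id=f"n{len(notes) + 1:05d}",
                patient_id=pid,
                text=text,
                gold=gold,
            )
            notes.append(inject_noise(note, cfg, rng))
    return notes


def corpus_to_frames(corpus: list[LabeledNote]):
    """(notes, gold) DataFrames: inputs for classify and evaluate."""
    import pandas as pd

    notes = pd.DataFrame(
        [{"note_id": n.note_id, "patient_id": n.patient_id, "text": n.text} for n in corpus]
    )
    gold = pd.DataFrame(
        [
            {"note_id": n.note_id, "patient_id": n.patient_id, **n.gold.as_dict()}
            for n in corpus
        ]
    )
    return notes, gold
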