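# Methods

## The extraction model

carelex implements a deterministic, rule-based classifier over free-text
clinical notes. The unit of analysis is the note: a patient's residence and
caregiver situation change over time, so each note is labelled independently,
using only its own text. Each note receives four binary flags — `home`,
`institution`, `formal`, `informal` — where 0 means *no evidence or explicit
negation* and 1 means *implied or explicit narration*. The model does not
distinguish "the note says there is no caregiver" from "the note says
nothing"; both are 0.

Two implications are enforced as hard constraints, in the gold-label type and
in the classifier output: a patient residing in an institution is under the
care of facility staff (`institution ⇒ formal`) and is not residing at home
(`institution ⇒ home = 0`). The remaining combinations are free — a patient
can have both a formal and an informal caregiver.

### Pipeline order

For each note: preprocessing rules 1–9 → sentence segmentation → institution
matching with the negation neighborhood → patient-term suppression in
facility sentences → visiting-nurse detection → formal-term matching →
informal-term matching → home self-care rule. The negation step must precede
suppression (suppression applies only to sentences whose facility mention
survived negation), and preprocessing must precede everything: the uppercase
`PT` rule is the canonical order dependency, since lowercasing first would
destroy the case signal that separates *physical therapy* from *patient*.

A token consumed by a surviving institution n-gram is masked before caregiver
matching, so a facility name cannot simultaneously serve as formal or
informal term evidence at the same position; institutional context dominates.

### Proximity window

Proximity rules use a word window of k = 4 tokens, measured between the
nearest ends of the two token spans, in either direction, within one sentence
only. The bidirectional reading is deliberate: patient-agency phrasing occurs
both as "pt agreed …" and "… agreed with pt", so a backward-only search would
miss half the pattern. k is configurable (`WindowConfig`); 4 is the default
because it is the best-performing window on the original development data
and we have no basis to re-tune it on synthetic text.

### Negation neighborhood

Negation cues are stored as stems (`discharged from`, `waiting list`,
`decline`, `rehab`, …) and expanded to a closed inflectional set — suffixes
{s, ed, ing, d} on the head verb, with the head de-inflected first where it
already carries -ed/-ing, plus the lexicalized pairs rehab/rehabilitation and
waiting list/wait list/waitlist. Expansion can generate a few unattested
forms (e.g. "rehabilitations"); these are harmless because matching is
verbatim and such tokens do not occur. When a cue co-occurs in a sentence
with a facility term, **all** mentions of that facility in the note are
disregarded (note-wide, per term): a note arranging a future placement
typically names the facility several times, and any one mention surviving
would flip the flag.

Whether the visiting-nurse rule's backward search should be limited to k
tokens rather than the whole sentence is genuinely open; the whole-sentence
reading is implemented, matching the rule's stated form. The open question is
noted for sensitivity analysis.

### Degenerate inputs and ties

Classification never raises: empty text, control characters, or
punctuation-only notes yield all-zero flags with empty evidence. Sentence
segmentation splits at `.`, `!`, `?` and newlines (telephone notes are
line-structured) and drops token-free segments. Tokens are maximal
letter/digit runs with internal apostrophes kept, so `patient's` is one token
and, conversely, `sister's` does **not** match the dictionary term `sister`
— an acknowledged conservative choice that mirrors verbatim matching of the
original design. Within a category, the longest dictionary match at a
position wins and consumes its tokens.

## The lexicon

All matching is driven by a two-column table (`term,category`), lowercase,
1–6 tokens per term. The bundled fixture is a *minimal starter dictionary*:
five facility names, six formal-caregiver terms, ten informal relations,
three patient verbs, the three patient-referring forms, eleven negation
stems and the four visiting variants. It is deliberately small — the full
institutional dictionary used to develop the approach (county facility
registries, state skilled-nursing-facility lists, consult-derived caregiver
terms) is site-specific — and the lexicon is a first-class runtime input so
deployments can swap in their own. One validation subtlety: the home
self-care rule hard-codes the three patient-referring forms, so a lexicon
that populates `PATIENT_TERM` at all must populate it exactly; an empty
category (e.g. an empty file) is valid, since the rule then simply finds no
patient terms.

## Evaluation machinery

Per-flag scoring treats gold = 1 as positive: precision = tp/(tp+fp),
sensitivity = recall = tp/(tp+fn), specificity = tn/(tn+fp),
accuracy = (tp+tn)/n, F1 = harmonic mean of precision and recall. Any 0/0 is
returned as `None` rather than 0, because silent zeros corrupt averages over
flags with empty positive classes.

"Overall accuracy over all four features" is implemented as **exact-match
accuracy**: the fraction of notes whose four flags are all correct. This is
the stricter and more standard multi-label summary; per-flag macro-average
accuracy is reported alongside for comparison since the two can differ
substantially.

Train/test splitting samples **patients**, not notes: patients are shuffled
by seed and moved into the test set until the test *note* fraction first
reaches the target. Note counts per patient vary, so the realized fraction
can overshoot the target slightly; patient-level grouping is the invariant
that matters (a patient's notes are correlated, and splitting them leaks
evaluation data). A corpus with fewer than two patients cannot be split.

Coverage reports, used to gauge dictionary transferability to new note types,
count the fraction of notes containing at least one triggering feature per
flag, on preprocessed text and *without* the implication guards (a note both
mentioning a facility and containing patient-agency phrasing counts toward
both `institution` and `home` coverage); `overall` is the union.

## The synthetic generator

Real telephone-encounter corpora are PHI and unavailable, so the generator
stands in for them. Each synthetic note is a newline-joined sequence of a
header line, evidence sentences drawn from fixed templates (facility
residence, negated facility mention, agency care, informal relation, patient
self-care) and neutral filler, with gold flags set from the evidence actually
inserted and the two implications applied at sampling time. Conditional
sampling keeps marginal prevalences on target even though institution notes
force `home = 0` and `formal = 1`; configurations whose targets are jointly
unachievable (`home + institution > 1`, `formal < institution`) are rejected.

Default prevalences (home 0.663, institution 0.213, formal 0.352, informal
0.806) follow the observed feature rates in telephone-encounter notes.
Patients carry 1–5 notes each (uniform) to exercise grouped splitting. All
randomness flows from one `random.Random(seed)`, making corpora byte-identical
per configuration.

Five noise classes emulate the documented misclassification causes:

* `facility_misspelling` — drop a character, truncate to the first word, or
  substitute a held-out facility absent from the dictionary;
* `uncommon_abbreviation` — replace informal relations with abbreviations the
  dictionary does not list (`daughter → dtr`);
* `template_injection` — prepend irregular template headers;
* `distractor_injection` — append false-positive bait (`family history:`
  lines, `patient portal`, `hearing aid`, `pt/ot`, uppercase `PT`) that
  preprocessing must defuse;
* `uncertainty_phrasing` — rewrite a residence sentence as a "final choice"
  or "declined" variant.

Noise perturbs **text only, never gold labels**: it models truth a human
annotator still resolves but the rule engine may miss. Default rates are 0.1
per class per note, a plausible perturbation level chosen once; the recovery
and degradation properties below override them explicitly.

### What the synthetic corpus does and does not show

By construction, a noise-free corpus is classified perfectly — every evidence
template is a pattern the rules recover exactly, and the test suite asserts
F1 = 1.0 on all four flags. This validates the *machinery* (rules fire when
and only when their evidence is present, and the documented interactions —
negation, suppression, implication — compose correctly), not real-world
accuracy: real notes contain paraphrase, misspellings, unlisted facilities
and ambiguous first-name caregivers that no closed dictionary captures, which
is exactly why the published scores on real notes sit well below 1. The noise
classes reintroduce those error modes in controlled doses; e.g. informal-flag
sensitivity degrades monotonically from 1.0 to 0.0 as the abbreviation rate
sweeps 0 → 1, reproducing the documented "uncommon abbreviations" failure
mode directionally, not numerically.

## Known limitations

* Verbatim matching only: no fuzzy/edit-distance facility matching, no
  spelling correction, no ML fallback. Unlisted or misspelled facilities are
  missed by design.
* Negation handling is the neighborhood rule only, not full negation-scope
  resolution (no NegEx-style scope parsing).
* A formal-caregiver term inside a negated-facility sentence is *not*
  suppressed (only the five patient/caregiver tokens are); whether it should
  be is undetermined and the quoted behavior is kept.
* Informal evidence does not contribute to `home`; the home rule uses only
  patient-agency verbs and the answered relationship field.
* The bundled dictionary is a starter set; coverage numbers computed with it
  understate what a full site dictionary would find.
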