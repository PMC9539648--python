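# carelex

Rule-based extraction of **caregiver availability** and **place of residence**
from free-text clinical notes.

Whether an older patient — for example someone living with dementia — has a
caregiver, and whether that caregiver is a paid professional or a family
member, is rarely recorded as structured EHR data, yet it drives discharge
planning and readmission risk. Telephone-encounter notes written by nursing
staff do contain this information in prose ("spoke with her daughter…",
"visiting nurse will stop by…", "pt now residing at Glacier Hills"). carelex
reads such notes and emits four note-level binary flags:

| flag | meaning |
|---|---|
| `home` | evidence the patient resides at home and self-manages care |
| `institution` | evidence the patient resides in a care facility |
| `formal` | a paid/professional caregiver (agency, visiting nurse, facility staff) |
| `informal` | an unpaid family member or friend providing care |

Flags are not mutually exclusive, except for two hard implications:
`institution = 1 ⇒ formal = 1` and `institution = 1 ⇒ home = 0`. A note with
no evidence gets all zeros; absence of information and explicit negation are
not distinguished.

## How it works

The pipeline is fully deterministic and dictionary-driven:

1. **Preprocessing (9 ordered rules)** — disambiguate uppercase `PT`
   (physical therapy) before lowercasing; delete boilerplate that raises
   false positives (`patient portal`, `family medicine`, unanswered
   `relationship to patient:` fields, …); strip `family history` sections to
   the end of line; remove device `aid(s)` collocations; neutralize
   `want(s) the patient`; expand `pt/ot`; normalize `e-mail` and
   `patient's partner`.
2. **Gazetteer matching** — terms from a two-column dictionary
   (`term,category`) are matched as verbatim token n-grams, longest match
   wins. Categories: facility names, formal and informal caregiver terms,
   patient terms, patient-agency verbs, negation cues, visiting variants.
3. **Neighborhood rules** —
   *visiting nurse*: a `visit` variant before `nurse` in the sentence, or
   after it in that sentence or the next, is formal-caregiver evidence;
   *institution negation*: a facility co-occurring with a cue such as
   `waiting list`, `discharged from`, `declined`, or `rehab` is disregarded
   note-wide;
   *patient suppression*: `patient`, `pt`, `care giver`, `caregiver`,
   `guardian` are dropped from sentences naming a (surviving) facility;
   *home self-care*: a patient-agency verb (`agreed`, `asked`, `reported`)
   within a 4-word window of `patient`/`pt`/`patient's`, or an answered
   `relationship to patient: self` field, when no institution was found.

Evaluation utilities score predictions per flag (F1, accuracy, sensitivity,
specificity, with 0/0 reported as undefined rather than 0), compute
exact-match accuracy over all four flags, split corpora **by patient** so no
patient's notes leak across train/test, and report dictionary *coverage* (the
fraction of notes containing any triggering feature per flag).

Because real note corpora are private, the package ships a seeded
**synthetic-note generator** that assembles telephone-encounter-style notes
with known gold flags and injects the documented noise classes (misspelled or
unlisted facility names, relation abbreviations such as `dtr` for daughter,
template headers, distractor phrases, uncertain phrasing).

## Worked example

```python
from carelex import ClassifierConfig, classify_note, explain

cfg = ClassifierConfig.default()          # bundled dictionary, 4-word window
note = ("PT saw pt this morning; pt agreed to continue home exercises.\n"
        "Spoke with her daughter about the medication schedule.\n"
        "Visiting nurse will stop by on Friday.")
labels, trace = classify_note(note, cfg=cfg)
print(labels.as_dict())
print(explain(trace))
```

prints

```
{'home': 1, 'institution': 0, 'formal': 1, 'informal': 1}
home: 1
  - patient-verb-window (sentence 0): 'pt ~ agreed'
  ...
formal: 1
  - visiting nurse (sentence 2): 'visiting nurse'
informal: 1
  - daughter (sentence 1): 'daughter'
```

`home=1` because the agency verb *agreed* sits within four words of *pt*;
*daughter* is informal evidence; *visiting nurse* is formal evidence; the
uppercase `PT` was rewritten to *physical therapy* and contributes nothing.
The scripts in `examples/` walk through single-note classification, a
synthetic train/test benchmark, and a dictionary-coverage report.

## Command line

```bash
carelex generate --config config.yaml --out notes.jsonl --gold gold.csv
carelex classify --notes notes.jsonl --lexicon mylex.csv --window 4 --out labels.jsonl
carelex evaluate --pred labels.jsonl --gold gold.csv --out metrics.json
carelex coverage --notes notes.jsonl
carelex lexicon validate mylex.csv
```

Notes are accepted as CSV (`note_id,patient_id,text`, RFC-4180 quoting) or
JSON-lines; JSONL is preferred since it trivially survives embedded newlines.
`metrics.json` holds one object per flag
(`{"f1": …, "accuracy": …, "sensitivity": …, "specificity": …, "precision": …}`,
`null` where undefined) plus `overall_exact_accuracy` and `macro_accuracy`.

The bundled dictionary is a minimal starter; real deployments should swap in
a site-specific facility registry and caregiver term list via `--lexicon`.

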