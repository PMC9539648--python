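"""Classify a single telephone-encounter note and show the evidence trace.

Run: python examples/classify_a_note.py
"""

from carelex import ClassifierConfig, classify_note, explain

cfg = ClassifierConfig.default()  # bundled dictionary, 4-word window

note = (
    "Telephone encounter.\n"
    "PT saw pt this morning; pt agreed to continue home exercises.\n"
    "Spoke with her daughter about the medication schedule.\n"
    "Family History: mother with dementia, sister with HTN\n"
    "Visiting nurse will stop by on Friday."
)

labels, trace = classify_note(note, note_id="demo-1", cfg=cfg)

print("flags:", labels.as_dict())
print()
print(explain(trace))

# Expected: home=1 (the patient-agency verb "agreed" sits next to "pt"),
# formal=1 (visiting nurse), informal=1 (daughter), institution=0.
# The "Family History" relatives and the uppercase "PT" (physical therapy)
# are neutralized by preprocessing and contribute no evidence.
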