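"""Measure what fraction of a note corpus the dictionary can speak to.

Coverage is the share of notes containing at least one triggering feature per
flag, computed on preprocessed text without the implication guards. It gauges
how transferable the dictionary is to a new note type before any annotation.

Run: python examples/dictionary_coverage.py
"""

from carelex import SyntheticConfig, bundled_fixture_lexicon, coverage_report, generate_corpus

corpus = generate_corpus(SyntheticConfig(n_notes=500, seed=7))
notes = [(n.note_id, n.patient_id, n.text) for n in corpus]

report = coverage_report(notes, bundled_fixture_lexicon())

print(f"notes scanned: {report['n_notes']}")
for key in ("home", "institution", "formal", "informal", "overall"):
    print(f"{key:12s} {report[key]:.1%}")

# "overall" is the union (any feature found) and therefore always at least
# as large as every per-flag fraction.
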