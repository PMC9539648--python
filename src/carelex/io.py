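"""Reading and writing note tables, label tables and metrics.

Notes are accepted as CSV (RFC-4180 quoting, via pandas) or JSON-lines, both
of which survive embedded newlines in note text; JSONL is preferred and is
the output format for classifications.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

NOTE_COLUMNS = ("note_id", "patient_id", "text")


def read_notes(path: str | Path) -> pd.DataFrame:
    """Read a note table (note_id, patient_id, text) from CSV or JSONL."""
    path = Path(path)
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        rows = []
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed JSON record: {exc}") from None
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(NOTE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df[list(NOTE_COLUMNS) + [c for c in df.columns if c not in NOTE_COLUMNS]]


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a label table (note_id plus the four flag columns) from CSV or JSONL."""
    path = Path(path)
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        with path.open(encoding="utf-8") as fh:
            df = pd.DataFrame([json.loads(line) for line in fh if line.strip()])
    else:
        df = pd.read_csv(path)
    required = {"note_id", "home", "institution", "formal", "informal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


def write_jsonl(records: list[dict], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for record in records:
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n", encoding="utf-8")
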