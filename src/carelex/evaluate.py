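"""Scoring predicted flags against gold chart-abstraction labels,
patient-grouped train/test splitting, and dictionary-coverage reporting.

Metrics follow the standard binary definitions with gold=1 as the positive
class. Any 0/0 ratio yields ``None`` (an undefined marker) rather than a
silent zero, so degenerate classes never corrupt averages.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import FLAGS, ClassifierConfig, extract_signals
from .lexicon import Lexicon
from .textmatch import WindowConfig


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """F1, accuracy, sensitivity (recall), specificity and precision.

    Fields are ``None`` where the defining ratio is 0/0.
    """

    f1: float | None
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "f1": self.f1,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def _aligned(preds: pd.DataFrame, golds: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if len(preds) != len(golds):
        raise ValueError(f"prediction/gold length mismatch: {len(preds)} vs {len(golds)}")
    p = preds.set_index("note_id") if "note_id" in preds.columns else preds
    g = golds.set_index("note_id") if "note_id" in golds.columns else golds
    if set(p.index) != set(g.index):
        raise ValueError("prediction and gold note_ids do not match")
    return p, g.loc[p.index]


def confusion(preds: pd.DataFrame, golds: pd.DataFrame, flag: str) -> ConfusionCounts:
    """Confusion counts for one flag, aligning rows by note_id."""
    p, g = _aligned(preds, golds)
    pv = p[flag].astype(int).to_numpy()
    gv = g[flag].astype(int).to_numpy()
    return ConfusionCounts(
        tp=int(((pv == 1) & (gv == 1)).sum()),
        fp=int(((pv == 1) & (gv == 0)).sum()),
        tn=int(((pv == 0) & (gv == 0)).sum()),
        fn=int(((pv == 0) & (gv == 1)).sum()),
    )


def compute_metrics(cc: ConfusionCounts) -> MetricSet:
    """Standard binary metrics from confusion counts; 0/0 -> None, never raises."""
    precision = _ratio(cc.tp, cc.tp + cc.fp)
    sensitivity = _ratio(cc.tp, cc.tp + cc.fn)
    specificity = _ratio(cc.tn, cc.tn + cc.fp)
    accuracy = _ratio(cc.tp + cc.tn, cc.total)
    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricSet(
        f1=f1,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
    )


def overall_exact_accuracy(preds: pd.DataFrame, golds: pd.DataFrame) -> float | None:
    """Fraction of notes whose four flags all match gold; None on empty input."""
    if len(preds) == 0 and len(golds) == 0:
        return None
    p, g = _aligned(preds, golds)
    exact = (p[list(FLAGS)].astype(int).to_numpy() == g[list(FLAGS)].astype(int).to_numpy()).all(axis=1)
    return float(exact.mean())


def evaluate_predictions(preds: pd.DataFrame, golds: pd.DataFrame) -> dict:
    """Per-flag metric sets plus overall exact-match and macro-average accuracy."""
    per_flag = {flag: compute_metrics(confusion(preds, golds, flag)) for flag in FLAGS}
    accuracies = [m.accuracy for m in per_flag.values() if m.accuracy is not None]
    return {
        "per_flag": per_flag,
        "overall_exact_accuracy": overall_exact_accuracy(preds, golds),
        "macro_accuracy": sum(accuracies) / len(accuracies) if accuracies else None,
    }


@dataclass(frozen=True)
class SplitAssignment:
    """patient_id -> 'train' | 'test'; all of a patient's notes share a split."""

    assignment: Mapping[str, str]

    def patients(self, split: str) -> set[str]:
        return {p for p, s in self.assignment.items() if s == split}

    def split_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]


def grouped_split(
    notes: Sequence[tuple[str, str, str]] | pd.DataFrame,
    test_fraction: float,
    seed: int,
) -> SplitAssignment:
    """Assign whole patients to train/test so no patient's notes leak across.

    Patients are drawn without replacement (shuffled by ``seed``) into the
    test set until the test NOTE fraction first reaches ``test_fraction``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if isinstance(notes, pd.DataFrame):
        patient_ids = list(notes["patient_id"])
    else:
        patient_ids = [p for _, p, *_ in notes]
    note_counts: dict[str, int] = {}
    for pid in patient_ids:
        note_counts[pid] = note_counts.get(pid, 0) + 1
    patients = sorted(note_counts)
    if len(patients) < 2:
        raise ValueError("cannot split a corpus with fewer than 2 patients")
    rng = random.Random(seed)
    rng.shuffle(patients)
    total = len(patient_ids)
    assignment = {p: "train" for p in patients}
    test_notes = 0
    for pid in patients:
        if test_notes / total >= test_fraction:
            break
        assignment[pid] = "test"
        test_notes += note_counts[pid]
    return SplitAssignment(assignment=assignment)


def coverage_report(
    notes: Iterable[tuple[str, str, str]] | pd.DataFrame,
    lexicon: Lexicon,
    k: int = 4,
) -> dict[str, float | int]:
    """Fraction of notes with at least one dictionary feature per category.

    Categories mirror the four flags (home self-care evidence, institution,
    formal, informal), computed on preprocessed text without the implication
    guards; ``overall`` is the fraction of notes triggering any category.
    Used to gauge how much of a new note corpus the dictionary can speak to.
    """
    if isinstance(notes, pd.DataFrame):
        records = list(notes[["note_id", "patient_id", "text"]].itertuples(index=False, name=None))
    else:
        records = list(notes)
    cfg = ClassifierConfig(lexicon=lexicon, window=WindowConfig(k=k))
    counts = {flag: 0 for flag in FLAGS}
    any_count = 0
    for _, _, text in records:
        sig = extract_signals(text, cfg)
        hits = {
            "home": bool(sig.home),
            "institution": bool(sig.institution),
            "formal": bool(sig.institution or sig.visiting_nurse or sig.formal_terms),
            "informal": bool(sig.informal_terms),
        }
        for flag, hit in hits.items():
            counts[flag] += hit
        any_count += any(hits.values())
    n = len(records)
    report: dict[str, float | int] = {"n_notes": n}
    for flag in FLAGS:
        report[flag] = counts[flag] / n if n else 0.0
    report["overall"] = any_count / n if n else 0.0
    return report
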