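"""Note quality control: the four-rule filter producing the HQ note set.

Rules, in application order:

1. collapse exact-duplicate note texts per patient, keeping one version;
2. remove notes with fewer than ``min_words`` whitespace tokens;
3. remove notes of diagnosed (ASD/PSYCH) patients dated outside
   ``diagnosis_date ± date_window_days``;
4. remove all notes of patients with fewer than ``min_visits`` distinct
   note dates among the surviving notes.

Deduplication runs before visit counting so that visit counts reflect the
surviving notes; a "visit" is a distinct note date per patient. The
department pre-filter (keeping psychiatric-type notes) is a separate,
optional step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .records import ClinicalNote, Patient

logger = logging.getLogger(__name__)


def word_count(text: str) -> int:
    """Number of whitespace-delimited tokens."""
    return len(text.split())


@dataclass
class QCReport:
    """Counts of notes removed by each rule, overall and per cohort."""

    n_notes_in: int = 0
    n_removed_duplicate: int = 0
    n_removed_short: int = 0
    n_removed_date_mismatch: int = 0
    n_removed_low_visits: int = 0
    n_patients_removed_low_visits: int = 0
    n_notes_out: int = 0
    per_cohort: dict[str, dict[str, int]] = field(default_factory=dict)

    def reconciles(self) -> bool:
        removed = (
            self.n_removed_duplicate
            + self.n_removed_short
            + self.n_removed_date_mismatch
            + self.n_removed_low_visits
        )
        return self.n_notes_out == self.n_notes_in - removed

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cohort, counts in sorted(self.per_cohort.items()):
            rows.append({"cohort": cohort, **counts})
        rows.append(
            {
                "cohort": "TOTAL",
                "n_notes_in": self.n_notes_in,
                "n_removed_duplicate": self.n_removed_duplicate,
                "n_removed_short": self.n_removed_short,
                "n_removed_date_mismatch": self.n_removed_date_mismatch,
                "n_removed_low_visits": self.n_removed_low_visits,
                "n_patients_removed_low_visits": self.n_patients_removed_low_visits,
                "n_notes_out": self.n_notes_out,
            }
        )
        return pd.DataFrame(rows)


def select_departments(
    notes: Iterable[ClinicalNote],
    keep: Sequence[str],
) -> list[ClinicalNote]:
    """Keep notes from the given departments (case-insensitive match)."""
    allowed = {d.lower() for d in keep}
    return [n for n in notes if n.department.lower() in allowed]


def qc_filter(
    notes: Sequence[ClinicalNote],
    patients: Sequence[Patient],
    min_words: int = 100,
    min_visits: int = 10,
    date_window_days: int = 365,
) -> tuple[list[ClinicalNote], QCReport]:
    """Apply the four QC rules; returns the HQ notes and a reconciled report.

    Notes referencing unknown patients are an error (listing their IDs).
    The word threshold is strict: a 99-word note is removed, a 100-word
    note retained. ``date_window_days=0`` recovers exact date matching.
    """
    by_id = {p.patient_id: p for p in patients}
    orphans = [n.note_id for n in notes if n.patient_id not in by_id]
    if orphans:
        raise ValueError(f"notes reference unknown patients: {orphans[:20]}")

    report = QCReport(n_notes_in=len(notes))

    def _cohort_bump(pid: str, key: str, amount: int = 1) -> None:
        cohort = by_id[pid].cohort
        report.per_cohort.setdefault(cohort, {})[key] = (
            report.per_cohort.get(cohort, {}).get(key, 0) + amount
        )

    # rule: deduplicate exact texts per patient, keep the first version
    seen: set[tuple[str, str]] = set()
    deduped: list[ClinicalNote] = []
    for n in notes:
        key = (n.patient_id, n.text)
        if key in seen:
            report.n_removed_duplicate += 1
            _cohort_bump(n.patient_id, "n_removed_duplicate")
        else:
            seen.add(key)
            deduped.append(n)

    # rule: remove short notes
    long_enough: list[ClinicalNote] = []
    for n in deduped:
        if word_count(n.text) < min_words:
            report.n_removed_short += 1
            _cohort_bump(n.patient_id, "n_removed_short")
        else:
            long_enough.append(n)

    # rule: notes of diagnosed patients must fall in the diagnosis window
    in_window: list[ClinicalNote] = []
    for n in long_enough:
        dx = by_id[n.patient_id].diagnosis_date
        if dx is not None and abs((n.date - dx).days) > date_window_days:
            report.n_removed_date_mismatch += 1
            _cohort_bump(n.patient_id, "n_removed_date_mismatch")
        else:
            in_window.append(n)

    # rule: drop patients with too few distinct visit dates
    visits: dict[str, set] = {}
    for n in in_window:
        visits.setdefault(n.patient_id, set()).add(n.date)
    low = {pid for pid, dates in visits.items() if len(dates) < min_visits}
    report.n_patients_removed_low_visits = len(low)
    hq: list[ClinicalNote] = []
    for n in in_window:
        if n.patient_id in low:
            report.n_removed_low_visits += 1
            _cohort_bump(n.patient_id, "n_removed_low_visits")
        else:
            hq.append(n)

    report.n_notes_out = len(hq)
    assert report.reconciles()
    logger.info(
        "qc: %d notes in, %d duplicates, %d short, %d date-mismatched, "
        "%d from %d low-visit patients removed, %d notes out",
        report.n_notes_in, report.n_removed_duplicate, report.n_removed_short,
        report.n_removed_date_mismatch, report.n_removed_low_visits,
        report.n_patients_removed_low_visits, report.n_notes_out,
    )
    return hq, report
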