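"""Readers and writers for the plain-text interchange formats.

Notes travel as JSONL (one note per line), patients and mentions as TSV.
All dates are ISO-8601 strings on disk.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .records import ClinicalNote, Mention, Patient


def write_notes_jsonl(notes: Iterable[ClinicalNote], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            rec = {
                "note_id": n.note_id,
                "patient_id": n.patient_id,
                "date": n.date.isoformat(),
                "department": n.department,
                "text": n.text,
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_notes_jsonl(path: str | Path) -> list[ClinicalNote]:
    notes = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                notes.append(
                    ClinicalNote(
                        note_id=rec["note_id"],
                        patient_id=rec["patient_id"],
                        date=_dt.date.fromisoformat(rec["date"]),
                        department=rec.get("department", ""),
                        text=rec["text"],
                    )
                )
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise ValueError(f"{path}: malformed note record on line {i}: {exc}") from exc
    return notes


def write_patients_tsv(patients: Iterable[Patient], path: str | Path) -> None:
    rows = []
    for p in patients:
        rows.append(
            {
                "patient_id": p.patient_id,
                "cohort": p.cohort,
                "sex": p.sex,
                "birth_date": p.birth_date.isoformat(),
                "diagnosis_date": p.diagnosis_date.isoformat() if p.diagnosis_date else "",
                "subgroup": "" if p.subgroup is None else str(p.subgroup),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_patients_tsv(path: str | Path) -> list[Patient]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    patients = []
    for row in df.itertuples(index=False):
        patients.append(
            Patient(
                patient_id=row.patient_id,
                cohort=row.cohort,
                sex=row.sex,
                birth_date=_dt.date.fromisoformat(row.birth_date),
                diagnosis_date=_dt.date.fromisoformat(row.diagnosis_date)
                if row.diagnosis_date
                else None,
                subgroup=int(row.subgroup) if row.subgroup != "" else None,
            )
        )
    return patients


def write_mentions_tsv(mentions: Iterable[Mention], path: str | Path) -> None:
    mentions_to_frame(mentions).to_csv(path, sep="\t", index=False)


def read_mentions_tsv(path: str | Path) -> list[Mention]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Mention(
                note_id=row.note_id,
                patient_id=row.patient_id,
                surface_form=row.surface_form,
                cui=row.cui or None,
                tuis=frozenset(t for t in row.tuis.split("|") if t),
                start=int(row.start),
                end=int(row.end),
            )
        )
    return out


def mentions_to_frame(mentions: Iterable[Mention]) -> pd.DataFrame:
    """Tabular view of a mention list (one row per mention)."""
    return pd.DataFrame(
        [
            {
                "note_id": m.note_id,
                "patient_id": m.patient_id,
                "surface_form": m.surface_form,
                "cui": m.cui or "",
                "tuis": "|".join(sorted(m.tuis)),
                "start": m.start,
                "end": m.end,
            }
            for m in mentions
        ],
        columns=["note_id", "patient_id", "surface_form", "cui", "tuis", "start", "end"],
    )
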