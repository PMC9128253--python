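"""Core record types shared across the pipeline.

A *patient* belongs to one of three cohorts: ``ASD`` (cases), ``PSYCH``
(psychiatric, non-ASD controls) and ``NONPSYCH`` (non-psychiatric controls).
A *clinical note* is a dated free-text document attached to one patient.
A *mention* is one dictionary-lookup hit of a lexicon surface form inside a
note, carrying the UMLS concept identifier (CUI) and semantic types (TUIs)
of the matched entry.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from typing import NamedTuple

COHORTS = ("ASD", "PSYCH", "NONPSYCH")

_CUI_RE = re.compile(r"^C\d+$")


@dataclass(frozen=True)
class Patient:
    """Cohort-labeled patient with demographics.

    ``diagnosis_date`` is present for ASD and PSYCH patients and absent for
    NONPSYCH patients; ``subgroup`` (a latent phenotype subgroup index) is
    present only for ASD patients.
    """

    patient_id: str
    cohort: str
    sex: str  # 'M', 'F' or 'U'
    birth_date: _dt.date
    diagnosis_date: _dt.date | None = None
    subgroup: int | None = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.sex not in ("M", "F", "U"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.cohort == "NONPSYCH" and self.diagnosis_date is not None:
            raise ValueError("NONPSYCH patients carry no diagnosis date")
        if (self.subgroup is not None) != (self.cohort == "ASD"):
            raise ValueError("subgroup present iff cohort is ASD")


@dataclass(frozen=True)
class ClinicalNote:
    """One dated free-text note for one patient."""

    note_id: str
    patient_id: str
    date: _dt.date
    department: str
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"note {self.note_id} has empty text")


@dataclass(frozen=True)
class LexiconEntry:
    """One row of the term lexicon: a surface form mapped to a UMLS concept.

    An empty ``cui`` models a surface form the concept normalizer failed to
    map; such mentions are later removed by ``drop_unmapped``.
    """

    surface_form: str
    cui: str | None
    preferred_name: str
    tuis: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.surface_form:
            raise ValueError("empty surface form")
        if self.cui is not None and not _CUI_RE.match(self.cui):
            raise ValueError(f"malformed CUI {self.cui!r}")
        if self.cui is not None and not self.tuis:
            raise ValueError(f"entry {self.surface_form!r} has no semantic types")


class Mention(NamedTuple):
    """A lexicon hit in a note; ``start:end`` is a 0-based half-open span."""

    note_id: str
    patient_id: str
    surface_form: str
    cui: str | None
    tuis: frozenset[str]
    start: int
    end: int
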