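"""Dictionary-lookup phenotype-term extraction and semantic-type filtering.

A pluggable stand-in for a clinical NER engine: surface forms from a CUI
lexicon are matched case-insensitively on token boundaries, longest match
first, without overlaps. Mentions that lack a CUI are dropped, and the
remainder is filtered against the 12-type UMLS semantic whitelist used to
separate phenotype concepts from irrelevant categories (lab tests, body
systems, chemicals, ...).

Externally produced NER output (e.g. from a clinical NLP engine) can bypass ``match_terms``
entirely: any mention TSV in the documented schema (0-based, half-open
character spans) is accepted by the downstream stages.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import ClinicalNote, LexiconEntry, Mention

#: The 12 whitelisted UMLS semantic types (TUI -> (abbreviation, full name)).
SEMANTIC_WHITELIST: dict[str, tuple[str, str]] = {
    "T052": ("acty", "Activity"),
    "T056": ("dora", "Daily or recreational activity"),
    "T047": ("dsyn", "Disease or syndrome"),
    "T033": ("fndg", "Finding"),
    "T058": ("hlca", "Healthcare activity"),
    "T055": ("inbe", "Individual behavior"),
    "T041": ("menp", "Mental process"),
    "T048": ("mobd", "Mental or behavioral dysfunction"),
    "T101": ("podg", "Patient or disabled group"),
    "T080": ("qlco", "Qualitative concept"),
    "T054": ("socb", "Social behavior"),
    "T184": ("sosy", "Sign or symptom"),
}


def normalize(text: str) -> str:
    """Matching normalization: lowercase and collapse runs of whitespace."""
    return " ".join(text.lower().split())


def load_lexicon(path: str | Path) -> list[LexiconEntry]:
    """Read a lexicon TSV (surface_form, cui, preferred_name, pipe-joined tuis)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"surface_form", "cui", "preferred_name", "tuis"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: lexicon is missing columns {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            LexiconEntry(
                surface_form=row.surface_form,
                cui=row.cui or None,
                preferred_name=row.preferred_name,
                tuis=frozenset(t for t in row.tuis.split("|") if t),
            )
        )
    return entries


@lru_cache(maxsize=1)
def _default_lexicon_cached() -> tuple[LexiconEntry, ...]:
    with resources.as_file(resources.files("asdpheno.data") / "lexicon.tsv") as p:
        return tuple(load_lexicon(p))


def load_default_lexicon() -> list[LexiconEntry]:
    """The packaged toy lexicon (replaceable by a user-supplied UMLS subset)."""
    return list(_default_lexicon_cached())


class DictionaryMatcher:
    """Compiled longest-match-first scanner over a lexicon.

    Token boundaries are non-alphanumeric characters, so a surface form
    never matches inside a longer word. Within multi-token surface forms
    any whitespace run is accepted.
    """

    def __init__(self, lexicon: Sequence[LexiconEntry]):
        if not lexicon:
            raise ValueError("empty lexicon")
        self._by_surface: dict[str, LexiconEntry] = {}
        for e in lexicon:
            self._by_surface[normalize(e.surface_form)] = e
        # longest first so the regex alternation prefers the longest match
        surfaces = sorted(self._by_surface, key=lambda s: (-len(s), s))
        alts = "|".join(re.escape(s).replace(r"\ ", r"\s+") for s in surfaces)
        self._re = re.compile(
            rf"(?<![A-Za-z0-9])(?:{alts})(?![A-Za-z0-9])", re.IGNORECASE
        )

    def __call__(self, note: ClinicalNote) -> list[Mention]:
        out = []
        for m in self._re.finditer(note.text):
            entry = self._by_surface[normalize(m.group(0))]
            out.append(
                Mention(
                    note_id=note.note_id,
                    patient_id=note.patient_id,
                    surface_form=entry.surface_form,
                    cui=entry.cui,
                    tuis=entry.tuis,
                    start=m.start(),
                    end=m.end(),
                )
            )
        return out


def match_terms(
    notes: Iterable[ClinicalNote] | ClinicalNote | str,
    lexicon: Sequence[LexiconEntry],
) -> list[Mention]:
    """Extract lexicon mentions from notes (or a bare text string).

    Matching is case-insensitive, longest-match-first and non-overlapping on
    token boundaries; every mention carries the CUI and semantic types of
    the matched lexicon entry.
    """
    matcher = DictionaryMatcher(lexicon)
    if isinstance(notes, str):
        import datetime

        notes = [ClinicalNote("_adhoc", "_adhoc", datetime.date(2000, 1, 1), "", notes)]
    elif isinstance(notes, ClinicalNote):
        notes = [notes]
    mentions: list[Mention] = []
    for note in notes:
        mentions.extend(matcher(note))
    return mentions


def drop_unmapped(mentions: Iterable[Mention]) -> list[Mention]:
    """Remove mentions whose surface form was not mapped to a UMLS CUI."""
    return [m for m in mentions if m.cui is not None]


def semantic_filter(
    mentions: Iterable[Mention],
    whitelist: Iterable[str] | None = None,
) -> list[Mention]:
    """Keep mentions whose semantic types intersect the whitelist."""
    allowed = frozenset(whitelist) if whitelist is not None else frozenset(SEMANTIC_WHITELIST)
    return [m for m in mentions if m.tuis & allowed]
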