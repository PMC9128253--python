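"""DSM-5 criterion mapping, patient criterion profiles and the diagnostic rule.

Each validated term is assigned to the DSM-5 criterion whose descriptor
phrases it is most similar to in embedding space (argmax over criteria of
the best-phrase cosine similarity; deterministic tie-break in canonical
criterion order A1 < A2 < A3 < B1 < B2 < B3 < B4 < E). A patient manifests
a criterion when at least one of their mentions maps to a terminology-level
ontology node descending from that criterion's node.

The diagnostic rule mirrors DSM-5: all of A1-A3 plus at least two of
B1-B4. Criterion E (diagnosis names and comorbidities) participates in
term mapping and the ontology but not in the rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .embedding import EmbeddingProvider, TrigramHashEmbedding, cosine
from .records import Mention

CRITERIA = ("A1", "A2", "A3", "B1", "B2", "B3", "B4", "E")
A_CRITERIA = ("A1", "A2", "A3")
B_CRITERIA = ("B1", "B2", "B3", "B4")
PROFILE_CRITERIA = A_CRITERIA + B_CRITERIA

DISPLAY_NAMES = {
    "A1": "social interaction",
    "A2": "social communication",
    "A3": "social relationship",
    "B1": "repetitive behaviors",
    "B2": "ritualized behaviors",
    "B3": "fascination and preoccupation",
    "B4": "unusual sensory and comorbidities",
    "E": "ASD and comorbidities",
}


@dataclass(frozen=True)
class CriterionLexicon:
    """Descriptor phrases for one DSM-5 criterion."""

    criterion: str
    display_name: str
    phrases: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if not self.phrases:
            raise ValueError(f"criterion {self.criterion} has no phrases")


def load_criterion_lexicons(path: str | Path | None = None) -> list[CriterionLexicon]:
    """Load criterion phrase lists; defaults to the packaged, replaceable fixture."""
    if path is None:
        with resources.as_file(resources.files("asdpheno.data") / "dsm5_criteria.tsv") as p:
            return load_criterion_lexicons(p)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for crit in CRITERIA:
        sub = df[df["criterion"] == crit]
        if sub.empty:
            if crit == "E":
                continue  # E is optional in user-supplied files
            raise ValueError(f"criterion {crit} missing from {path}")
        out.append(
            CriterionLexicon(crit, sub["display_name"].iloc[0], tuple(sub["phrase"]))
        )
    return out


def map_term_to_criterion(
    term: str,
    lexicons: Sequence[CriterionLexicon],
    provider: EmbeddingProvider | None = None,
    min_score: float | None = None,
) -> tuple[str | None, float]:
    """(criterion, score) with the highest best-phrase cosine similarity.

    With ``min_score`` set, a term scoring at or below it maps to no
    criterion (``(None, score)``); by default every term gets its argmax.
    """
    if not term or not term.strip():
        raise ValueError("cannot map an empty term")
    if provider is None:
        provider = TrigramHashEmbedding()
    vec = provider.embed(term)
    best_crit, best_score = None, -np.inf
    for lex in lexicons:  # canonical order; strict > keeps the earlier tie
        score = max(cosine(vec, provider.embed(ph)) for ph in lex.phrases)
        if score > best_score:
            best_crit, best_score = lex.criterion, score
    if min_score is not None and best_score <= min_score:
        return None, float(best_score)
    return best_crit, float(best_score)


def map_terms(
    surface_by_key: Mapping[str, str],
    lexicons: Sequence[CriterionLexicon],
    provider: EmbeddingProvider | None = None,
    min_score: float | None = None,
) -> pd.DataFrame:
    """Criterion assignment for a set of terms (key -> surface form)."""
    if provider is None:
        provider = TrigramHashEmbedding()
    rows = []
    for key in sorted(surface_by_key):
        crit, score = map_term_to_criterion(
            surface_by_key[key], lexicons, provider, min_score
        )
        rows.append({"term_key": key, "surface_form": surface_by_key[key],
                     "criterion": crit or "", "score": score})
    return pd.DataFrame(rows, columns=["term_key", "surface_form", "criterion", "score"])


@dataclass(frozen=True)
class CriterionProfile:
    """Per-patient indicators over the seven diagnostic criteria."""

    patient_id: str
    presence: frozenset[str]  # subset of PROFILE_CRITERIA

    def __post_init__(self) -> None:
        if not self.presence <= set(PROFILE_CRITERIA):
            raise ValueError(f"non-diagnostic criteria in profile: {self.presence}")


def patient_profile(
    patient_id: str,
    mentions: Iterable[Mention],
    ontology,
) -> CriterionProfile:
    """Criterion indicators from the patient's mentions via the ontology.

    A criterion is present when >= 1 mention maps (by CUI) to a
    terminology-level node that transitively descends from the criterion's
    level-3 node. Mentions whose CUI is absent from the ontology are
    ignored.
    """
    present: set[str] = set()
    for m in mentions:
        if m.patient_id != patient_id or m.cui is None:
            continue
        for crit in ontology.criteria_for_cui(m.cui):
            if crit in PROFILE_CRITERIA:
                present.add(crit)
    return CriterionProfile(patient_id, frozenset(present))


def dsm5_rule(profile: CriterionProfile) -> bool:
    """True iff A1, A2 and A3 are all present and >= 2 of B1-B4 are."""
    a_ok = all(c in profile.presence for c in A_CRITERIA)
    b_count = sum(c in profile.presence for c in B_CRITERIA)
    return a_ok and b_count >= 2


def cluster_radar(
    profiles: Sequence[CriterionProfile],
    clusters: Mapping[str, int],
) -> pd.DataFrame:
    """Percentage of patients per cluster manifesting each criterion.

    Rows indexed by cluster; cells are 100 * (# with criterion) / (cluster
    size). Every profiled patient must carry a cluster label. Empty
    clusters (labels present in ``clusters`` but without profiles) get NaN
    rows.
    """
    missing = [p.patient_id for p in profiles if p.patient_id not in clusters]
    if missing:
        raise ValueError(f"profiled patients without a cluster: {missing[:10]}")
    all_clusters = sorted(set(clusters.values()))
    counts = {k: np.zeros(len(PROFILE_CRITERIA)) for k in all_clusters}
    sizes = {k: 0 for k in all_clusters}
    for p in profiles:
        k = clusters[p.patient_id]
        sizes[k] += 1
        for j, crit in enumerate(PROFILE_CRITERIA):
            if crit in p.presence:
                counts[k][j] += 1
    rows = {}
    for k in all_clusters:
        rows[k] = (100.0 * counts[k] / sizes[k]) if sizes[k] else np.full(
            len(PROFILE_CRITERIA), np.nan
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(PROFILE_CRITERIA))
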