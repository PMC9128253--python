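"""Gold-standard seed list management and embedding-based term validation.

Candidate terms surviving the odds-ratio filter are accepted as ASD
phenotype terms when their embedding cosine similarity to at least one
gold-standard seed term strictly exceeds a threshold (default 0.5).
Accepted novel terms get IDs prefixed ``ASD``; seed terms keep their
``S``-prefixed IDs. A clinician-verified alias list (e.g. output of an
external NER discovery step) can be merged into the gold list.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .embedding import EmbeddingProvider, TrigramHashEmbedding, cosine
from .extraction import normalize

GOLD_CATEGORIES = ("diagnosis", "dsm_feature", "associated_behavior", "non_asd_psych")


@dataclass(frozen=True)
class GoldTerm:
    """A clinician-curated seed term (``S``-prefixed ID)."""

    term_id: str
    surface_form: str
    category: str

    def __post_init__(self) -> None:
        if not self.term_id.startswith("S"):
            raise ValueError(f"gold term id must start with 'S': {self.term_id}")
        if self.category not in GOLD_CATEGORIES:
            raise ValueError(f"unknown gold category {self.category!r}")


@dataclass(frozen=True)
class ValidatedTerm:
    """A candidate accepted into the ASD terminology set."""

    term_id: str  # "ASD%04d"
    surface_form: str
    cui: str | None
    max_similarity: float
    nearest_gold: str

    def __post_init__(self) -> None:
        if not self.term_id.startswith("ASD"):
            raise ValueError(f"validated term id must start with 'ASD': {self.term_id}")
        if not -1.0 <= self.max_similarity <= 1.0 + 1e-12:
            raise ValueError("similarity outside [-1, 1]")


def load_gold_terms(path: str | Path | None = None) -> list[GoldTerm]:
    """Load a gold list TSV; defaults to the packaged seed fixture."""
    if path is None:
        with resources.as_file(resources.files("asdpheno.data") / "gold_terms.tsv") as p:
            return load_gold_terms(p)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [GoldTerm(r.term_id, r.surface_form, r.category) for r in df.itertuples(index=False)]


def import_alias_list(
    path: str | Path,
    gold: Sequence[GoldTerm],
    category: str = "dsm_feature",
) -> list[GoldTerm]:
    """Append novel aliases (TSV of surface forms) to the gold list.

    Duplicates of existing gold terms (case/whitespace-insensitive) are
    skipped, so re-importing the same file is idempotent. New entries get
    fresh ``S``-prefixed IDs continuing the existing numbering.
    """
    existing = {normalize(g.surface_form) for g in gold}
    max_id = max((int(g.term_id[1:]) for g in gold), default=0)
    out = list(gold)
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or (i == 1 and line.lower() in ("surface_form", "term")):
                continue
            surface = line.split("\t")[0].strip()
            if not surface:
                raise ValueError(f"{path}: empty surface form on line {i}")
            if "\t" in line and len(line.split("\t")) > 2:
                raise ValueError(f"{path}: too many columns on line {i}")
            key = normalize(surface)
            if key in existing:
                continue
            existing.add(key)
            max_id += 1
            out.append(GoldTerm(f"S{max_id:04d}", surface, category))
    return out


def validate_terms(
    candidates: pd.DataFrame,
    gold: Sequence[GoldTerm],
    provider: EmbeddingProvider | None = None,
    threshold: float = 0.5,
) -> list[ValidatedTerm]:
    """Accept candidates whose best gold-similarity strictly exceeds ``threshold``.

    ``candidates`` is a term-stats frame (``cui``, ``surface_form`` columns,
    e.g. the output of ``or_filter``). For each candidate the maximum cosine
    similarity over the gold list is recorded along with the nearest gold
    term (ties broken by smallest gold ID). Accepted terms are assigned
    ``ASD%04d`` IDs in sorted (cui, surface form) order.
    """
    if not len(gold):
        raise ValueError("empty gold list")
    if provider is None:
        provider = TrigramHashEmbedding()
    gold_sorted = sorted(gold, key=lambda g: g.term_id)
    gold_vecs = np.stack([provider.embed(g.surface_form) for g in gold_sorted])
    rows = candidates[["cui", "surface_form"]].drop_duplicates()
    accepted: list[ValidatedTerm] = []
    scored = []
    for row in rows.itertuples(index=False):
        vec = provider.embed(row.surface_form)
        sims = [cosine(vec, gv) for gv in gold_vecs]
        best = int(np.argmax(sims))  # argmax returns the first (smallest-id) tie
        scored.append((row.cui, row.surface_form, sims[best], gold_sorted[best].term_id))
    scored.sort(key=lambda t: (t[0] or "", t[1]))
    counter = 0
    for cui, surface, sim, nearest in scored:
        if sim > threshold:
            counter += 1
            accepted.append(ValidatedTerm(f"ASD{counter:04d}", surface, cui, sim, nearest))
    return accepted


def validated_to_frame(terms: Sequence[ValidatedTerm]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": t.term_id,
                "surface_form": t.surface_form,
                "cui": t.cui or "",
                "max_similarity": t.max_similarity,
                "nearest_gold": t.nearest_gold,
            }
            for t in terms
        ],
        columns=["term_id", "surface_form", "cui", "max_similarity", "nearest_gold"],
    )
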