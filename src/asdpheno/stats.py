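"""Case-control enrichment statistics for extracted phenotype terms.

For each concept (CUI) the per-cohort patient frequency is the fraction of
cohort patients whose notes contain at least one mention of the concept.
Two odds ratios are computed for every term: ASD vs the non-psychiatric
cohort and ASD vs the psychiatric (non-ASD) cohort,

    OR = [f1 * (1 - f2)] / [f2 * (1 - f1)],

identical to the cross-product ratio of the patient-level 2x2 table.
Candidate terms are those exceeding a cutoff (default 1.5), against the
non-psychiatric cohort alone or against both control cohorts.

Boundary cells (a term absent from a control cohort, or present in every
case) are handled with the Haldane-Anscombe continuity correction (+0.5 to
each 2x2 cell), flagged per term.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal

import pandas as pd

from .records import COHORTS, Mention, Patient

Mode = Literal["nonpsych_only", "both"]


def patient_frequency(
    mentions: Iterable[Mention],
    patients: list[Patient],
    cohort: str,
) -> dict[str, float]:
    """Per-term fraction of ``cohort`` patients with >= 1 mention of the term.

    A term is counted once per patient regardless of mention multiplicity.
    """
    ids = {p.patient_id for p in patients if p.cohort == cohort}
    if not ids:
        raise ValueError(f"empty cohort {cohort!r}")
    seen: dict[str, set[str]] = {}
    for m in mentions:
        if m.cui is not None and m.patient_id in ids:
            seen.setdefault(m.cui, set()).add(m.patient_id)
    return {cui: len(pts) / len(ids) for cui, pts in seen.items()}


def odds_ratio(
    f1: float,
    f2: float,
    counts: tuple[int, int, int, int] | None = None,
    correction: bool = True,
) -> tuple[float, bool]:
    """Odds ratio between two patient-level frequencies.

    Returns ``(or_value, corrected)``. At a boundary (``f2 == 0`` or
    ``f1 == 1`` and their mirrors) the uncorrected value is ``inf``/``0``;
    with ``correction`` and the underlying 2x2 ``counts``
    ``(n1_with, n1_total, n2_with, n2_total)``, the Haldane-Anscombe
    adjusted finite value is returned and flagged.
    """
    if not (0.0 <= f1 <= 1.0 and 0.0 <= f2 <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    boundary = f1 in (0.0, 1.0) or f2 in (0.0, 1.0)
    if boundary and correction:
        if counts is None:
            raise ValueError("continuity correction requires the 2x2 counts")
        a, n1, c, n2 = counts
        b, d = n1 - a, n2 - c
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)), True
    num = f1 * (1.0 - f2)
    den = f2 * (1.0 - f1)
    if den == 0.0:
        return (math.inf if num > 0 else math.nan), False
    return num / den, False


def compute_term_stats(
    mentions: Iterable[Mention],
    patients: list[Patient],
    correction: bool = True,
) -> pd.DataFrame:
    """Per-term cohort counts, frequencies and both odds ratios.

    One row per CUI with columns ``n_asd/n_psych/n_nonpsych`` (patients with
    the term), ``freq_*``, ``or_vs_nonpsych``, ``or_vs_psych`` and the
    continuity-correction flags. Terms never mentioned in any cohort do not
    appear.
    """
    sizes = {c: sum(1 for p in patients if p.cohort == c) for c in COHORTS}
    for c, n in sizes.items():
        if n == 0:
            raise ValueError(f"cohort {c} is empty")
    mentions = list(mentions)
    surfaces: dict[str, str] = {}
    tuis: dict[str, set[str]] = {}
    for m in mentions:
        if m.cui is not None:
            surfaces.setdefault(m.cui, m.surface_form)
            tuis.setdefault(m.cui, set()).update(m.tuis)
    freqs = {c: patient_frequency(mentions, patients, c) for c in COHORTS}
    rows = []
    for cui in sorted(surfaces):
        f = {c: freqs[c].get(cui, 0.0) for c in COHORTS}
        n = {c: round(f[c] * sizes[c]) for c in COHORTS}
        or_np, corr_np = odds_ratio(
            f["ASD"], f["NONPSYCH"],
            counts=(n["ASD"], sizes["ASD"], n["NONPSYCH"], sizes["NONPSYCH"]),
            correction=correction,
        )
        or_p, corr_p = odds_ratio(
            f["ASD"], f["PSYCH"],
            counts=(n["ASD"], sizes["ASD"], n["PSYCH"], sizes["PSYCH"]),
            correction=correction,
        )
        rows.append(
            {
                "cui": cui,
                "surface_form": surfaces[cui],
                "tuis": "|".join(sorted(tuis.get(cui, ()))),
                "n_asd": n["ASD"],
                "n_psych": n["PSYCH"],
                "n_nonpsych": n["NONPSYCH"],
                "freq_asd": f["ASD"],
                "freq_psych": f["PSYCH"],
                "freq_nonpsych": f["NONPSYCH"],
                "or_vs_nonpsych": or_np,
                "or_vs_psych": or_p,
                "continuity_corrected": corr_np or corr_p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cui", "surface_form", "tuis", "n_asd", "n_psych", "n_nonpsych",
            "freq_asd", "freq_psych", "freq_nonpsych",
            "or_vs_nonpsych", "or_vs_psych", "continuity_corrected",
        ],
    )


def or_filter(
    stats: pd.DataFrame,
    cutoff: float = 1.5,
    mode: Mode = "both",
) -> pd.DataFrame:
    """Candidate terms whose odds ratios strictly exceed ``cutoff``.

    ``nonpsych_only`` applies the cutoff to the ASD-vs-non-psychiatric odds
    ratio alone; ``both`` (default) additionally requires the ASD-vs-
    psychiatric ratio to exceed it. Output sorted by descending
    ``or_vs_nonpsych``, ties broken by CUI.
    """
    if mode not in ("nonpsych_only", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    keep = stats["or_vs_nonpsych"] > cutoff
    if mode == "both":
        keep &= stats["or_vs_psych"] > cutoff
    out = stats[keep].sort_values(
        ["or_vs_nonpsych", "cui"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)
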