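"""Synthetic EHR corpus generator.

Emulates the statistical structure the downstream pipeline assumes: three
cohorts (ASD cases, psychiatric non-ASD controls, non-psychiatric controls),
an ~4:1 male:female ratio in ASD with diagnosis ages between 18 months and
18 years, per-patient visit counts with a tail below the 10-visit QC
threshold, note texts built from filler vocabulary with lexicon surface
forms planted at per-cohort rates, latent ASD subgroups that differ in
their DSM-5 criterion-B term profiles, and injected QC-failing notes
(short, exact-duplicate, date-mismatched).

Alongside patients and notes the generator emits a ground-truth ledger
(planted rates, per-note QC flags and planted mentions, per-patient
subgroup and sampling counts) used as the oracle by downstream recovery
tests.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .extraction import load_default_lexicon
from .records import COHORTS, ClinicalNote, Patient

# Filler vocabulary: deliberately disjoint from every token appearing in a
# lexicon surface form, so planted mentions are the only mentions and the
# generator ledger is an exact extraction oracle.
FILLER_VOCAB: tuple[str, ...] = (
    "the", "patient", "was", "seen", "in", "clinic", "today", "for", "a",
    "scheduled", "session", "caregiver", "reports", "that", "child", "has",
    "been", "doing", "generally", "stable", "at", "home", "school", "teacher",
    "describes", "some", "progress", "toward", "current", "goals", "continues",
    "weekly", "therapy", "services", "sibling", "denies", "concerns", "since",
    "last", "encounter", "appetite", "adequate", "growth", "parameters",
    "reviewed", "vital", "signs", "normal", "limits", "physical", "examination",
    "unremarkable", "alert", "cooperative", "during", "this", "plan",
    "discussed", "return", "three", "months", "prescription", "renewed",
    "dosage", "unchanged", "counseling", "provided", "regarding", "safety",
    "handout", "given", "answered", "monitor", "closely", "recheck", "next",
    "quarter", "summer", "program", "enrolled", "supports", "resource", "room",
    "aide", "assists", "daily", "schedule", "posted", "chart", "used",
    "consistently", "gradual", "steady", "overall", "status", "acute",
    "issues", "documented", "updated", "tolerating", "regimen", "guardian",
    "accompanied", "appointment", "routine", "care", "coordination",
    "completed", "forms", "signed", "records", "requested", "pending",
)

_REF_DATE = _dt.date(2017, 1, 1)
_NOTE_DATE_SPREAD = 300  # days around diagnosis for in-window notes
_MISMATCH_MIN, _MISMATCH_MAX = 400, 700  # days outside the window


@dataclass(frozen=True)
class QCNoise:
    """Fractions of injected QC-failing notes, relative to clean visits."""

    short_frac: float = 0.05
    duplicate_frac: float = 0.05
    date_mismatch_frac: float = 0.05

    def __post_init__(self) -> None:
        for f in (self.short_frac, self.duplicate_frac, self.date_mismatch_frac):
            if not 0.0 <= f <= 1.0:
                raise ValueError("noise fractions must lie in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Sizes, demographics and note-generation parameters for a corpus.

    Visit counts follow a negative binomial with mean ``visits_mean`` and
    shape ``visits_size`` (mean 15 by default, so the <10-visit QC rule
    removes a predictable tail). Clean notes have
    ``words_min + Poisson(words_extra_mean)`` filler tokens, keeping every
    clean note above the 100-word QC threshold.
    """

    n_asd: int = 2000
    n_psych: int = 2000
    n_nonpsych: int = 2000
    asd_male_fraction: float = 0.8
    diagnosis_age_range: tuple[int, int] = (18, 216)  # months
    visits_mean: float = 15.0
    visits_size: float = 5.0
    words_min: int = 110
    words_extra_mean: float = 60.0
    n_subgroups: int = 4
    qc_noise: QCNoise = field(default_factory=QCNoise)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_asd, self.n_psych, self.n_nonpsych) < 0:
            raise ValueError("cohort sizes must be non-negative")
        if not 0.0 <= self.asd_male_fraction <= 1.0:
            raise ValueError("asd_male_fraction must lie in [0, 1]")
        lo, hi = self.diagnosis_age_range
        if not lo < hi:
            raise ValueError("diagnosis_age_range must be (low, high) with low < high")
        if self.n_subgroups < 1:
            raise ValueError("need at least one subgroup")
        if self.visits_mean <= 0 or self.visits_size <= 0:
            raise ValueError("visit distribution parameters must be positive")


@dataclass(frozen=True)
class TermProfile:
    """Planting profile for one lexicon surface form.

    ``base_rate_per_note`` gives the per-note inclusion probability in the
    (ASD, PSYCH, NONPSYCH) cohorts; ``subgroup_multipliers`` scale the ASD
    rate per latent subgroup. ``dsm5_truth`` is the planted criterion label
    used by recovery oracles.
    """

    term_id: str
    base_rate_per_note: tuple[float, float, float]
    subgroup_multipliers: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    dsm5_truth: str = "none"

    @property
    def surface_form(self) -> str:
        return self.term_id

    def __post_init__(self) -> None:
        if any(not 0.0 <= r <= 1.0 for r in self.base_rate_per_note):
            raise ValueError(f"{self.term_id}: rates must lie in [0, 1]")
        if any(m < 0 for m in self.subgroup_multipliers):
            raise ValueError(f"{self.term_id}: multipliers must be >= 0")
        if self.dsm5_truth not in {"A1", "A2", "A3", "B1", "B2", "B3", "B4", "E", "none"}:
            raise ValueError(f"{self.term_id}: unknown dsm5_truth {self.dsm5_truth!r}")

    def rate_for(self, cohort: str, subgroup: int | None) -> float:
        rate = self.base_rate_per_note[COHORTS.index(cohort)]
        if cohort == "ASD" and subgroup is not None:
            k = min(subgroup, len(self.subgroup_multipliers) - 1)
            rate *= self.subgroup_multipliers[k]
        return min(rate, 1.0)


@dataclass
class GroundTruth:
    """Sidecar ledger of planted structure, the oracle for recovery tests.

    ``note_flags.flag`` is one of ``clean``, ``short``, ``duplicate``,
    ``date_mismatch``; ``planted`` is the pipe-joined list of term ids
    planted in that note. ``patient_truth.n_sampled_notes`` counts the
    notes whose text sampled term inclusions independently (clean +
    date-mismatched; duplicates are verbatim copies and short notes are
    filler-only).
    """

    term_truth: pd.DataFrame
    note_flags: pd.DataFrame
    patient_truth: pd.DataFrame

    def expected_patient_frequency(self, term_id: str, cohort: str) -> tuple[float, float]:
        """Mean and standard error of the patient-level presence frequency.

        Presence of a term for patient *i* with per-note rate ``r_i`` and
        ``k_i`` independently sampled notes is Bernoulli(1 - (1-r_i)^k_i);
        the cohort frequency estimator is the mean of independent
        Bernoullis, whose exact moments are returned.
        """
        row = self.term_truth.set_index("term_id").loc[term_id]
        pts = self.patient_truth[self.patient_truth["cohort"] == cohort]
        if pts.empty:
            raise ValueError(f"no patients in cohort {cohort}")
        base = row[f"rate_{cohort.lower()}"]
        mults = [row[c] for c in self.term_truth.columns if c.startswith("mult_")]
        p = np.empty(len(pts))
        for j, (_, pt) in enumerate(pts.iterrows()):
            r = base
            if cohort == "ASD" and pt["subgroup"] >= 0:
                r = min(base * mults[int(pt["subgroup"])], 1.0)
            p[j] = 1.0 - (1.0 - r) ** pt["n_sampled_notes"]
        mean = float(p.mean())
        se = float(np.sqrt(np.sum(p * (1.0 - p))) / len(p))
        return mean, se

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.term_truth.to_csv(outdir / "ledger_terms.tsv", sep="\t", index=False)
        self.note_flags.to_csv(outdir / "ledger_notes.tsv", sep="\t", index=False)
        self.patient_truth.to_csv(outdir / "ledger_patients.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, outdir: str | Path) -> "GroundTruth":
        outdir = Path(outdir)
        return cls(
            term_truth=pd.read_csv(outdir / "ledger_terms.tsv", sep="\t", keep_default_na=False),
            note_flags=pd.read_csv(outdir / "ledger_notes.tsv", sep="\t", keep_default_na=False),
            patient_truth=pd.read_csv(outdir / "ledger_patients.tsv", sep="\t", keep_default_na=False),
        )


def _check_profiles(profiles: list[TermProfile]) -> None:
    surfaces = {e.surface_form for e in load_default_lexicon()}
    unknown = [p.term_id for p in profiles if p.surface_form not in surfaces]
    if unknown:
        raise ValueError(f"term profiles not present in the packaged lexicon: {unknown}")


def _sample_tokens(rng: np.random.Generator, n: int, filler: np.ndarray) -> list[str]:
    return list(filler[rng.integers(0, len(filler), size=n)])


def _sample_note(
    rng: np.random.Generator,
    rates: np.ndarray,
    term_ids: list[str],
    n_filler: int,
    filler: np.ndarray,
) -> tuple[str, list[str]]:
    tokens = _sample_tokens(rng, n_filler, filler)
    include = rng.random(len(rates)) < rates
    planted: list[str] = []
    if include.any():
        idx = np.flatnonzero(include)
        positions = rng.integers(0, len(tokens) + 1, size=len(idx))
        # insert from the rightmost position so earlier offsets stay valid
        for pos, i in sorted(zip(positions.tolist(), idx.tolist()), reverse=True):
            tokens.insert(pos, term_ids[i])
        planted = [term_ids[i] for i in sorted(idx.tolist())]
    return " ".join(tokens), planted


def sample_note_text(
    patient: Patient,
    profiles: list[TermProfile],
    rng: np.random.Generator,
    n_words: int = 150,
) -> str:
    """Draw one note text for ``patient``: filler interleaved with planted terms.

    Each profiled term is included with probability
    ``base_rate × subgroup_multiplier`` for the patient's cohort/subgroup.
    """
    _check_profiles(profiles)
    rates = np.array([p.rate_for(patient.cohort, patient.subgroup) for p in profiles])
    filler = np.array(FILLER_VOCAB)
    text, _ = _sample_note(rng, rates, [p.term_id for p in profiles], n_words, filler)
    return text


def generate_patients(config: CohortConfig) -> list[Patient]:
    """Generate the demographic layer only (no notes); deterministic in seed."""
    rng = np.random.default_rng(config.seed)
    patients: list[Patient] = []
    counter = 0
    lo_m, hi_m = config.diagnosis_age_range
    for cohort, n in zip(COHORTS, (config.n_asd, config.n_psych, config.n_nonpsych)):
        for _ in range(n):
            counter += 1
            pid = f"P{counter:06d}"
            sex = "M" if rng.random() < config.asd_male_fraction else "F"
            if cohort == "NONPSYCH":
                birth = _REF_DATE - _dt.timedelta(days=int(rng.integers(365, 365 * 18)))
                patients.append(Patient(pid, cohort, sex, birth))
            else:
                age_months = int(rng.integers(lo_m, hi_m))
                dx = _REF_DATE + _dt.timedelta(days=int(rng.integers(0, 730)))
                birth = dx - _dt.timedelta(days=int(age_months * 30.44))
                sub = int(rng.integers(config.n_subgroups)) if cohort == "ASD" else None
                patients.append(Patient(pid, cohort, sex, birth, diagnosis_date=dx, subgroup=sub))
    return patients


def generate_cohorts(
    config: CohortConfig,
    profiles: list[TermProfile] | None = None,
) -> tuple[list[Patient], list[ClinicalNote], GroundTruth]:
    """Generate patients, notes and the ground-truth ledger.

    Identical ``config`` (including seed) yields a byte-identical corpus.
    """
    if profiles is None:
        _, profiles = default_scenario()
    _check_profiles(profiles)

    patients = generate_patients(config)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    filler = np.array(FILLER_VOCAB)
    term_ids = [p.term_id for p in profiles]
    rate_cache: dict[tuple[str, int | None], np.ndarray] = {}
    nb_p = config.visits_size / (config.visits_size + config.visits_mean)

    notes: list[ClinicalNote] = []
    flag_rows: list[tuple[str, str, str, str]] = []
    patient_rows: list[tuple[str, str, int, int, int]] = []
    noise = config.qc_noise
    note_counter = 0

    def _new_id() -> str:
        nonlocal note_counter
        note_counter += 1
        return f"N{note_counter:08d}"

    def _dept(r: np.random.Generator) -> str:
        return "psychiatry" if r.random() < 0.9 else "behavioral health"

    for pt in patients:
        key = (pt.cohort, pt.subgroup)
        if key not in rate_cache:
            rate_cache[key] = np.array([p.rate_for(pt.cohort, pt.subgroup) for p in profiles])
        rates = rate_cache[key]
        anchor = pt.diagnosis_date or _REF_DATE + _dt.timedelta(days=int(rng.integers(0, 730)))
        v = int(rng.negative_binomial(config.visits_size, nb_p))
        offsets = rng.choice(2 * _NOTE_DATE_SPREAD + 1, size=v, replace=False)
        clean: list[ClinicalNote] = []
        n_sampled = 0
        for off in offsets:
            n_words = config.words_min + int(rng.poisson(config.words_extra_mean))
            text, planted = _sample_note(rng, rates, term_ids, n_words, filler)
            note = ClinicalNote(
                _new_id(), pt.patient_id,
                anchor + _dt.timedelta(days=int(off) - _NOTE_DATE_SPREAD),
                _dept(rng), text,
            )
            clean.append(note)
            n_sampled += 1
            flag_rows.append((note.note_id, pt.patient_id, "clean", "|".join(planted)))
        notes.extend(clean)

        # QC-noise injection: short filler-only notes, exact-copy duplicates,
        # and (for diagnosed patients) notes dated outside the QC window.
        n_short = int(rng.binomial(v, noise.short_frac)) if v else 0
        for _ in range(n_short):
            n_words = min(15 + int(rng.poisson(20.0)), 99)
            text = " ".join(_sample_tokens(rng, n_words, filler))
            off = int(rng.integers(-_NOTE_DATE_SPREAD, _NOTE_DATE_SPREAD + 1))
            note = ClinicalNote(_new_id(), pt.patient_id,
                                anchor + _dt.timedelta(days=off), _dept(rng), text)
            notes.append(note)
            flag_rows.append((note.note_id, pt.patient_id, "short", ""))
        n_dup = int(rng.binomial(v, noise.duplicate_frac)) if v else 0
        for _ in range(n_dup):
            src = clean[int(rng.integers(len(clean)))]
            note = ClinicalNote(_new_id(), pt.patient_id, src.date, src.department, src.text)
            notes.append(note)
            flag_rows.append((note.note_id, pt.patient_id, "duplicate", ""))
        if pt.diagnosis_date is not None:
            n_mm = int(rng.binomial(v, noise.date_mismatch_frac)) if v else 0
            for _ in range(n_mm):
                n_words = config.words_min + int(rng.poisson(config.words_extra_mean))
                text, planted = _sample_note(rng, rates, term_ids, n_words, filler)
                sign = 1 if rng.random() < 0.5 else -1
                off = sign * int(rng.integers(_MISMATCH_MIN, _MISMATCH_MAX + 1))
                note = ClinicalNote(_new_id(), pt.patient_id,
                                    anchor + _dt.timedelta(days=off), _dept(rng), text)
                notes.append(note)
                n_sampled += 1
                flag_rows.append((note.note_id, pt.patient_id, "date_mismatch", "|".join(planted)))
        patient_rows.append(
            (pt.patient_id, pt.cohort, -1 if pt.subgroup is None else pt.subgroup, v, n_sampled)
        )

    n_mult = max(len(p.subgroup_multipliers) for p in profiles)
    lex = {e.surface_form: e for e in load_default_lexicon()}
    term_truth = pd.DataFrame(
        [
            {
                "term_id": p.term_id,
                "cui": lex[p.surface_form].cui or "",
                "dsm5_truth": p.dsm5_truth,
                "rate_asd": p.base_rate_per_note[0],
                "rate_psych": p.base_rate_per_note[1],
                "rate_nonpsych": p.base_rate_per_note[2],
                **{
                    f"mult_{k}": (p.subgroup_multipliers[k]
                                  if k < len(p.subgroup_multipliers) else 1.0)
                    for k in range(n_mult)
                },
            }
            for p in profiles
        ]
    )
    truth = GroundTruth(
        term_truth=term_truth,
        note_flags=pd.DataFrame(flag_rows, columns=["note_id", "patient_id", "flag", "planted"]),
        patient_truth=pd.DataFrame(
            patient_rows,
            columns=["patient_id", "cohort", "subgroup", "n_clean_notes", "n_sampled_notes"],
        ),
    )
    return patients, notes, truth


def _p(term_id, asd, psych, nonpsych, truth, mults=(1.0, 1.0, 1.0, 1.0)):
    return TermProfile(term_id, (asd, psych, nonpsych), tuple(mults), truth)


def default_scenario() -> tuple[CohortConfig, list[TermProfile]]:
    """The packaged study scenario.

    Core social-interaction/communication (A) and ritualized-behavior (B2)
    terms are strongly ASD-enriched in every subgroup; three of the four
    latent ASD subgroups carry an elevated signature in one criterion-B
    block each (B1 repetitive behaviors, B3 fascination/preoccupation, B4
    unusual sensory), while the fourth is a low-signature baseline that
    mixes with psychiatric controls. Confounder terms (e.g. "aggressive
    behavior") are enriched in the psychiatric cohort only, and a set of
    ubiquitous clinical terms provides negative controls whose planted odds
    ratios sit below the 1.5 cutoff.
    """
    s0 = (8.0, 0.25, 0.25, 0.25)   # B1-signature subgroup
    s1 = (0.25, 8.0, 0.25, 0.25)   # B3-signature subgroup
    s2 = (0.25, 0.25, 8.0, 0.25)   # B4-signature subgroup
    profiles = [
        # A1 — social interaction
        _p("poor eye contact", 0.15, 0.010, 0.002, "A1"),
        _p("avoids eye contact", 0.05, 0.005, 0.001, "A1"),
        _p("limited social interaction", 0.12, 0.010, 0.002, "A1"),
        _p("social withdrawal", 0.10, 0.020, 0.003, "A1"),
        _p("difficulty with joint attention", 0.08, 0.004, 0.001, "A1"),
        # A2 — social communication
        _p("speech delay", 0.15, 0.010, 0.002, "A2"),
        _p("language delay", 0.10, 0.010, 0.002, "A2"),
        _p("nonverbal communication", 0.18, 0.004, 0.0005, "A2"),
        _p("does not respond to name", 0.08, 0.003, 0.001, "A2"),
        _p("communication impairment", 0.09, 0.008, 0.002, "A2"),
        # A3 — social relationship
        _p("difficulty making friends", 0.10, 0.020, 0.004, "A3"),
        _p("poor peer relationships", 0.08, 0.015, 0.003, "A3"),
        _p("lack of social reciprocity", 0.07, 0.004, 0.001, "A3"),
        _p("prefers to play alone", 0.08, 0.010, 0.002, "A3"),
        # B2 — ritualized behaviors (high in all ASD subgroups, Fig.-style)
        _p("insistence on sameness", 0.12, 0.005, 0.001, "B2"),
        _p("rigid routines", 0.10, 0.008, 0.002, "B2"),
        _p("ritualized behavior", 0.08, 0.004, 0.001, "B2"),
        _p("difficulty switching between activities", 0.07, 0.006, 0.002, "B2"),
        # B1 — repetitive behaviors (signature of subgroup 0)
        _p("hand flapping", 0.03, 0.001, 0.0005, "B1", s0),
        _p("rocking back and forth", 0.03, 0.001, 0.0005, "B1", s0),
        _p("repetitive movements", 0.035, 0.002, 0.001, "B1", s0),
        _p("stereotyped phrases", 0.03, 0.001, 0.0003, "B1", s0),
        _p("repetitive language", 0.03, 0.001, 0.0005, "B1", s0),
        # B3 — fascination and preoccupation (signature of subgroup 1)
        _p("restricted interests", 0.03, 0.002, 0.0005, "B3", s1),
        _p("intense preoccupation", 0.03, 0.001, 0.0005, "B3", s1),
        _p("fascination with spinning objects", 0.025, 0.001, 0.0003, "B3", s1),
        _p("preoccupation with parts of objects", 0.025, 0.001, 0.0003, "B3", s1),
        _p("unusual attachment to objects", 0.025, 0.001, 0.0005, "B3", s1),
        # B4 — unusual sensory and comorbidities (signature of subgroup 2)
        _p("sensory sensitivity", 0.03, 0.002, 0.0005, "B4", s2),
        _p("covers ears to loud sounds", 0.025, 0.001, 0.0003, "B4", s2),
        _p("unusual sensory interests", 0.025, 0.001, 0.0003, "B4", s2),
        _p("food selectivity", 0.025, 0.002, 0.0005, "B4", s2),
        _p("aversion to textures", 0.025, 0.001, 0.0003, "B4", s2),
        # E — diagnosis names and comorbidities
        _p("autism", 0.20, 0.010, 0.001, "E"),
        _p("autistic behavior", 0.12, 0.008, 0.001, "E"),
        _p("pervasive developmental disorder", 0.06, 0.004, 0.001, "E"),
        _p("asperger syndrome", 0.05, 0.003, 0.001, "E"),
        _p("intellectual disability", 0.06, 0.020, 0.002, "E"),
        _p("sleep disturbance", 0.08, 0.050, 0.010, "E"),
        _p("seizure disorder", 0.03, 0.010, 0.003, "E"),
        # Confounders: enriched in the psychiatric cohort only
        _p("aggressive behavior", 0.04, 0.18, 0.010, "none"),
        _p("anxiety", 0.05, 0.20, 0.020, "none"),
        _p("depressed mood", 0.03, 0.18, 0.020, "none"),
        _p("suicidal ideation", 0.005, 0.10, 0.002, "none"),
        _p("hyperactivity", 0.06, 0.15, 0.010, "none"),
        _p("anger outbursts", 0.03, 0.12, 0.010, "none"),
        _p("temper tantrum", 0.06, 0.08, 0.010, "none"),
        # Shared in both clinical cohorts: passes the non-psychiatric cutoff
        # but not the psychiatric one (distinguishes the two filter modes).
        _p("attention difficulties", 0.10, 0.10, 0.010, "none"),
        # Ubiquitous terms: planted odds ratios ~1 (< 1.5 negative controls)
        _p("well nourished", 0.10, 0.10, 0.10, "none"),
        _p("follow up visit", 0.12, 0.12, 0.12, "none"),
        # Off-whitelist semantic types (removed by the semantic filter)
        _p("blood test", 0.05, 0.05, 0.05, "none"),
        _p("medication refill", 0.05, 0.05, 0.05, "none"),
        # Surface form the concept normalizer cannot map to a CUI
        _p("fussy eater", 0.04, 0.02, 0.02, "none"),
        # ASD-enriched but lexically far from every gold seed term: passes
        # the odds-ratio filter yet fails embedding validation.
        _p("classroom elopement", 0.06, 0.005, 0.001, "none"),
    ]
    return CohortConfig(), profiles


def zero_subgroup_effects(profiles: list[TermProfile]) -> list[TermProfile]:
    """Negative-control scenario: flatten every subgroup multiplier to 1."""
    return [
        dataclasses.replace(p, subgroup_multipliers=tuple(1.0 for _ in p.subgroup_multipliers))
        for p in profiles
    ]
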