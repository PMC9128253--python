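"""DSM-5 machinery: criterion mapping, patient profiles, radar table and
the A/B diagnostic rule (with a brute-force enumeration oracle)."""

import itertools

import numpy as np
import pandas as pd
import pytest

from asdpheno.dsm5 import (
    CRITERIA,
    PROFILE_CRITERIA,
    CriterionLexicon,
    CriterionProfile,
    cluster_radar,
    dsm5_rule,
    load_criterion_lexicons,
    map_term_to_criterion,
    map_terms,
    patient_profile,
)
from asdpheno.embedding import cosine
from asdpheno.records import Mention


def test_packaged_criterion_lexicons_cover_all_criteria():
    lex = load_criterion_lexicons()
    assert [l.criterion for l in lex] == list(CRITERIA)
    assert all(l.phrases for l in lex)


def test_exact_phrase_maps_to_its_criterion(provider):
    lex = load_criterion_lexicons()
    crit, score = map_term_to_criterion("insistence on sameness", lex, provider)
    assert crit == "B2" and score == pytest.approx(1.0)


def test_every_packaged_phrase_self_maps(provider):
    """Self-consistency: each descriptor phrase maps back to its criterion."""
    lex = load_criterion_lexicons()
    for l in lex:
        for phrase in l.phrases:
            crit, score = map_term_to_criterion(phrase, lex, provider)
            assert crit == l.criterion, (phrase, crit)
            assert score == pytest.approx(1.0)


class _StubProvider:
    dimension = 2

    def __init__(self, table):
        self._table = table

    def embed(self, term):
        return np.asarray(self._table[term], dtype=float)


def test_tie_breaks_to_earlier_criterion():
    table = {"t": (1.0, 0.0), "pa": (1.0, 0.0), "pb": (1.0, 0.0)}
    lex = [CriterionLexicon("B3", "fascination and preoccupation", ("pa",)),
           CriterionLexicon("A2", "social communication", ("pb",))]
    # canonical order is the order of the supplied lexicons after sorting
    ordered = sorted(lex, key=lambda l: CRITERIA.index(l.criterion))
    crit, score = map_term_to_criterion("t", ordered, _StubProvider(table))
    assert crit == "A2" and score == pytest.approx(1.0)


def test_empty_term_rejected(provider):
    with pytest.raises(ValueError):
        map_term_to_criterion("", load_criterion_lexicons(), provider)


def test_mapping_equals_exhaustive_phrase_scan(provider):
    lex = load_criterion_lexicons()
    terms = ["hand flapping", "speech delay", "rigid routines", "autism",
             "sensory sensitivity", "poor peer relationships", "spinning toys",
             "eats only white foods", "lines up blocks", "social play",
             "covers ears", "repeats phrases", "intense focus on trains",
             "prefers solitary games", "no response when called"]
    got = map_terms({t: t for t in terms}, lex, provider)
    for row in got.itertuples(index=False):
        vec = provider.embed(row.surface_form)
        best_crit, best = None, -np.inf
        for l in lex:
            s = max(cosine(vec, provider.embed(p)) for p in l.phrases)
            if s > best:
                best_crit, best = l.criterion, s
        assert row.criterion == best_crit
        assert row.score == pytest.approx(best)


def test_min_score_floor(provider):
    lex = load_criterion_lexicons()
    crit, _ = map_term_to_criterion("zzz qqq vvv", lex, provider, min_score=0.99)
    assert crit is None


def _profile(*crits):
    return CriterionProfile("P1", frozenset(crits))


@pytest.mark.parametrize(
    "crits,expected",
    [(("A1", "A2", "A3", "B1", "B2"), True),
     (("A1", "A2", "B1", "B2", "B3"), False),  # A3 missing
     (("A1", "A2", "A3", "B1"), False),        # only one B
     (("A1", "A2", "A3", "B1", "B2", "B3", "B4"), True),
     ((), False)],
)
def test_dsm5_rule_examples(crits, expected):
    assert dsm5_rule(_profile(*crits)) is expected


def test_dsm5_rule_brute_force_enumeration():
    """Exactly 11 of the 128 presence patterns satisfy the rule."""
    satisfying = 0
    for bits in itertools.product([0, 1], repeat=7):
        present = [c for c, b in zip(PROFILE_CRITERIA, bits) if b]
        expected = (all(c in present for c in ("A1", "A2", "A3"))
                    and sum(c.startswith("B") for c in present) >= 2)
        got = dsm5_rule(_profile(*present))
        assert got is expected
        satisfying += got
    assert satisfying == 11


def test_dsm5_rule_is_monotone():
    for bits in itertools.product([0, 1], repeat=7):
        present = frozenset(c for c, b in zip(PROFILE_CRITERIA, bits) if b)
        base = dsm5_rule(CriterionProfile("P", present))
        for extra in set(PROFILE_CRITERIA) - present:
            assert dsm5_rule(CriterionProfile("P", present | {extra})) >= base


def test_profile_rejects_unknown_criteria():
    with pytest.raises(ValueError):
        CriterionProfile("P1", frozenset({"E"}))


def _mini_ontology():
    """Two-term ontology: C1 under A1, C2 under B1."""
    from asdpheno.dsm5 import load_criterion_lexicons
    from asdpheno.ontology import build_ontology
    from asdpheno.validation import ValidatedTerm

    terms = [ValidatedTerm("ASD0001", "poor eye contact", "C1", 0.9, "S0001"),
             ValidatedTerm("ASD0002", "hand flapping", "C2", 0.9, "S0002")]
    mappings = pd.DataFrame({"term_key": ["C1", "C2"],
                             "surface_form": ["poor eye contact", "hand flapping"],
                             "criterion": ["A1", "B1"], "score": [0.9, 0.9]})
    stats = pd.DataFrame({"cui": ["C1", "C2"],
                          "surface_form": ["poor eye contact", "hand flapping"],
                          "tuis": ["T033", "T033"],
                          "or_vs_nonpsych": [3.0, 4.0], "or_vs_psych": [2.0, 3.0]})
    return build_ontology(terms, mappings, stats, load_criterion_lexicons())


def _m(pid, cui):
    import datetime

    return Mention(f"N{pid}{cui}", pid, "s", cui, frozenset({"T033"}), 0, 1)


def test_patient_profile_follows_ontology_paths():
    onto = _mini_ontology()
    p1 = patient_profile("P1", [_m("P1", "C1")], onto)
    assert p1.presence == frozenset({"A1"})
    p2 = patient_profile("P2", [_m("P2", "C1"), _m("P2", "C2")], onto)
    assert p2.presence == frozenset({"A1", "B1"})
    p3 = patient_profile("P3", [], onto)
    assert p3.presence == frozenset()
    # unlinked CUIs are ignored
    p4 = patient_profile("P4", [_m("P4", "C999")], onto)
    assert p4.presence == frozenset()


def test_cluster_radar_percentages():
    profiles = [CriterionProfile(f"P{i}", frozenset({"B1"}) if i < 3 else frozenset())
                for i in range(4)]
    clusters = {f"P{i}": 0 for i in range(4)}
    radar = cluster_radar(profiles, clusters)
    assert radar.loc[0, "B1"] == pytest.approx(75.0)
    all_present = [CriterionProfile(f"Q{i}", frozenset(PROFILE_CRITERIA))
                   for i in range(3)]
    radar2 = cluster_radar(all_present, {f"Q{i}": 1 for i in range(3)})
    assert (radar2.loc[1] == 100.0).all()


def test_radar_weighted_average_equals_pooled():
    rng = np.random.default_rng(0)
    profiles, clusters = [], {}
    for i in range(40):
        crits = frozenset(c for c in PROFILE_CRITERIA if rng.random() < 0.4)
        profiles.append(CriterionProfile(f"P{i}", crits))
        clusters[f"P{i}"] = int(rng.integers(3))
    radar = cluster_radar(profiles, clusters)
    sizes = pd.Series(clusters).value_counts().sort_index()
    pooled = cluster_radar(profiles, {p: 0 for p in clusters})
    weighted = (radar.mul(sizes, axis=0).sum() / sizes.sum())
    assert np.allclose(weighted.values, pooled.loc[0].values)
    assert ((radar.values >= 0) & (radar.values <= 100)).all()


def test_radar_requires_cluster_for_every_profile():
    with pytest.raises(ValueError):
        cluster_radar([CriterionProfile("P1", frozenset())], {})


def test_radar_flags_empty_cluster():
    profiles = [CriterionProfile("P1", frozenset({"A1"}))]
    radar = cluster_radar(profiles, {"P1": 0, "P2": 1})
    assert radar.loc[1].isna().all()
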