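"""Embedding provider contracts, cosine similarity, gold-list management
and the 0.5-similarity validation rule."""

import math

import numpy as np
import pandas as pd
import pytest

from asdpheno.embedding import PrecomputedEmbedding, TrigramHashEmbedding, cosine
from asdpheno.validation import (
    GoldTerm,
    import_alias_list,
    load_gold_terms,
    validate_terms,
)


def test_embedding_is_deterministic_and_unit_norm(provider):
    v1 = provider.embed("eye contact")
    v2 = provider.embed("eye contact")
    assert np.array_equal(v1, v2)
    assert v1.shape == (700,)
    assert abs(np.linalg.norm(v1) - 1.0) < 1e-9


def test_embedding_invariant_under_matching_normalization(provider):
    assert np.array_equal(provider.embed("eye contact"),
                          provider.embed("eye  Contact"))


def test_embedding_rejects_empty_term(provider):
    with pytest.raises(ValueError):
        provider.embed("   ")


def test_cosine_basics():
    x = np.array([1.0, 1.0, 0.0])
    assert cosine(x, x) == pytest.approx(1.0)
    assert cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(0.0)
    assert cosine(x, np.array([1.0, 0.0, 0.0])) == pytest.approx(1 / math.sqrt(2))
    with pytest.raises(ValueError):
        cosine(x, np.zeros(3))
    with pytest.raises(ValueError):
        cosine(x, np.ones(4))


def test_precomputed_provider_roundtrip(tmp_path):
    p = tmp_path / "vecs.tsv"
    p.write_text("eye contact\t1.0\t0.0\nHand  Flapping\t0.0\t1.0\n")
    prov = PrecomputedEmbedding(p)
    assert prov.dimension == 2
    assert cosine(prov.embed("eye contact"), prov.embed("hand flapping")) == 0.0
    with pytest.raises(KeyError):
        prov.embed("unknown")


def test_precomputed_provider_rejects_bad_files(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("term\t1.0\nother\t1.0\t2.0\n")
    with pytest.raises(ValueError, match="line 2"):
        PrecomputedEmbedding(bad)


def test_packaged_gold_list_is_well_formed():
    gold = load_gold_terms()
    assert len(gold) >= 40
    assert all(g.term_id.startswith("S") for g in gold)
    assert len({g.term_id for g in gold}) == len(gold)
    assert {g.category for g in gold} == {
        "diagnosis", "dsm_feature", "associated_behavior", "non_asd_psych"
    }


class _StubProvider:
    """2-D provider with hand-set vectors for exact-threshold checks."""

    dimension = 2

    def __init__(self, table):
        self._table = table

    def embed(self, term):
        return np.asarray(self._table[term], dtype=float)


def _cands(*surfaces):
    return pd.DataFrame({"cui": [f"C{i}" for i, _ in enumerate(surfaces, 1)],
                         "surface_form": list(surfaces)})


def test_candidate_identical_to_gold_is_accepted(provider):
    gold = [GoldTerm("S0001", "hand flapping", "dsm_feature")]
    out = validate_terms(_cands("hand flapping"), gold, provider)
    assert len(out) == 1
    assert out[0].max_similarity == pytest.approx(1.0)
    assert out[0].nearest_gold == "S0001"
    assert out[0].term_id == "ASD0001"


def test_similarity_exactly_at_threshold_is_rejected():
    """Acceptance requires similarity strictly greater than the threshold."""
    table = {"gold": (1.0, 0.0), "cand": (1.0, 1.0)}
    gold = [GoldTerm("S0001", "gold", "dsm_feature")]
    prov = _StubProvider(table)
    sim = cosine(np.array(table["cand"]), np.array(table["gold"]))
    at = validate_terms(_cands("cand"), gold, prov, threshold=sim)
    below = validate_terms(_cands("cand"), gold, prov, threshold=sim - 1e-9)
    assert at == [] and [t.surface_form for t in below] == ["cand"]


def test_acceptance_set_equals_brute_force_scan(provider):
    gold = load_gold_terms()[:5]
    surfaces = [g.surface_form for g in gold[:3]] + [
        "zzz qqq xxw", "jkl mnop", "social withdrawal", "speech delay",
        "random words entirely", "hand flapping", "covers ears to loud sounds",
        "depressed mood", "poor eye contact variant", "totally unrelated string",
        "pddnos", "autism spectrum", "asperger", "spinning objects",
        "rigid routines daily", "sameness", "eye contact poor",
    ]
    cands = pd.DataFrame({"cui": [f"C{i:03d}" for i in range(len(surfaces))],
                          "surface_form": surfaces})
    out = validate_terms(cands, gold, provider)
    accepted = {t.surface_form for t in out}
    brute = set()
    for s in surfaces:
        best = max(cosine(provider.embed(s), provider.embed(g.surface_form))
                   for g in gold)
        if best > 0.5:
            brute.add(s)
    assert accepted == brute


def test_ids_assigned_in_sorted_order(provider):
    gold = [GoldTerm("S0001", "hand flapping", "dsm_feature"),
            GoldTerm("S0002", "speech delay", "dsm_feature")]
    cands = pd.DataFrame({"cui": ["C9", "C1"],
                          "surface_form": ["speech delay", "hand flapping"]})
    out = validate_terms(cands, gold, provider)
    assert [(t.term_id, t.cui) for t in out] == [("ASD0001", "C1"), ("ASD0002", "C9")]


def test_empty_gold_list_rejected(provider):
    with pytest.raises(ValueError):
        validate_terms(_cands("x"), [], provider)


def test_gold_terms_validate_against_themselves(provider):
    gold = load_gold_terms()[:8]
    cands = pd.DataFrame({"cui": [f"C{i}" for i in range(len(gold))],
                          "surface_form": [g.surface_form for g in gold]})
    out = validate_terms(cands, gold, provider)
    assert len(out) == len(gold)
    assert all(t.max_similarity == pytest.approx(1.0) for t in out)


def test_threshold_monotonicity(provider):
    gold = load_gold_terms()[:10]
    cands = _cands("hand flapping", "speech del", "unrelated thing", "autism")
    low = {t.surface_form for t in validate_terms(cands, gold, provider, threshold=0.3)}
    high = {t.surface_form for t in validate_terms(cands, gold, provider, threshold=0.7)}
    assert high <= low


def test_gold_enlargement_monotonicity(provider):
    cands = _cands("hand flapping", "toe walking", "unrelated thing")
    small = load_gold_terms()[:5]
    big = load_gold_terms()
    acc_small = {t.surface_form for t in validate_terms(cands, small, provider)}
    acc_big = {t.surface_form for t in validate_terms(cands, big, provider)}
    assert acc_small <= acc_big


def test_import_alias_list(tmp_path):
    gold = load_gold_terms()
    n0 = len(gold)
    f = tmp_path / "aliases.tsv"
    f.write_text("surface_form\nAutism\nnew alias one\nnew alias two\nnew alias three\n")
    merged = import_alias_list(f, gold)
    assert len(merged) == n0 + 3  # "Autism" duplicates an existing seed
    again = import_alias_list(f, merged)
    assert len(again) == len(merged)
    assert all(g.term_id.startswith("S") for g in merged)
    bad = tmp_path / "bad.tsv"
    bad.write_text("ok\n\t\n")
    with pytest.raises(ValueError, match="line 2"):
        import_alias_list(bad, gold)
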