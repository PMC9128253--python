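"""Matrix construction, tf-idf against a naive double loop, the
multiplicative-update NMF (including an sklearn cross-check), cluster
assignment and the 2-D view."""

import datetime

import numpy as np
import pytest

from asdpheno.clustering import (
    FactorizationResult,
    PatientTermMatrix,
    assign_clusters,
    build_matrix,
    embed_2d,
    factorize,
    select_top_patients,
    tfidf,
)
from asdpheno.records import Mention, Patient

D = datetime.date


def _patients(n, cohort="ASD"):
    return [
        Patient(f"P{i:02d}", cohort, "M", D(2010, 1, 1),
                diagnosis_date=D(2015, 1, 1),
                subgroup=0 if cohort == "ASD" else None)
        for i in range(n)
    ]


def _mention(pid, cui, k=0):
    return Mention(f"N{pid}{cui}{k}", pid, "s", cui, frozenset({"T048"}), 0, 1)


def test_build_matrix_matches_hand_tabulation():
    pts = _patients(3)
    mentions = [_mention("P00", "C1"), _mention("P00", "C1", 1),
                _mention("P01", "C2"), _mention("P02", "C1")]
    count = build_matrix(pts, ["C1", "C2"], mentions, mode="count")
    assert count.values.tolist() == [[2.0, 0.0], [0.0, 1.0], [1.0, 0.0]]
    binary = build_matrix(pts, ["C1", "C2"], mentions, mode="binary")
    assert binary.values.tolist() == [[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]]


def test_patient_with_no_mentions_has_zero_row():
    m = build_matrix(_patients(2), ["C1"], [_mention("P00", "C1")])
    assert m.values[1].sum() == 0.0


def test_matrix_mtx_roundtrip(tmp_path):
    m = PatientTermMatrix(["P1", "P2"], ["C1", "C2"],
                          np.array([[1.0, 0.0], [3.0, 2.0]]), "count")
    m.write(tmp_path / "mat")
    back = PatientTermMatrix.read(tmp_path / "mat")
    assert back.patient_ids == m.patient_ids
    assert back.term_keys == m.term_keys
    assert np.array_equal(back.values, m.values)


def test_select_top_patients_by_distinct_terms():
    pts = _patients(3)
    mentions = [_mention("P01", "C1"), _mention("P01", "C2"), _mention("P02", "C1")]
    m = build_matrix(pts, ["C1", "C2"], mentions)
    top = select_top_patients(m, pts, 2)
    assert top.patient_ids == ["P01", "P02"]


def _naive_tfidf(X):
    m, n = X.shape
    out = np.zeros_like(X, dtype=float)
    for j in range(n):
        df = sum(1 for i in range(m) if X[i, j] > 0)
        for i in range(m):
            out[i, j] = X[i, j] * (np.log(m / df) if df else 0.0)
    return out


def test_tfidf_matches_naive_double_loop():
    rng = np.random.default_rng(0)
    X = rng.integers(0, 4, size=(20, 30)).astype(float)
    X[:, 5] = 0.0  # df = 0 column must be dropped
    m = PatientTermMatrix([f"P{i}" for i in range(20)],
                          [f"C{j}" for j in range(30)], X, "count")
    w = tfidf(m)
    naive = _naive_tfidf(X)
    keep = [j for j in range(30) if (X[:, j] > 0).any()]
    assert w.term_keys == [f"C{j}" for j in keep]
    assert np.abs(w.values - naive[:, keep]).max() < 1e-12


def test_tfidf_ubiquitous_term_gets_zero_weight():
    X = np.array([[2.0, 1.0], [1.0, 0.0], [3.0, 1.0]])
    m = PatientTermMatrix(["P1", "P2", "P3"], ["C1", "C2"], X, "count")
    w = tfidf(m)
    assert np.all(w.values[:, 0] == 0.0)  # ln(3/3) = 0
    # tf=2, N=100, df=10 worked example
    X2 = np.zeros((100, 1))
    X2[:10, 0] = 1.0
    X2[0, 0] = 2.0
    w2 = tfidf(PatientTermMatrix([f"P{i}" for i in range(100)], ["C1"], X2, "count"))
    assert w2.values[0, 0] == pytest.approx(2 * np.log(10.0))


def test_tfidf_rejects_empty_matrix():
    with pytest.raises(ValueError):
        tfidf(PatientTermMatrix([], ["C1"], np.zeros((0, 1)), "count"))


def test_nmf_recovers_rank_one_exactly():
    rng = np.random.default_rng(1)
    X = np.outer(rng.random(30), rng.random(12))
    m = PatientTermMatrix([f"P{i}" for i in range(30)],
                          [f"C{j}" for j in range(12)], X, "count")
    res = factorize(m, a=1, seed=0, max_iter=2000, tol=1e-14)
    assert res.reconstruction_error < 1e-6 * np.linalg.norm(X)


def test_nmf_objective_is_non_increasing_each_iteration():
    rng = np.random.default_rng(2)
    X = rng.random((40, 15))
    m = PatientTermMatrix([f"P{i}" for i in range(40)],
                          [f"C{j}" for j in range(15)], X, "count")
    res = factorize(m, a=4, seed=3)
    hist = np.array(res.error_history)
    assert np.all(np.diff(hist) <= 1e-10)


def test_nmf_capacity_monotone_and_deterministic():
    rng = np.random.default_rng(4)
    X = rng.random((30, 20))
    m = PatientTermMatrix([f"P{i}" for i in range(30)],
                          [f"C{j}" for j in range(20)], X, "count")
    e2 = factorize(m, a=2, seed=7).reconstruction_error
    e8 = factorize(m, a=8, seed=7).reconstruction_error
    assert e8 <= e2
    r1 = factorize(m, a=3, seed=9)
    r2 = factorize(m, a=3, seed=9)
    assert np.array_equal(r1.W, r2.W) and np.array_equal(r1.H, r2.H)
    with pytest.raises(ValueError):
        factorize(m, a=0)
    with pytest.raises(ValueError):
        factorize(m, a=21)


def test_nmf_error_comparable_to_sklearn():
    """Independent cross-check: same objective class as sklearn's NMF."""
    from sklearn.decomposition import NMF

    rng = np.random.default_rng(5)
    X = rng.random((50, 25))
    m = PatientTermMatrix([f"P{i}" for i in range(50)],
                          [f"C{j}" for j in range(25)], X, "count")
    ours = factorize(m, a=5, seed=0, max_iter=500).reconstruction_error
    sk = NMF(n_components=5, init="random", random_state=0, max_iter=500,
             solver="mu").fit(X)
    sk_err = np.linalg.norm(X - sk.transform(X) @ sk.components_)
    assert abs(ours - sk_err) / sk_err < 0.05


def test_assign_clusters_argmax_ties_and_zero_rows():
    W = np.array([[0.1, 0.9, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 0.0]])
    res = FactorizationResult(W=W, H=np.zeros((3, 1)), a=3, reconstruction_error=0.0)
    out = assign_clusters(res, ["P1", "P2", "P3"])
    assert out.labels == {"P1": 1, "P2": 0, "P3": 0}
    assert out.zero_rows == ["P3"]
    with pytest.raises(ValueError):
        assign_clusters(res, ["P1"])


def test_embed_2d_contracts():
    rng = np.random.default_rng(6)
    W = np.vstack([rng.random((20, 3)), rng.random((1, 3))])
    W[20] = W[0]  # duplicated loading row
    res = FactorizationResult(W=W, H=np.zeros((3, 1)), a=3, reconstruction_error=0.0)
    ids = [f"P{i}" for i in range(21)]
    c1 = embed_2d(res, ids, seed=0, perplexity=5)
    c2 = embed_2d(res, ids, seed=0, perplexity=5)
    assert c1 == c2
    # identical rows land closer together than the typical pair
    pts = np.array(list(c1.values()))
    d_dup = np.hypot(*(np.array(c1["P0"]) - np.array(c1["P20"])))
    from scipy.spatial.distance import pdist

    assert d_dup < np.median(pdist(pts))
    small = FactorizationResult(W=W[:4], H=np.zeros((3, 1)), a=3,
                                reconstruction_error=0.0)
    with pytest.raises(ValueError):
        embed_2d(small, ids[:4], perplexity=2)
    with pytest.raises(ValueError):
        embed_2d(res, ids, perplexity=21)


def test_binary_mode_validation():
    with pytest.raises(ValueError):
        PatientTermMatrix(["P1"], ["C1"], np.array([[2.0]]), "binary")
    with pytest.raises(ValueError):
        PatientTermMatrix(["P1"], ["C1"], np.array([[-1.0]]), "count")


def test_cohort_separation_degrades_with_impoverished_vocabulary(small_corpus, lexicon):
    """A linear classifier on the NMF loadings separates ASD from
    psychiatric controls; restricting the vocabulary to 20 low-coverage
    terms (emulating a small legacy vocabulary) scores strictly lower."""
    import dataclasses

    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import cross_val_score

    from asdpheno.extraction import drop_unmapped, match_terms, semantic_filter
    from asdpheno.synthetic import default_scenario, generate_cohorts

    cfg, profiles = default_scenario()
    cfg = dataclasses.replace(cfg, n_asd=600, n_psych=600, n_nonpsych=0, seed=17)
    patients, notes, _ = generate_cohorts(cfg, profiles)
    mentions = semantic_filter(drop_unmapped(match_terms(notes, lexicon)))
    cuis = sorted({m.cui for m in mentions})
    cohort = {p.patient_id: p.cohort for p in patients}

    def accuracy(term_keys):
        mat = build_matrix(patients, term_keys, mentions)
        fact = factorize(tfidf(mat), a=8, seed=17)
        y = np.array([cohort[p] == "ASD" for p in mat.patient_ids])
        clf = LogisticRegression(max_iter=1000)
        return cross_val_score(clf, fact.W, y, cv=5).mean()

    full = accuracy(cuis)
    # 20 lowest-coverage terms: few patients carry any of them
    mat_all = build_matrix(patients, cuis, mentions)
    coverage = (mat_all.values > 0).sum(axis=0)
    poor = [t for _, t in sorted(zip(coverage, mat_all.term_keys))[:20]]
    impoverished = accuracy(poor)
    assert full > 0.85
    assert impoverished < full
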