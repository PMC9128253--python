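"""Patient x term matrix construction, tf-idf weighting, NMF subtyping.

Each patient's HQ notes form one document. The binary (or count) patient x
term matrix is weighted by

    w[i, j] = tf[i, j] * ln(N / df[i]),

where tf is the occurrence count (or indicator) of term *i* in patient
*j*'s notes, df the number of patients whose notes contain the term, and N
the number of patients (natural log; terms present in every patient get
weight zero, terms present in none are dropped).

The weighted matrix is factorized as X ~ W @ H with nonnegative factors by
multiplicative updates from a fixed-seed nonnegative random start; the
per-iteration Frobenius objective is recorded and is non-increasing.
Patients are assigned to the component with the largest loading (argmax of
the W row, ties to the lowest index). t-SNE supplies 2-D view coordinates
for plotting only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .records import Mention, Patient

logger = logging.getLogger(__name__)

MatrixMode = Literal["binary", "count", "tfidf"]


@dataclass
class PatientTermMatrix:
    """Dense patients x terms matrix with row/column identity."""

    patient_ids: list[str]
    term_keys: list[str]  # CUIs (or term ids), sorted
    values: np.ndarray  # shape (m, n), nonnegative
    mode: MatrixMode = "binary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_ids), len(self.term_keys)):
            raise ValueError("matrix shape inconsistent with row/column ids")
        if (self.values < 0).any():
            raise ValueError("matrix values must be nonnegative")
        if self.mode == "binary" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("binary mode requires 0/1 values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def write(self, prefix: str | Path) -> None:
        """Write MTX (sparse) plus row/column id sidecars."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        mmwrite(str(prefix) + ".mtx", csr_matrix(self.values))
        Path(str(prefix) + ".rows.txt").write_text("\n".join(self.patient_ids) + "\n")
        Path(str(prefix) + ".cols.txt").write_text("\n".join(self.term_keys) + "\n")

    @classmethod
    def read(cls, prefix: str | Path, mode: MatrixMode = "count") -> "PatientTermMatrix":
        prefix = str(prefix)
        values = np.asarray(mmread(prefix + ".mtx").todense())
        rows = Path(prefix + ".rows.txt").read_text().splitlines()
        cols = Path(prefix + ".cols.txt").read_text().splitlines()
        return cls(rows, cols, values, mode)


def build_matrix(
    patients: Sequence[Patient],
    term_keys: Iterable[str],
    mentions: Iterable[Mention],
    mode: Literal["binary", "count"] = "binary",
) -> PatientTermMatrix:
    """Tabulate term presence (or mention counts) per patient.

    Rows and columns are sorted by ID for determinism; only mentions whose
    CUI is in ``term_keys`` contribute.
    """
    term_keys = sorted(set(term_keys))
    if not term_keys:
        raise ValueError("no terms to tabulate")
    pids = sorted(p.patient_id for p in patients)
    prow = {pid: i for i, pid in enumerate(pids)}
    tcol = {t: j for j, t in enumerate(term_keys)}
    values = np.zeros((len(pids), len(term_keys)))
    for m in mentions:
        i = prow.get(m.patient_id)
        j = tcol.get(m.cui)
        if i is not None and j is not None:
            values[i, j] += 1.0
    if mode == "binary":
        values = (values > 0).astype(float)
    return PatientTermMatrix(pids, term_keys, values, mode)


def select_top_patients(
    matrix: PatientTermMatrix,
    patients: Sequence[Patient],
    n_per_cohort: int,
) -> PatientTermMatrix:
    """Per cohort, keep the ``n`` patients with the most distinct terms.

    Implements the "patients whose notes contain the most phenotypic
    concept information" selection; ties broken by patient ID.
    """
    cohort = {p.patient_id: p.cohort for p in patients}
    richness = (matrix.values > 0).sum(axis=1)
    keep: list[int] = []
    by_cohort: dict[str, list[int]] = {}
    for i, pid in enumerate(matrix.patient_ids):
        by_cohort.setdefault(cohort[pid], []).append(i)
    for _, idxs in sorted(by_cohort.items()):
        ranked = sorted(idxs, key=lambda i: (-richness[i], matrix.patient_ids[i]))
        keep.extend(ranked[:n_per_cohort])
    keep.sort()
    return PatientTermMatrix(
        [matrix.patient_ids[i] for i in keep],
        list(matrix.term_keys),
        matrix.values[keep],
        matrix.mode,
    )


def tfidf(matrix: PatientTermMatrix) -> PatientTermMatrix:
    """tf-idf weighting with natural log; df=0 columns are dropped."""
    m, _ = matrix.shape
    if m == 0:
        raise ValueError("empty matrix")
    df = (matrix.values > 0).sum(axis=0)
    keep = df > 0
    if not keep.all():
        dropped = [t for t, k in zip(matrix.term_keys, keep) if not k]
        logger.info("tfidf: dropping %d terms absent from every patient: %s",
                    len(dropped), dropped[:10])
    values = matrix.values[:, keep] * np.log(m / df[keep])
    return PatientTermMatrix(
        list(matrix.patient_ids),
        [t for t, k in zip(matrix.term_keys, keep) if k],
        values,
        "tfidf",
    )


@dataclass
class FactorizationResult:
    """NMF factors, per-iteration objective history and metadata."""

    W: np.ndarray  # (m, a) patient loadings
    H: np.ndarray  # (a, n) term loadings
    a: int
    reconstruction_error: float  # final Frobenius norm ||X - WH||_F
    error_history: list[float] = field(default_factory=list)
    seed: int = 0


def factorize(
    matrix: PatientTermMatrix,
    a: int = 8,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> FactorizationResult:
    """Nonnegative matrix factorization X ~ W @ H by multiplicative updates.

    Initialization is a fixed-seed nonnegative random start scaled to the
    data magnitude; the Frobenius objective is recorded each iteration and
    iteration stops when its relative improvement falls below ``tol``.
    """
    X = matrix.values
    m, n = X.shape
    if not 1 <= a <= min(m, n):
        raise ValueError(f"reduced dimension a={a} outside [1, {min(m, n)}]")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / a) if X.mean() > 0 else 1.0
    W = rng.random((m, a)) * scale + 1e-6
    H = rng.random((a, n)) * scale + 1e-6
    eps = 1e-12
    history: list[float] = []
    prev = None
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + eps)
        W *= (X @ H.T) / (W @ (H @ H.T) + eps)
        err = float(np.linalg.norm(X - W @ H))
        history.append(err)
        if prev is not None and prev - err < tol * max(prev, 1e-30):
            break
        prev = err
    return FactorizationResult(W=W, H=H, a=a,
                               reconstruction_error=history[-1],
                               error_history=history, seed=seed)


@dataclass
class ClusterAssignment:
    """Patient -> cluster index, with flags for degenerate all-zero rows."""

    labels: dict[str, int]
    zero_rows: list[str] = field(default_factory=list)
    coordinates: dict[str, tuple[float, float]] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid in sorted(self.labels):
            row = {"patient_id": pid, "cluster": self.labels[pid]}
            if self.coordinates and pid in self.coordinates:
                row["x"], row["y"] = self.coordinates[pid]
            rows.append(row)
        return pd.DataFrame(rows)


def assign_clusters(
    result: FactorizationResult,
    patient_ids: Sequence[str],
) -> ClusterAssignment:
    """cluster(j) = argmax_k W[j, k]; ties and all-zero rows go to index 0."""
    if result.W.shape[0] != len(patient_ids):
        raise ValueError("patient id list does not match W rows")
    labels = {}
    zero_rows = []
    arg = result.W.argmax(axis=1)  # numpy argmax takes the lowest tied index
    for pid, row, k in zip(patient_ids, result.W, arg):
        if (row == 0).all():
            labels[pid] = 0
            zero_rows.append(pid)
        else:
            labels[pid] = int(k)
    return ClusterAssignment(labels=labels, zero_rows=zero_rows)


def embed_2d(
    result: FactorizationResult,
    patient_ids: Sequence[str],
    seed: int = 0,
    perplexity: float = 30.0,
) -> dict[str, tuple[float, float]]:
    """2-D t-SNE view of the patient loadings (visualization only)."""
    from sklearn.manifold import TSNE

    m = result.W.shape[0]
    if m < 5:
        raise ValueError("need at least 5 patients for a 2-D embedding")
    if perplexity >= m:
        raise ValueError(f"perplexity {perplexity} must be < number of patients {m}")
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(result.W)
    return {pid: (float(x), float(y)) for pid, (x, y) in zip(patient_ids, coords)}
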