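"""TF-IDF vectorization, NMF topic extraction and model selection.

The corpus of prepared unfavorable reviews is vectorized with smoothed
TF-IDF and factorized as A ~ W H with W, H >= 0: rows of W weight each
review over k latent topics, rows of H weight each topic over the
vocabulary.  A review's *dominant topic* is the argmax of its W row - the
issue voiced most firmly in it.

The factorization minimizes the Frobenius objective ||A - WH||^2_F by
Lee-Seung multiplicative updates from a seeded random nonnegative
initialization; the per-iteration objective is recorded and is provably
non-increasing, which the test suite asserts on every fit.

The number of topics is chosen over a grid (default 3-13) by UMass topic
coherence with the silhouette of the dominant-topic clustering as
tie-breaker; the full per-k report is always emitted so a human can
overrule the automatic choice.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics import silhouette_score

from .textprep import TokenStream

logger = logging.getLogger(__name__)

#: Sentinel label for documents whose W row is entirely zero.
UNASSIGNED = -1


def _identity(x):
    return x


@dataclass
class DocumentTermMatrix:
    """Sparse nonnegative TF-IDF matrix with document and term registries."""

    A: sp.csr_matrix
    doc_index: list[str]
    term_index: list[str]
    vectorizer_params: dict

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        mmwrite(str(d / "dtm.mtx"), self.A)
        (d / "doc_index.txt").write_text("\n".join(self.doc_index) + "\n")
        (d / "vocabulary.txt").write_text("\n".join(self.term_index) + "\n")
        (d / "vectorizer.json").write_text(
            json.dumps(self.vectorizer_params, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory) -> "DocumentTermMatrix":
        d = Path(directory)
        A = sp.csr_matrix(mmread(str(d / "dtm.mtx")))
        docs = (d / "doc_index.txt").read_text().splitlines()
        terms = (d / "vocabulary.txt").read_text().splitlines()
        params = json.loads((d / "vectorizer.json").read_text())
        return cls(A=A, doc_index=docs, term_index=terms,
                   vectorizer_params=params)


def build_tfidf(
    streams: Sequence[TokenStream],
    min_df: int = 5,
    max_df: float = 0.95,
) -> DocumentTermMatrix:
    """Vectorize token streams with smoothed TF-IDF.

    The weight of term t in document d is

        tf(d, t) * (ln((1 + N) / (1 + df(t))) + 1)

    with each document row then scaled to unit Euclidean norm.  Terms whose
    document frequency falls outside ``[min_df, max_df * N]`` are excluded,
    trimming both rare noise and near-ubiquitous words.
    """
    if len(streams) < 2:
        raise ValueError("TF-IDF needs at least 2 documents")
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    if not 0 < max_df <= 1:
        raise ValueError("max_df must be in (0, 1]")
    vec = TfidfVectorizer(
        analyzer=_identity, lowercase=False,
        min_df=min_df, max_df=max_df,
        norm="l2", smooth_idf=True, sublinear_tf=False,
    )
    try:
        A = vec.fit_transform([list(s.tokens) for s in streams])
    except ValueError as exc:
        raise ValueError(
            f"empty vocabulary after pruning (min_df={min_df}, "
            f"max_df={max_df}) over {len(streams)} documents: {exc}"
        ) from exc
    terms = vec.get_feature_names_out().tolist()
    return DocumentTermMatrix(
        A=sp.csr_matrix(A),
        doc_index=[s.doc_id for s in streams],
        term_index=terms,
        vectorizer_params={"min_df": min_df, "max_df": max_df,
                           "idf": "smooth, ln((1+N)/(1+df))+1, l2-normalized"},
    )


@dataclass
class TopicModel:
    """A fitted nonnegative factorization A ~ W H."""

    W: np.ndarray
    H: np.ndarray
    k: int
    seed: int
    objective_trace: list[float]
    converged: bool

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        mmwrite(str(d / "W.mtx"), sp.coo_matrix(self.W))
        mmwrite(str(d / "H.mtx"), sp.coo_matrix(self.H))
        meta = {"k": self.k, "seed": self.seed,
                "objective_trace": self.objective_trace,
                "converged": self.converged}
        (d / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "TopicModel":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        W = mmread(str(d / "W.mtx"))
        H = mmread(str(d / "H.mtx"))
        W = W.toarray() if sp.issparse(W) else np.asarray(W)
        H = H.toarray() if sp.issparse(H) else np.asarray(H)
        return cls(W=W, H=H, k=meta["k"],
                   seed=meta["seed"], objective_trace=meta["objective_trace"],
                   converged=meta["converged"])


def _frobenius_sq(A: sp.csr_matrix, W: np.ndarray, H: np.ndarray,
                  normA2: float) -> float:
    # ||A - WH||^2 = ||A||^2 - 2<A, WH> + ||WH||^2, without forming WH
    cross = float(np.sum((A @ H.T) * W))
    gram = float(np.sum((W.T @ W) * (H @ H.T)))
    return normA2 - 2.0 * cross + gram


def fit_nmf(
    dtm: DocumentTermMatrix | sp.spmatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> TopicModel:
    """Factorize the document-term matrix by multiplicative updates.

    Stops when the relative objective decrease per iteration drops below
    *tol* or after *max_iter* iterations.  After fitting, rows of H are
    rescaled to unit L2 norm with compensating column scaling of W (the
    product WH, and hence dominant-topic assignments, are unchanged).
    """
    A = dtm.A if isinstance(dtm, DocumentTermMatrix) else sp.csr_matrix(dtm)
    if (A < 0).nnz if sp.issparse(A) else np.any(A < 0):
        raise ValueError("input matrix must be nonnegative")
    n, v = A.shape
    if not 1 <= k <= min(n, v):
        raise ValueError(f"k={k} outside [1, min(N,V)={min(n, v)}]")
    normA2 = float(A.multiply(A).sum())
    if normA2 == 0.0:
        raise ValueError("all-zero matrix cannot be factorized")

    rng = np.random.default_rng(seed)
    scale = math.sqrt(A.mean() / k)
    W = scale * rng.random((n, k))
    H = scale * rng.random((k, v))
    eps = 1e-12

    trace: list[float] = [_frobenius_sq(A, W, H, normA2)]
    converged = False
    for _ in range(max_iter):
        # Lee-Seung updates under the Frobenius objective
        H *= (W.T @ A) / (W.T @ W @ H + eps)
        W *= (A @ H.T) / (W @ (H @ H.T) + eps)
        obj = _frobenius_sq(A, W, H, normA2)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            converged = True
            break

    # resolve the scale indeterminacy: unit-L2 rows of H
    norms = np.linalg.norm(H, axis=1)
    nonzero = norms > 0
    H[nonzero] /= norms[nonzero, None]
    W[:, nonzero] *= norms[nonzero]

    return TopicModel(W=W, H=H, k=k, seed=seed, objective_trace=trace,
                      converged=converged)


def dominant_topic(W: np.ndarray) -> np.ndarray:
    """Per-document dominant-topic labels: argmax of each W row.

    Ties break toward the lowest topic index; all-zero rows get the
    :data:`UNASSIGNED` sentinel and are counted in a warning.
    """
    W = np.asarray(W)
    labels = np.argmax(W, axis=1)
    zero_rows = ~np.any(W > 0, axis=1)
    if zero_rows.any():
        logger.warning("%d document(s) have all-zero topic weights - "
                       "labeled unassigned", int(zero_rows.sum()))
        labels = labels.copy()
        labels[zero_rows] = UNASSIGNED
    return labels


def top_terms(H: np.ndarray, term_index: Sequence[str], n: int = 10) -> list[list[str]]:
    """The n highest-weight terms per topic, descending, ties alphabetical."""
    if n < 1:
        raise ValueError("n must be >= 1")
    H = np.asarray(H)
    v = H.shape[1]
    if n > v:
        logger.warning("requested %d top terms but vocabulary has %d", n, v)
        n = v
    out: list[list[str]] = []
    for t in range(H.shape[0]):
        ranked = sorted(range(v), key=lambda j: (-H[t, j], term_index[j]))
        out.append([term_index[j] for j in ranked[:n]])
    return out


def coherence_score(
    topic_terms: Sequence[Sequence[str]],
    streams: Sequence[TokenStream],
) -> tuple[list[float], float]:
    """UMass coherence per topic, and the mean over topics.

    For a topic's ranked terms w_1..w_n the score sums, over ordered pairs
    i > j, ln((D(w_i, w_j) + 1) / D(w_j)) where D counts the documents
    containing the term(s).  Pairs whose conditioning term is absent from
    the corpus are skipped and counted.
    """
    doc_sets = [frozenset(s.tokens) for s in streams]
    vocab = set().union(*doc_sets) if doc_sets else set()
    df: dict[str, int] = {}
    for terms in topic_terms:
        for w in terms:
            if w not in df and w in vocab:
                df[w] = sum(1 for ds in doc_sets if w in ds)

    skipped = 0
    scores: list[float] = []
    for terms in topic_terms:
        total = 0.0
        for i in range(1, len(terms)):
            for j in range(i):
                wi, wj = terms[i], terms[j]
                dj = df.get(wj, 0)
                if dj == 0:
                    skipped += 1
                    continue
                dij = sum(1 for ds in doc_sets if wi in ds and wj in ds)
                total += math.log((dij + 1) / dj)
        scores.append(total)
    if skipped:
        logger.warning("coherence: skipped %d pairs with absent terms", skipped)
    mean = float(np.mean(scores)) if scores else float("nan")
    return scores, mean


def silhouette_on_topics(
    W: np.ndarray | sp.spmatrix,
    labels: np.ndarray,
    max_docs: int = 2000,
    seed: int = 0,
) -> float:
    """Mean silhouette (cosine distance) of document rows under
    dominant-topic labels.

    The first argument is any per-document representation: rows of the
    document-topic matrix W, or rows of the TF-IDF matrix itself.  The
    latter is what model selection uses - document-topic rows collapse onto
    their dominant axis, which hides the damage done by merging two real
    themes into one topic, whereas term-space rows expose it.

    Unassigned documents are excluded; corpora larger than *max_docs* are
    subsampled with a fixed seed for tractability.  Returns NaN with a
    warning when fewer than two clusters remain.
    """
    W = W.tocsr() if sp.issparse(W) else np.asarray(W)
    labels = np.asarray(labels)
    keep = labels != UNASSIGNED
    W, labels = W[keep], labels[keep]
    if len(np.unique(labels)) < 2:
        logger.warning("silhouette undefined for a single cluster")
        return float("nan")
    if W.shape[0] > max_docs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(W.shape[0], size=max_docs, replace=False)
        idx.sort()
        if len(np.unique(labels[idx])) < 2:  # degenerate subsample
            logger.warning("silhouette subsample collapsed to one cluster")
            return float("nan")
        W, labels = W[idx], labels[idx]
    return float(silhouette_score(W, labels, metric="cosine"))


@dataclass
class ModelSelectionReport:
    """Per-k diagnostics and the automatically chosen topic count."""

    rows: list[dict]
    chosen_k: int
    criterion: str
    models: dict[int, TopicModel] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [{k: v for k, v in row.items() if k != "top_terms"}
             for row in self.rows]
        )


def select_model(
    dtm: DocumentTermMatrix,
    streams: Sequence[TokenStream],
    k_grid: Iterable[int] = range(3, 14),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    top_n: int = 10,
    max_iter: int = 500,
    tol: float = 1e-5,
    criterion: str = "coherence",
    tie_tol: float = 0.10,
    keep_models: bool = False,
) -> ModelSelectionReport:
    """Fit every k on the grid and choose one by the configured criterion.

    Each k is fit once per seed and the best fit by final objective kept.
    With the default ``criterion="coherence"``, the chosen k maximizes mean
    UMass coherence, with a near-tie rule: ks whose coherence lies within
    ``tie_tol * |best coherence|`` of the best are ties, broken by the
    silhouette of the dominant-topic clustering in term space, then by the
    smaller k.  The band reflects how the two scores fail differently -
    coherence collapses (by several times its usual spread) when a topic
    mixes two unrelated themes but barely moves otherwise, while silhouette
    resolves the remaining choice in both directions.
    ``criterion="silhouette"`` ranks by silhouette directly.  The full
    report is always emitted so domain judgment can overrule the automatic
    choice.
    """
    k_grid = sorted(set(k_grid))
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    rows: list[dict] = []
    models: dict[int, TopicModel] = {}
    for k in k_grid:
        try:
            fits = [fit_nmf(dtm, k, seed=s, max_iter=max_iter, tol=tol)
                    for s in seeds]
            best = min(fits, key=lambda m: m.objective_trace[-1])
            labels = dominant_topic(best.W)
            terms = top_terms(best.H, dtm.term_index, n=top_n)
            _, coh = coherence_score(terms, streams)
            sil = silhouette_on_topics(dtm.A, labels)
            rows.append({"k": k, "seed": best.seed,
                         "objective": best.objective_trace[-1],
                         "coherence": coh, "silhouette": sil,
                         "top_terms": terms})
            if keep_models:
                models[k] = best
        except Exception as exc:  # record the failure, continue the grid
            logger.error("k=%d failed: %s", k, exc)
            rows.append({"k": k, "seed": None, "objective": float("nan"),
                         "coherence": float("nan"),
                         "silhouette": float("nan"), "top_terms": [],
                         "error": str(exc)})
    ok = [r for r in rows if not math.isnan(r["coherence"])]
    if not ok:
        raise RuntimeError("model selection failed for every k on the grid")

    if criterion == "silhouette":
        chosen = max(ok, key=lambda r: (r["silhouette"], -r["k"]))["k"]
    elif criterion == "coherence":
        best_coh = max(r["coherence"] for r in ok)
        band = tie_tol * abs(best_coh)
        tied = [r for r in ok if r["coherence"] >= best_coh - band]
        chosen = max(tied, key=lambda r: (r["silhouette"], -r["k"]))["k"]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return ModelSelectionReport(rows=rows, chosen_k=chosen,
                                criterion=criterion, models=models)
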