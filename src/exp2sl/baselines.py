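"""Comparison methods: symmetric-input classifiers and NetLapRLS.

The standard classifiers (logistic regression, random forest, SVM, gradient
boosting) see each labeled pair in both concatenation orders during training
and average the two ordered probabilities at prediction time, making them
order-invariant by construction. NetLapRLS is a semi-supervised
graph-Laplacian-regularized least-squares regressor over a gene-gene
similarity kernel (PPI-neighborhood Jaccard, absolute L1000 Pearson
correlation, or their probabilistic-OR combination).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

# hyperparameter grids searched for each baseline family
BASELINE_GRIDS: dict[str, dict[str, list]] = {
    "LR": {"C": [10, 1, 0.5, 0.1, 0.05, 0.01]},
    "RF": {"n_estimators": [32, 64, 128], "max_depth": [8, 16, None]},
    "SVM": {"C": [100, 50, 10, 5, 1, 0.5, 0.1]},
    "GBDT": {"n_estimators": [32, 64, 128], "max_depth": [4, 8, 16]},
}


# ---------------------------------------------------------------------------
# similarity kernels


@dataclass
class SimilarityMatrix:
    """Symmetric gene x gene kernel with entries in [0, 1]."""

    genes: list[str]
    values: np.ndarray
    kind: str  # ppi_jaccard | l1000_pearson | combined

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape must match the gene list")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("similarity entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)


def ppi_jaccard(edges: pd.DataFrame, genes, score_threshold: float = 0.8) -> SimilarityMatrix:
    """Neighborhood Jaccard similarity over a thresholded PPI network.

    Edges with confidence strictly above ``score_threshold`` are kept;
    S(i, j) = |N(i) & N(j)| / |N(i) | N(j)| with N(x) the neighbor set of x,
    defined as 0 when both neighborhoods are empty. Genes absent from the
    network simply have empty neighborhoods.
    """
    genes = list(genes)
    graph = nx.Graph()
    kept = edges[edges["combined_score"] > score_threshold]
    graph.add_edges_from(zip(kept["protein_a"], kept["protein_b"]))
    neighbor_sets = [set(graph.neighbors(g)) if g in graph else set() for g in genes]
    n = len(genes)
    s = np.zeros((n, n))
    for i in range(n):
        s[i, i] = 1.0 if neighbor_sets[i] else 0.0
        for j in range(i + 1, n):
            union = neighbor_sets[i] | neighbor_sets[j]
            if union:
                s[i, j] = s[j, i] = len(neighbor_sets[i] & neighbor_sets[j]) / len(union)
    return SimilarityMatrix(genes=genes, values=s, kind="ppi_jaccard")


def l1000_pearson(signatures: pd.DataFrame) -> SimilarityMatrix:
    """Absolute pairwise Pearson correlation of gene signatures."""
    if signatures.shape[0] < 2:
        raise ValueError("need at least two gene signatures")
    x = signatures.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("%d zero-variance signatures; their correlations set to 0",
                       int(zero.sum()))
        norms[zero] = 1.0
    unit = x / norms[:, None]
    corr = np.abs(np.clip(unit @ unit.T, -1.0, 1.0))
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    return SimilarityMatrix(genes=list(signatures.index), values=corr, kind="l1000_pearson")


def combine_similarities(s_ppi: SimilarityMatrix, s_expr: SimilarityMatrix) -> SimilarityMatrix:
    """Probabilistic-OR fusion: 1 - (1 - S_p)(1 - S_l), elementwise."""
    if s_ppi.genes != s_expr.genes:
        raise ValueError("similarity matrices must share the gene ordering")
    combined = 1.0 - (1.0 - s_ppi.values) * (1.0 - s_expr.values)
    return SimilarityMatrix(genes=list(s_ppi.genes), values=combined, kind="combined")


# ---------------------------------------------------------------------------
# symmetric pair classifiers


class SymmetricPairClassifier(BaseEstimator, ClassifierMixin):
    """Order-invariant wrapper around any probabilistic classifier.

    The feature vector of a pair is the concatenation [f_i, f_j]; at fit time
    both orderings enter the training set with the same label, and at
    prediction time the probabilities of the two orderings are averaged, so
    p(i, j) == p(j, i) exactly.
    """

    def __init__(self, base_estimator=None):
        self.base_estimator = base_estimator

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[1] % 2 != 0:
            raise ValueError("pair features must concatenate two equal-length signatures")
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        half = X.shape[1] // 2
        swapped = np.hstack([X[:, half:], X[:, :half]])
        base = self.base_estimator if self.base_estimator is not None else LogisticRegression()
        self.estimator_ = clone(base)
        self.estimator_.fit(np.vstack([X, swapped]), np.concatenate([y, y]))
        self.classes_ = self.estimator_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        half = X.shape[1] // 2
        swapped = np.hstack([X[:, half:], X[:, :half]])
        return 0.5 * (self.estimator_.predict_proba(X) + self.estimator_.predict_proba(swapped))

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def decision_function(self, X):
        """Probability of the positive (last) class, for ranking metrics."""
        return self.predict_proba(X)[:, -1]


def make_baseline(name: str, random_state: int = 0, **hyper) -> SymmetricPairClassifier:
    """Construct one of the four reference pair classifiers by family name."""
    name = name.upper()
    if name == "LR":
        base = LogisticRegression(max_iter=5000, random_state=random_state, **hyper)
    elif name == "RF":
        base = RandomForestClassifier(random_state=random_state, **hyper)
    elif name == "SVM":
        base = SVC(probability=True, random_state=random_state, **hyper)
    elif name == "GBDT":
        from xgboost import XGBClassifier

        base = XGBClassifier(random_state=random_state, eval_metric="logloss", **hyper)
    else:
        raise ValueError(f"unknown baseline family {name!r}")
    return SymmetricPairClassifier(base_estimator=base)


def pair_features(signatures: pd.DataFrame, pairs) -> np.ndarray:
    """Concatenated signature features [f_i, f_j] for a list of gene pairs."""
    feat = signatures.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(signatures.index)}
    idx = np.array([[pos[a], pos[b]] for a, b in pairs], dtype=int)
    return np.hstack([feat[idx[:, 0]], feat[idx[:, 1]]])


# ---------------------------------------------------------------------------
# NetLapRLS


class NetLapRLS(BaseEstimator):
    """Graph-Laplacian-regularized least squares over a similarity kernel.

    The working kernel fuses the supplied similarity with the linear kernel
    of the (training-masked) interaction profiles,

        W = (S + gamma * R R^T) / (1 + gamma),   diag(W) = 0,

    and the score matrix solves the normalized-Laplacian-regularized system

        F = W (W + beta * L W)^+ Y,   L = D^-1/2 (D - W) D^-1/2,

    followed by symmetrization F <- (F + F^T)/2. With beta = 0 and invertible
    W this returns Y itself. Pairs (i, j) and (j, i) are treated identically
    throughout, so no order averaging is needed.
    """

    def __init__(self, gamma: float = 0.01, beta: float = 0.3):
        self.gamma = gamma
        self.beta = beta

    def fit(self, similarity: SimilarityMatrix, y_train: np.ndarray):
        """Fit from a kernel and a training-masked 0/1 label adjacency.

        ``y_train`` holds 1 for known-positive training pairs and 0 elsewhere
        (untrained and negative entries alike), matching the interaction-
        prediction convention.
        """
        s = similarity.values
        y = np.asarray(y_train, dtype=float)
        if y.shape != s.shape:
            raise ValueError("label adjacency must match the similarity matrix")
        if not np.allclose(y, y.T):
            raise ValueError("label adjacency must be symmetric")
        r = y.copy()
        w = (s + self.gamma * (r @ r.T)) / (1.0 + self.gamma)
        np.fill_diagonal(w, 0.0)
        if not np.any(w):
            raise ValueError("working kernel W is identically zero")
        d = w.sum(axis=1)
        with np.errstate(divide="ignore"):
            d_isqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
        lap = d_isqrt[:, None] * (np.diag(d) - w) * d_isqrt[None, :]
        a = w + self.beta * (lap @ w)
        try:
            f = w @ np.linalg.solve(a, y)
        except np.linalg.LinAlgError:
            f = w @ (np.linalg.pinv(a) @ y)
        self.genes_ = list(similarity.genes)
        self.scores_ = 0.5 * (f + f.T)
        return self

    def predict_pairs(self, pairs) -> np.ndarray:
        """Scores for unordered gene pairs from the fitted score matrix."""
        if not hasattr(self, "scores_"):
            raise AttributeError("NetLapRLS instance is not fitted yet")
        pos = {g: i for i, g in enumerate(self.genes_)}
        return np.array([self.scores_[pos[a], pos[b]] for a, b in pairs])
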