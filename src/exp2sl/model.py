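"""The EXP2SL pair-scoring network and its semi-supervised objective.

A gene's 978-dimensional L1000 z-score signature f is passed through E
fully-connected ReLU layers (E = 0 means the raw signature is used directly).
A pair (i, j) is scored symmetrically by a linear head over both
concatenation orders,

    s_ij = 1/2 (W_out [h_i, h_j] + W_out [h_j, h_i]) + b_out,

which collapses to s_ij = q . (h_i + h_j) + b_out with q = (u + v)/2 for
W_out = [u, v]; symmetry s_ij = s_ji therefore holds by construction.

Training minimizes

    L = sum_{(i,j) in P u N} (s_ij - y_ij)^2
        + lambda_bpr * L_BPR + lambda_l2 * ||theta||^2,

with targets y = +1 (positive SL) / -1 (negative). L_BPR is a semi-supervised
Bayesian-personalized-ranking term: each epoch, |P| unknown and |P| negative
pairs are resampled, and the loss -log sigma(s_pos - s_unk) - log
sigma(s_unk - s_neg) pushes positives above unknowns and unknowns above
negatives. Optimization is full-batch Adam (lr 0.001, 1000 epochs) with the
global gradient norm clipped at 5.

The network is small enough that the forward pass and analytic backprop are
implemented directly in NumPy; gradients are validated against finite
differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .labels import SLLabelSet, canonical_pair


# ---------------------------------------------------------------------------
# functional pieces


def encode(f: np.ndarray, weights: list[np.ndarray], biases: list[np.ndarray]) -> np.ndarray:
    """Apply the ReLU encoder stack to one signature or a stack of them.

    With no layers the input passes through unchanged.
    """
    h = np.asarray(f, dtype=float)
    for w, b in zip(weights, biases):
        if w.shape[1] != h.shape[-1]:
            raise ValueError(f"layer expects input dim {w.shape[1]}, got {h.shape[-1]}")
        h = np.maximum(h @ w.T + b, 0.0)
    return h


def score_pair(h_i: np.ndarray, h_j: np.ndarray, w_out: np.ndarray, b_out: float) -> float:
    """Order-averaged linear score of an encoded gene pair."""
    h_i = np.asarray(h_i, dtype=float)
    h_j = np.asarray(h_j, dtype=float)
    if h_i.shape != h_j.shape:
        raise ValueError("encoded pair members must have equal length")
    if w_out.shape[0] != 2 * h_i.shape[0]:
        raise ValueError(
            f"output head expects length {w_out.shape[0]}, pair gives {2 * h_i.shape[0]}"
        )
    s_ij = w_out @ np.concatenate([h_i, h_j])
    s_ji = w_out @ np.concatenate([h_j, h_i])
    return float(0.5 * (s_ij + s_ji) + b_out)


def mse_loss(scores: np.ndarray, targets: np.ndarray) -> float:
    """Sum of squared errors against +-1 targets (a sum, not a mean)."""
    scores = np.asarray(scores, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if scores.size == 0:
        raise ValueError("mse_loss over an empty set")
    if scores.shape != targets.shape:
        raise ValueError("scores and targets must align")
    return float(np.sum((scores - targets) ** 2))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def bpr_loss(pos_scores, unk_scores, neg_scores) -> float:
    """Ranking loss pushing positive > unknown > negative, paired one-to-one.

    Implemented as softplus(-(margin)) per triple element, the numerically
    stable form of -log sigma(margin); it is zero only in the limit of
    infinite margins.
    """
    pos = np.asarray(pos_scores, dtype=float)
    unk = np.asarray(unk_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if not (pos.shape == unk.shape == neg.shape) or pos.size == 0:
        raise ValueError("pos/unk/neg score vectors must be non-empty and equal length")
    return float(np.sum(_softplus(-(pos - unk))) + np.sum(_softplus(-(unk - neg))))


def total_objective(labeled_scores, targets, pos_scores, unk_scores, neg_scores,
                    lambda_bpr: float, lambda_l2: float, param_sq_norm: float) -> float:
    """Full training objective: sum-MSE + lambda_bpr * BPR + lambda_l2 * ||theta||^2."""
    loss = mse_loss(labeled_scores, targets)
    if lambda_bpr != 0:
        loss += lambda_bpr * bpr_loss(pos_scores, unk_scores, neg_scores)
    return loss + lambda_l2 * param_sq_norm


# ---------------------------------------------------------------------------
# estimator


class EXP2SL(BaseEstimator):
    """Semi-supervised symmetric pair classifier over gene expression signatures.

    Parameters
    ----------
    n_encoder_layers : int
        Number of fully-connected ReLU layers E in {0, ..., 4}; 0 scores the
        raw signatures directly.
    hidden_dim : int
        Width d of each encoder layer.
    lambda_bpr : float
        Weight of the ranking term; 0 disables semi-supervision (the
        supervised ablation).
    lambda_l2 : float
        Weight of the squared-L2 penalty over all weights and biases.
    learning_rate, n_epochs, grad_clip :
        Adam step size, number of full-batch epochs, and the global
        gradient-norm ceiling.
    bpr_pairing : {"one_to_one", "product"}
        Whether each epoch's BPR term pairs the k-th positive with the k-th
        sampled unknown/negative, or evaluates the full Cartesian product of
        the sampled sets.
    random_state : int
        Seeds weight initialization and the per-epoch unknown/negative
        resampling jointly; identical seeds give bitwise-identical fits.

    Attributes
    ----------
    encoder_weights_, encoder_biases_ : lists of arrays
    output_weight_ : array of length 2*d' (d' = hidden_dim if E >= 1 else n features)
    output_bias_ : float
    loss_curve_ : per-epoch training objective
    genes_ : index of the signature matrix seen at fit time
    """

    def __init__(self, n_encoder_layers: int = 1, hidden_dim: int = 64,
                 lambda_bpr: float = 32.0, lambda_l2: float = 0.01,
                 learning_rate: float = 1e-3, n_epochs: int = 1000,
                 grad_clip: float = 5.0, bpr_pairing: str = "one_to_one",
                 random_state: int = 0):
        self.n_encoder_layers = n_encoder_layers
        self.hidden_dim = hidden_dim
        self.lambda_bpr = lambda_bpr
        self.lambda_l2 = lambda_l2
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.grad_clip = grad_clip
        self.bpr_pairing = bpr_pairing
        self.random_state = random_state

    # -- parameter plumbing -------------------------------------------------

    def _init_params(self, n_features: int, rng: np.random.Generator) -> list[np.ndarray]:
        """Uniform fan-in initialization, one flat list [W1, b1, ..., w_out, b_out]."""
        params: list[np.ndarray] = []
        fan_in = n_features
        for _ in range(self.n_encoder_layers):
            bound = 1.0 / np.sqrt(fan_in)
            params.append(rng.uniform(-bound, bound, size=(self.hidden_dim, fan_in)))
            params.append(rng.uniform(-bound, bound, size=self.hidden_dim))
            fan_in = self.hidden_dim
        bound = 1.0 / np.sqrt(2 * fan_in)
        params.append(rng.uniform(-bound, bound, size=2 * fan_in))
        params.append(rng.uniform(-bound, bound, size=()))
        return params

    @staticmethod
    def _split_params(params):
        ws, bs = params[:-2:2], params[1:-2:2]
        return ws, bs, params[-2], params[-1]

    def _loss_and_grads(self, params, feat, lab_idx, lab_y, bpr_margins):
        """Objective and its analytic gradient for one (fixed) epoch batch.

        ``lab_idx`` is an (n_labeled, 2) gene-index array with targets
        ``lab_y`` in {+1, -1}; ``bpr_margins`` is a list of (upper, lower)
        pair-index arrays, each contributing softplus(-(s_upper - s_lower)).
        Exposed separately so tests can check the gradient against finite
        differences.
        """
        ws, bs, w_out, b_out = self._split_params(params)
        dprime = self.hidden_dim if self.n_encoder_layers else feat.shape[1]
        q = 0.5 * (w_out[:dprime] + w_out[dprime:])

        hs = [feat]
        for w, b in zip(ws, bs):
            hs.append(np.maximum(hs[-1] @ w.T + b, 0.0))
        h = hs[-1]
        hq = h @ q  # per-gene head projection; s_ij = hq_i + hq_j + b_out

        def pair_scores(idx):
            return hq[idx[:, 0]] + hq[idx[:, 1]] + float(b_out)

        s_lab = pair_scores(lab_idx)
        loss = np.sum((s_lab - lab_y) ** 2)
        g_lab = 2.0 * (s_lab - lab_y)

        grads_s = [(lab_idx, g_lab)]
        for upper, lower in bpr_margins:
            m = pair_scores(upper) - pair_scores(lower)
            loss += self.lambda_bpr * np.sum(_softplus(-m))
            sig = 1.0 / (1.0 + np.exp(np.clip(m, -500, 500)))  # sigma(-m)
            grads_s.append((upper, -self.lambda_bpr * sig))
            grads_s.append((lower, self.lambda_bpr * sig))

        # every pair's score gradient points along q, so the per-gene
        # accumulation collapses to a weighted occurrence count
        n_genes = h.shape[0]
        coeff = np.zeros(n_genes)
        g_b_out = 0.0
        for idx, g in grads_s:
            coeff += np.bincount(idx[:, 0], weights=g, minlength=n_genes)
            coeff += np.bincount(idx[:, 1], weights=g, minlength=n_genes)
            g_b_out += float(np.sum(g))
        g_q = coeff @ h
        dh = np.outer(coeff, q)

        g_w_out = np.concatenate([0.5 * g_q, 0.5 * g_q])

        g_ws, g_bs = [], []
        for e in range(len(ws) - 1, -1, -1):
            dz = dh * (hs[e + 1] > 0)
            g_ws.append(dz.T @ hs[e])
            g_bs.append(dz.sum(axis=0))
            dh = dz @ ws[e]

        grads: list[np.ndarray] = []
        for gw, gb in zip(reversed(g_ws), reversed(g_bs)):
            grads.extend([gw, gb])
        grads.extend([g_w_out, np.asarray(g_b_out)])

        if self.lambda_l2:
            loss += self.lambda_l2 * sum(float(np.sum(p * p)) for p in params)
            grads = [g + 2.0 * self.lambda_l2 * p for g, p in zip(grads, params)]
        return float(loss), grads

    # -- fitting ------------------------------------------------------------

    def fit(self, signatures: pd.DataFrame, pairs, y):
        """Train on labeled gene pairs.

        Parameters
        ----------
        signatures : DataFrame, genes x features
            One z-score signature per gene; must cover every gene in ``pairs``.
        pairs : sequence of (gene_a, gene_b)
        y : array-like in {+1, -1}
        """
        y = np.asarray(y, dtype=float)
        if not set(np.unique(y)) <= {-1.0, 1.0}:
            raise ValueError("targets must be +-1")
        pairs = [canonical_pair(a, b) for a, b in pairs]
        if len(pairs) != len(y):
            raise ValueError("pairs and y must align")
        n_pos, n_neg = int(np.sum(y > 0)), int(np.sum(y < 0))
        if n_pos == 0:
            raise ValueError("training set P is empty: at least one positive pair required")
        if n_neg == 0:
            raise ValueError("training set N is empty: at least one negative pair required")

        self.genes_ = signatures.index
        gene_pos = {g: i for i, g in enumerate(self.genes_)}
        missing = sorted({g for p in pairs for g in p if g not in gene_pos})
        if missing:
            raise KeyError(f"genes without signatures: {missing}")
        feat = signatures.to_numpy(dtype=float)
        self._features = feat

        lab_idx = np.array([[gene_pos[a], gene_pos[b]] for a, b in pairs], dtype=int)
        pos_idx = lab_idx[y > 0]
        neg_idx = lab_idx[y < 0]

        # unknown pairs are sampled from the training gene universe only, so a
        # split-gene evaluation never sees held-out genes during training
        train_gene_ids = np.unique(lab_idx)
        labeled_set = {(min(a, b), max(a, b)) for a, b in lab_idx}

        rng = np.random.default_rng(self.random_state)
        params = self._init_params(feat.shape[1], rng)
        moments = [(np.zeros_like(p), np.zeros_like(p)) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        k = n_pos

        self.loss_curve_ = []
        for epoch in range(1, self.n_epochs + 1):
            bpr_margins = []
            if self.lambda_bpr != 0:
                unk_idx = self._sample_unknown(rng, train_gene_ids, labeled_set, k)
                rows = rng.choice(n_neg, size=k, replace=n_neg < k)
                neg_samp = neg_idx[rows]
                if self.bpr_pairing == "product":
                    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
                    bpr_margins = [(pos_idx[ii.ravel()], unk_idx[jj.ravel()]),
                                   (unk_idx[ii.ravel()], neg_samp[jj.ravel()])]
                else:
                    bpr_margins = [(pos_idx, unk_idx), (unk_idx, neg_samp)]
            loss, grads = self._loss_and_grads(params, feat, lab_idx, y, bpr_margins)
            gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
            if self.grad_clip and gnorm > self.grad_clip:
                grads = [g * (self.grad_clip / gnorm) for g in grads]
            for i, (p, g) in enumerate(zip(params, grads)):
                m, v = moments[i]
                m = beta1 * m + (1 - beta1) * g
                v = beta2 * v + (1 - beta2) * g * g
                moments[i] = (m, v)
                mhat = m / (1 - beta1 ** epoch)
                vhat = v / (1 - beta2 ** epoch)
                params[i] = p - self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            self.loss_curve_.append(loss)

        ws, bs, w_out, b_out = self._split_params(params)
        self.encoder_weights_ = ws
        self.encoder_biases_ = bs
        self.output_weight_ = w_out
        self.output_bias_ = float(b_out)
        return self

    def fit_label_set(self, signatures: pd.DataFrame, labels: SLLabelSet):
        """Convenience: fit from an SLLabelSet instead of explicit pair arrays."""
        pairs = labels.labeled_pairs()
        y = [labels.labels()[p] for p in pairs]
        return self.fit(signatures, pairs, y)

    @staticmethod
    def _sample_unknown(rng, gene_ids, labeled_set, k):
        """Uniform rejection sampling of k unlabeled unordered pairs."""
        chunks, n = [], 0
        while n < k:
            cand = gene_ids[rng.integers(0, len(gene_ids), size=(2 * k + 8, 2))]
            lo, hi = cand.min(axis=1), cand.max(axis=1)
            ok = lo != hi
            keep = [(a, b) for a, b in zip(lo[ok], hi[ok]) if (a, b) not in labeled_set]
            if keep:
                chunks.append(np.asarray(keep, dtype=int))
                n += len(keep)
        return np.concatenate(chunks)[:k]

    # -- inference ----------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "output_weight_"):
            raise AttributeError("EXP2SL instance is not fitted yet")

    def decision_function(self, pairs, signatures: pd.DataFrame | None = None) -> np.ndarray:
        """Real-valued symmetric SL scores for gene pairs (threshold at 0)."""
        self._check_fitted()
        sig = signatures if signatures is not None else pd.DataFrame(
            self._features, index=self.genes_)
        gene_pos = {g: i for i, g in enumerate(sig.index)}
        missing = sorted({g for p in pairs for g in p if g not in gene_pos})
        if missing:
            raise KeyError(f"genes without signatures: {missing}")
        feat = sig.to_numpy(dtype=float)
        h = encode(feat, self.encoder_weights_, self.encoder_biases_)
        dprime = h.shape[1]
        q = 0.5 * (self.output_weight_[:dprime] + self.output_weight_[dprime:])
        idx = np.array([[gene_pos[a], gene_pos[b]] for a, b in pairs], dtype=int)
        return (h[idx[:, 0]] + h[idx[:, 1]]) @ q + self.output_bias_

    def predict(self, pairs, signatures: pd.DataFrame | None = None) -> np.ndarray:
        """Hard +-1 labels at the natural threshold 0."""
        return np.where(self.decision_function(pairs, signatures) > 0, 1, -1)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: named parameter arrays + hyperparameter record."""
        self._check_fitted()
        arrays = {f"W_enc_{e}": w for e, w in enumerate(self.encoder_weights_)}
        arrays.update({f"b_enc_{e}": b for e, b in enumerate(self.encoder_biases_)})
        arrays["w_out"] = self.output_weight_
        arrays["b_out"] = np.asarray(self.output_bias_)
        arrays["features"] = self._features
        arrays["genes"] = np.asarray(list(self.genes_), dtype=object)
        arrays["hyper_json"] = np.asarray(json.dumps(self.get_params()))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "EXP2SL":
        data = np.load(path, allow_pickle=True)
        model = cls(**json.loads(str(data["hyper_json"])))
        model.encoder_weights_ = [data[f"W_enc_{e}"] for e in range(model.n_encoder_layers)]
        model.encoder_biases_ = [data[f"b_enc_{e}"] for e in range(model.n_encoder_layers)]
        model.output_weight_ = data["w_out"]
        model.output_bias_ = float(data["b_out"])
        model._features = data["features"]
        model.genes_ = pd.Index(data["genes"])
        model.loss_curve_ = []
        return model


# ---------------------------------------------------------------------------
# feature attribution


@dataclass
class ImportanceVector:
    """Saliency importance per input feature dimension, summed over labeled
    pairs and over an ensemble of trained models."""

    weights: np.ndarray
    n_models: int
    n_pairs: int
    top_k: np.ndarray

    def top_features(self, names) -> list:
        return [names[i] for i in self.top_k]


def saliency_importance(models: list[EXP2SL], signatures: pd.DataFrame,
                        labeled_pairs, k: int = 50) -> ImportanceVector:
    """Gradient-magnitude feature importance over the labeled pairs.

    For each model the importance of input dimension t is
    sum_{(i,j) in P u N} |d s_ij / d f_i|_t + |d s_ij / d f_j|_t, and the
    ensemble importance is the sum across models (a 10-model ensemble is
    typical; it damps initialization and sampling variance). Because the score is
    linear in the head and piecewise-linear in the encoder, d s / d f_i
    depends only on gene i's ReLU activation pattern, so the per-gene input
    gradient is computed once and weighted by how often the gene appears.
    """
    if not models:
        raise ValueError("need at least one trained model")
    if len(labeled_pairs) == 0:
        raise ValueError("saliency importance requires labeled pairs")
    gene_pos = {g: i for i, g in enumerate(signatures.index)}
    feat = signatures.to_numpy(dtype=float)
    counts = np.zeros(len(gene_pos))
    for a, b in labeled_pairs:
        counts[gene_pos[a]] += 1
        counts[gene_pos[b]] += 1

    w = np.zeros(feat.shape[1])
    for model in models:
        model._check_fitted()
        ws, bs = model.encoder_weights_, model.encoder_biases_
        hs = [feat]
        for wm, bm in zip(ws, bs):
            hs.append(np.maximum(hs[-1] @ wm.T + bm, 0.0))
        dprime = hs[-1].shape[1]
        q = 0.5 * (model.output_weight_[:dprime] + model.output_weight_[dprime:])
        dh = np.broadcast_to(q, hs[-1].shape).copy()
        for e in range(len(ws) - 1, -1, -1):
            dz = dh * (hs[e + 1] > 0)
            dh = dz @ ws[e]
        w += counts @ np.abs(dh)
    top = np.argsort(-w, kind="stable")[:k]
    return ImportanceVector(weights=w, n_models=len(models), n_pairs=len(labeled_pairs),
                            top_k=top)


def train_exp2sl(signatures: pd.DataFrame, labels: SLLabelSet, hyper: dict | None = None,
                 seed: int = 0) -> EXP2SL:
    """Functional wrapper: train an EXP2SL model from a label set."""
    model = EXP2SL(**(hyper or {}), random_state=seed)
    return model.fit_label_set(signatures, labels)
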