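"""Cross-validation protocols, the metric panel, grid search, and the driver.

Two splitting protocols are supported. "split pair" partitions the labeled
pairs at random (stratified by label) into k folds. "split gene" partitions
the *genes* into k folds: fold f's test pairs are the labeled pairs touching
a fold-f gene, and its training pairs are those whose genes both lie outside
fold f, so every test pair contains at least one gene never seen in training.
A pair whose two genes land in different folds is consequently tested in both
folds. Split-gene generalization to unseen genes is the harder, more
practical setting.

Metrics: AUC (Mann-Whitney / rank formulation with tie correction, via
sklearn), AUPR (step-interpolated precision-recall area, i.e. average
precision), and threshold metrics (F1, accuracy, precision, sensitivity,
specificity) at the model's natural cut: 0 for the +-1-target network, 0.5
for probabilistic classifiers and for min-max-normalized NetLapRLS scores.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .baselines import NetLapRLS, SimilarityMatrix, make_baseline, pair_features
from .labels import SLLabelSet
from .model import EXP2SL

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass
class CVFoldPlan:
    """Train/test pair assignments for one repeat of a CV protocol."""

    protocol: str  # split_pair | split_gene
    folds: list[tuple[list[Pair], list[Pair]]]
    n_folds: int
    repeat_seed: int

    def validate(self):
        """Assert the protocol's defining property on every fold."""
        for train, test in self.folds:
            overlap = set(train) & set(test)
            if overlap:
                raise AssertionError(f"train/test overlap: {sorted(overlap)[:3]}")
            if self.protocol == "split_gene":
                train_genes = {g for p in train for g in p}
                for a, b in test:
                    if a in train_genes and b in train_genes:
                        raise AssertionError(
                            f"split-gene leakage: test pair ({a}, {b}) fully inside "
                            "the training gene set"
                        )
        if self.protocol == "split_pair":
            tested = [p for _, test in self.folds for p in test]
            if len(tested) != len(set(tested)):
                raise AssertionError("split-pair fold test sets overlap")
        return self


def split_pair_folds(labeled_pairs: dict[Pair, int], k: int = 5, seed: int = 0) -> CVFoldPlan:
    """Stratified random partition of labeled pairs into k folds."""
    pairs = sorted(labeled_pairs)
    y = np.array([labeled_pairs[p] for p in pairs])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_ix, test_ix in skf.split(np.zeros(len(pairs)), y):
        folds.append(([pairs[i] for i in train_ix], [pairs[i] for i in test_ix]))
    return CVFoldPlan(protocol="split_pair", folds=folds, n_folds=k, repeat_seed=seed).validate()


def split_gene_folds(labeled_pairs: dict[Pair, int], k: int = 5, seed: int = 0) -> CVFoldPlan:
    """Partition the genes into k folds; test pairs touch the held-out genes.

    Folds whose test set has no positive pair are dropped with a warning (no
    ranking metric is defined there).
    """
    genes = sorted({g for p in labeled_pairs for g in p})
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(genes))
    assignment = {}
    for rank, gi in enumerate(perm):
        assignment[genes[gi]] = rank % k
    folds = []
    for f in range(k):
        held = {g for g, fold in assignment.items() if fold == f}
        test = [p for p in sorted(labeled_pairs) if p[0] in held or p[1] in held]
        train = [p for p in sorted(labeled_pairs) if p[0] not in held and p[1] not in held]
        if not any(labeled_pairs[p] > 0 for p in test):
            logger.warning("split-gene fold %d has no positive test pair; skipped", f)
            continue
        folds.append((train, test))
    return CVFoldPlan(protocol="split_gene", folds=folds, n_folds=k, repeat_seed=seed).validate()


@dataclass
class MetricPanel:
    auc: float
    aupr: float
    f1: float
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def compute_metrics(scores, labels, threshold: float) -> MetricPanel:
    """Full panel for one fold. ``labels`` may be {1, 0} or {+1, -1}."""
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) > 0).astype(int)
    if y.min() == y.max():
        raise ValueError("metrics require both classes in the fold")
    pred = (scores > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if (precision + sensitivity) else 0.0)
    return MetricPanel(
        auc=float(roc_auc_score(y, scores)),
        aupr=float(average_precision_score(y, scores)),
        f1=f1,
        accuracy=(tp + tn) / len(y),
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
    )


# ---------------------------------------------------------------------------
# model dispatch


def _fold_scores(model_name: str, hyper: dict, signatures: pd.DataFrame,
                 train_pairs, train_y, test_pairs, seed: int,
                 similarities: dict[str, SimilarityMatrix] | None = None):
    """Fit one model on a fold and return (test scores, threshold).

    ``train_y`` is +-1 throughout; families that want {1, 0} get it mapped.
    """
    train_y = np.asarray(train_y)
    if model_name.startswith("EXP2SL"):
        params = dict(hyper)
        if "no_bpr" in model_name.lower() or "nobpr" in model_name.lower():
            params["lambda_bpr"] = 0.0
        model = EXP2SL(random_state=seed, **params)
        model.fit(signatures, train_pairs, train_y)
        return model.decision_function(test_pairs, signatures), 0.0
    if model_name.startswith("NetLapRLS"):
        variant = model_name.partition("(")[2].rstrip(")") or "L1000"
        sim = (similarities or {}).get(variant)
        if sim is None:
            raise ValueError(f"no similarity matrix registered for {model_name!r}")
        n = len(sim.genes)
        pos = {g: i for i, g in enumerate(sim.genes)}
        y_adj = np.zeros((n, n))
        for (a, b), lab in zip(train_pairs, train_y):
            if lab > 0:
                y_adj[pos[a], pos[b]] = y_adj[pos[b], pos[a]] = 1.0
        model = NetLapRLS(**hyper).fit(sim, y_adj)
        raw = model.predict_pairs(test_pairs)
        lo, hi = raw.min(), raw.max()
        scores = (raw - lo) / (hi - lo) if hi > lo else np.full_like(raw, 0.5)
        return scores, 0.5
    clf = make_baseline(model_name, random_state=seed, **hyper)
    x_train = pair_features(signatures, train_pairs)
    x_test = pair_features(signatures, test_pairs)
    clf.fit(x_train, (train_y > 0).astype(int))
    return clf.decision_function(x_test), 0.5


def cross_validate(model_name: str, hyper: dict, signatures: pd.DataFrame,
                   labels: SLLabelSet, protocol: str = "split_pair", k: int = 5,
                   n_repeats: int = 1, seed: int = 0,
                   similarities=None) -> list[MetricPanel]:
    """Per-fold metric panels over ``n_repeats`` repeats of k-fold CV."""
    labeled = labels.labels()
    splitter = split_pair_folds if protocol == "split_pair" else split_gene_folds
    panels = []
    for rep in range(n_repeats):
        plan = splitter(labeled, k=k, seed=seed + rep)
        for fold_i, (train, test) in enumerate(plan.folds):
            test_y = np.array([labeled[p] for p in test])
            if test_y.min() == test_y.max():
                logger.warning("fold %d has a single test class; skipped", fold_i)
                continue
            train_y = np.array([labeled[p] for p in train])
            scores, thr = _fold_scores(model_name, hyper, signatures, train, train_y,
                                       test, seed=seed + rep, similarities=similarities)
            panels.append(compute_metrics(scores, test_y, thr))
    return panels


def grid_search(model_name: str, grids: dict[str, list], signatures: pd.DataFrame,
                labels: SLLabelSet, seed: int = 0, n_repeats: int = 5, k: int = 5,
                similarities=None) -> tuple[dict, float]:
    """Exhaustive hyperparameter search scored by mean split-pair CV AUC.

    Model selection always uses the split-pair protocol (5 repeats of 5-fold
    by default), whatever protocol the final report uses; ties keep the first
    grid point in iteration order.
    """
    keys = list(grids)
    best, best_auc = None, -np.inf
    for combo in itertools.product(*(grids[k_] for k_ in keys)):
        hyper = dict(zip(keys, combo))
        panels = cross_validate(model_name, hyper, signatures, labels,
                                protocol="split_pair", k=k, n_repeats=n_repeats,
                                seed=seed, similarities=similarities)
        mean_auc = float(np.mean([p.auc for p in panels]))
        if mean_auc > best_auc:
            best, best_auc = hyper, mean_auc
    return best, best_auc


def run_experiment(signatures: pd.DataFrame, labels: SLLabelSet,
                   models: list[dict], protocols=("split_pair", "split_gene"),
                   n_repeats: int = 10, k: int = 5, seed: int = 0,
                   similarities=None):
    """Evaluate every model under every protocol; mean/std over all fold values.

    ``models`` is a list of {"name": ..., "hyper": {...}} records. Returns a
    summary DataFrame (one row per model x protocol, mean and std columns per
    metric) and the per-fold raw panels for ROC/PR export.
    """
    rows, raw = [], {}
    for protocol in protocols:
        for spec in models:
            name, hyper = spec["name"], spec.get("hyper", {})
            logger.info("evaluating %s under %s", name, protocol)
            panels = cross_validate(name, hyper, signatures, labels, protocol=protocol,
                                    k=k, n_repeats=n_repeats, seed=seed,
                                    similarities=similarities)
            raw[(name, protocol)] = panels
            values = pd.DataFrame([p.as_dict() for p in panels])
            row = {"model": name, "protocol": protocol, "n_folds": len(panels)}
            for metric in values.columns:
                row[f"{metric}_mean"] = values[metric].mean()
                row[f"{metric}_std"] = values[metric].std(ddof=0)
            rows.append(row)
    return pd.DataFrame(rows), raw
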