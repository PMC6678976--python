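"""FastEMC: dual-objective Monte Carlo simulated-annealing feature selection.

FastEMC searches the space of fixed-size feature subsets for sets that
classify molecular subtypes well.  It anneals on a cheap *fast* objective
(a low-budget cross-validated classifier F-score) and periodically scores
the current set with an expensive *full* objective (the full-budget CV
F-score), offering it to a bounded best-set list.  The final signature is
assembled by ranking genes by how often they appear across the best list.

Moves are Metropolis at a fixed temperature gamma: a candidate set produced
by swapping 1..m features is accepted with probability min(1, exp(dF/gamma)).
For non-iterative classifiers (nearest centroid) the fast/full budget split
is realized as 2-fold vs k-fold cross-validation; for iterative classifiers
(logistic regression, linear SVM) the fast budget caps training iterations
at ``fast_budget_ratio`` times the full budget.

Everything is reproducible: one integer seed drives subset initialization,
mutation, acceptance, and fold construction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .types import ExprMatrix

__all__ = [
    "LabeledDataset",
    "FastEMCConfig",
    "FeatureSet",
    "BestSetList",
    "FastEMCResult",
    "ConfusionMatrix",
    "CentroidModel",
    "fscore",
    "cv_objective",
    "mutate",
    "accept_move",
    "run_fastemc",
    "per_class_classifiers",
    "fit_nearest_centroid",
    "predict_nearest_centroid",
    "evaluate_predictions",
]

FULL_ITER_BUDGET = 1000  # full-objective iteration cap for iterative classifiers


@dataclass
class LabeledDataset:
    """Z-scored expression with one class label per sample."""

    expr: ExprMatrix
    labels: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.expr.sample_ids if s not in self.labels]
        if missing:
            raise ValueError(f"unlabeled samples: {missing}")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels[s] for s in self.expr.sample_ids))

    def arrays(self) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
        """(samples x genes matrix, integer labels, class names, gene names)."""
        X = self.expr.values.to_numpy().T
        classes = self.classes
        code = {c: i for i, c in enumerate(classes)}
        y = np.array([code[self.labels[s]] for s in self.expr.sample_ids])
        return X, y, classes, self.expr.genes

    def relabel_binary(self, positive: str, rest_label: str = "rest") -> "LabeledDataset":
        labels = {
            s: (positive if self.labels[s] == positive else rest_label)
            for s in self.expr.sample_ids
        }
        return LabeledDataset(expr=self.expr, labels=labels)


@dataclass
class FastEMCConfig:
    init_size: int = 20
    n_outer: int = 10_000
    n_inner: int = 20
    best_list_size: int = 40
    gamma: float = 0.03
    cv_folds: int = 5
    fast_budget_ratio: float = 0.1
    classifier: str = "nearest_centroid"
    final_signature_size: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("init_size", "n_outer", "n_inner", "best_list_size", "cv_folds",
                     "final_signature_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0 < self.fast_budget_ratio <= 1:
            raise ValueError("fast_budget_ratio must lie in (0, 1]")
        if self.classifier not in {"nearest_centroid", "logistic", "svm"}:
            raise ValueError(f"unknown classifier {self.classifier!r}")


@dataclass(frozen=True)
class FeatureSet:
    """A candidate subset with its fast score and (optionally) full score."""

    features: frozenset[int]
    fast_score: float
    full_score: float | None = None


class BestSetList:
    """Bounded list of the highest-full-score feature sets seen so far."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.entries: list[FeatureSet] = []

    def offer(self, fs: FeatureSet) -> bool:
        """Insert if novel and better than the current minimum; keep sorted."""
        if fs.full_score is None:
            raise ValueError("offered FeatureSet must carry a full score")
        if any(e.features == fs.features for e in self.entries):
            return False
        if len(self.entries) < self.capacity:
            self.entries.append(fs)
        elif fs.full_score > self.entries[-1].full_score:
            self.entries[-1] = fs
        else:
            return False
        self.entries.sort(key=lambda e: -e.full_score)
        return True

    @property
    def min_score(self) -> float:
        return self.entries[-1].full_score if self.entries else -math.inf

    def __len__(self) -> int:
        return len(self.entries)


class ConfusionMatrix:
    """True x predicted counts over an ordered class list."""

    def __init__(self, classes: Sequence[str], counts):
        self.classes = list(classes)
        arr = np.asarray(counts, dtype=int)
        k = len(self.classes)
        if arr.shape != (k, k) or (arr < 0).any():
            raise ValueError("counts must be a nonnegative k x k matrix")
        self.counts = arr

    @classmethod
    def from_labels(
        cls, truth: Sequence[str], predicted: Sequence[str], classes: Sequence[str] | None = None
    ) -> "ConfusionMatrix":
        if len(truth) != len(predicted):
            raise ValueError("label vectors differ in length")
        classes = list(classes) if classes else sorted(set(truth) | set(predicted))
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(truth, predicted):
            counts[idx[t], idx[p]] += 1
        return cls(classes, counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Combined accuracy: diagonal sum over total."""
        return float(np.trace(self.counts)) / self.total

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("class orders differ")
        return ConfusionMatrix(self.classes, self.counts + other.counts)


def fscore(confusion: ConfusionMatrix, positive_class: str | None = None) -> float:
    """Classifier F-score from a confusion matrix.

    Multiclass: macro-averaged F1, with classes that were never predicted
    and never present contributing 0.  Binary: the F1 of the positive class
    (the first class in order unless ``positive_class`` is given).
    """
    counts = confusion.counts
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    pred = counts.sum(axis=0).astype(float)
    true = counts.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred > 0, tp / pred, 0.0)
        recall = np.where(true > 0, tp / true, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    if len(confusion.classes) == 2:
        pos = positive_class if positive_class is not None else confusion.classes[0]
        return float(f1[confusion.classes.index(pos)])
    return float(f1.mean())


# ---------------------------------------------------------------------------
# Cross-validated objective
# ---------------------------------------------------------------------------

def _make_folds(y: np.ndarray, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"cannot build {n_folds} stratified folds: smallest class has {counts.min()} samples"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def _fold_standardize(Xtr: np.ndarray, Xte: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # z-scoring is refit on the training fold only (no leakage)
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (Xtr - mu) / sd, (Xte - mu) / sd


def _nc_predict(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, n_classes: int) -> np.ndarray:
    centroids = np.stack([Xtr[ytr == c].mean(axis=0) for c in range(n_classes)])
    d2 = ((Xte[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)  # argmin resolves ties to the first class in order


def _cv_confusion(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    folds: list[tuple[np.ndarray, np.ndarray]],
    classifier: str,
    budget: int | None,
    seed: int,
) -> np.ndarray:
    conf = np.zeros((n_classes, n_classes), dtype=int)
    for tr, te in folds:
        Xtr, Xte = _fold_standardize(X[tr], X[te])
        ytr = y[tr]
        if classifier == "nearest_centroid":
            pred = _nc_predict(Xtr, ytr, Xte, n_classes)
        elif classifier == "logistic":
            clf = LogisticRegression(
                max_iter=budget or FULL_ITER_BUDGET, random_state=seed % (2**31)
            ).fit(Xtr, ytr)
            pred = clf.predict(Xte)
        else:  # svm
            clf = LinearSVC(
                max_iter=budget or FULL_ITER_BUDGET, random_state=seed % (2**31)
            ).fit(Xtr, ytr)
            pred = clf.predict(Xte)
        np.add.at(conf, (y[te], pred), 1)
    return conf


def cv_objective(
    data: LabeledDataset,
    features: Sequence[int] | Sequence[str],
    classifier: str = "nearest_centroid",
    budget: int | None = None,
    folds: int = 5,
    seed: int = 0,
    positive_class: str | None = None,
) -> float:
    """Stratified k-fold CV F-score of a classifier on a feature subset.

    Per-fold confusion matrices are summed before scoring, so every sample
    contributes exactly once.  ``features`` may be gene names or column
    indices into the dataset's gene list.
    """
    X, y, classes, genes = data.arrays()
    if len(features) == 0:
        raise ValueError("empty feature set")
    if isinstance(next(iter(features)), str):
        index = {g: i for i, g in enumerate(genes)}
        cols = np.array([index[f] for f in features])
    else:
        cols = np.asarray(list(features), dtype=int)
    fold_idx = _make_folds(y, folds, seed)
    conf = _cv_confusion(X[:, cols], y, len(classes), fold_idx, classifier, budget, seed)
    return fscore(ConfusionMatrix(classes, conf), positive_class=positive_class)


# ---------------------------------------------------------------------------
# Annealing moves
# ---------------------------------------------------------------------------

def mutate(features: frozenset[int], pool_size: int, rng: np.random.Generator) -> frozenset[int]:
    """Swap a uniform 1..m of the features for genes outside the set."""
    m = len(features)
    if pool_size <= m:
        raise ValueError(f"pool size {pool_size} must exceed set size {m}")
    u = int(rng.integers(1, m + 1))
    members = np.fromiter(features, dtype=int)
    drop = rng.choice(members, size=u, replace=False)
    outside = np.setdiff1d(np.arange(pool_size), members, assume_unique=False)
    add = rng.choice(outside, size=u, replace=False)
    out = (features - set(drop.tolist())) | set(add.tolist())
    assert len(out) == m
    return frozenset(out)


def accept_move(delta: float, gamma: float, rng: np.random.Generator) -> bool:
    """Metropolis at fixed temperature: accept w.p. min(1, exp(delta/gamma))."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if delta >= 0:
        return True
    return bool(rng.random() < math.exp(delta / gamma))


# ---------------------------------------------------------------------------
# The selector
# ---------------------------------------------------------------------------

@dataclass
class FastEMCResult:
    best_list: BestSetList
    feature_frequency: pd.Series  # gene symbol -> appearance count in best list
    final_signature: list[str]
    trace: pd.DataFrame  # per outer iteration: fast_score, full_score, accepted
    classes: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "final_signature": self.final_signature,
            "feature_frequency": self.feature_frequency.to_dict(),
            "best_list": [
                {
                    "features": sorted(self.genes[i] for i in e.features),
                    "fast_score": e.fast_score,
                    "full_score": e.full_score,
                }
                for e in self.best_list.entries
            ],
            "trace": self.trace.to_dict(orient="list"),
        }


def _objectives(
    data: LabeledDataset, config: FastEMCConfig, seed: int, positive_class: str | None
) -> tuple[Callable[[frozenset[int]], float], Callable[[frozenset[int]], float]]:
    """Build (fast, full) objective closures over precomputed arrays/folds."""
    X, y, classes, _ = data.arrays()
    n_classes = len(classes)
    full_folds = _make_folds(y, config.cv_folds, seed)
    if config.classifier == "nearest_centroid":
        # non-iterative: the cheap budget is realized as coarser (2-fold) CV
        fast_folds = _make_folds(y, 2, seed)
        fast_budget = full_budget = None
    else:
        fast_folds = full_folds
        full_budget = FULL_ITER_BUDGET
        fast_budget = max(1, int(round(full_budget * config.fast_budget_ratio)))

    def _score(cols: frozenset[int], folds, budget) -> float:
        arr = np.fromiter(cols, dtype=int)
        arr.sort()
        conf = _cv_confusion(X[:, arr], y, n_classes, folds, config.classifier, budget, seed)
        return fscore(ConfusionMatrix(classes, conf), positive_class=positive_class)

    cache: dict[frozenset[int], float] = {}

    def fast(cols: frozenset[int]) -> float:
        if cols not in cache:
            cache[cols] = _score(cols, fast_folds, fast_budget)
        return cache[cols]

    def full(cols: frozenset[int]) -> float:
        return _score(cols, full_folds, full_budget)

    return fast, full


def run_fastemc(
    data: LabeledDataset,
    config: FastEMCConfig | None = None,
    positive_class: str | None = None,
) -> FastEMCResult:
    """Run the annealing search and assemble the final signature.

    Each outer iteration performs ``n_inner`` mutate/accept steps under the
    fast objective, then scores the current set with the full objective and
    offers it to the best list.  The final signature ranks genes by best-list
    appearance frequency, ties broken by the mean full score of the sets
    containing the gene, then by symbol.
    """
    config = config or FastEMCConfig()
    X, y, classes, genes = data.arrays()
    p = len(genes)
    m = config.init_size
    if p < m:
        raise ValueError(f"pool of {p} genes smaller than init_size {m}")
    rng = np.random.default_rng(config.rng_seed)
    fast_obj, full_obj = _objectives(data, config, config.rng_seed, positive_class)

    current = frozenset(rng.choice(p, size=m, replace=False).tolist())
    current_fast = fast_obj(current)
    best = BestSetList(config.best_list_size)
    rows = []
    degenerate = p == m  # no outside genes to swap in
    for _ in range(config.n_outer):
        accepted = 0
        if not degenerate:
            for _ in range(config.n_inner):
                cand = mutate(current, p, rng)
                cand_fast = fast_obj(cand)
                if accept_move(cand_fast - current_fast, config.gamma, rng):
                    current, current_fast = cand, cand_fast
                    accepted += 1
        full = full_obj(current)
        best.offer(FeatureSet(current, current_fast, full))
        rows.append({"fast_score": current_fast, "full_score": full, "accepted": accepted})

    freq: dict[int, int] = {}
    score_sum: dict[int, float] = {}
    for entry in best.entries:
        for i in entry.features:
            freq[i] = freq.get(i, 0) + 1
            score_sum[i] = score_sum.get(i, 0.0) + entry.full_score
    ranked = sorted(
        freq,
        key=lambda i: (-freq[i], -(score_sum[i] / freq[i]), genes[i]),
    )
    final = [genes[i] for i in ranked[: config.final_signature_size]]
    frequency = pd.Series(
        {genes[i]: freq[i] for i in ranked}, dtype=int, name="frequency"
    )
    return FastEMCResult(
        best_list=best,
        feature_frequency=frequency,
        final_signature=final,
        trace=pd.DataFrame(rows),
        classes=classes,
        genes=genes,
    )


def per_class_classifiers(
    data: LabeledDataset, config: FastEMCConfig | None = None
) -> dict[str, FastEMCResult]:
    """One binary (class vs rest) FastEMC run per class.

    Each run keeps ``final_signature_size // n_classes`` genes so the union
    of the per-class signatures stays within the overall budget.
    """
    config = config or FastEMCConfig()
    classes = data.classes
    X, y, _, _ = data.arrays()
    counts = np.bincount(y)
    if counts.min() < config.cv_folds:
        small = classes[int(counts.argmin())]
        raise ValueError(
            f"class {small!r} has {counts.min()} samples; fewer than cv_folds={config.cv_folds}"
        )
    per_size = max(1, config.final_signature_size // len(classes))
    out: dict[str, FastEMCResult] = {}
    for k, cls in enumerate(classes):
        sub = replace(config, final_signature_size=per_size, rng_seed=config.rng_seed + k)
        binary = data.relabel_binary(cls)
        out[cls] = run_fastemc(binary, sub, positive_class=cls)
    return out


def combine_signatures(results: dict[str, FastEMCResult]) -> list[str]:
    """Union of per-class final signatures, class order then rank order."""
    seen: list[str] = []
    for cls in sorted(results):
        for g in results[cls].final_signature:
            if g not in seen:
                seen.append(g)
    return seen


# ---------------------------------------------------------------------------
# Nearest-centroid classifier on a chosen signature
# ---------------------------------------------------------------------------

@dataclass
class CentroidModel:
    features: list[str]
    classes: list[str]
    centroids: pd.DataFrame  # classes x features


def fit_nearest_centroid(data: LabeledDataset, features: Sequence[str]) -> CentroidModel:
    """Per-class mean profile over the given features (z-scored input)."""
    features = list(features)
    expr = data.expr.subset_genes(features)
    X = expr.values.to_numpy().T
    classes = data.classes
    labels = np.array([data.labels[s] for s in expr.sample_ids])
    centroids = np.stack([X[labels == c].mean(axis=0) for c in classes])
    return CentroidModel(
        features=features,
        classes=classes,
        centroids=pd.DataFrame(centroids, index=classes, columns=features),
    )


def predict_nearest_centroid(
    model: CentroidModel, expr: ExprMatrix
) -> tuple[list[str], pd.DataFrame]:
    """Predicted class per sample plus the per-class distance table.

    Distances are Euclidean on the model's feature space; ties go to the
    first class in the model's class order.
    """
    missing = [f for f in model.features if f not in expr.values.index]
    if missing:
        raise KeyError(f"features absent at prediction time: {missing}")
    X = expr.values.loc[model.features].to_numpy().T  # samples x features
    C = model.centroids.to_numpy()
    d = np.sqrt(((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2))
    dist = pd.DataFrame(d, index=expr.sample_ids, columns=model.classes)
    labels = [model.classes[i] for i in d.argmin(axis=1)]
    return labels, dist


def evaluate_predictions(
    predicted: Sequence[str], truth: Sequence[str], classes: Sequence[str] | None = None
) -> tuple[ConfusionMatrix, float]:
    """Confusion matrix and combined accuracy (diagonal / total)."""
    cm = ConfusionMatrix.from_labels(truth, predicted, classes)
    return cm, cm.accuracy
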