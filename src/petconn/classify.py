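"""Subject classification from connectome adjacency + edge attribution.

Repeated stratified 3-fold cross-validation of the GCN classifier with
perturbation-based edge-ablation saliency, and a logistic-regression
baseline on the standardized edge vector (ridge, lasso, or
stability-weighted lasso whose per-edge L1 penalty grows for unstable
edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import RepeatedStratifiedKFold

from ._rng import child_rng
from .connectome.build import Connectome
from .gcn import GCNConfig, gcn_forward, predict, train_gcn

__all__ = [
    "CVPlan",
    "CVResult",
    "SaliencyMap",
    "cross_validate",
    "edge_saliency",
    "aggregate_saliency",
    "logistic_baseline",
]


@dataclass(frozen=True)
class CVPlan:
    n_folds: int = 3
    n_repeats: int = 9
    stratified: bool = True
    seed: int = 0

    @property
    def n_splits(self) -> int:
        return self.n_folds * self.n_repeats


@dataclass
class SaliencyMap:
    roi_names: tuple[str, ...]
    importance: np.ndarray
    weighting: str = "uniform"

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        if np.any(self.importance < 0):
            raise ValueError("importance must be >= 0")
        if not np.allclose(np.diag(self.importance), 0.0):
            raise ValueError("importance diagonal must be 0")


@dataclass
class CVResult:
    accuracies: np.ndarray
    saliency: SaliencyMap | None = None
    per_split_saliency: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1))


def _labels_to_binary(labels) -> np.ndarray:
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    return np.array([classes.index(l) for l in labels], dtype=float)


def edge_saliency(params: dict, subject: Connectome) -> SaliencyMap:
    """Importance of each present edge = |Δ predicted probability| on ablation.

    Both symmetric entries of the edge are zeroed; edges already absent
    (zero weight) get importance 0.
    """
    a = subject.C.copy()
    np.fill_diagonal(a, 0.0)  # self-loops re-added by normalization
    base = gcn_forward(subject.C, params)
    n = len(subject.roi_names)
    imp = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if subject.C[i, j] == 0:
                continue
            ablated = subject.C.copy()
            ablated[i, j] = ablated[j, i] = 0.0
            imp[i, j] = imp[j, i] = abs(gcn_forward(ablated, params) - base)
    return SaliencyMap(subject.roi_names, imp, weighting="uniform")


def aggregate_saliency(per_split: list[tuple[SaliencyMap, float]]) -> SaliencyMap:
    """Accuracy-weighted average of per-split saliency maps."""
    if not per_split:
        raise ValueError("need at least one saliency map")
    names = per_split[0][0].roi_names
    weights = np.array([acc for _, acc in per_split], dtype=float)
    if np.all(weights == 0):
        warnings.warn("all accuracy weights are zero; using uniform weighting", stacklevel=2)
        weights = np.ones_like(weights)
    weights = weights / weights.sum()
    imp = sum(w * m.importance for (m, _), w in zip(per_split, weights))
    return SaliencyMap(names, imp, weighting="accuracy-weighted")


def cross_validate(
    dataset: list[tuple[Connectome, str]],
    plan: CVPlan,
    config: GCNConfig,
    compute_saliency: bool = True,
    saliency_subjects: str = "positive",
) -> CVResult:
    """Repeated stratified k-fold CV of the GCN; models trained per split.

    Saliency maps are computed on each split's held-out subjects and
    averaged within the fold. ``saliency_subjects`` selects which held-out
    subjects contribute: ``"positive"`` (default) uses the positive-class
    subjects — ablation is run "for a given patient" — while ``"all"``
    averages over every test subject.
    """
    conns = [c for c, _ in dataset]
    y = _labels_to_binary([l for _, l in dataset])
    names = conns[0].roi_names
    adjacencies = [c.C for c in conns]
    counts = np.bincount(y.astype(int))
    if counts.min() < plan.n_folds:
        raise ValueError("a class is too small to stratify into the requested folds")
    splitter = RepeatedStratifiedKFold(
        n_splits=plan.n_folds, n_repeats=plan.n_repeats, random_state=plan.seed
    )
    accuracies = []
    per_split = []
    for split_idx, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        cfg = GCNConfig(
            channels=config.channels,
            mlp_units=config.mlp_units,
            l2_lambda=config.l2_lambda,
            dropout=config.dropout,
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            seed=int(child_rng(config.seed, "cv-split", split_idx).integers(0, 2**31 - 1)),
        )
        params, _ = train_gcn([adjacencies[i] for i in train_idx], y[train_idx], cfg)
        probs = predict(params, [adjacencies[i] for i in test_idx])
        acc = float(np.mean((probs > 0.5) == (y[test_idx] > 0.5)))
        accuracies.append(acc)
        if compute_saliency:
            if saliency_subjects == "positive":
                subjects = [i for i in test_idx if y[i] > 0.5] or list(test_idx)
            else:
                subjects = list(test_idx)
            maps = [edge_saliency(params, conns[i]).importance for i in subjects]
            per_split.append(
                (SaliencyMap(names, np.mean(maps, axis=0)), acc)
            )
    result = CVResult(np.asarray(accuracies), per_split_saliency=per_split)
    if compute_saliency:
        result.saliency = aggregate_saliency(per_split)
    return result


def _edge_features(conns: list[Connectome]) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    n = len(conns[0].roi_names)
    iu = np.triu_indices(n, k=1)
    return np.stack([c.C[iu] for c in conns]), iu


def logistic_baseline(
    dataset: list[tuple[Connectome, str]],
    plan: CVPlan,
    mode: str = "ridge",
    stability: np.ndarray | None = None,
    n_permutations: int = 0,
    seed: int = 0,
) -> tuple[float, float | None, np.ndarray]:
    """Cross-validated logistic baseline on the 78-edge feature vector.

    Returns (mean balanced accuracy, permutation p-value or None,
    per-edge |coefficient| importance matrix). In stability-weighted mode
    each edge's L1 penalty is scaled by 1 / max(rho_l, 0.1) where rho_l is
    the edge's mean stability, implemented by rescaling features before a
    standard lasso.
    """
    if mode not in ("ridge", "lasso", "stability_weighted_lasso"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "stability_weighted_lasso" and stability is None:
        raise ValueError("stability matrix required for stability_weighted_lasso")
    conns = [c for c, _ in dataset]
    y = _labels_to_binary([l for _, l in dataset])
    names = conns[0].roi_names
    X, iu = _edge_features(conns)

    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant edge features", stacklevel=2)
    X = X[:, keep]

    stability_factor = None
    if mode == "stability_weighted_lasso":
        rho = np.asarray(stability, dtype=float)[iu][keep]
        stability_factor = np.maximum(rho, 0.1)

    def cv_balanced_accuracy(y_in: np.ndarray) -> tuple[float, np.ndarray]:
        splitter = RepeatedStratifiedKFold(
            n_splits=plan.n_folds, n_repeats=plan.n_repeats, random_state=plan.seed
        )
        accs, coefs = [], []
        for train_idx, test_idx in splitter.split(X, y_in):
            mu = X[train_idx].mean(axis=0)
            sd = X[train_idx].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (X[train_idx] - mu) / sd
            Xte = (X[test_idx] - mu) / sd
            if stability_factor is not None:
                Xtr = Xtr * stability_factor
                Xte = Xte * stability_factor
            l1_ratio = 0.0 if mode == "ridge" else 1.0
            clf = LogisticRegression(C=1.0, l1_ratio=l1_ratio, solver="liblinear", max_iter=2000)
            clf.fit(Xtr, y_in[train_idx])
            accs.append(balanced_accuracy_score(y_in[test_idx], clf.predict(Xte)))
            beta = clf.coef_[0].copy()
            if stability_factor is not None:
                beta = beta * stability_factor  # map back to unscaled features
            coefs.append(np.abs(beta))
        return float(np.mean(accs)), np.mean(coefs, axis=0)

    observed, coef_mean = cv_balanced_accuracy(y)

    p_value = None
    if n_permutations > 0:
        rng = child_rng(seed, "logistic-permutation")
        exceed = 0
        for _ in range(n_permutations):
            perm_acc, _ = cv_balanced_accuracy(rng.permutation(y))
            if perm_acc >= observed:
                exceed += 1
        p_value = (1 + exceed) / (n_permutations + 1)

    n = len(names)
    coef_full = np.zeros(len(keep))
    coef_full[keep] = coef_mean
    imp = np.zeros((n, n))
    imp[iu] = coef_full
    imp = imp + imp.T
    return observed, p_value, imp
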