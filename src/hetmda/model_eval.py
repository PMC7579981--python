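"""Classifier training, metrics and the leakage-controlled CV protocol.

The classifier is gradient-boosted trees (XGBoost) with learning rate 0.15,
650 boosting rounds and maximum tree depth 4; random forest, RBF-kernel SVM
and sklearn gradient tree boosting are available through the same hook for
comparison runs.

Cross-validation removes each validation fold's known miRNA-disease
association edges from the network and re-extracts every feature vector
(diffusion embeddings and HeteSim scores) from the modified network before
training, so a validation pair's label can never leak into its own features
through the association block.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import diffusion as _diffusion
from . import featurize as _featurize
from . import hetesim as _hetesim
from .hetnet import HetNet

__all__ = [
    "ModelConfig",
    "CVReport",
    "make_folds",
    "metrics",
    "auc",
    "train",
    "predict",
    "cv_with_reextraction",
]

CLASSIFIERS = ("xgboost", "rf", "svm", "gtb")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the boosted-tree model (other parameters stay at
    library defaults)."""

    learning_rate: float = 0.15
    n_rounds: int = 650
    max_depth: int = 4
    classifier: str = "xgboost"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(
                f"classifier must be one of {CLASSIFIERS}, got {self.classifier!r}"
            )


def train(features: np.ndarray, labels: np.ndarray, config: ModelConfig):
    """Fit the configured classifier; returns the fitted estimator."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2 or features.shape[0] != labels.shape[0]:
        raise ValueError("features must be 2-D with one row per label")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if config.classifier == "xgboost":
        model = XGBClassifier(
            learning_rate=config.learning_rate,
            n_estimators=config.n_rounds,
            max_depth=config.max_depth,
            random_state=config.seed,
            n_jobs=1,
            tree_method="hist",
        )
    elif config.classifier == "rf":
        model = RandomForestClassifier(random_state=config.seed, n_jobs=1)
    elif config.classifier == "svm":
        model = SVC(kernel="rbf", probability=True, random_state=config.seed)
    else:  # gtb
        model = GradientBoostingClassifier(
            learning_rate=config.learning_rate,
            n_estimators=config.n_rounds,
            max_depth=config.max_depth,
            random_state=config.seed,
        )
    model.fit(features, labels)
    model._n_features_expected = features.shape[1]
    return model


def predict(model, features: np.ndarray) -> np.ndarray:
    """Positive-class probability for each feature row, in [0, 1]."""
    features = np.asarray(features, dtype=float)
    expected = getattr(model, "_n_features_expected", features.shape[1])
    if features.shape[1] != expected:
        raise ValueError(
            f"feature width {features.shape[1]} does not match training width {expected}"
        )
    scores = model.predict_proba(features)[:, 1]
    return np.clip(scores, 0.0, 1.0)


def metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Precision, recall, accuracy and F-score at a score threshold.

    A degenerate denominator (no predicted positives for precision, no actual
    positives for recall, both zero for F-score) yields 0 with a warning.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    preds = (scores >= threshold).astype(int)
    tp = int(np.sum((preds == 1) & (labels == 1)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    tn = int(np.sum((preds == 0) & (labels == 0)))

    def ratio(num: int, denom: int, name: str) -> float:
        if denom == 0:
            warnings.warn(f"{name} undefined (zero denominator); reported as 0", stacklevel=3)
            return 0.0
        return num / denom

    pre = ratio(tp, tp + fp, "PRE")
    rec = ratio(tp, tp + fn, "REC")
    acc = (tp + tn) / len(labels) if len(labels) else 0.0
    fsc = _fscore(pre, rec)
    return {"PRE": pre, "REC": rec, "ACC": acc, "FSC": fsc}


def _fscore(pre: float, rec: float) -> float:
    if pre + rec == 0:
        return 0.0
    return 2 * pre * rec / (pre + rec)


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (concordance probability, ties count 1/2)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes to be present")
    return float(roc_auc_score(labels, scores))


def make_folds(
    positives: Sequence, negatives: Sequence, k: int = 10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Assign positives and negatives each to k folds.

    Each class is shuffled, then split into k - 1 folds of floor(n/k) items
    and a final fold holding the remainder (so 11824 positives give nine
    folds of 1182 and a tenth of 1186).  Returns per-item fold indices for
    positives and for negatives.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)

    def assign(n: int) -> np.ndarray:
        if n < k:
            raise ValueError(f"cannot split {n} samples into {k} folds")
        base = n // k
        folds = np.empty(n, dtype=int)
        order = rng.permutation(n)
        for f in range(k - 1):
            folds[order[f * base : (f + 1) * base]] = f
        folds[order[(k - 1) * base :]] = k - 1
        return folds

    return assign(len(positives)), assign(len(negatives))


@dataclass
class CVReport:
    """Per-fold and mean evaluation of the cross-validated pipeline."""

    fold_metrics: list[dict[str, float]]
    mean_metrics: dict[str, float]
    fold_sizes: list[dict[str, int]]
    roc_curves: list[dict[str, list[float]]]
    seeds: dict[str, int]
    config: dict
    feature_set: str
    network_fingerprint: str
    leakage_checked: bool

    @property
    def mean_auc(self) -> float:
        return self.mean_metrics["AUC"]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


_FEATURE_SETS = ("combined", "diffusion", "hetesim")


def _select_features(features: np.ndarray, k: int, feature_set: str) -> np.ndarray:
    if feature_set == "combined":
        return features
    if feature_set == "diffusion":
        return features[:, : 2 * k]
    if feature_set == "hetesim":
        return features[:, 2 * k :]
    raise ValueError(f"feature_set must be one of {_FEATURE_SETS}, got {feature_set!r}")


def cv_with_reextraction(
    net: HetNet,
    positives: Sequence[tuple[int, int]],
    negatives: Sequence[tuple[int, int]],
    config: ModelConfig | None = None,
    k: int = 10,
    seed: int = 0,
    *,
    svd_k: int = _diffusion.DEFAULT_SVD_K,
    alpha: float = _diffusion.DEFAULT_ALPHA,
    tol: float = _diffusion.DEFAULT_TOL,
    max_iter: int = _diffusion.DEFAULT_MAX_ITER,
    feature_set: str = "combined",
    label_permutation_seed: int | None = None,
) -> CVReport:
    """k-fold cross-validation with per-fold feature re-extraction.

    For each fold the validation positives' association edges are deleted
    from the miRNA-disease block, diffusion embeddings and HeteSim features
    are recomputed on the modified network, all pair feature vectors are
    rebuilt from it, the classifier is fitted on the other k - 1 folds and
    scored on the held-out fold.  The original network is never mutated.

    ``feature_set`` restricts the classifier to the diffusion or HeteSim
    columns for ablation runs.  ``label_permutation_seed`` permutes the 0/1
    labels across all pairs (features and the edge-removal protocol
    untouched), giving a shuffled-label null whose AUC should sit near 0.5.
    """
    if config is None:
        config = ModelConfig(seed=seed)
    if feature_set not in _FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {_FEATURE_SETS}, got {feature_set!r}")
    positives = [(int(i), int(j)) for i, j in positives]
    negatives = [(int(i), int(j)) for i, j in negatives]
    for i, j in positives:
        if net.C[i, j] == 0:
            raise ValueError(
                f"positive pair ({net.mirna_ids[i]}, {net.disease_ids[j]}) is not an "
                "edge of the miRNA-disease block"
            )

    pos_folds, neg_folds = make_folds(positives, negatives, k=k, seed=seed)
    all_pairs = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    if label_permutation_seed is not None:
        labels = np.random.default_rng(label_permutation_seed).permutation(labels)
    fold_of_pair = np.concatenate([pos_folds, neg_folds])
    id_pairs = [(net.mirna_ids[i], net.disease_ids[j]) for i, j in all_pairs]

    fold_metrics: list[dict[str, float]] = []
    fold_sizes: list[dict[str, int]] = []
    roc_curves: list[dict[str, list[float]]] = []
    for fold in range(k):
        val_mask = fold_of_pair == fold
        val_positives = [p for p, f in zip(positives, pos_folds) if f == fold]
        fold_net = net.without_md_edges(val_positives)
        for i, j in val_positives:  # leakage invariant, checked every fold
            assert fold_net.C[i, j] == 0.0, "validation edge survived removal"

        embedding = _diffusion.embed_network(
            fold_net, k=svd_k, alpha=alpha, tol=tol, max_iter=max_iter
        )
        hfeat = _hetesim.hetesim_features(fold_net)
        table = _featurize.pair_features(embedding, hfeat, id_pairs)
        X = _select_features(table.features, embedding.k, feature_set)

        model = train(X[~val_mask], labels[~val_mask], config)
        scores = predict(model, X[val_mask])
        y_val = labels[val_mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate folds report 0s
            fm = metrics(y_val, scores)
        fm["AUC"] = auc(y_val, scores)
        fold_metrics.append(fm)
        fold_sizes.append(
            {
                "train": int((~val_mask).sum()),
                "validation": int(val_mask.sum()),
                "validation_positives": int(y_val.sum()),
            }
        )
        fpr, tpr, _ = roc_curve(y_val, scores)
        roc_curves.append({"FPR": fpr.tolist(), "TPR": tpr.tolist()})

    mean_metrics = {
        key: float(np.mean([fm[key] for fm in fold_metrics]))
        for key in fold_metrics[0]
    }
    return CVReport(
        fold_metrics=fold_metrics,
        mean_metrics=mean_metrics,
        fold_sizes=fold_sizes,
        roc_curves=roc_curves,
        seeds={
            "cv_seed": seed,
            "model_seed": config.seed,
            **(
                {"label_permutation_seed": label_permutation_seed}
                if label_permutation_seed is not None
                else {}
            ),
        },
        config=asdict(config),
        feature_set=feature_set,
        network_fingerprint=net.fingerprint(),
        leakage_checked=True,
    )
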