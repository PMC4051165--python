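"""Surrogate base classifiers and the 4-decision committee.

Four base classifiers mirror the published committee composition:

====================  ================  ==============
surrogate             learning algo     feature space
====================  ================  ==============
triplet_svm_like      RBF-SVM           triplet32
mipred_like           random forest     hybrid34
virgo_like            RBF-SVM           seqstruct512
eumir_like            RBF-SVM           seqstruct512
====================  ================  ==============

The original published models are unavailable, so surrogates with the same
algorithm/feature-space pairing are trained on user-supplied or synthetic
corpora.  The two 512-dimensional surrogates differ only in training corpus
(mirroring viral vs. broad-eukaryote provenance); on synthetic data they are
trained on disjoint subsets.  Each classifier contributes a hard decision in
{-1, +1} (sign of its margin; ties map to +1) and the four decisions, in the
fixed order above, form the input vector of the fusion network.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .feature_extraction import FeatureBundle, build_feature_bundle
from .structure_fold import FoldResult

FEATURE_SPACES = ("triplet32", "hybrid34", "seqstruct512")
SPACE_DIMS = {"triplet32": 32, "hybrid34": 34, "seqstruct512": 512}

#: fixed committee order; index i feeds fusion-network input i
COMMITTEE_ORDER = ("triplet_svm_like", "mipred_like", "virgo_like", "eumir_like")
COMMITTEE_SPACES = ("triplet32", "hybrid34", "seqstruct512", "seqstruct512")

MODEL_FORMAT_VERSION = 1


class CommitteeError(ValueError):
    pass


class DegenerateTrainingError(CommitteeError):
    """Training data with fewer than two samples in some class."""


class InvalidHyperparameterError(CommitteeError):
    pass


class SpaceMismatchError(CommitteeError):
    """Features presented to a model of a different feature space."""


@dataclass
class LabeledDataset:
    """A feature matrix with +-1 labels, tagged by feature space."""

    features: np.ndarray
    labels: np.ndarray
    feature_space: str

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.feature_space not in FEATURE_SPACES:
            raise CommitteeError(f"unknown feature space {self.feature_space!r}")
        if self.features.ndim != 2:
            raise CommitteeError("feature matrix must be 2-D")
        if self.features.shape[1] != SPACE_DIMS[self.feature_space]:
            raise SpaceMismatchError(
                f"{self.feature_space} expects "
                f"{SPACE_DIMS[self.feature_space]} columns, "
                f"got {self.features.shape[1]}"
            )
        if self.labels.shape != (self.features.shape[0],):
            raise CommitteeError("label/row count mismatch")
        if not np.isin(self.labels, (-1, 1)).all():
            raise CommitteeError("labels must be -1 or +1")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]


@dataclass
class BaseModel:
    """A fitted surrogate classifier with its training metadata."""

    kind: str  # "svm-rbf" | "random-forest"
    feature_space: str
    estimator: object
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DecisionVector:
    """The ordered 4-tuple of base decisions (and margins) for one sample."""

    decisions: tuple  # each in {-1, +1}, COMMITTEE_ORDER
    scores: tuple | None = None

    def __post_init__(self) -> None:
        if len(self.decisions) != 4 or any(
            d not in (-1, 1) for d in self.decisions
        ):
            raise CommitteeError("decisions must be a 4-tuple over {-1, +1}")
        if self.scores is not None and len(self.scores) != 4:
            raise CommitteeError("scores must be a 4-tuple when present")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.decisions, dtype=float)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _check_two_classes(data: LabeledDataset) -> None:
    n_pos = int(np.sum(data.labels == 1))
    n_neg = int(np.sum(data.labels == -1))
    if n_pos < 2 or n_neg < 2:
        raise DegenerateTrainingError(
            f"need >= 2 samples per class, got {n_pos} positive / {n_neg} negative"
        )


def train_svm(
    data: LabeledDataset,
    gamma: float | str = "auto",
    cost: float = 1.0,
    seed: int = 0,
) -> BaseModel:
    """Fit an RBF-kernel SVM surrogate.

    ``gamma="auto"`` is 1/n_features; ``cost`` is the soft-margin C.
    Training accuracy is recorded in the model metadata.
    """
    _check_two_classes(data)
    if cost <= 0:
        raise InvalidHyperparameterError("cost must be positive")
    est = SVC(kernel="rbf", C=cost, gamma=gamma, random_state=seed)
    est.fit(data.features, data.labels)
    acc = float(np.mean(est.predict(data.features) == data.labels))
    return BaseModel(
        kind="svm-rbf",
        feature_space=data.feature_space,
        estimator=est,
        metadata={
            "seed": seed,
            "gamma": gamma,
            "cost": cost,
            "n_samples": data.n_samples,
            "training_accuracy": acc,
        },
    )


def train_rf(
    data: LabeledDataset, n_trees: int = 500, seed: int = 0
) -> BaseModel:
    """Fit a random-forest surrogate (hybrid34 features by convention)."""
    _check_two_classes(data)
    if n_trees < 1:
        raise InvalidHyperparameterError("n_trees must be >= 1")
    est = RandomForestClassifier(
        n_estimators=n_trees, oob_score=data.n_samples >= 10, random_state=seed
    )
    est.fit(data.features, data.labels)
    acc = float(np.mean(est.predict(data.features) == data.labels))
    meta = {
        "seed": seed,
        "n_trees": n_trees,
        "n_samples": data.n_samples,
        "training_accuracy": acc,
    }
    if est.oob_score:
        meta["oob_error"] = 1.0 - float(est.oob_score_)
    return BaseModel(
        kind="random-forest",
        feature_space=data.feature_space,
        estimator=est,
        metadata=meta,
    )


def train_svm_best_specificity(
    data: LabeledDataset, k: int = 5, seed: int = 0, **svm_kwargs
) -> BaseModel:
    """K-fold model selection keeping the fold-model of best specificity.

    Optional training mode for the 512-dim surrogates: the data are split
    into *k* folds; one SVM is trained per training split and the model with
    the highest validation specificity (ties -> higher accuracy) is kept.
    """
    from sklearn.model_selection import StratifiedKFold

    _check_two_classes(data)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    best = None
    for fold_i, (tr, va) in enumerate(
        skf.split(data.features, data.labels)
    ):
        sub = LabeledDataset(
            data.features[tr], data.labels[tr], data.feature_space
        )
        model = train_svm(sub, seed=seed, **svm_kwargs)
        pred = model.estimator.predict(data.features[va])
        neg = data.labels[va] == -1
        specificity = (
            float(np.mean(pred[neg] == -1)) if neg.any() else 0.0
        )
        accuracy = float(np.mean(pred == data.labels[va]))
        key = (specificity, accuracy)
        if best is None or key > best[0]:
            model.metadata.update(
                {"selection": "max-specificity", "fold": fold_i,
                 "val_specificity": specificity}
            )
            best = (key, model)
    return best[1]


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _margin(model: BaseModel, X: np.ndarray) -> np.ndarray:
    est = model.estimator
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    # forest: signed vote margin P(+1) - P(-1)
    proba = est.predict_proba(X)
    classes = list(est.classes_)
    return np.asarray(
        proba[:, classes.index(1)] - proba[:, classes.index(-1)], dtype=float
    )


def predict_scores(model: BaseModel, X) -> np.ndarray:
    """Real-valued margins for the rows of a feature matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != SPACE_DIMS[model.feature_space]:
        raise SpaceMismatchError(
            f"model expects {model.feature_space} "
            f"({SPACE_DIMS[model.feature_space]} features), got {X.shape[1]}"
        )
    return _margin(model, X)


def predict_decision(model: BaseModel, features) -> tuple[int, float]:
    """Hard decision and margin for one feature vector (ties -> +1)."""
    score = float(predict_scores(model, features)[0])
    return (1 if score >= 0 else -1), score


def _bundle_vector(bundle: FeatureBundle, space: str) -> np.ndarray:
    return getattr(bundle, space)


def committee_decisions(
    fold_result: FoldResult,
    models,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
) -> DecisionVector:
    """Run all four base classifiers on one folded sequence.

    *models* must be given in :data:`COMMITTEE_ORDER`, with feature spaces
    matching :data:`COMMITTEE_SPACES`.  The feature bundle is built once.
    """
    models = list(models)
    if len(models) != 4:
        raise CommitteeError("the committee has exactly 4 models")
    for model, space in zip(models, COMMITTEE_SPACES):
        if model.feature_space != space:
            raise SpaceMismatchError(
                f"expected committee spaces {COMMITTEE_SPACES}, "
                f"got a {model.feature_space} model out of order"
            )
    bundle = build_feature_bundle(fold_result, n_shuffles=n_shuffles, rng=rng)
    decisions = []
    scores = []
    for model, space in zip(models, COMMITTEE_SPACES):
        d, s = predict_decision(model, _bundle_vector(bundle, space))
        decisions.append(d)
        scores.append(s)
    return DecisionVector(decisions=tuple(decisions), scores=tuple(scores))


def committee_decision_matrix(bundles, models) -> np.ndarray:
    """(n, 4) hard-decision matrix for many precomputed feature bundles."""
    models = list(models)
    if len(models) != 4:
        raise CommitteeError("the committee has exactly 4 models")
    cols = []
    for model, space in zip(models, COMMITTEE_SPACES):
        X = np.vstack([_bundle_vector(b, space) for b in bundles])
        margins = predict_scores(model, X)
        cols.append(np.where(margins >= 0, 1, -1))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# persistence: versioned pickle with a header dict
# ---------------------------------------------------------------------------

def save_model(model: BaseModel, path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": model.kind,
        "feature_space": model.feature_space,
        "metadata": model.metadata,
        "estimator": model.estimator,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path, expect_space: str | None = None) -> BaseModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise CommitteeError(f"unsupported model format in {path}")
    model = BaseModel(
        kind=payload["kind"],
        feature_space=payload["feature_space"],
        estimator=payload["estimator"],
        metadata=payload["metadata"],
    )
    if expect_space is not None and model.feature_space != expect_space:
        raise SpaceMismatchError(
            f"model in {path} is {model.feature_space}, expected {expect_space}"
        )
    return model


def train_committee(
    datasets: dict, seed: int = 0, best_specificity: bool = False
) -> list[BaseModel]:
    """Train the four surrogates from per-space labeled datasets.

    *datasets* maps feature-space tags to :class:`LabeledDataset`.  The
    seqstruct512 dataset is split into two disjoint halves (stratified by
    label) so the virgo-like and eumir-like surrogates see different
    corpora, as the originals did.
    """
    for space in FEATURE_SPACES:
        if space not in datasets:
            raise CommitteeError(f"missing dataset for {space}")
    rng = np.random.default_rng(seed)
    models = [
        train_svm(datasets["triplet32"], seed=seed),
        train_rf(datasets["hybrid34"], seed=seed),
    ]
    big = datasets["seqstruct512"]
    halves = ([], [])
    for label in (-1, 1):
        idx = np.flatnonzero(big.labels == label)
        idx = idx[rng.permutation(idx.size)]
        halves[0].extend(idx[: idx.size // 2])
        halves[1].extend(idx[idx.size // 2 :])
    trainer = train_svm_best_specificity if best_specificity else train_svm
    for half in halves:
        half = np.sort(np.asarray(half))
        sub = LabeledDataset(
            big.features[half], big.labels[half], "seqstruct512"
        )
        models.append(trainer(sub, seed=seed))
    for model, name in zip(models, COMMITTEE_ORDER):
        model.metadata["committee_role"] = name
    return models
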