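"""Gaussian naive Bayes subgroup classifier over pathway scores.

The subgroup labels discovered by unsupervised clustering are turned into
a supervised model: class priors from training frequencies and one
Gaussian per (class, pathway) with a floored variance, assuming
conditional independence of pathways given the class.  Generalization is
assessed by stratified 10-fold cross-validation.  Models serialize to
JSON so a trained pathway panel can be applied to new cohorts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from sialonet.errors import ValidationError

logger = logging.getLogger(__name__)

#: relative variance floor (fraction of each feature's global variance)
VAR_FLOOR_FRACTION = 1e-9


@dataclass
class NBModel:
    classes: list[str]
    priors: np.ndarray  # (n_class,)
    means: np.ndarray  # (n_class, n_feature)
    variances: np.ndarray  # (n_class, n_feature), floored > 0
    features: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": self.classes,
            "priors": self.priors.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "features": self.features,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "NBModel":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(
            classes=list(payload["classes"]),
            priors=np.asarray(payload["priors"], dtype=float),
            means=np.asarray(payload["means"], dtype=float),
            variances=np.asarray(payload["variances"], dtype=float),
            features=list(payload["features"]),
        )


def train_nb(scores: pd.DataFrame, labels: pd.Series) -> NBModel:
    """Fit class-conditional Gaussians per feature.

    ``scores`` is samples x features (e.g. the transposed pathway score
    matrix); ``labels`` maps each sample to its subgroup.
    """
    labels = labels.loc[scores.index].astype(str)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValidationError("training needs >= 2 classes")
    for cls in classes:
        if (labels == cls).sum() < 2:
            raise ValidationError(f"class {cls!r} has < 2 training samples")
    values = scores.to_numpy(dtype=float)
    global_var = values.var(axis=0, ddof=0)
    floor = np.maximum(VAR_FLOOR_FRACTION * global_var, 1e-12)
    priors = np.array([(labels == c).mean() for c in classes])
    means = np.vstack(
        [values[(labels == c).to_numpy()].mean(axis=0) for c in classes]
    )
    variances = np.vstack(
        [
            np.maximum(values[(labels == c).to_numpy()].var(axis=0, ddof=0), floor)
            for c in classes
        ]
    )
    return NBModel(
        classes=classes,
        priors=priors,
        means=means,
        variances=variances,
        features=list(scores.columns),
    )


def predict_nb(
    model: NBModel, scores: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Class labels and normalized posterior probabilities per sample.

    Ties in the joint log-likelihood resolve to the earlier class in the
    model's class order.
    """
    missing = [f for f in model.features if f not in scores.columns]
    if missing:
        raise ValidationError(f"missing feature(s): {missing[:5]}")
    x = scores[model.features].to_numpy(dtype=float)
    log_like = np.empty((x.shape[0], len(model.classes)))
    for i in range(len(model.classes)):
        mu, var = model.means[i], model.variances[i]
        log_density = -0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var)
        log_like[:, i] = np.log(model.priors[i]) + log_density.sum(axis=1)
    shifted = log_like - log_like.max(axis=1, keepdims=True)
    posterior = np.exp(shifted)
    posterior /= posterior.sum(axis=1, keepdims=True)
    winner = log_like.argmax(axis=1)  # argmax takes the first on ties
    labels = pd.Series(
        [model.classes[i] for i in winner], index=scores.index, name="predicted"
    )
    post_df = pd.DataFrame(posterior, index=scores.index, columns=model.classes)
    return labels, post_df


@dataclass
class CVResult:
    fold_accuracy: list[float]
    mean_accuracy: float
    fold_assignment: pd.Series  # sample -> fold index


def cv10(
    scores: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    n_folds: int = 10,
) -> CVResult:
    """Stratified k-fold cross-validated accuracy of the classifier.

    Falls back to unstratified folds (with a warning) when a class has
    fewer members than the fold count.
    """
    labels = labels.loc[scores.index].astype(str)
    if scores.shape[0] < n_folds:
        raise ValidationError(
            f"need >= {n_folds} samples for {n_folds}-fold CV, got {scores.shape[0]}"
        )
    class_counts = labels.value_counts()
    if (class_counts < n_folds).any():
        logger.warning(
            "class smaller than fold count; using plain (unstratified) folds"
        )
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(scores)
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(scores, labels)
    accuracies = []
    assignment = pd.Series(index=scores.index, dtype=int, name="fold")
    for fold, (train_idx, test_idx) in enumerate(splits):
        model = train_nb(scores.iloc[train_idx], labels.iloc[train_idx])
        predicted, _ = predict_nb(model, scores.iloc[test_idx])
        truth = labels.iloc[test_idx]
        accuracies.append(float((predicted.to_numpy() == truth.to_numpy()).mean()))
        assignment.iloc[test_idx] = fold
    return CVResult(
        fold_accuracy=accuracies,
        mean_accuracy=float(np.mean(accuracies)),
        fold_assignment=assignment,
    )
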