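"""Random-subspace tree ensemble with hard-vote aggregation.

The classifier is a forest of 100 fully grown decision trees, each trained
on a bootstrap resample of the training set; at each split 22 randomly drawn
candidate features are considered (the random subspace, ~ sqrt(500) for the
default encoding).  The score of a sample is the fraction of trees voting
positive, so with hard votes it is a multiple of 1/n_trees; the decision
threshold is 0.5, with ties called positive.

An alternative per-tree subspace mode (each tree restricted to one fixed
random 22-feature subset) is available for fidelity experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import IncompatibilityError, InputError

MODEL_FORMAT_VERSION = 1

DEFAULT_N_TREES = 100
DEFAULT_SUBSPACE_DIM = 22


@dataclass(frozen=True)
class ForestConfig:
    """Ensemble hyperparameters: tree count, subspace dimension, seed, bootstrap."""

    n_trees: int = DEFAULT_N_TREES
    subspace_dim: int = DEFAULT_SUBSPACE_DIM
    seed: int = 0
    bootstrap: bool = True
    subspace_mode: str = "split"  # "split": per-split candidates; "tree": fixed per-tree subset

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise InputError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.subspace_dim < 1:
            raise InputError(f"subspace_dim must be >= 1, got {self.subspace_dim}")
        if self.subspace_mode not in ("split", "tree"):
            raise InputError(f"subspace_mode must be 'split' or 'tree', got {self.subspace_mode}")


class VoteForestClassifier(ClassifierMixin, BaseEstimator):
    """Bootstrap tree ensemble scored by the fraction of positive votes.

    Parameters
    ----------
    n_trees : int, default=100
        Number of trees in the forest.
    subspace_dim : int, default=22
        Random-subspace dimension.  In ``subspace_mode="split"`` (default)
        this many candidate features are evaluated at every split; in
        ``"tree"`` mode each tree sees one fixed random subset of this size.
    bootstrap : bool, default=True
        Train each tree on a with-replacement resample of the data.
    random_state : int, default=0
        Seed; training is deterministic given (X, y, random_state).
    threshold : float, default=0.5
        Vote fraction at or above which a sample is called positive.
    subspace_mode : {"split", "tree"}, default="split"

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    n_features_in_ : int
    forest_ : fitted ensemble (mode "split") or list of (features, tree)
        pairs (mode "tree").

    Trees are grown to purity (no depth or leaf-size limits).
    """

    def __init__(
        self,
        n_trees: int = DEFAULT_N_TREES,
        subspace_dim: int = DEFAULT_SUBSPACE_DIM,
        bootstrap: bool = True,
        random_state: int = 0,
        threshold: float = 0.5,
        subspace_mode: str = "split",
    ) -> None:
        self.n_trees = n_trees
        self.subspace_dim = subspace_dim
        self.bootstrap = bootstrap
        self.random_state = random_state
        self.threshold = threshold
        self.subspace_mode = subspace_mode

    @classmethod
    def from_config(cls, config: ForestConfig, threshold: float = 0.5) -> "VoteForestClassifier":
        return cls(
            n_trees=config.n_trees,
            subspace_dim=config.subspace_dim,
            bootstrap=config.bootstrap,
            random_state=config.seed,
            threshold=threshold,
            subspace_mode=config.subspace_mode,
        )

    def fit(self, X, y) -> "VoteForestClassifier":
        X, y = validate_data(self, X, y)
        classes = np.unique(y)
        if classes.size != 2:
            raise InputError(f"need exactly two classes in y, got {classes.size}")
        if X.shape[0] < 2:
            raise InputError("need at least two samples")
        if not 1 <= self.subspace_dim <= X.shape[1]:
            raise InputError(
                f"subspace_dim={self.subspace_dim} outside [1, {X.shape[1]}]"
            )
        if self.subspace_mode not in ("split", "tree"):
            raise InputError(f"subspace_mode must be 'split' or 'tree', got {self.subspace_mode}")
        self.classes_ = classes
        if self.subspace_mode == "split":
            self.forest_ = RandomForestClassifier(
                n_estimators=self.n_trees,
                max_features=self.subspace_dim,
                bootstrap=self.bootstrap,
                random_state=self.random_state,
                n_jobs=1,
            ).fit(X, y)
        else:
            rng = np.random.default_rng(self.random_state)
            members = []
            for _ in range(self.n_trees):
                feats = np.sort(rng.choice(X.shape[1], size=self.subspace_dim, replace=False))
                rows = (
                    rng.integers(0, X.shape[0], size=X.shape[0])
                    if self.bootstrap
                    else np.arange(X.shape[0])
                )
                if np.unique(y[rows]).size < 2:  # degenerate bootstrap: redraw once
                    rows = np.arange(X.shape[0])
                tree = DecisionTreeClassifier(
                    random_state=int(rng.integers(0, 2**31 - 1))
                ).fit(X[rows][:, feats], y[rows])
                members.append((feats, tree))
            self.forest_ = members
        return self

    def _votes(self, X) -> np.ndarray:
        """Fraction of trees voting for the positive (larger) class label."""
        check_is_fitted(self, "forest_")
        X = validate_data(self, X, reset=False)
        pos = self.classes_[1]
        if self.subspace_mode == "split":
            votes = np.mean(
                [t.predict(X) == pos for t in self.forest_.estimators_], axis=0
            )
        else:
            votes = np.mean([t.predict(X[:, f]) == pos for f, t in self.forest_], axis=0)
        return votes

    def predict_proba(self, X) -> np.ndarray:
        """Column-stacked [P(neg), P(pos)] where P(pos) is the vote fraction."""
        v = self._votes(X)
        return np.column_stack([1.0 - v, v])

    def decision_function(self, X) -> np.ndarray:
        return self._votes(X)

    def predict(self, X) -> np.ndarray:
        """Positive iff vote fraction >= threshold (ties at the threshold are positive)."""
        if not 0.0 <= self.threshold <= 1.0:
            raise InputError(f"threshold must be within [0, 1], got {self.threshold}")
        v = self._votes(X)
        return np.where(v >= self.threshold, self.classes_[1], self.classes_[0])


# ---------------------------------------------------------------------------
# Functional wrappers and model persistence


@dataclass
class ForestModel:
    """A fitted ensemble plus the metadata needed to apply it safely."""

    estimator: VoteForestClassifier
    feature_dim: int
    config: ForestConfig
    layout_version: str = ""
    property_checksum: str = ""


def train(
    X,
    y,
    config: ForestConfig | None = None,
    layout_version: str = "",
    property_checksum: str = "",
) -> ForestModel:
    """Fit the vote forest; deterministic given (X, y, config.seed)."""
    config = config or ForestConfig()
    X = np.asarray(X)
    est = VoteForestClassifier.from_config(config).fit(X, y)
    return ForestModel(
        estimator=est,
        feature_dim=X.shape[1],
        config=config,
        layout_version=layout_version,
        property_checksum=property_checksum,
    )


def _check_compatible(model: ForestModel, X, layout_version=None, property_checksum=None) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != model.feature_dim:
        raise IncompatibilityError(
            f"model expects {model.feature_dim} features, input has "
            f"{X.shape[1] if X.ndim == 2 else 'non-matrix shape'}"
        )
    if layout_version is not None and model.layout_version and layout_version != model.layout_version:
        raise IncompatibilityError(
            f"feature layout {layout_version!r} != model layout {model.layout_version!r}"
        )
    if (
        property_checksum is not None
        and model.property_checksum
        and property_checksum != model.property_checksum
    ):
        raise IncompatibilityError("property-table checksum differs from the one the model was trained with")
    return X


def predict_proba(model: ForestModel, X, **compat) -> np.ndarray:
    """Vote-fraction scores in [0, 1] for the positive class."""
    X = _check_compatible(model, X, **compat)
    return model.estimator.predict_proba(X)[:, 1]


def predict(model: ForestModel, X, threshold: float = 0.5, **compat) -> np.ndarray:
    """Hard labels at the given vote-fraction threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise InputError(f"threshold must be within [0, 1], got {threshold}")
    X = _check_compatible(model, X, **compat)
    scores = model.estimator.predict_proba(X)[:, 1]
    return (scores >= threshold).astype(int)


def save_model(model: ForestModel, path: str | Path) -> None:
    """Serialize a model with a versioned metadata header."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_dim": model.feature_dim,
        "config": model.config,
        "layout_version": model.layout_version,
        "property_checksum": model.property_checksum,
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> ForestModel:
    """Load a model saved by :func:`save_model`."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # joblib raises a zoo of unpickling errors
        raise InputError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise InputError(f"{path} is not a recognized model file")
    return ForestModel(
        estimator=payload["estimator"],
        feature_dim=payload["feature_dim"],
        config=payload["config"],
        layout_version=payload["layout_version"],
        property_checksum=payload["property_checksum"],
    )
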