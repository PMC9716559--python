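"""Per-residue error classification.

The final feature set is fixed to seven weakly-correlated validation
metrics (Accuracy, FP rate, smoothed Sensitivity, smoothed wRMSD and the
spatial Z-scores of Accuracy, Sensitivity and wRMSD) plus the residue's
relative solvent accessibility and a one-hot secondary-structure
encoding — 11 numbers per residue.  A linear-kernel SVM is trained on a
class-balanced 80:20 split with a seeded 200-iteration random
hyperparameter search scored by cross-validated mean accuracy; decision
values are turned into probabilities by Platt (sigmoid) calibration on
out-of-fold predictions.  ``correlation_prune`` ships as the reusable
utility that produced the fixed feature set; it is not re-run at
inference time.

The trained model is serialized as a single versioned JSON file (scaler,
weights, calibration, metadata) rather than an opaque pickle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SELECTED_METRICS",
    "FEATURE_NAMES",
    "FeatureVector",
    "LabelledDataset",
    "TrainedClassifier",
    "ErrorCall",
    "build_feature_matrix",
    "correlation_prune",
    "make_balanced_split",
    "train_error_classifier",
    "score_residues",
    "flag_error_runs",
    "load_default_classifier",
]

#: The seven metrics surviving |r| >= 0.4 correlation pruning.
SELECTED_METRICS = ("accuracy", "fp_rate", "smooth_sensitivity", "smooth_wrmsd",
                    "z_accuracy", "z_sensitivity", "z_wrmsd")
FEATURE_NAMES = SELECTED_METRICS + ("acc", "ss_helix", "ss_sheet", "ss_coil")

FeatureVector = np.ndarray  # one row of the 11-column feature matrix


@dataclass
class LabelledDataset:
    """Per-residue features with binary labels (1 = within modelling error)
    and a group id (source chain) for leakage-aware splitting."""

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        self.groups = np.asarray(self.groups)
        if len(self.X) != len(self.y) or len(self.y) != len(self.groups):
            raise ValueError("features, labels and groups differ in length")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "LabelledDataset":
        return LabelledDataset(self.X.iloc[idx].reset_index(drop=True),
                               self.y[idx], self.groups[idx])


def build_feature_matrix(table: pd.DataFrame, chain) -> pd.DataFrame:
    """Assemble the 11-column feature matrix from a metric table and an
    annotated chain (solvent accessibility + secondary structure)."""
    feats = table[list(SELECTED_METRICS)].copy()
    acc = np.zeros(chain.L)
    onehot = np.zeros((chain.L, 3))
    classes = {"helix": 0, "sheet": 1, "coil": 2}
    for i, r in enumerate(chain.residues):
        acc[i] = r.acc if r.acc is not None else 0.0
        onehot[i, classes.get(r.ss_class, 2)] = 1.0
    feats["acc"] = acc
    feats["ss_helix"] = onehot[:, 0]
    feats["ss_sheet"] = onehot[:, 1]
    feats["ss_coil"] = onehot[:, 2]
    return feats


# ---------------------------------------------------------------------------
# feature engineering


def correlation_prune(table: pd.DataFrame, labels: Sequence[int],
                      threshold: float = 0.4) -> List[str]:
    """Drop redundant metric columns by absolute Pearson correlation.

    Columns whose pairwise |r| reaches ``threshold`` are grouped by
    transitive closure; one representative per group survives, chosen as
    the column with the largest absolute linear-discriminant coefficient
    against the labels.  Constant columns are dropped with a warning.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.preprocessing import StandardScaler

    labels = np.asarray(labels, dtype=int)
    cols = [c for c in table.columns if c != "mask"]
    keep_cols = []
    for c in cols:
        if np.std(table[c].to_numpy()) == 0:
            warnings.warn(f"column {c!r} is constant; correlation undefined, dropped")
        else:
            keep_cols.append(c)
    if len(keep_cols) < 2:
        return keep_cols
    X = table[keep_cols].to_numpy(dtype=float)
    r = np.corrcoef(X, rowvar=False)
    adj = np.abs(r) >= threshold
    # connected components = transitive closure of the correlation graph
    n = len(keep_cols)
    comp = -np.ones(n, dtype=int)
    ncomp = 0
    for s in range(n):
        if comp[s] >= 0:
            continue
        stack = [s]
        comp[s] = ncomp
        while stack:
            u = stack.pop()
            for v in np.where(adj[u])[0]:
                if comp[v] < 0:
                    comp[v] = ncomp
                    stack.append(v)
        ncomp += 1
    lda = LinearDiscriminantAnalysis()
    lda.fit(StandardScaler().fit_transform(X), labels)
    coefs = np.abs(lda.coef_[0])
    survivors = []
    for c in range(ncomp):
        members = np.where(comp == c)[0]
        best = members[np.argmax(coefs[members])]
        survivors.append(keep_cols[best])
    return [c for c in keep_cols if c in survivors]


# ---------------------------------------------------------------------------
# splitting


def make_balanced_split(dataset: LabelledDataset, train_fraction: float = 0.8,
                        seed: int = 0, by_group: bool = False
                        ) -> Tuple[LabelledDataset, LabelledDataset]:
    """Class-balanced train/test split.

    Positives are split floor(train_fraction * P) / rest; an equal number
    of negatives is sampled into each side, so both sides are exactly
    balanced.  With ``by_group=True`` whole groups (source chains) are
    assigned to one side before balancing, so residues from the same
    error never appear on both sides.
    """
    rng = np.random.default_rng(seed)
    pos = np.where(dataset.y == 1)[0]
    neg = np.where(dataset.y == 0)[0]
    if len(neg) < len(pos):
        raise ValueError(f"need at least as many negatives as positives "
                         f"({len(neg)} < {len(pos)})")
    if by_group:
        groups = np.unique(dataset.groups)
        rng.shuffle(groups)
        pos_per_group = {g: int(((dataset.groups == g) & (dataset.y == 1)).sum())
                         for g in groups}
        target = train_fraction * len(pos)
        train_groups, acc = set(), 0
        for g in groups:
            if acc < target:
                train_groups.add(g)
                acc += pos_per_group[g]
        test_groups = [g for g in groups if g not in train_groups]
        if not any(pos_per_group[g] > 0 for g in test_groups):
            # make sure the hold-out side sees at least one error: move the
            # smallest positive-bearing group out of training
            movable = [g for g in train_groups if pos_per_group[g] > 0]
            if not movable or len(train_groups) < 2:
                raise ValueError("too few positive-bearing groups to split")
            train_groups.discard(min(movable, key=lambda g: pos_per_group[g]))
        in_train = np.isin(dataset.groups, list(train_groups))
        tr_pos = pos[in_train[pos]]
        te_pos = pos[~in_train[pos]]
        tr_negpool = neg[in_train[neg]]
        te_negpool = neg[~in_train[neg]]
        if len(tr_negpool) == 0 or len(te_negpool) == 0 or len(te_pos) == 0:
            raise ValueError("group split left one side without usable rows")
        # exact balance within each side; a side short of negatives drops
        # excess positives instead (group splits cannot hit exact 80:20)
        n_tr = min(len(tr_pos), len(tr_negpool))
        n_te = min(len(te_pos), len(te_negpool))
        tr_pos = rng.choice(tr_pos, size=n_tr, replace=False)
        te_pos = rng.choice(te_pos, size=n_te, replace=False)
        tr_neg = rng.choice(tr_negpool, size=n_tr, replace=False)
        te_neg = rng.choice(te_negpool, size=n_te, replace=False)
    else:
        pos = rng.permutation(pos)
        n_train = int(np.floor(train_fraction * len(pos)))
        tr_pos, te_pos = pos[:n_train], pos[n_train:]
        neg_sample = rng.choice(neg, size=len(pos), replace=False)
        tr_neg = neg_sample[:len(tr_pos)]
        te_neg = neg_sample[len(tr_pos):]
    train_idx = np.sort(np.concatenate([tr_pos, tr_neg]))
    test_idx = np.sort(np.concatenate([te_pos, te_neg]))
    return dataset.subset(train_idx), dataset.subset(test_idx)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedClassifier:
    """Standard scaler + linear SVM + Platt calibration, JSON-serializable.

    Probability of class 1 for a feature row x:
        p = sigmoid(a * (w . (x - mean) / scale + b) + c)
    where (mean, scale) were fitted only on training rows.
    """

    feature_names: Tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    coef: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    metadata: dict = field(default_factory=dict)

    def decision_function(self, X) -> np.ndarray:
        X = self._as_array(X)
        Z = (X - self.scaler_mean) / self.scaler_scale
        return Z @ self.coef + self.intercept

    def predict_proba(self, X) -> np.ndarray:
        z = self.platt_a * self.decision_function(X) + self.platt_b
        return 1.0 / (1.0 + np.exp(-z))

    def _as_array(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            X = X[list(self.feature_names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError(f"expected {len(self.feature_names)} features, "
                             f"got {X.shape[1]}")
        return X

    def save(self, path) -> None:
        data = {
            "format": "regval-classifier",
            "version": 1,
            "feature_names": list(self.feature_names),
            "scaler": {"mean": self.scaler_mean.tolist(),
                       "scale": self.scaler_scale.tolist()},
            "svm": {"coef": self.coef.tolist(), "intercept": self.intercept},
            "calibration": {"a": self.platt_a, "b": self.platt_b},
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        data = json.loads(Path(path).read_text())
        if data.get("format") != "regval-classifier":
            raise ValueError("not a regval classifier file")
        return cls(
            feature_names=tuple(data["feature_names"]),
            scaler_mean=np.array(data["scaler"]["mean"]),
            scaler_scale=np.array(data["scaler"]["scale"]),
            coef=np.array(data["svm"]["coef"]),
            intercept=float(data["svm"]["intercept"]),
            platt_a=float(data["calibration"]["a"]),
            platt_b=float(data["calibration"]["b"]),
            metadata=data.get("metadata", {}),
        )


def train_error_classifier(train: LabelledDataset, n_iter: int = 200,
                           seed: int = 0, cv: int = 5) -> TrainedClassifier:
    """Train the linear SVM with a seeded random hyperparameter search.

    The regularization strength is drawn log-uniformly from [1e-3, 1e3]
    and the class weight from {balanced, none}; ``n_iter`` draws are
    scored by ``cv``-fold cross-validated mean accuracy.  The standard
    scaler is fitted on the training rows only.  Platt calibration is
    fitted on out-of-fold decision values so that probabilities are not
    read off the same rows the SVM was fitted on.
    """
    from scipy.stats import loguniform
    from sklearn.base import clone
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import (RandomizedSearchCV, StratifiedKFold,
                                         cross_val_predict)
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import LinearSVC

    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    y = train.y
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    X = train.X[list(FEATURE_NAMES)].to_numpy(dtype=float) \
        if isinstance(train.X, pd.DataFrame) else np.asarray(train.X, dtype=float)

    pipe = Pipeline([("scaler", StandardScaler()),
                     ("svm", LinearSVC(random_state=seed, max_iter=20000))])
    space = {"svm__C": loguniform(1e-3, 1e3),
             "svm__class_weight": ["balanced", None]}
    folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    search = RandomizedSearchCV(pipe, space, n_iter=n_iter, scoring="accuracy",
                                cv=folds, random_state=seed, n_jobs=1, refit=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X, y)
        best = search.best_estimator_
        df = cross_val_predict(clone(best), X, y, cv=folds,
                               method="decision_function")
    platt = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    platt.fit(df[:, None], y)
    scaler = best.named_steps["scaler"]
    svm = best.named_steps["svm"]
    meta = {
        "seed": int(seed),
        "n_iter": int(n_iter),
        "cv": int(cv),
        "n_train": int(len(y)),
        "best_params": {"C": float(search.best_params_["svm__C"]),
                        "class_weight": search.best_params_["svm__class_weight"]},
        "cv_accuracy": float(search.best_score_),
    }
    return TrainedClassifier(
        feature_names=tuple(train.X.columns) if isinstance(train.X, pd.DataFrame)
        else tuple(FEATURE_NAMES),
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        coef=svm.coef_[0].copy(),
        intercept=float(svm.intercept_[0]),
        platt_a=float(platt.coef_[0, 0]),
        platt_b=float(platt.intercept_[0]),
        metadata=meta,
    )


def score_residues(clf: TrainedClassifier, features) -> np.ndarray:
    """Calibrated per-residue probability of being within a model error."""
    return clf.predict_proba(features)


# ---------------------------------------------------------------------------
# error calling


@dataclass
class ErrorCall:
    """A maximal run of consecutive residues flagged by the classifier."""

    start: int
    end: int
    mean_score: float

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1


def flag_error_runs(scores: np.ndarray, min_run: int = 6,
                    threshold: float = 0.9) -> List[ErrorCall]:
    """Maximal runs of >= min_run consecutive residues scoring >= threshold.

    Defaults (six residues at 90%) favour precision over recall.
    Indices in the returned calls are 1-based and inclusive.
    """
    scores = np.asarray(scores, dtype=float)
    calls = []
    start = None
    for i, s in enumerate(scores):
        if s >= threshold:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_run:
                calls.append(ErrorCall(start + 1, i, float(scores[start:i].mean())))
            start = None
    if start is not None and len(scores) - start >= min_run:
        calls.append(ErrorCall(start + 1, len(scores),
                               float(scores[start:].mean())))
    return calls


def load_default_classifier() -> TrainedClassifier:
    """The classifier shipped with the package, trained on the default
    synthetic labelled dataset."""
    from importlib import resources

    with resources.as_file(resources.files("regval").joinpath(
            "data/default_classifier.json")) as p:
        return TrainedClassifier.load(p)
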