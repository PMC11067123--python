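"""Classification pipeline: preprocessing, balancing, selection, training.

The pipeline reproduces a fixed stage order on the training rows only:

1. drop features whose missing fraction exceeds a threshold;
2. standardize (subtract mean, scale to unit variance; constant features
   are scaled by 1);
3. drop features whose post-scaling variance falls below a threshold;
4. impute remaining gaps by a k-nearest-neighbor search (Euclidean distance
   over co-observed features, mean of the neighbors);
5. greedily prune correlated feature pairs (|Pearson r| above a threshold
   drops the later column in canonical order);
6. oversample the minority class to parity with SMOTE-style interpolation;
7. select features by thresholding absolute LASSO regression coefficients;
8. train an RBF-kernel SVM (with calibrated probabilities) or a random
   forest.

Hyperparameters for stages 1–8 are drawn uniformly from fixed ranges by a
randomized search scored with tenfold cross-validated F1.  Oversampling
happens inside each training fold only, so synthetic rows are never scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import KNNImputer
from sklearn.linear_model import Lasso
from sklearn.metrics import f1_score
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Videos × features with binary labels and participant identity.

    ``features`` rows are videos (index = video id); ``labels`` holds the
    binarized symptom label (1 = any symptom present); ``participants``
    gives the participant id per row, used for grouped splitting.
    """

    features: pd.DataFrame
    labels: pd.Series
    participants: pd.Series
    task: str = "FTN"

    def __post_init__(self) -> None:
        if self.features.columns.duplicated().any():
            raise ValueError("duplicate feature column names")
        if not set(pd.unique(self.labels)).issubset({0, 1}):
            raise ValueError("labels must be binary 0/1")
        for name, s in (("labels", self.labels), ("participants", self.participants)):
            if len(s) != len(self.features):
                raise ValueError(f"{name} length does not match feature rows")
        if self.participants.isna().any():
            raise ValueError("every row needs a participant id")

    def __len__(self) -> int:
        return len(self.features)

    def subset(self, index) -> "FeatureTable":
        return FeatureTable(
            features=self.features.loc[index].copy(),
            labels=self.labels.loc[index].copy(),
            participants=self.participants.loc[index].copy(),
            task=self.task,
        )


#: (low, high, kind) hyperparameter ranges; integer ranges are half-open.
HYPERPARAMETER_RANGES = {
    "max_missing_frac": (0.0, 1.0, "float"),
    "min_variance": (0.0, 0.4, "float"),
    "max_corr": (0.7, 0.90, "float"),
    "impute_k": (1, 4, "int"),
    "lasso_coef_threshold": (0.01, 0.035, "float"),
    "smote_k": (1, 4, "int"),
    "svm_C": (0.0, 2.0, "float"),
    "svm_gamma": (0.0, 0.1, "float"),
}

_GAMMA_FLOOR = 1e-6


@dataclass(frozen=True)
class HyperparameterSet:
    """One draw of the tunable pipeline settings (see module docstring)."""

    max_missing_frac: float = 0.5
    min_variance: float = 0.2
    max_corr: float = 0.8
    impute_k: int = 2
    lasso_coef_threshold: float = 0.02
    smote_k: int = 2
    svm_C: float = 1.0
    svm_gamma: float = 0.05

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            lo, hi, kind = HYPERPARAMETER_RANGES[f.name]
            v = getattr(self, f.name)
            if kind == "int" and not (lo <= v < hi and float(v).is_integer()):
                raise ValueError(f"{f.name}={v} outside integer range [{lo}, {hi})")
            if kind == "float":
                # svm_gamma's range is closed on the right; C=0 and gamma=0
                # are degenerate for an SVM and replaced by a small floor.
                closed = f.name == "svm_gamma"
                if not (lo <= v <= hi if closed else lo <= v < hi):
                    raise ValueError(f"{f.name}={v} outside range [{lo}, {hi}{']' if closed else ')'}")

    @classmethod
    def sample(cls, rng: np.random.Generator) -> "HyperparameterSet":
        """Draw one set uniformly from the tuning ranges."""
        kw = {}
        for name, (lo, hi, kind) in HYPERPARAMETER_RANGES.items():
            if kind == "int":
                kw[name] = int(rng.integers(lo, hi))
            else:
                kw[name] = float(rng.uniform(lo, hi))
        # exclude the degenerate 0 endpoints for the SVM
        kw["svm_C"] = max(kw["svm_C"], _GAMMA_FLOOR)
        kw["svm_gamma"] = max(kw["svm_gamma"], _GAMMA_FLOOR)
        return cls(**kw)


def binarize_label(sma_score: int) -> int:
    """Symptom presence: 1 iff the clinical severity score exceeds zero."""
    if sma_score not in (0, 1, 2, 3, 4):
        raise ValueError(f"sma_score {sma_score!r} outside 0..4")
    return int(sma_score > 0)


def split_by_participant(
    t: FeatureTable, train_frac: float = 0.8, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Partition rows at the participant level (no participant in both sets).

    The training set holds round(train_frac · n_participants) participants
    (at least one on each side).
    """
    participants = np.array(sorted(t.participants.unique()))
    if len(participants) < 2:
        raise ValueError("need at least 2 participants to split")
    rng = np.random.default_rng(seed)
    rng.shuffle(participants)
    n_train = int(round(train_frac * len(participants)))
    n_train = min(max(n_train, 1), len(participants) - 1)
    train_p = set(participants[:n_train])
    mask = t.participants.isin(train_p)
    return t.subset(t.features.index[mask]), t.subset(t.features.index[~mask])


@dataclass
class Preprocessor:
    """Frozen preprocessing state (stages 1–5), applied identically at
    training and prediction time using training-derived statistics only."""

    kept_after_missing: list[str]
    means: pd.Series
    scales: pd.Series
    kept_after_variance: list[str]
    imputer: KNNImputer
    kept_after_corr: list[str]
    n_corr_dropped: int = 0

    @property
    def kept_features(self) -> list[str]:
        return list(self.kept_after_corr)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X1 = X[self.kept_after_missing]
        Xs = (X1 - self.means) / self.scales
        X3 = Xs[self.kept_after_variance]
        imputed = self.imputer.transform(X3.to_numpy(dtype=float))
        X4 = pd.DataFrame(imputed, index=X3.index, columns=X3.columns)
        return X4[self.kept_after_corr]


def _greedy_corr_prune(X: np.ndarray, names: list[str], max_corr: float) -> list[str]:
    """Scan columns in canonical (sorted-name) order; drop any column whose
    |Pearson r| with an already-kept column exceeds the threshold."""
    order = np.argsort(names)
    Z = X[:, order].astype(np.float32)
    Z = Z - Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z /= sd
    n = Z.shape[0]
    C = (Z.T @ Z) / np.float32(n)
    kept_idx: list[int] = []
    for j in range(Z.shape[1]):
        if kept_idx and np.any(np.abs(C[j, kept_idx]) > max_corr):
            continue
        kept_idx.append(j)
    sorted_names = [names[i] for i in order]
    return [sorted_names[i] for i in kept_idx]


def fit_preprocessor(train: FeatureTable, h: HyperparameterSet) -> Preprocessor:
    """Fit preprocessing stages 1–5 on the training rows (see module docstring)."""
    X = train.features
    if X.shape[1] == 0 or len(X) == 0:
        raise ValueError("empty feature set after preprocessing")

    # 1: missing-fraction filter
    frac = X.isna().mean()
    kept1 = list(X.columns[frac <= h.max_missing_frac])
    if not kept1:
        raise ValueError("empty feature set after preprocessing (missing filter)")
    X1 = X[kept1]

    # 2: standardize; constant (or all-missing) features scaled by 1
    means = X1.mean()
    means = means.fillna(0.0)
    scales = X1.std(ddof=0)
    scales = scales.replace(0.0, 1.0).fillna(1.0)
    Xs = (X1 - means) / scales

    # 3: post-scaling variance filter
    var = Xs.var(ddof=0).fillna(0.0)
    kept3 = list(Xs.columns[var >= h.min_variance]) if h.min_variance > 0 else list(Xs.columns)
    if not kept3:
        raise ValueError("empty feature set after preprocessing (variance filter)")
    X3 = Xs[kept3]

    # 4: k-NN imputation over co-observed standardized features
    imputer = KNNImputer(n_neighbors=h.impute_k)
    imputed = imputer.fit_transform(X3.to_numpy(dtype=float))
    if imputed.shape[1] != len(kept3):  # all-NaN columns vanish
        keep_mask = ~np.all(np.isnan(X3.to_numpy(dtype=float)), axis=0)
        kept3 = [c for c, m in zip(kept3, keep_mask) if m]
        X3 = X3[kept3]
        imputed = imputer.fit_transform(X3.to_numpy(dtype=float))

    # 5: correlation pruning
    kept5 = _greedy_corr_prune(imputed, kept3, h.max_corr)
    if not kept5:
        raise ValueError("empty feature set after preprocessing (correlation filter)")
    n_dropped = len(kept3) - len(kept5)
    logger.info("correlation pruning dropped %d of %d features", n_dropped, len(kept3))
    return Preprocessor(
        kept_after_missing=kept1,
        means=means,
        scales=scales,
        kept_after_variance=kept3,
        imputer=imputer,
        kept_after_corr=kept5,
        n_corr_dropped=n_dropped,
    )


def oversample_minority(train: FeatureTable, k: int, seed: int = 0) -> FeatureTable:
    """SMOTE-style oversampling of the minority class to exact parity.

    Each synthetic row is x + u·(x′ − x) for a random minority row x, one
    of its k nearest minority neighbors x′ (Euclidean), and u ~ U(0, 1).
    A balanced table is returned unchanged.
    """
    y = train.labels.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to oversample")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return train
    if n_min <= k:
        raise ValueError("too few minority samples for k neighbors")
    Xm = train.features[y == minority].to_numpy(dtype=float)
    if np.isnan(Xm).any():
        raise ValueError("oversampling requires imputed (complete) features")
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)
    n_new = int(n_maj - n_min)
    base = rng.integers(0, len(Xm), size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)      # skip self at position 0
    u = rng.uniform(0.0, 1.0, size=n_new)
    neighbors = Xm[idx[base, pick]]
    synth = Xm[base] + u[:, None] * (neighbors - Xm[base])

    syn_index = [f"syn{i}" for i in range(n_new)]
    min_part = train.participants[y == minority].to_numpy()
    features = pd.concat(
        [train.features, pd.DataFrame(synth, index=syn_index, columns=train.features.columns)]
    )
    labels = pd.concat([train.labels, pd.Series(minority, index=syn_index)])
    participants = pd.concat(
        [train.participants, pd.Series([f"{p}+syn" for p in min_part[base]], index=syn_index)]
    )
    return FeatureTable(features=features, labels=labels, participants=participants, task=train.task)


def lasso_select(
    train: FeatureTable, coef_threshold: float, alpha: float = 0.01, max_iter: int = 5000
) -> list[str]:
    """Keep features whose |LASSO regression coefficient| meets the threshold.

    An L1-penalized linear regression of the binary label on the (already
    standardized) features; the penalty strength ``alpha`` is fixed — only
    the coefficient threshold is tuned.
    """
    X = train.features.to_numpy(dtype=float)
    y = train.labels.to_numpy(dtype=float)
    model = Lasso(alpha=alpha, max_iter=max_iter)
    model.fit(X, y)
    kept = [c for c, w in zip(train.features.columns, model.coef_) if abs(w) >= coef_threshold]
    if not kept:
        raise ValueError("no feature survived the LASSO coefficient threshold")
    return kept


def fit_classifier(train: FeatureTable, kind: str, h: HyperparameterSet, seed: int = 0):
    """Train the final classifier on selected features.

    ``svm``: RBF kernel, C and γ from the hyperparameter set, with
    calibrated class probabilities (sigmoid fit on internal folds, needed
    for the 0.5 operating point).  ``rf``: default tree settings.
    """
    y = train.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training data")
    X = train.features.to_numpy(dtype=float)
    kind = kind.lower()
    if kind == "svm":
        # Class probabilities via a sigmoid fit to decision values on
        # internal folds (needed for the 0.5 operating point).
        svc = SVC(
            C=max(h.svm_C, _GAMMA_FLOOR),
            gamma=max(h.svm_gamma, _GAMMA_FLOOR),
            kernel="rbf",
            random_state=seed,
        )
        n_min = int(np.bincount(y.astype(int)).min())
        clf = CalibratedClassifierCV(svc, method="sigmoid", cv=min(5, n_min), ensemble=False)
    elif kind == "rf":
        clf = RandomForestClassifier(random_state=seed)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; expected 'svm' or 'rf'")
    clf.fit(X, y)
    return clf


@dataclass
class FittedPipeline:
    """Frozen end-to-end pipeline: preprocessing state + selection + classifier.

    Prediction applies the stages in the exact training order using only
    training-derived statistics.
    """

    preprocessor: Preprocessor
    selected_features: list[str]
    classifier: object
    kind: str
    hyperparameters: HyperparameterSet
    task: str = "FTN"

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """Positive-class probability per row."""
        Xp = self.preprocessor.transform(features)[self.selected_features]
        proba = self.classifier.predict_proba(Xp.to_numpy(dtype=float))
        pos_col = list(self.classifier.classes_).index(1)
        return proba[:, pos_col]

    def selection_summary(self) -> pd.DataFrame:
        """Selected features decomposed into type / joint / signal / filter /
        detail columns, the layout used to report interpretable features."""
        rows = []
        for name in self.selected_features:
            if "|" in name:
                channel, ftype, detail = name.split("|", 2)
                parts = channel.split(".")
                source, quantity, width = parts[0], parts[1], ".".join(parts[2:])
            else:
                source = quantity = width = ""
                ftype, detail = "unknown", name
            rows.append(
                {"type": ftype, "joint": source, "signal": quantity,
                 "filter_width": width, "detail": detail, "feature": name}
            )
        return pd.DataFrame(rows)


def fit_pipeline(
    train: FeatureTable, kind: str, h: HyperparameterSet, seed: int = 0
) -> FittedPipeline:
    """Run the full training chain: preprocess → oversample → select → fit."""
    pre = fit_preprocessor(train, h)
    Xp = pre.transform(train.features)
    processed = FeatureTable(
        features=Xp, labels=train.labels.copy(), participants=train.participants.copy(),
        task=train.task,
    )
    balanced = oversample_minority(processed, k=h.smote_k, seed=seed)
    selected = lasso_select(balanced, h.lasso_coef_threshold)
    sel_table = FeatureTable(
        features=balanced.features[selected], labels=balanced.labels,
        participants=balanced.participants, task=balanced.task,
    )
    clf = fit_classifier(sel_table, kind, h, seed=seed)
    return FittedPipeline(
        preprocessor=pre, selected_features=selected, classifier=clf, kind=kind,
        hyperparameters=h, task=train.task,
    )


def _cv_folds(t: FeatureTable, cv_folds: int, seed: int):
    """Fold indices over original rows; grouped by participant when enough
    participants exist, otherwise stratified."""
    y = t.labels.to_numpy()
    groups = t.participants.to_numpy()
    if len(t) < cv_folds:
        raise ValueError(f"need at least {cv_folds} rows for {cv_folds}-fold CV")
    if len(np.unique(groups)) >= cv_folds and len(np.unique(groups)) >= 10:
        splitter = GroupKFold(n_splits=cv_folds)
        return list(splitter.split(t.features, y, groups))
    splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    return list(splitter.split(t.features, y))


def cross_val_f1(
    train: FeatureTable, kind: str, h: HyperparameterSet, cv_folds: int = 10, seed: int = 0
) -> float:
    """Mean cross-validated F1 of the full chain.

    The entire preprocess → oversample → select → fit chain is refit inside
    every training fold; oversampling never touches the held-out fold, and
    only original rows are scored.
    """
    folds = _cv_folds(train, cv_folds, seed)
    index = train.features.index
    scores = []
    for i, (tr_idx, te_idx) in enumerate(folds):
        sub = train.subset(index[tr_idx])
        held = train.subset(index[te_idx])
        pipe = fit_pipeline(sub, kind, h, seed=seed + i)
        pred = (pipe.predict_proba(held.features) >= 0.5).astype(int)
        scores.append(f1_score(held.labels.to_numpy(), pred, zero_division=0))
    return float(np.mean(scores))


def random_search(
    train: FeatureTable,
    kind: str,
    n_iter: int = 80,
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[HyperparameterSet, float]:
    """Randomized hyperparameter search scored by cross-validated F1.

    Draws ``n_iter`` parameter sets uniformly from the tuning ranges and
    returns the arg-max.  Draws that empty the feature set (or otherwise
    fail) score −∞.
    """
    rng = np.random.default_rng(seed)
    best_h, best_f1 = None, -np.inf
    for i in range(n_iter):
        h = HyperparameterSet.sample(rng)
        try:
            score = cross_val_f1(train, kind, h, cv_folds=cv_folds, seed=seed)
        except ValueError as e:
            logger.info("draw %d failed: %s", i, e)
            score = -np.inf
        if score > best_f1:
            best_h, best_f1 = h, score
    if best_h is None:
        raise ValueError("all randomized-search draws failed")
    return best_h, float(best_f1)
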