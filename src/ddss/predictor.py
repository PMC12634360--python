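"""Per-cluster difficulty classifiers and their evaluation.

One classifier (RBF-kernel SVM, random forest, or gradient-boosted trees) is trained
per surgeon cluster on that cluster's training records; at test time each record is
routed to a cluster (by its surgeon's membership, with a standardized-feature
centroid fallback for unknown surgeons) and scored by that cluster's model — a
mixture-of-experts over experience groups.  Hyperparameters are chosen per cluster by
seeded five-fold cross-validated grid search maximizing the one-vs-rest macro-average
ROC AUC over the three difficulty classes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import LabelEncoder, StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import decoupler as _dec
from .decoupler import Partition, assign_sample
from .exceptions import ValidationError
from .records import label_dataset
from .schema import Dataset
from .trajectory import surgeon_sequences

__all__ = [
    "SplitSpec",
    "split_dataset",
    "ModelBundle",
    "train_models",
    "predict",
    "MetricsReport",
    "evaluate",
    "compare_pipelines",
    "DecoupledDifficultyClassifier",
    "DIFFICULTY_CLASSES",
]

DIFFICULTY_CLASSES = (1, 2, 3)

#: Hyperparameter grids searched per cluster (pipeline step "clf").
PARAM_GRIDS = {
    "svm": {
        "clf__C": [0.1, 1.0, 10.0, 100.0, 1000.0],
        "clf__gamma": ["scale", 0.001, 0.01, 0.1, 1.0],
    },
    "rf": {
        "clf__n_estimators": [100, 300],
        "clf__max_depth": [None, 5, 10],
    },
    "xgb": {
        "clf__max_depth": [3, 6],
        "clf__learning_rate": [0.1, 0.3],
    },
}


@dataclass(frozen=True)
class SplitSpec:
    """Per-surgeon train/test split: 4:1 by default, stratified by class."""

    test_fraction: float = 0.2
    stratify_by_class: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValidationError("test_fraction must be in (0, 1)")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(ds: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset]:
    """Split every surgeon's records at the configured ratio; pool the pieces.

    Test size per surgeon is round(test_fraction * n), at least 1; stratification
    allocates that budget across difficulty classes by largest remainder.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    test_rids: set[str] = set()
    for sid, sub in ds.by_surgeon().items():
        n = len(sub)
        if n < 2:
            raise ValidationError(
                f"surgeon {sid!r} has {n} record(s); cannot split into train and test"
            )
        if not spec.stratify_by_class and n < 5:
            raise ValidationError(
                f"surgeon {sid!r} has {n} records; need >= 5 for an unstratified split"
            )
        n_test = min(max(1, _round_half_up(spec.test_fraction * n)), n - 1)
        rids = np.asarray(sub.record_ids)
        if spec.stratify_by_class:
            y = label_dataset(sub)
            classes, counts = np.unique(y, return_counts=True)
            quotas = {int(c): n_test * cnt / n for c, cnt in zip(classes, counts)}
            alloc = {c: int(math.floor(q)) for c, q in quotas.items()}
            short = n_test - sum(alloc.values())
            for c in sorted(quotas, key=lambda c: (-(quotas[c] - alloc[c]), c)):
                if short <= 0:
                    break
                if alloc[c] < int(counts[classes.tolist().index(c)]):
                    alloc[c] += 1
                    short -= 1
            for c, k in alloc.items():
                pool = rids[y == c]
                picked = rng.permutation(pool.size)[:k]
                test_rids.update(pool[picked])
        else:
            picked = rng.permutation(n)[:n_test]
            test_rids.update(rids[picked])
    train = ds.subset(lambda r: r.record_id not in test_rids)
    test = ds.subset(lambda r: r.record_id in test_rids)
    return train, test


def _macro_ovr_auc(y_true, scores, classes) -> float:
    """Unweighted mean of one-vs-rest AUCs over classes present in y_true."""
    y_true = np.asarray(y_true)
    aucs = []
    for i, c in enumerate(classes):
        pos = y_true == c
        if 0 < pos.sum() < pos.size:
            aucs.append(roc_auc_score(pos, scores[:, i]))
    return float(np.mean(aucs)) if aucs else 0.5


def _auc_scorer(estimator, X, y) -> float:
    # rank candidates on decision values where available (margin AUC is invariant
    # to probability calibration noise); probabilities stay the prediction contract
    if hasattr(estimator, "decision_function"):
        scores = estimator.decision_function(X)
        if scores.ndim == 1:  # binary fold: column for classes_[1]
            scores = np.column_stack([-scores, scores])
    else:
        scores = estimator.predict_proba(X)
    return _macro_ovr_auc(y, scores, estimator.classes_)


def _make_pipeline(model_kind: str, seed: int) -> Pipeline:
    if model_kind == "svm":
        clf = SVC(kernel="rbf", probability=True, random_state=seed)
    elif model_kind == "rf":
        clf = RandomForestClassifier(random_state=seed)
    elif model_kind == "xgb":
        clf = XGBClassifier(
            n_estimators=200,
            random_state=seed,
            verbosity=0,
            eval_metric="mlogloss",
        )
    else:
        raise ValidationError(f"unknown model_kind {model_kind!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class ModelBundle:
    """One fitted model (plus its label encoder and chosen hyperparameters) per cluster."""

    model_kind: str
    models: dict[int, Pipeline]
    encoders: dict[int, LabelEncoder]
    best_params: dict[int, dict]
    cv_scores: dict[int, float]
    classes: tuple[int, ...] = DIFFICULTY_CLASSES


def train_models(
    train: Dataset,
    partition: Partition,
    model_kind: str = "svm",
    cv_folds: int = 5,
    seed: int = 0,
) -> ModelBundle:
    """Grid-search and fit one classifier per non-empty cluster.

    Features are the 14 ordinal codes standardized on the cluster's training data
    (inside the model pipeline); the selection metric is macro-average one-vs-rest
    AUC under a seeded stratified ``cv_folds``-fold CV.
    """
    if model_kind not in PARAM_GRIDS:
        raise ValidationError(f"unknown model_kind {model_kind!r}")
    surgeons = np.asarray(train.surgeon_of_record)
    models, encoders, best_params, cv_scores = {}, {}, {}, {}
    for c in partition.clusters:
        members = set(partition.members(c))
        sub = train.subset(np.isin(surgeons, list(members)))
        if len(sub) < cv_folds * 3:
            raise ValidationError(
                f"cluster {c} has {len(sub)} training records; "
                f"need >= {cv_folds * 3}"
            )
        X = sub.codes
        if np.isnan(X).any():
            raise ValidationError("training data contains missing values; impute first")
        y = label_dataset(sub)
        if np.unique(y).size < 2:
            raise ValidationError(f"cluster {c} has a single difficulty class")
        le = LabelEncoder()
        y_enc = le.fit_transform(y)
        # a class rarer than the fold count would break stratification; shrink the
        # fold count to the rarest class (>=2), falling back to unstratified folds
        # when a class is a singleton
        min_class = int(np.bincount(y_enc).min())
        if min_class >= 2:
            cv = StratifiedKFold(
                n_splits=min(cv_folds, min_class), shuffle=True, random_state=seed
            )
        else:
            cv = KFold(
                n_splits=min(cv_folds, len(y_enc) // 2),
                shuffle=True,
                random_state=seed,
            )
        pipe = _make_pipeline(model_kind, seed)
        if model_kind == "svm":
            # candidates are ranked on decision-value AUC, so the (5x more
            # expensive) probability calibration is only fitted on the winner
            pipe.set_params(clf__probability=False)
        search = GridSearchCV(
            pipe,
            PARAM_GRIDS[model_kind],
            scoring=_auc_scorer,
            cv=cv,
            refit=False,
            n_jobs=None,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(X, y_enc)
        final = _make_pipeline(model_kind, seed)
        final.set_params(**search.best_params_)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final.fit(X, y_enc)
        models[c] = final
        encoders[c] = le
        best_params[c] = {
            k.removeprefix("clf__"): v for k, v in search.best_params_.items()
        }
        cv_scores[c] = float(search.best_score_)
    return ModelBundle(
        model_kind=model_kind,
        models=models,
        encoders=encoders,
        best_params=best_params,
        cv_scores=cv_scores,
    )


def predict(
    bundle: ModelBundle,
    test: Dataset,
    partition: Partition,
    train: Dataset,
    routing: str = "surgeon",
) -> pd.DataFrame:
    """Route each test record to a cluster and score it with that cluster's model.

    Returns a DataFrame with one row per record: assigned ``cluster``, predicted
    ``pred`` class, and a probability column per difficulty class (a simplex; classes
    unseen by the routed model get probability 0).
    """
    clusters = np.array(
        [assign_sample(r, partition, train, mode=routing) for r in test.records]
    )
    n = len(test)
    scores = np.zeros((n, len(bundle.classes)))
    preds = np.zeros(n, dtype=int)
    col_of = {c: i for i, c in enumerate(bundle.classes)}
    for c in np.unique(clusters):
        if c not in bundle.models:
            raise ValidationError(f"no trained model for cluster {c}")
        sel = clusters == c
        model, le = bundle.models[c], bundle.encoders[c]
        proba = model.predict_proba(test.codes[sel])
        for enc_label, col in zip(model.classes_, range(proba.shape[1])):
            orig = int(le.inverse_transform([enc_label])[0])
            scores[sel, col_of[orig]] = proba[:, col]
        preds[sel] = le.inverse_transform(model.predict(test.codes[sel]))
    return pd.DataFrame(
        {
            "record_id": test.record_ids,
            "surgeon_id": test.surgeon_of_record,
            "cluster": clusters,
            "pred": preds,
            **{
                f"score_{c}": scores[:, i] for i, c in enumerate(bundle.classes)
            },
        }
    )


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, per-class one-vs-rest rates, macro F1 and macro AUC."""

    accuracy: float
    per_class: dict[int, dict[str, float]]
    macro_f1: float
    macro_auc: float
    confusion: np.ndarray = field(repr=False)
    classes: tuple[int, ...] = DIFFICULTY_CLASSES

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "macro_f1": self.macro_f1,
            "macro_auc": self.macro_auc,
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
        }


def evaluate(y_true, y_pred, scores) -> MetricsReport:
    """Confusion-matrix metrics plus one-vs-rest macro-average AUC.

    ``scores`` is an (n, 3) matrix of class probabilities in class order (1, 2, 3).
    Classes absent from ``y_true`` have undefined AUC/sensitivity and are skipped
    from the macro averages with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.size != y_pred.size or scores.shape != (y_true.size, 3):
        raise ValidationError("evaluate: shape mismatch between labels and scores")
    classes = DIFFICULTY_CLASSES
    k = len(classes)
    conf = np.zeros((k, k), dtype=int)
    idx = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        conf[idx[t], idx[p]] += 1
    n = conf.sum()
    accuracy = float(np.trace(conf) / n)

    per_class: dict[int, dict[str, float]] = {}
    absent = [c for c in classes if (y_true == c).sum() == 0]
    if absent:
        warnings.warn(
            f"classes {absent} absent from y_true; their AUC/sensitivity are "
            "undefined and excluded from macro averages",
            stacklevel=2,
        )
    f1s, aucs = [], []
    for i, c in enumerate(classes):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if (tp + fn) else float("nan")
        spec = tn / (tn + fp) if (tn + fp) else float("nan")
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
        per_class[c] = {
            "sensitivity": float(sens),
            "specificity": float(spec),
            "f1": float(f1),
        }
        if c not in absent:
            f1s.append(f1)
            aucs.append(roc_auc_score(y_true == c, scores[:, i]))
    return MetricsReport(
        accuracy=accuracy,
        per_class=per_class,
        macro_f1=float(np.mean(f1s)),
        macro_auc=float(np.mean(aucs)),
        confusion=conf,
    )


class DecoupledDifficultyClassifier(BaseEstimator, ClassifierMixin):
    """Decouple surgeons into experience groups, then train one expert per group.

    ``fit`` takes the training :class:`Dataset` (records carry surgeon, month,
    indicators and operative time); difficulty labels default to the 600 s / 1200 s
    three-class rule.  ``partitioner='lasso'`` builds per-surgeon Lasso-path
    preference sequences and clusters them by Levenshtein distance;
    ``'gmm'`` uses the Gaussian-mixture baseline; ``'none'`` trains a single
    pooled model.
    """

    def __init__(
        self,
        partitioner: str = "lasso",
        model_kind: str = "svm",
        k: int = 2,
        linkage: str = "average",
        grid_size: int = 200,
        cv_folds: int = 5,
        routing: str = "surgeon",
        random_state: int = 0,
    ):
        self.partitioner = partitioner
        self.model_kind = model_kind
        self.k = k
        self.linkage = linkage
        self.grid_size = grid_size
        self.cv_folds = cv_folds
        self.routing = routing
        self.random_state = random_state

    def fit(self, ds: Dataset, y=None):
        if self.partitioner == "lasso":
            seqs = surgeon_sequences(ds, grid_size=self.grid_size)
            est = _dec.SequencePartitioner(k=self.k, linkage=self.linkage).fit(seqs)
            self.sequences_ = seqs
            self.partition_ = est.partition_
        elif self.partitioner == "gmm":
            self.partition_ = _dec.gmm_partition(ds, k=self.k, seed=self.random_state)
        elif self.partitioner == "none":
            self.partition_ = Partition(
                assignment={sid: 1 for sid in ds.surgeon_ids}
            )
        else:
            raise ValidationError(f"unknown partitioner {self.partitioner!r}")
        self.bundle_ = train_models(
            ds,
            self.partition_,
            model_kind=self.model_kind,
            cv_folds=self.cv_folds,
            seed=self.random_state,
        )
        self.train_ds_ = ds
        self.classes_ = np.asarray(DIFFICULTY_CLASSES)
        return self

    def _frame(self, ds: Dataset) -> pd.DataFrame:
        return predict(
            self.bundle_, ds, self.partition_, self.train_ds_, routing=self.routing
        )

    def predict(self, ds: Dataset) -> np.ndarray:
        return self._frame(ds)["pred"].to_numpy()

    def predict_proba(self, ds: Dataset) -> np.ndarray:
        frame = self._frame(ds)
        return frame[[f"score_{c}" for c in DIFFICULTY_CLASSES]].to_numpy()

    def score(self, ds: Dataset, y=None) -> float:
        y = label_dataset(ds) if y is None else np.asarray(y)
        return float(np.mean(self.predict(ds) == y))


def compare_pipelines(
    ds: Dataset,
    seed: int = 0,
    model_kinds: tuple[str, ...] = ("svm", "rf", "xgb"),
    partitioners: tuple[str, ...] = ("lasso", "gmm", "none"),
    cv_folds: int = 5,
    routing: str = "surgeon",
    grid_size: int = 200,
) -> dict:
    """Partitioner x model comparison on a single seeded 4:1 split.

    Returns accuracy and macro-AUC tables (rows = partitioner, columns = model
    kind, fractions) plus the full per-cell metric reports.
    """
    train, test = split_dataset(ds, SplitSpec(seed=seed))
    y_true = label_dataset(test)
    acc = pd.DataFrame(index=list(partitioners), columns=list(model_kinds), dtype=float)
    auc = acc.copy()
    reports: dict[tuple[str, str], MetricsReport] = {}
    for part in partitioners:
        for kind in model_kinds:
            clf = DecoupledDifficultyClassifier(
                partitioner=part,
                model_kind=kind,
                cv_folds=cv_folds,
                routing=routing,
                grid_size=grid_size,
                random_state=seed,
            ).fit(train)
            frame = clf._frame(test)
            scores = frame[[f"score_{c}" for c in DIFFICULTY_CLASSES]].to_numpy()
            rep = evaluate(y_true, frame["pred"].to_numpy(), scores)
            acc.loc[part, kind] = rep.accuracy
            auc.loc[part, kind] = rep.macro_auc
            reports[(part, kind)] = rep
    return {"accuracy": acc, "macro_auc": auc, "reports": reports}
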