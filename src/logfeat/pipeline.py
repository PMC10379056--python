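"""Mixed-categorical classification pipeline.

Feature tables assembled from the annotation modules are bisected into
LLPS / non-LLPS datasets by domain content, numeric array variables
are converted to categoricals (direct mapping or clustering), the data
are deduplicated, singleton classes dropped, training folds rebalanced
(stratified resampling with replacement, or majority-class
subsampling), and a bagged random forest (100 trees) is evaluated
under three schemes: stratified 10-fold cross-validation, a stratified
66/34 percentage split, and a persisted stratified holdout.  Reports
carry accuracy, per-class precision/recall/F1, the confusion matrix
and a per-instance class-probability distribution table.

Rebalancing and categorical-conversion fitting happen strictly inside
each training fold — test folds are never touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.mixture import BayesianGaussianMixture, GaussianMixture
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import OneHotEncoder
from sklearn.tree import export_text
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FeatureTable",
    "CategoricalConversion",
    "ClassifierConfig",
    "EvaluationReport",
    "bisect_llps",
    "to_categorical",
    "prepare_dataset",
    "balance",
    "split",
    "train_random_forest",
    "evaluate",
    "MixedRandomForestClassifier",
]

UNSEEN = "__unseen__"
SCHEMES = ("cv10", "split66", "stratified_holdout")


@dataclass
class FeatureTable:
    """Instances x named categorical variables plus a class column."""

    df: pd.DataFrame
    class_col: str
    provenance: dict = field(default_factory=dict)  # column -> source module

    def __post_init__(self) -> None:
        if self.class_col not in self.df.columns:
            raise ValueError(f"class column {self.class_col!r} missing")
        if self.df[self.class_col].isna().any():
            raise ValueError("missing class values are not allowed")

    @property
    def feature_cols(self) -> list[str]:
        return [c for c in self.df.columns if c != self.class_col]

    def to_tsv(self, path, schema_path=None) -> None:
        self.df.to_csv(path, sep="\t", index=False)
        if schema_path is not None:
            schema = {
                "class_col": self.class_col,
                "columns": {c: str(self.df[c].dtype) for c in self.df.columns},
                "provenance": self.provenance,
            }
            with open(schema_path, "w") as fh:
                json.dump(schema, fh, indent=2, sort_keys=True)

    @classmethod
    def from_tsv(cls, path, class_col, schema_path=None) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        provenance = {}
        if schema_path is not None:
            with open(schema_path) as fh:
                schema = json.load(fh)
            class_col = schema["class_col"]
            provenance = schema.get("provenance", {})
        return cls(df=df, class_col=class_col, provenance=provenance)


def bisect_llps(
    table: FeatureTable,
    llps_pfams: set[str],
    pfam_col: str = "pfams",
    sep: str = ";",
) -> tuple[FeatureTable, FeatureTable]:
    """Partition instances by the presence of LLPS-associated Pfams.

    An instance with at least one Pfam from ``llps_pfams`` goes to the
    LLPS table, all others to the non-LLPS table; the partition is
    exhaustive and exclusive.
    """
    if not llps_pfams:
        raise ValueError("llps_pfams must be non-empty")
    if pfam_col not in table.df.columns:
        raise ValueError(f"column {pfam_col!r} missing from table")

    def has_llps(cell) -> bool:
        pfams = set(str(cell).split(sep)) if pd.notna(cell) else set()
        return bool(pfams & llps_pfams)

    mask = table.df[pfam_col].map(has_llps)
    return (
        FeatureTable(table.df[mask].copy(), table.class_col, dict(table.provenance)),
        FeatureTable(table.df[~mask].copy(), table.class_col, dict(table.provenance)),
    )


class CategoricalConversion(BaseEstimator):
    """Convert a numeric array variable into a categorical column.

    ``method="map"`` stringifies distinct values directly; the
    clustering methods (``kmeans``, ``em`` for a Gaussian mixture,
    ``density`` for a Dirichlet-process mixture) assign cluster
    memberships as category values, labelled ``cluster_0`` ... by
    descending cluster size.  Deterministic under a fixed seed.
    """

    def __init__(self, method: str = "map", k: int = 2, seed: int = 0):
        self.method = method
        self.k = k
        self.seed = seed

    def fit(self, values, y=None) -> "CategoricalConversion":
        x = np.asarray(values, dtype=float).reshape(-1, 1)
        if self.method == "map":
            self.categories_ = sorted({self._fmt(v) for v in x.ravel()})
            return self
        n_distinct = len(np.unique(x))
        if self.k > n_distinct:
            raise ValueError(
                f"k={self.k} exceeds the {n_distinct} distinct values present"
            )
        if self.method == "kmeans":
            model = KMeans(n_clusters=self.k, n_init=10, random_state=self.seed)
            raw = model.fit_predict(x)
        elif self.method == "em":
            model = GaussianMixture(n_components=self.k, random_state=self.seed)
            raw = model.fit_predict(x)
        elif self.method == "density":
            model = BayesianGaussianMixture(
                n_components=self.k, random_state=self.seed, max_iter=500
            )
            raw = model.fit_predict(x)
        else:
            raise ValueError(f"unknown conversion method {self.method!r}")
        self.model_ = model
        # stable labels: cluster_0 is the largest fitted cluster
        # (ties broken by raw cluster index for determinism)
        counts = pd.Series(raw).value_counts()
        order = sorted(counts.index, key=lambda c: (-counts[c], c))
        self.label_map_ = {
            int(c): f"cluster_{i}" for i, c in enumerate(order)
        }
        self.categories_ = sorted(set(self.label_map_.values()))
        return self

    @staticmethod
    def _fmt(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else repr(float(v))

    def transform(self, values) -> pd.Series:
        check_is_fitted(self, "categories_")
        x = np.asarray(values, dtype=float).reshape(-1, 1)
        if self.method == "map":
            return pd.Series([self._fmt(v) for v in x.ravel()], dtype="object")
        raw = self.model_.predict(x)
        return pd.Series(
            [self.label_map_.get(int(c), UNSEEN) for c in raw], dtype="object"
        )

    def fit_transform(self, values, y=None) -> pd.Series:
        return self.fit(values).transform(values)


def to_categorical(values, conv: CategoricalConversion) -> pd.Series:
    """Fit-and-apply a categorical conversion to one array variable."""
    return clone(conv).fit_transform(values)


def prepare_dataset(
    table: FeatureTable,
    drop_duplicates: bool = True,
    drop_singleton_classes: bool = False,
) -> FeatureTable:
    """Remove duplicate rows (non-redundant data) and, when flagged,
    classes with exactly one instance.  Removal counts are recorded in
    the returned table's provenance."""
    df = table.df
    n0 = len(df)
    if drop_duplicates:
        df = df.drop_duplicates()
    n_dupes = n0 - len(df)
    n_singleton_classes = 0
    if drop_singleton_classes:
        sizes = df[table.class_col].value_counts()
        keep = sizes[sizes > 1].index
        n_singleton_classes = int((sizes == 1).sum())
        df = df[df[table.class_col].isin(keep)]
        if df.empty:
            raise ValueError("all classes are singletons; nothing left to learn")
    prov = dict(table.provenance)
    prov["_prepare"] = {
        "duplicates_removed": int(n_dupes),
        "singleton_classes_removed": n_singleton_classes,
    }
    return FeatureTable(df.reset_index(drop=True), table.class_col, prov)


def balance(
    table: FeatureTable, method: str = "spread_subsample", seed: int = 0,
    max_spread: float = 1.0,
) -> FeatureTable:
    """Rebalance class masses on a training table.

    ``resample`` draws a stratified sample with replacement of the
    original size with uniform class mass (bias-to-uniform 1.0);
    ``spread_subsample`` downsamples majority classes to at most
    ``max_spread`` x the minority class size.  Apply to training folds
    only.
    """
    df, col = table.df, table.class_col
    sizes = df[col].value_counts()
    if (sizes == 0).any() or df.empty:
        raise ValueError("empty class in training data")
    rng = np.random.default_rng(seed)
    if method == "resample":
        classes = sorted(sizes.index)
        n = len(df)
        per = [n // len(classes)] * len(classes)
        for i in range(n - sum(per)):
            per[i] += 1
        parts = []
        for cls_label, k in zip(classes, per):
            members = df[df[col] == cls_label]
            idx = rng.integers(0, len(members), size=k)
            parts.append(members.iloc[idx])
        out = pd.concat(parts, ignore_index=True)
    elif method == "spread_subsample":
        cap = int(np.floor(max_spread * sizes.min()))
        parts = []
        for cls_label in sorted(sizes.index):
            members = df[df[col] == cls_label]
            if len(members) > cap:
                idx = rng.choice(len(members), size=cap, replace=False)
                members = members.iloc[np.sort(idx)]
            parts.append(members)
        out = pd.concat(parts, ignore_index=True)
    else:
        raise ValueError(f"unknown balance method {method!r}")
    return FeatureTable(out, col, dict(table.provenance))


def split(
    table: FeatureTable, scheme: str, seed: int = 0, holdout_folds: int = 10
):
    """Train/test indices for an evaluation scheme.

    ``cv10`` yields 10 stratified folds (every instance tested once);
    ``split66`` a single stratified 66/34 split; ``stratified_holdout``
    a single stratified 1/``holdout_folds`` holdout intended to be
    persisted to disk.  Classes with one instance raise, pointing to
    :func:`prepare_dataset`.
    """
    df, col = table.df, table.class_col
    y = df[col]
    if (y.value_counts() < 2).any():
        raise ValueError(
            "classes with a single instance cannot be stratified; "
            "run prepare_dataset(drop_singleton_classes=True) first"
        )
    idx = np.arange(len(df))
    if scheme == "cv10":
        cv = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
        return list(cv.split(idx, y))
    if scheme == "split66":
        tr, te = train_test_split(
            idx, test_size=0.34, stratify=y, random_state=seed
        )
        return [(tr, te)]
    if scheme == "stratified_holdout":
        cv = StratifiedKFold(n_splits=holdout_folds, shuffle=True, random_state=seed)
        tr, te = next(iter(cv.split(idx, y)))
        return [(tr, te)]
    raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")


@dataclass
class ClassifierConfig:
    """Bagged random-forest settings (100 bootstrapped trees by default)."""

    n_trees: int = 100
    seed: int = 0
    export_trees: bool = False
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


class MixedRandomForestClassifier(BaseEstimator, ClassifierMixin):
    """Random forest over one-hot-encoded categorical features.

    sklearn-compatible: ``fit(X, y)`` takes a DataFrame of categorical
    columns, ``predict``/``predict_proba`` accept frames with the same
    columns.  Category levels unseen during training are mapped to an
    explicit ``__unseen__`` bucket rather than raising — small classes
    make novel levels at predict time common.

    Attributes (after fit): ``classes_``, ``encoder_``, ``forest_``,
    ``feature_names_in_``.
    """

    def __init__(self, n_trees: int = 100, seed: int = 0,
                 max_depth: int | None = None):
        self.n_trees = n_trees
        self.seed = seed
        self.max_depth = max_depth

    def fit(self, X: pd.DataFrame, y) -> "MixedRandomForestClassifier":
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        y = pd.Series(y).astype(str).to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        X = X.astype(str)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.levels_ = {c: set(X[c].unique()) for c in X.columns}
        self.encoder_ = OneHotEncoder(handle_unknown="ignore", sparse_output=False)
        Xe = self.encoder_.fit_transform(X)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            bootstrap=True,
            random_state=self.seed,
            max_depth=self.max_depth,
        )
        self.forest_.fit(Xe, y)
        self.classes_ = self.forest_.classes_
        return self

    def _encode(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X = X[list(self.feature_names_in_)].astype(str).copy()
        for c in X.columns:
            known = self.levels_[c]
            X[c] = X[c].map(lambda v, known=known: v if v in known else UNSEEN)
        return self.encoder_.transform(X)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.forest_.predict_proba(self._encode(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        # argmax with lexicographically-smallest tie-break (classes_
        # is sorted, argmax returns the first maximum)
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def export_trees(self, max_trees: int | None = None) -> str:
        """Readable text dump of the fitted trees."""
        check_is_fitted(self, "forest_")
        names = list(self.encoder_.get_feature_names_out(self.feature_names_in_))
        chunks = []
        for i, tree in enumerate(self.forest_.estimators_):
            if max_trees is not None and i >= max_trees:
                break
            chunks.append(f"=== tree {i} ===\n" + export_text(tree, feature_names=names))
        return "\n".join(chunks)


def train_random_forest(
    table: FeatureTable, config: ClassifierConfig | None = None
) -> MixedRandomForestClassifier:
    """Fit the bagged random forest on a (training) feature table."""
    config = config or ClassifierConfig()
    model = MixedRandomForestClassifier(
        n_trees=config.n_trees, seed=config.seed, max_depth=config.max_depth
    )
    return model.fit(table.df[table.feature_cols], table.df[table.class_col])


@dataclass
class EvaluationReport:
    scheme: str
    accuracy: float
    per_class: pd.DataFrame  # class -> precision/recall/f1/support
    confusion: pd.DataFrame
    class_distribution: pd.DataFrame  # per-instance probability rows
    tree_model: str = ""

    def to_json(self) -> str:
        doc = {
            "scheme": self.scheme,
            "accuracy": round(self.accuracy, 12),
            "per_class": {
                str(k): {m: round(float(v), 12) for m, v in row.items()}
                for k, row in self.per_class.to_dict(orient="index").items()
            },
            "confusion": {
                str(k): {str(c): int(v) for c, v in row.items()}
                for k, row in self.confusion.to_dict(orient="index").items()
            },
            "class_distribution": [
                {
                    k: (round(float(v), 12) if isinstance(v, float) else v)
                    for k, v in rec.items()
                }
                for rec in self.class_distribution.to_dict(orient="records")
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def evaluate(
    table: FeatureTable,
    scheme: str = "cv10",
    config: ClassifierConfig | None = None,
    balance_method: str | None = "spread_subsample",
    conversions: Mapping[str, CategoricalConversion] | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Run one evaluation scheme end to end.

    Per fold: numeric columns named in ``conversions`` are converted to
    categoricals with parameters fitted on the training rows only, the
    training fold is rebalanced (``balance_method``), the forest is
    fitted, and the held-out rows are scored.  Predictions across
    folds are pooled into one report.
    """
    config = config or ClassifierConfig(seed=seed)
    folds = split(table, scheme, seed=seed)
    df, col = table.df, table.class_col
    classes = np.asarray(sorted(df[col].astype(str).unique()))

    pred = pd.Series(index=df.index, dtype="object")
    proba = pd.DataFrame(0.0, index=df.index, columns=classes)
    tree_model = ""
    for fold_i, (tr, te) in enumerate(folds):
        train_df = df.iloc[tr].copy()
        test_df = df.iloc[te].copy()
        if conversions:
            for c, conv in conversions.items():
                fitted = clone(conv).fit(train_df[c])
                train_df[c] = fitted.transform(train_df[c]).to_numpy()
                test_df[c] = fitted.transform(test_df[c]).to_numpy()
        train_t = FeatureTable(train_df, col)
        if balance_method is not None:
            train_t = balance(train_t, balance_method, seed=seed + fold_i)
        model = MixedRandomForestClassifier(
            n_trees=config.n_trees, seed=config.seed, max_depth=config.max_depth
        ).fit(train_t.df[table.feature_cols], train_t.df[col])
        p = model.predict_proba(test_df[table.feature_cols])
        frame = pd.DataFrame(p, index=test_df.index, columns=model.classes_)
        proba.loc[test_df.index, frame.columns] = frame
        pred.loc[test_df.index] = model.classes_[np.argmax(p, axis=1)]
        if config.export_trees and fold_i == 0:
            tree_model = model.export_trees(max_trees=1)

    tested = pred.notna()
    y_true = df.loc[tested, col].astype(str).to_numpy()
    y_pred = pred[tested].to_numpy()
    acc = float((y_true == y_pred).mean())
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=classes,
    )
    conf = pd.DataFrame(
        confusion_matrix(y_true, y_pred, labels=classes),
        index=classes,
        columns=classes,
    )
    dist = proba.loc[tested].copy()
    dist.insert(0, "predicted", y_pred)
    dist.insert(0, "true_class", y_true)
    dist.insert(0, "instance", dist.index.astype(str))
    return EvaluationReport(
        scheme=scheme,
        accuracy=acc,
        per_class=per_class,
        confusion=conf,
        class_distribution=dist.reset_index(drop=True),
        tree_model=tree_model,
    )
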