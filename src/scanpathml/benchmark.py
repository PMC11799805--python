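"""Cross-validated classification benchmark for encoded vs traditional features.

The evaluation protocol: stratified k-fold cross-validation (each fold
holds out a fixed number of trials per expertise class), a full-factorial
sweep over grid sizes and temporal-group counts for the encoded features,
optional PCA/kernel-PCA feature extraction fitted per fold on the training
split only, a roster of classifiers tuned by inner grid search on balanced
accuracy, and per-fold metrics (AUC, F1, accuracy, sensitivity,
specificity) recorded at the lowest level of granularity and averaged
upward from there.

Class orientation: **trainee is the positive class** — sensitivity is
recall on trainees, specificity is recall on faculty (the experienced
readers are the "true negatives").
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA, KernelPCA
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler

from .encoder import EncodingConfig, encode_dataset
from .gaze_model import GazeDataset, TRAINEE, validate_dataset
from .traditional_features import FEATURE_COLUMNS, extract_traditional

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["auc", "f1", "accuracy", "sensitivity", "specificity"]
KEY_COLUMNS = ["device", "classifier", "data_type", "fe", "grid", "t", "seed", "fold"]

CLASSIFIER_NAMES = ("gp", "lr", "knn", "xgboost")


class SizingError(ValueError):
    """A class has too few members for the requested folds."""


class ComparisonError(ValueError):
    """A comparison needs both data types present."""


@dataclass(frozen=True)
class FeatureExtractionSpec:
    """One dimensionality-reduction variant.

    ``mode="dims"`` keeps exactly ``dims`` components (2 in the reference
    protocol); ``mode="variance"`` keeps the smallest component count whose
    cumulative (kernel-space, for KPCA) eigenvalue fraction reaches
    ``variance_target`` (0.50 / 0.90 / 0.99).  ``method="none"`` passes
    features through untouched.
    """

    method: Literal["none", "pca", "kpca"] = "none"
    mode: Literal["dims", "variance"] = "dims"
    dims: int = 2
    variance_target: float | None = None
    kernel: str = "rbf"  # kpca only; gamma=None means the median heuristic
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("none", "pca", "kpca"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.mode == "variance" and self.method != "none":
            if self.variance_target is None or not 0 < self.variance_target <= 1:
                raise ValueError(
                    "variance mode needs variance_target in (0, 1]"
                )
        if self.mode == "dims" and self.dims < 1:
            raise ValueError("dims must be >= 1")

    @property
    def tag(self) -> str:
        """Short label used in record tables, e.g. ``pca_var90``."""
        if self.method == "none":
            return "none"
        if self.mode == "dims":
            return f"{self.method}_{self.dims}d"
        return f"{self.method}_var{int(round(self.variance_target * 100))}"


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier plus its inner-tuning grid (balanced-accuracy objective).

    Default grids: KNN k in {1,3,5,7,11}; LR C over 5 log-spaced values;
    XGBoost depth {2,3,4} x estimators {50,100,200} x learning rate
    {0.1, 0.3}.  The Gaussian process uses an RBF kernel whose scale is
    optimised on the marginal likelihood (Laplace-approximated binary
    link), so it carries no grid.
    """

    name: str
    param_grid: dict | None = None

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.name!r}; roster: {CLASSIFIER_NAMES}"
            )


DEFAULT_GRIDS: dict[str, dict] = {
    "lr": {"C": list(np.logspace(-2, 2, 5))},
    "knn": {"n_neighbors": [1, 3, 5, 7, 11]},
    "xgboost": {
        "max_depth": [2, 3, 4],
        "n_estimators": [50, 100, 200],
        "learning_rate": [0.1, 0.3],
    },
}


@dataclass(frozen=True)
class SweepConfig:
    """The full-factorial benchmark configuration."""

    grid_sizes: tuple[int, ...] = (5, 7, 10, 15)
    temporal_groups: tuple[int, ...] = (3, 5, 10, 20)
    data_types: tuple[str, ...] = ("encoded", "traditional")
    fe_specs: tuple[FeatureExtractionSpec, ...] = (FeatureExtractionSpec(),)
    classifiers: tuple[ClassifierSpec, ...] = tuple(
        ClassifierSpec(n) for n in ("gp", "lr", "knn", "xgboost")
    )
    k_folds: int = 10
    per_class_holdout: int | None = 5
    seeds: tuple[int, ...] = (0,)
    binning_mode: str = "time"
    standardize_encoded: bool = False
    loc_grid_size: int = 5

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        for dt in self.data_types:
            if dt not in ("encoded", "traditional"):
                raise ValueError(f"unknown data_type {dt!r}")
        if not self.classifiers or not self.fe_specs:
            raise ValueError("classifier and feature-extraction lists must be non-empty")


def stratified_folds(
    labels: Sequence[str] | np.ndarray,
    k: int,
    per_class_holdout: int | None,
    seed: int,
) -> list[np.ndarray]:
    """k disjoint test-index sets, each with a fixed per-class hold-out.

    With ``per_class_holdout`` set, each class's indices are shuffled
    (seeded) and the first ``k * per_class_holdout`` are dealt into k
    disjoint chunks; leftovers never appear in a test set (they stay in
    every training split).  With ``per_class_holdout=None`` a plain
    shuffled stratified k-fold partition is returned.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    if per_class_holdout is None:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in skf.split(np.zeros(len(y)), y)]
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        need = k * per_class_holdout
        if len(idx) < need:
            raise SizingError(
                f"class {cls!r} has {len(idx)} trials; "
                f"{need} needed for {k} folds x {per_class_holdout} hold-out"
            )
        picked = rng.permutation(idx)[:need]
        for f in range(k):
            folds[f].extend(picked[f * per_class_holdout : (f + 1) * per_class_holdout])
    return [np.sort(np.array(f, dtype=np.intp)) for f in folds]


def _median_heuristic_gamma(X: np.ndarray, max_rows: int = 400) -> float:
    """RBF gamma from the median pairwise distance of (a subsample of) X."""
    if len(X) > max_rows:
        X = X[:: max(1, len(X) // max_rows)][:max_rows]
    d = pdist(X)
    med = np.median(d[d > 0]) if np.any(d > 0) else 0.0
    return 1.0 / (2.0 * med * med) if med > 0 else 1.0


def reduce_features(
    train: np.ndarray,
    test: np.ndarray,
    spec: FeatureExtractionSpec,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the projection on ``train`` only and apply it to both splits."""
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if spec.method == "none":
        return train, test
    max_comp = min(train.shape)
    if spec.method == "pca":
        if spec.mode == "dims":
            n = spec.dims
            if n > max_comp:
                logger.warning("dims=%d exceeds rank %d; reduced", n, max_comp)
                n = max_comp
            model = PCA(n_components=n, random_state=seed)
        else:
            # float n_components = smallest count reaching the variance target
            model = PCA(n_components=spec.variance_target, svd_solver="full")
        tr = model.fit_transform(train)
        te = model.transform(test)
        return tr, te
    # kpca
    gamma = spec.gamma
    if gamma is None and spec.kernel == "rbf":
        gamma = _median_heuristic_gamma(train)
    if spec.mode == "dims":
        n = min(spec.dims, max_comp)
        if n < spec.dims:
            logger.warning("dims=%d exceeds rank %d; reduced", spec.dims, max_comp)
        model = KernelPCA(n_components=n, kernel=spec.kernel, gamma=gamma,
                          random_state=seed)
        return model.fit_transform(train), model.transform(test)
    model = KernelPCA(n_components=None, kernel=spec.kernel, gamma=gamma,
                      random_state=seed)
    tr = model.fit_transform(train)
    te = model.transform(test)
    ev = model.eigenvalues_
    frac = np.cumsum(ev) / ev.sum()
    n = int(np.searchsorted(frac, spec.variance_target) + 1)
    return tr[:, :n], te[:, :n]


@dataclass(frozen=True)
class Metrics:
    auc: float
    f1: float
    accuracy: float
    sensitivity: float
    specificity: float


def compute_metrics(
    y_true: np.ndarray, y_score: np.ndarray, y_pred: np.ndarray
) -> Metrics:
    """Fold metrics with trainee as the positive class.

    AUC is the rank statistic (ties count 1/2): the probability a random
    trainee trial scores above a random faculty trial.  On a single-class
    ``y_true`` the AUC is undefined and reported as NaN (with a warning);
    the other metrics are still computed.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    if len(np.unique(y_true)) < 2:
        logger.warning("single-class y_true: AUC undefined, reported as NaN")
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y_true, y_score))
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = (tp + tn) / len(y_true)
    f1 = float(f1_score(y_true, y_pred, pos_label=1, zero_division=0))
    return Metrics(auc=auc, f1=f1, accuracy=acc, sensitivity=sens, specificity=spec)


def make_classifier(spec: ClassifierSpec, seed: int, X_train: np.ndarray | None = None):
    """Instantiate a (tunable) estimator for one classifier spec.

    The Gaussian process RBF length scale starts from the median pairwise
    distance of the training features (when given) before the
    marginal-likelihood optimisation; a unit start is a poor basin for
    unscaled count vectors.
    """
    inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    if spec.name == "gp":
        ls = 1.0
        if X_train is not None and len(X_train) > 1:
            d = pdist(X_train[:400])
            med = float(np.median(d[d > 0])) if np.any(d > 0) else 0.0
            ls = med if med > 0 else 1.0
        kernel = ConstantKernel(1.0) * RBF(ls, length_scale_bounds=(1e-3, 1e6))
        return GaussianProcessClassifier(
            kernel=kernel, random_state=seed, n_restarts_optimizer=0
        )
    if spec.name == "lr":
        est = LogisticRegression(max_iter=2000, random_state=seed)
    elif spec.name == "knn":
        est = KNeighborsClassifier()
    elif spec.name == "xgboost":
        from xgboost import XGBClassifier

        est = XGBClassifier(
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
        )
    else:  # pragma: no cover
        raise ValueError(spec.name)
    grid = spec.param_grid or DEFAULT_GRIDS[spec.name]
    return GridSearchCV(est, grid, scoring="balanced_accuracy", cv=inner, n_jobs=1)


def fit_and_score(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    fe: FeatureExtractionSpec,
    seed: int = 0,
    standardize: bool = False,
) -> Metrics:
    """Tune on the training split, refit, and score the held-out split."""
    if len(np.unique(y_train)) < 2:
        raise SizingError("training split is single-class")
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if standardize:
        scaler = StandardScaler().fit(X_train)
        X_train = scaler.transform(X_train)
        X_test = scaler.transform(X_test)
    X_train, X_test = reduce_features(X_train, X_test, fe, seed=seed)
    clf = make_classifier(spec, seed, X_train)
    clf.fit(X_train, y_train)
    score = clf.predict_proba(X_test)[:, 1]
    pred = clf.predict(X_test)
    return compute_metrics(y_test, score, pred)


def _binary_labels(labels: np.ndarray) -> np.ndarray:
    return (np.asarray(labels) == TRAINEE).astype(int)


def run_sweep(ds: GazeDataset, sweep: SweepConfig) -> pd.DataFrame:
    """Full-factorial benchmark; one record per
    (data_type x fe x grid x t x classifier x seed x fold).

    Traditional-feature rows carry the sentinel ``grid = t = 0``.  The
    returned table is sorted on its key columns so it is independent of
    sweep-list ordering.
    """
    report = validate_dataset(ds)
    for issue in report.issues:
        logger.warning("dataset issue: %s", issue)
    y = _binary_labels(ds.labels)

    feature_sets: dict[tuple[str, int, int], np.ndarray] = {}
    if "encoded" in sweep.data_types:
        for g, t in itertools.product(sweep.grid_sizes, sweep.temporal_groups):
            cfg = EncodingConfig(grid_x=g, t=t, binning_mode=sweep.binning_mode)
            X, _, _, _ = encode_dataset(ds, cfg)
            feature_sets[("encoded", g, t)] = X.astype(float)
    if "traditional" in sweep.data_types:
        table = extract_traditional(ds, loc_grid_size=sweep.loc_grid_size)
        feature_sets[("traditional", 0, 0)] = table[FEATURE_COLUMNS].to_numpy(float)

    rows = []
    for seed in sweep.seeds:
        folds = stratified_folds(y, sweep.k_folds, sweep.per_class_holdout, seed)
        all_idx = np.arange(len(y))
        for (data_type, g, t), X in feature_sets.items():
            standardize = (data_type == "traditional") or sweep.standardize_encoded
            for fe, cspec in itertools.product(sweep.fe_specs, sweep.classifiers):
                for fold_i, test_idx in enumerate(folds):
                    train_idx = np.setdiff1d(all_idx, test_idx)
                    try:
                        m = fit_and_score(
                            cspec,
                            X[train_idx],
                            y[train_idx],
                            X[test_idx],
                            y[test_idx],
                            fe,
                            seed=seed,
                            standardize=standardize,
                        )
                    except SizingError as exc:
                        logger.warning(
                            "skipping fold (classifier=%s data=%s grid=%d t=%d "
                            "seed=%d fold=%d): %s",
                            cspec.name, data_type, g, t, seed, fold_i, exc,
                        )
                        continue
                    except Exception as exc:
                        raise RuntimeError(
                            f"sweep cell failed (classifier={cspec.name} "
                            f"data={data_type} fe={fe.tag} grid={g} t={t} "
                            f"seed={seed} fold={fold_i}): {exc}"
                        ) from exc
                    rows.append(
                        {
                            "device": ds.device,
                            "classifier": cspec.name,
                            "data_type": data_type,
                            "fe": fe.tag,
                            "grid": g,
                            "t": t,
                            "seed": seed,
                            "fold": fold_i,
                            "auc": m.auc,
                            "f1": m.f1,
                            "accuracy": m.accuracy,
                            "sensitivity": m.sensitivity,
                            "specificity": m.specificity,
                        }
                    )
    df = pd.DataFrame(rows, columns=KEY_COLUMNS + METRIC_COLUMNS)
    return df.sort_values(KEY_COLUMNS, kind="stable").reset_index(drop=True)


def aggregate(records: pd.DataFrame, level: Sequence[str]) -> pd.DataFrame:
    """Mean and variance of every metric over records sharing the level key.

    Averaging always starts from the lowest-level records (one per fold),
    never from intermediate averages.
    """
    level = list(level)
    unknown = set(level) - set(KEY_COLUMNS)
    if unknown:
        raise ValueError(f"unknown level columns: {sorted(unknown)}")
    if records.empty:
        cols = level + [f"{m}_{s}" for m in METRIC_COLUMNS for s in ("mean", "var")]
        return pd.DataFrame(columns=cols)
    g = records.groupby(level, as_index=False)[METRIC_COLUMNS].agg(["mean", "var"])
    g.columns = [c if isinstance(c, str) else "_".join(c).rstrip("_") for c in g.columns]
    return g


_FE_ORDER = {"none": 0}  # fe=none sorts first in tie-breaks


def select_best_config(records: pd.DataFrame, classifier: str) -> tuple[int, int, str]:
    """(grid, t, fe) with the highest seed/fold-averaged encoded AUC.

    Ties prefer the smaller grid, then fewer temporal groups, then
    ``fe="none"`` (the simpler model).
    """
    sub = records[
        (records["classifier"] == classifier) & (records["data_type"] == "encoded")
    ]
    if sub.empty:
        raise KeyError(f"no encoded records for classifier {classifier!r}")
    means = sub.groupby(["grid", "t", "fe"])["auc"].mean()
    best = min(
        means.items(),
        key=lambda kv: (-kv[1], kv[0][0], kv[0][1], _FE_ORDER.get(kv[0][2], 1), kv[0][2]),
    )
    return best[0]


def compare_gain(records: pd.DataFrame) -> pd.DataFrame:
    """Encoded-minus-traditional mean gain per device and metric (points).

    Means are taken over all lowest-level records of each data type; the
    difference is expressed in absolute percentage points (x100).
    """
    present = set(records["data_type"].unique()) if not records.empty else set()
    if not {"encoded", "traditional"} <= present:
        raise ComparisonError(
            f"need both data types, found {sorted(present)}"
        )
    rows = []
    for device, dgroup in records.groupby("device"):
        enc = dgroup[dgroup["data_type"] == "encoded"]
        trad = dgroup[dgroup["data_type"] == "traditional"]
        if enc.empty or trad.empty:
            raise ComparisonError(f"device {device!r} lacks one data type")
        for metric in METRIC_COLUMNS:
            rows.append(
                {
                    "device": device,
                    "metric": metric,
                    "encoded_mean": enc[metric].mean(),
                    "traditional_mean": trad[metric].mean(),
                    "gain_points": 100.0 * (enc[metric].mean() - trad[metric].mean()),
                }
            )
    return pd.DataFrame(rows)
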