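"""Nested cross-validated classification of intervention condition.

The evaluation scheme: (1) stratified 80/20 train/test split; (2) the
training set is split into thirds; (3-4) models are fit at each penalty in
the regularization grid on two thirds and validated on the held-out third,
rotating so every third validates once; (5) the penalty with the best mean
inner-validation accuracy is selected (ties go to the strongest
regularization), the model is refit on the full training set and scored on
the test set; (6) the whole procedure is repeated with fresh splits and the
mean and standard error of train/test accuracy over repeats are reported.

Four model families are supported. The linear families (L1 logistic
regression, L1 linear SVM) take the grid values as L1 penalty strengths;
random forests and AdaBoost-SVM have no L1 penalty, so their native
complexity controls (tree depth; number of boosting stages) are searched
over an analogous grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.decomposition import PCA
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .eeg import reduce_pca

logger = logging.getLogger("affectpipe.ml")

__all__ = [
    "MODEL_FAMILIES",
    "CVConfig",
    "FamilyResult",
    "CVResult",
    "GroupwisePCA",
    "nested_cv_classify",
    "reduce_group_pca",
    "hierarchical_evaluation",
]

MODEL_FAMILIES = ("logistic_l1", "svm_l1", "adaboost_svm", "random_forest")

#: Penalty 0 is read as "no regularization" (linear models only).
_NO_PENALTY_C = 1e6


@dataclass
class CVConfig:
    """Cross-validation settings.

    ``regularization_grid`` lists penalty strengths lambda; linear models
    use C = 1/lambda. On equal inner-validation accuracy the largest lambda
    (most regularized model) is selected.
    """

    outer_test_fraction: float = 0.2
    inner_folds: int = 3
    regularization_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
    n_repeats: int = 20
    seed: int = 0
    model_families: tuple[str, ...] = ("logistic_l1",)
    rf_estimators: int = 100

    def validate(self) -> None:
        if not 0.0 < self.outer_test_fraction < 1.0:
            raise ValueError("outer_test_fraction must lie in (0, 1)")
        if not self.regularization_grid:
            raise ValueError("regularization grid must be nonempty")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        unknown = set(self.model_families) - set(MODEL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")


@dataclass
class FamilyResult:
    family: str
    train_accuracies: np.ndarray
    test_accuracies: np.ndarray
    selected_penalties: list[float]
    coefficients: pd.Series | None = None
    failure: str | None = None

    @property
    def train_mean(self) -> float:
        return float(self.train_accuracies.mean())

    @property
    def train_se(self) -> float:
        n = len(self.train_accuracies)
        return float(self.train_accuracies.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    @property
    def test_mean(self) -> float:
        return float(self.test_accuracies.mean())

    @property
    def test_se(self) -> float:
        n = len(self.test_accuracies)
        return float(self.test_accuracies.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0


@dataclass
class CVResult:
    families: dict[str, FamilyResult]

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, fr in self.families.items():
            rows.append(
                {
                    "family": name,
                    "train_mean": fr.train_mean,
                    "train_se": fr.train_se,
                    "test_mean": fr.test_mean,
                    "test_se": fr.test_se,
                    "failure": fr.failure,
                }
            )
        return pd.DataFrame(rows)


def _make_classifier(family: str, lam: float, config: CVConfig, seed: int):
    if family == "logistic_l1":
        C = _NO_PENALTY_C if lam == 0 else 1.0 / lam
        return LogisticRegression(l1_ratio=1.0, solver="liblinear", C=C, max_iter=2000)
    if family == "svm_l1":
        C = _NO_PENALTY_C if lam == 0 else 1.0 / lam
        return LinearSVC(penalty="l1", dual=False, C=C, max_iter=5000)
    if family == "adaboost_svm":
        n_est = 200 if lam == 0 else int(np.clip(round(10.0 / lam), 1, 200))
        return AdaBoostClassifier(
            estimator=LinearSVC(C=1.0, max_iter=5000),
            n_estimators=n_est,
            random_state=seed,
        )
    if family == "random_forest":
        depth = None if lam == 0 else max(1, int(round(3.0 / np.sqrt(lam))))
        return RandomForestClassifier(
            n_estimators=config.rf_estimators, max_depth=depth, random_state=seed
        )
    raise ValueError(f"unknown model family {family!r}")


def _make_pipeline(family, lam, config, seed, preprocessor):
    steps = []
    if preprocessor is not None:
        steps.append(("reduce", clone(preprocessor)))
    steps.append(("scale", StandardScaler()))
    steps.append(("clf", _make_classifier(family, lam, config, seed)))
    return Pipeline(steps)


def _repeat_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def nested_cv_classify(
    features: pd.DataFrame | np.ndarray,
    labels,
    config: CVConfig,
    *,
    preprocessor: "GroupwisePCA | None" = None,
) -> CVResult:
    """Run the full nested cross-validation scheme for each model family.

    Features are standardized inside each training fold; rows with missing
    values are dropped (and logged). For linear families the coefficient
    vector of the best run (highest test accuracy) is reported.
    """
    config.validate()
    if isinstance(features, pd.DataFrame):
        feat_names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        feat_names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(labels).astype(int).ravel()
    ok = ~np.isnan(X).any(axis=1)
    if not ok.all():
        logger.info("dropping %d rows with missing values", int((~ok).sum()))
        X, y = X[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    seeds = _repeat_seeds(config.seed, config.n_repeats)
    grid = sorted(config.regularization_grid)
    results: dict[str, FamilyResult] = {}
    for family in config.model_families:
        tr_accs, te_accs, chosen = [], [], []
        best_coef, best_te = None, -1.0
        failure = None
        try:
            for rep, rs in enumerate(seeds):
                rs = int(rs)
                X_tr, X_te, y_tr, y_te = train_test_split(
                    X, y, test_size=config.outer_test_fraction,
                    stratify=y, random_state=rs,
                )
                skf = StratifiedKFold(
                    n_splits=config.inner_folds, shuffle=True, random_state=rs
                )
                inner_scores = []
                for lam in grid:
                    accs = []
                    for tr_i, va_i in skf.split(X_tr, y_tr):
                        model = _make_pipeline(family, lam, config, rs, preprocessor)
                        model.fit(X_tr[tr_i], y_tr[tr_i])
                        accs.append(model.score(X_tr[va_i], y_tr[va_i]))
                    inner_scores.append(float(np.mean(accs)))
                # Ties go to the strongest regularization (largest lambda).
                best_lam = max(
                    zip(grid, inner_scores), key=lambda t: (t[1], t[0])
                )[0]
                chosen.append(best_lam)
                model = _make_pipeline(family, best_lam, config, rs, preprocessor)
                model.fit(X_tr, y_tr)
                tr_accs.append(model.score(X_tr, y_tr))
                te_acc = model.score(X_te, y_te)
                te_accs.append(te_acc)
                clf = model.named_steps["clf"]
                if te_acc > best_te and hasattr(clf, "coef_"):
                    best_te = te_acc
                    names = feat_names
                    if preprocessor is not None:
                        names = model.named_steps["reduce"].get_feature_names()
                    best_coef = pd.Series(np.ravel(clf.coef_), index=names)
        except Exception as exc:
            failure = f"{type(exc).__name__}: {exc}"
            logger.warning("family %s failed: %s", family, failure)
        results[family] = FamilyResult(
            family=family,
            train_accuracies=np.asarray(tr_accs, dtype=float),
            test_accuracies=np.asarray(te_accs, dtype=float),
            selected_penalties=chosen,
            coefficients=best_coef,
            failure=failure,
        )
    return CVResult(families=results)


# ---------------------------------------------------------------------------
# Group PCA
# ---------------------------------------------------------------------------


def reduce_group_pca(table: pd.DataFrame, k: int = 5):
    """Reduce one feature-group table to k component scores (shared
    implementation with the EEG feature reduction)."""
    return reduce_pca(table, k=k)


class GroupwisePCA(BaseEstimator, TransformerMixin):
    """Per-block standardize + PCA transformer for leak-free group reduction.

    ``blocks`` maps block name -> column indices into the input matrix.
    Blocks wider than ``k`` are standardized and reduced to ``k``
    components fitted on the training data only; narrower blocks pass
    through unchanged.
    """

    def __init__(self, blocks: dict[str, list[int]], k: int = 5):
        self.blocks = blocks
        self.k = k

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.models_ = {}
        for name, cols in self.blocks.items():
            if len(cols) > self.k:
                sub = X[:, cols]
                mu = sub.mean(axis=0)
                sd = sub.std(axis=0, ddof=1)
                sd[sd == 0] = 1.0
                pca = PCA(n_components=self.k, svd_solver="full")
                pca.fit((sub - mu) / sd)
                self.models_[name] = (mu, sd, pca)
            else:
                self.models_[name] = None
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        parts = []
        for name, cols in self.blocks.items():
            model = self.models_[name]
            if model is None:
                parts.append(X[:, cols])
            else:
                mu, sd, pca = model
                parts.append(pca.transform((X[:, cols] - mu) / sd))
        return np.hstack(parts)

    def get_feature_names(self) -> list[str]:
        names = []
        for name, cols in self.blocks.items():
            if self.models_[name] is None:
                names.extend(f"{name}_{i}" for i in range(len(cols)))
            else:
                names.extend(f"{name}_PC{i + 1}" for i in range(self.k))
        return names


# ---------------------------------------------------------------------------
# Hierarchical feature-group evaluation
# ---------------------------------------------------------------------------


def _check_alignment(groups: dict[str, pd.DataFrame]) -> pd.Index:
    names = list(groups)
    ref = groups[names[0]].index
    for name in names[1:]:
        idx = groups[name].index
        if not ref.equals(idx):
            missing = ref.symmetric_difference(idx).tolist()
            raise ValueError(
                f"participant misalignment between {names[0]!r} and {name!r}: {missing}"
            )
    return ref


def hierarchical_evaluation(
    groups: dict[str, pd.DataFrame],
    labels,
    config: CVConfig,
    *,
    k: int = 5,
    pca_mode: str = "fold",
) -> pd.DataFrame:
    """Stepwise addition of feature groups to a baseline group.

    The first group in ``groups`` (conventionally the self-report changes)
    is the baseline; every group is also evaluated alone, and the baseline
    is evaluated together with each additional group. Wide groups (> k
    columns) are PCA-reduced to k components -- inside each training fold
    when ``pca_mode="fold"`` (leak-free, default), or once on the full
    sample when ``pca_mode="global"``.

    Returns a tidy frame with mean +/- SE accuracies per (combination,
    family) and the test-accuracy delta against the baseline-alone result.
    """
    if pca_mode not in ("fold", "global"):
        raise ValueError("pca_mode must be 'fold' or 'global'")
    _check_alignment(groups)
    names = list(groups)
    baseline = names[0]
    combos: list[tuple[str, list[str]]] = [(baseline, [baseline])]
    for name in names[1:]:
        combos.append((name, [name]))
        combos.append((f"{baseline}+{name}", [baseline, name]))

    def evaluate(members: list[str]) -> CVResult:
        if pca_mode == "global":
            parts = []
            for m in members:
                tab = groups[m]
                if tab.shape[1] > k:
                    scores = reduce_group_pca(tab, k=k).scores
                    scores.columns = [f"{m}_{c}" for c in scores.columns]
                    parts.append(scores)
                else:
                    parts.append(tab.add_prefix(f"{m}_"))
            X = pd.concat(parts, axis=1)
            return nested_cv_classify(X, labels, config)
        # fold mode: concatenate raw columns, reduce inside the pipeline
        parts = [groups[m].add_prefix(f"{m}_") for m in members]
        X = pd.concat(parts, axis=1)
        blocks, start = {}, 0
        for m in members:
            width = groups[m].shape[1]
            blocks[m] = list(range(start, start + width))
            start += width
        return nested_cv_classify(
            X, labels, config, preprocessor=GroupwisePCA(blocks, k=k)
        )

    rows = []
    base_test: dict[str, float] = {}
    for combo_name, members in combos:
        result = evaluate(members)
        for family, fr in result.families.items():
            if combo_name == baseline:
                base_test[family] = fr.test_mean
            rows.append(
                {
                    "combination": combo_name,
                    "family": family,
                    "train_mean": fr.train_mean,
                    "train_se": fr.train_se,
                    "test_mean": fr.test_mean,
                    "test_se": fr.test_se,
                    "delta_test_vs_baseline": fr.test_mean - base_test.get(family, np.nan),
                    "failure": fr.failure,
                }
            )
    return pd.DataFrame(rows)
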