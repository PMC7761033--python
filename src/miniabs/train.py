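"""Cross-validated training, model selection and stepwise gene reduction.

The search space is (ssDEG level k, learning algorithm, slack margin alpha):
each configuration trains one classifier on the PGER features of the
level-k candidate gene set with repeated stratified k-fold cross-validation
and a small automatic hyperparameter grid. The initial model is the one
with the smallest gene set whose accuracy is within a tolerance of the
global best; its random-forest Gini importances, summed per gene over the
n-1 incident pair features, rank the genes. Reduction then removes genes
one at a time from the bottom of that ranking (a protected head of the
ranking, located at the largest importance gap, is never touched),
retraining after each removal, and returns the smallest panel whose
accuracy stays within a tolerance of the best seen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import (
    GridSearchCV,
    RepeatedStratifiedKFold,
    train_test_split,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .features import GeneSet, PgerTransformer, _as_samples_by_genes, build_gene_set
from .resources import ALGORITHM_ORDER, ALPHA_GRID, SEED_GENES


def _spawn_seeds(seed: int | None, n: int) -> list[int]:
    """n reproducible child seeds below 2**31 (None stays None)."""
    if seed is None:
        return [None] * n
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def split_train_test(X, labels: pd.Series, ratio: float = 0.8, seed: int | None = None):
    """Stratified train/test split of samples (default 4:1).

    Returns ``(X_train, y_train, X_test, y_test)`` with per-class
    proportions preserved to within rounding.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    X = _as_samples_by_genes(X)
    common = X.index.intersection(labels.index)
    if len(common) == 0:
        raise ValueError("no overlap between expression samples and labels")
    X, y = X.loc[common], labels.loc[common]
    counts = y.value_counts()
    small = sorted(counts.index[counts < 2])
    if small:
        raise ValueError(f"classes with fewer than 2 samples: {small}")
    idx_tr, idx_te = train_test_split(
        np.arange(len(y)),
        train_size=ratio,
        stratify=y.to_numpy(),
        random_state=seed,
        shuffle=True,
    )
    idx_tr, idx_te = np.sort(idx_tr), np.sort(idx_te)
    return X.iloc[idx_tr], y.iloc[idx_tr], X.iloc[idx_te], y.iloc[idx_te]


def _base_and_grid(
    algorithm: str, n_features: int, tune_grid_size: int, n_estimators: int, seed
):
    """Base estimator + automatic hyperparameter grid for one algorithm.

    The grid has ``tune_grid_size`` values per tunable parameter: RF tunes
    the number of features considered per split, SVM the cost (RBF width by
    the usual 1/(p·Var) heuristic), CART the pruning strength, NB the
    variance smoothing.
    """
    g = int(tune_grid_size)
    if g < 1:
        raise ValueError("tune_grid_size must be >= 1")
    if algorithm == "rf":
        base = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        if g == 1:
            vals = [max(1, int(round(np.sqrt(n_features))))]
        else:
            vals = sorted(
                set(
                    int(v)
                    for v in np.round(np.linspace(2, n_features, g)).clip(1, n_features)
                )
            )
        return base, {"max_features": vals}
    if algorithm == "svm":
        base = SVC(kernel="rbf", gamma="scale", random_state=seed)
        return base, {"C": [0.25 * 2**i for i in range(g)]}
    if algorithm == "cart":
        base = DecisionTreeClassifier(random_state=seed)
        return base, {"ccp_alpha": list(np.linspace(0.0, 0.02, g))}
    if algorithm == "nb":
        return GaussianNB(), {"var_smoothing": list(np.logspace(-9, -5, g))}
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHM_ORDER}")


class PairRatioClassifier(BaseEstimator, ClassifierMixin):
    """One (gene set, algorithm, alpha) configuration, tuned by repeated CV.

    Fit builds the PGER feature matrix for ``genes`` at slack margin
    ``alpha`` and tunes the base learner by repeated stratified k-fold
    cross-validation over a small automatic hyperparameter grid, then
    refits on all training data with the winning combination.

    Attributes (after fit)
    ----------------------
    cv_accuracy_ : mean held-out accuracy of the winning combination.
    best_params_ : winning hyperparameters.
    best_estimator_ : refitted base learner.
    feature_names_ : PGER pair names, in feature-matrix column order.
    """

    def __init__(
        self,
        genes: Sequence[str] | None = None,
        alpha: float = 0.0,
        algorithm: str = "rf",
        folds: int = 5,
        repeats: int = 10,
        tune_grid_size: int = 3,
        n_estimators: int = 100,
        random_state: int | None = None,
    ):
        self.genes = genes
        self.alpha = alpha
        self.algorithm = algorithm
        self.folds = folds
        self.repeats = repeats
        self.tune_grid_size = tune_grid_size
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_samples_by_genes(X)
        if isinstance(y, pd.Series):
            y = y.reindex(X.index)
            if y.isna().any():
                missing = sorted(X.index[y.isna()])
                raise ValueError(f"samples without labels: {missing}")
        else:
            y = pd.Series(np.asarray(y, dtype=object), index=X.index)
        counts = y.value_counts()
        small = sorted(counts.index[counts < self.folds])
        if small:
            raise ValueError(
                f"classes with fewer than folds={self.folds} samples: {small}"
            )
        cv_seed, est_seed = _spawn_seeds(self.random_state, 2)
        self.transformer_ = PgerTransformer(list(self.genes), self.alpha).fit(X)
        F = self.transformer_.transform(X)
        base, grid = _base_and_grid(
            self.algorithm, F.shape[1], self.tune_grid_size, self.n_estimators, est_seed
        )
        cv = RepeatedStratifiedKFold(
            n_splits=self.folds, n_repeats=self.repeats, random_state=cv_seed
        )
        search = GridSearchCV(base, grid, scoring="accuracy", cv=cv, refit=True)
        search.fit(F.to_numpy(), y.to_numpy())
        self.cv_accuracy_ = float(search.best_score_)
        self.best_params_ = dict(search.best_params_)
        self.best_estimator_ = search.best_estimator_
        self.feature_names_ = list(self.transformer_.get_feature_names_out())
        self.classes_ = self.best_estimator_.classes_
        return self

    def _features(self, X) -> np.ndarray:
        check_is_fitted(self, "best_estimator_")
        return self.transformer_.transform(_as_samples_by_genes(X)).to_numpy()

    def predict(self, X):
        return self.best_estimator_.predict(self._features(X))

    def predict_proba(self, X):
        return self.best_estimator_.predict_proba(self._features(X))

    @property
    def feature_importances_(self) -> np.ndarray:
        check_is_fitted(self, "best_estimator_")
        if not hasattr(self.best_estimator_, "feature_importances_"):
            raise AttributeError(
                f"algorithm {self.algorithm!r} exposes no Gini feature importances"
            )
        return self.best_estimator_.feature_importances_


def cv_train(
    features_or_X,
    labels: pd.Series,
    algorithm: str = "rf",
    *,
    genes: Sequence[str] | None = None,
    alpha: float = 0.0,
    folds: int = 5,
    repeats: int = 10,
    tune_grid_size: int = 3,
    n_estimators: int = 100,
    seed: int | None = None,
) -> PairRatioClassifier:
    """Thin functional wrapper over :class:`PairRatioClassifier`.

    ``features_or_X`` is a samples-by-genes expression frame (with
    ``genes`` naming the panel) — the estimator computes PGER features
    internally.
    """
    if genes is None:
        genes = list(_as_samples_by_genes(features_or_X).columns)
    model = PairRatioClassifier(
        genes=list(genes),
        alpha=alpha,
        algorithm=algorithm,
        folds=folds,
        repeats=repeats,
        tune_grid_size=tune_grid_size,
        n_estimators=n_estimators,
        random_state=seed,
    )
    return model.fit(features_or_X, labels)


@dataclass
class GridResult:
    """Cross-validation accuracies and fitted models over the search grid."""

    table: pd.DataFrame  # columns: level, algorithm, alpha, n_genes, cv_accuracy
    models: Mapping[tuple[int, str, float], PairRatioClassifier]
    gene_sets: Mapping[int, GeneSet]


def run_grid(
    X,
    labels: pd.Series,
    ssdeg_table: pd.DataFrame,
    seeds: Sequence[str] = SEED_GENES,
    levels: Sequence[int] = (1, 2, 3, 4, 5),
    algorithms: Sequence[str] = ALGORITHM_ORDER,
    alphas: Sequence[float] = ALPHA_GRID,
    *,
    gene_mode: str = "seeds+ssdeg",
    folds: int = 5,
    repeats: int = 10,
    tune_grid_size: int = 3,
    n_estimators: int = 100,
    seed: int | None = None,
) -> GridResult:
    """Train one configuration per (level, algorithm, alpha).

    ``gene_mode`` supports the ablations ``'seeds_only'`` (candidate set is
    the seed genes at every level) and ``'ssdeg_only'`` (no seed genes).
    """
    levels, algorithms, alphas = list(levels), list(algorithms), list(alphas)
    if not levels or not algorithms or not alphas:
        raise ValueError("levels, algorithms and alphas must all be non-empty")
    if gene_mode not in ("seeds+ssdeg", "seeds_only", "ssdeg_only"):
        raise ValueError(f"unknown gene_mode {gene_mode!r}")
    gene_sets: dict[int, GeneSet] = {}
    for k in levels:
        if gene_mode == "seeds_only":
            gene_sets[k] = GeneSet(tuple(seeds), level=k)
        elif gene_mode == "ssdeg_only":
            gene_sets[k] = build_gene_set((), ssdeg_table, k)
        else:
            gene_sets[k] = build_gene_set(seeds, ssdeg_table, k)
    configs = [(k, a, al) for k in levels for a in algorithms for al in alphas]
    child_seeds = _spawn_seeds(seed, len(configs))
    rows, models = [], {}
    for (k, algorithm, alpha), s in zip(configs, child_seeds):
        model = PairRatioClassifier(
            genes=list(gene_sets[k]),
            alpha=alpha,
            algorithm=algorithm,
            folds=folds,
            repeats=repeats,
            tune_grid_size=tune_grid_size,
            n_estimators=n_estimators,
            random_state=s,
        ).fit(X, labels)
        models[(k, algorithm, alpha)] = model
        rows.append(
            dict(
                level=k,
                algorithm=algorithm,
                alpha=alpha,
                n_genes=len(gene_sets[k]),
                cv_accuracy=model.cv_accuracy_,
            )
        )
    return GridResult(pd.DataFrame(rows), models, gene_sets)


def select_initial_model(
    grid: GridResult, tolerance: float = 0.005
) -> tuple[int, PairRatioClassifier]:
    """Smallest level within ``tolerance`` of the global best accuracy.

    Within the chosen level, ties between configurations break by the fixed
    algorithm order then by smaller alpha.
    """
    t = grid.table
    if t.empty:
        raise ValueError("empty grid")
    best_by_level = t.groupby("level")["cv_accuracy"].max()
    global_best = best_by_level.max()
    k_star = int(min(k for k, a in best_by_level.items() if a >= global_best - tolerance))
    sub = t[t["level"] == k_star].copy()
    best_acc = sub["cv_accuracy"].max()
    sub = sub[sub["cv_accuracy"] == best_acc]
    sub["_algo_rank"] = sub["algorithm"].map(
        {a: i for i, a in enumerate(ALGORITHM_ORDER)}
    )
    pick = sub.sort_values(["_algo_rank", "alpha"], kind="stable").iloc[0]
    return k_star, grid.models[(k_star, pick["algorithm"], pick["alpha"])]


def gene_importance(model: PairRatioClassifier) -> pd.DataFrame:
    """Per-gene importance: sum of mean-decrease-Gini over incident pairs.

    Returns a DataFrame (``gene``, ``importance``, ``rank``) sorted by
    descending importance; ties break lexicographically by symbol. Only
    defined for algorithms exposing Gini importances (random forest).
    """
    imp = model.feature_importances_  # raises for non-Gini algorithms
    scores: dict[str, float] = {g: 0.0 for g in model.genes}
    for name, w in zip(model.feature_names_, imp):
        a, b = name.split("/")
        scores[a] += float(w)
        scores[b] += float(w)
    out = (
        pd.DataFrame(
            {"gene": list(scores), "importance": [scores[g] for g in scores]}
        )
        .sort_values(["importance", "gene"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def detect_importance_gap(
    importance: pd.DataFrame, override: int | None = None
) -> int:
    """Protected-gene count: position of the largest consecutive drop.

    The sorted importance sequence is scanned for the largest gap between
    neighbours; everything above the gap is protected from reduction.
    ``override`` short-circuits the detection.
    """
    if override is not None:
        return int(override)
    s = importance.sort_values(
        ["importance", "gene"], ascending=[False, True]
    )["importance"].to_numpy(float)
    if len(s) < 3:
        raise ValueError("need at least 3 genes to detect an importance gap")
    gaps = s[:-1] - s[1:]
    return int(np.argmax(gaps) + 1)


@dataclass
class ReductionResult:
    """Outcome of stepwise gene-set reduction."""

    model: PairRatioClassifier
    genes: tuple[str, ...]
    history: pd.DataFrame = field(repr=False)  # n_genes, removed_gene, cv_accuracy, kept


def reduce_genes(
    initial: PairRatioClassifier,
    X,
    labels: pd.Series,
    importance: pd.DataFrame | None = None,
    protected_count: int | None = None,
    drop_tolerance: float = 0.005,
    *,
    rerank: bool = False,
    seed: int | None = None,
    retrain: Callable[[list[str]], PairRatioClassifier] | None = None,
) -> ReductionResult:
    """Remove low-importance genes one at a time, keep the smallest good panel.

    Starting from the fitted ``initial`` model, the currently
    lowest-ranked unprotected gene is removed and the model retrained with
    the same algorithm/alpha/CV protocol. Removal stops when accuracy falls
    more than ``drop_tolerance`` below the running best, when only
    protected genes remain, or when fewer than three genes would be left.
    Among all models trained (initial included), the one with the fewest
    genes whose accuracy is within ``drop_tolerance`` of the best wins.

    ``rerank=True`` recomputes the importance ranking after each removal
    instead of consuming the initial ranking bottom-up. ``retrain`` may
    replace the default retraining (clone-and-fit) — e.g. for testing.
    """
    if importance is None:
        importance = gene_importance(initial)
    if protected_count is None:
        protected_count = detect_importance_gap(importance)
    genes = list(initial.genes)
    if len(genes) <= protected_count:
        raise ValueError("initial gene set is not larger than the protected count")

    child_seeds = iter(_spawn_seeds(seed, max(len(genes), 1)))

    def _default_retrain(panel: list[str]) -> PairRatioClassifier:
        model = clone(initial)
        model.set_params(genes=list(panel), random_state=next(child_seeds))
        return model.fit(X, labels)

    retrain = retrain or _default_retrain

    ranked = importance.sort_values(
        ["importance", "gene"], ascending=[False, True]
    )["gene"].tolist()
    protected = set(ranked[:protected_count])
    queue = [g for g in reversed(ranked) if g not in protected]

    history = [
        dict(
            n_genes=len(genes),
            removed_gene=None,
            cv_accuracy=initial.cv_accuracy_,
            kept=True,
        )
    ]
    candidates = [(initial, tuple(genes))]
    running_best = initial.cv_accuracy_
    current = list(genes)
    current_model = initial
    while queue and len(current) > 3:
        victim = queue.pop(0)
        trial = [g for g in current if g != victim]
        model = retrain(trial)
        acc = model.cv_accuracy_
        dropped = acc < running_best - drop_tolerance
        history.append(
            dict(
                n_genes=len(trial),
                removed_gene=victim,
                cv_accuracy=acc,
                kept=not dropped,
            )
        )
        if dropped:
            break
        candidates.append((model, tuple(trial)))
        running_best = max(running_best, acc)
        current = trial
        current_model = model
        if rerank:
            new_imp = gene_importance(current_model)
            new_ranked = new_imp.sort_values(
                ["importance", "gene"], ascending=[False, True]
            )["gene"].tolist()
            protected = set(new_ranked[:protected_count])
            queue = [g for g in reversed(new_ranked) if g not in protected]

    best_acc = max(m.cv_accuracy_ for m, _ in candidates)
    good = [(m, g) for m, g in candidates if m.cv_accuracy_ >= best_acc - drop_tolerance]
    model, panel = min(good, key=lambda mg: len(mg[1]))
    return ReductionResult(model=model, genes=panel, history=pd.DataFrame(history))
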