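"""Training grid, model selection, importance ranking and gene reduction."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from miniabs import (
    GridResult,
    cv_train,
    detect_importance_gap,
    gene_importance,
    reduce_genes,
    run_grid,
    select_initial_model,
    split_train_test,
)
from miniabs.resources import SUBTYPES
from conftest import NOISE_GENES, make_cohort


class TestSplit:
    def test_exact_proportions(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            rng.uniform(1, 10, size=(100, 3)),
            index=[f"S{i}" for i in range(100)],
            columns=["GA", "GB", "GC"],
        )
        y = pd.Series(np.repeat(list(SUBTYPES), 20), index=X.index)
        X_tr, y_tr, X_te, y_te = split_train_test(X, y, 0.8, seed=1)
        assert y_tr.value_counts().eq(16).all()
        assert y_te.value_counts().eq(4).all()
        assert set(X_tr.index) | set(X_te.index) == set(X.index)
        assert set(X_tr.index).isdisjoint(X_te.index)

    def test_same_seed_same_partition(self):
        mat, labels = make_cohort(n_per_class=10, seed=2)
        X = mat.to_samples_by_genes()
        a = split_train_test(X, labels, 0.8, seed=9)
        b = split_train_test(X, labels, 0.8, seed=9)
        assert list(a[0].index) == list(b[0].index)
        assert list(a[2].index) == list(b[2].index)

    def test_degenerate_ratios_and_classes(self):
        mat, labels = make_cohort(n_per_class=10, seed=2)
        X = mat.to_samples_by_genes()
        with pytest.raises(ValueError, match="ratio"):
            split_train_test(X, labels, 1.0)
        solo = labels.copy()
        solo.iloc[:] = "LumA"
        solo.iloc[0] = "Her2E"
        with pytest.raises(ValueError, match="Her2E"):
            split_train_test(X, solo, 0.8)


def _two_class_frame(n=60, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    genes = ["GA", "GB", "GC", "GD"]
    X = pd.DataFrame(
        rng.uniform(5, 15, size=(n, len(genes))),
        index=[f"S{i}" for i in range(n)],
        columns=genes,
    )
    y = pd.Series(["LumA"] * (n // 2) + ["LumB"] * (n - n // 2), index=X.index)
    if separable:
        X.loc[y == "LumA", "GA"] *= 16  # +4 log2 units
    return X, y


class TestCvTrain:
    def test_separable_two_class_rf(self):
        X, y = _two_class_frame()
        model = cv_train(X, y, "rf", folds=5, repeats=2, tune_grid_size=2, seed=0)
        assert model.cv_accuracy_ >= 0.95
        assert list(model.feature_names_) == ["GA/GB", "GA/GC", "GA/GD", "GB/GC", "GB/GD", "GC/GD"]

    def test_permuted_labels_near_chance(self):
        X, y = _two_class_frame(separable=False)
        rng = np.random.default_rng(4)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        model = cv_train(X, y_perm, "rf", folds=5, repeats=2, tune_grid_size=1, seed=0)
        majority = y_perm.value_counts(normalize=True).max()
        assert abs(model.cv_accuracy_ - majority) <= 0.1

    def test_deterministic_given_seed(self):
        X, y = _two_class_frame()
        a = cv_train(X, y, "rf", folds=3, repeats=1, tune_grid_size=2, seed=5)
        b = cv_train(X, y, "rf", folds=3, repeats=1, tune_grid_size=2, seed=5)
        assert a.cv_accuracy_ == b.cv_accuracy_
        assert a.best_params_ == b.best_params_

    def test_too_few_per_class_rejected(self):
        X, y = _two_class_frame(n=8)
        with pytest.raises(ValueError, match="fewer than folds"):
            cv_train(X, y, "rf", folds=5, repeats=1)


@pytest.fixture(scope="module")
def tiny_grid():
    mat, labels = make_cohort(delta=3.0, sigma=0.5, n_per_class=10, n_normal_like=6, seed=6)
    from miniabs import call_ssdegs

    table = call_ssdegs(mat, labels, gene_universe=list(mat.genes))
    X = mat.to_samples_by_genes()
    grid = run_grid(
        X,
        labels,
        table,
        levels=[1],
        algorithms=["rf", "nb"],
        alphas=[0.0, 0.1],
        folds=3,
        repeats=1,
        tune_grid_size=1,
        n_estimators=25,
        seed=0,
    )
    return grid, X, labels, table


class TestRunGrid:
    def test_row_count_is_product_of_axes(self, tiny_grid):
        grid, *_ = tiny_grid
        assert len(grid.table) == 1 * 2 * 2
        assert set(grid.models) == {
            (1, "rf", 0.0), (1, "rf", 0.1), (1, "nb", 0.0), (1, "nb", 0.1),
        }

    def test_empty_axes_rejected(self, tiny_grid):
        _, X, labels, table = tiny_grid
        with pytest.raises(ValueError, match="non-empty"):
            run_grid(X, labels, table, algorithms=[])

    def test_ablation_modes_change_gene_sets(self, tiny_grid):
        _, X, labels, table = tiny_grid
        grid_seed = run_grid(
            X, labels, table, levels=[1], algorithms=["nb"], alphas=[0.0],
            gene_mode="seeds_only", folds=3, repeats=1, tune_grid_size=1, seed=0,
        )
        assert list(grid_seed.gene_sets[1]) == ["ESR1", "PGR", "ERBB2", "MKI67"]
        grid_nd = run_grid(
            X, labels, table, levels=[1], algorithms=["nb"], alphas=[0.0],
            gene_mode="ssdeg_only", folds=3, repeats=1, tune_grid_size=1, seed=0,
        )
        # top-1 ssDEG of each subtype, deduplicated, no forced seeds
        assert 1 <= len(grid_nd.gene_sets[1]) <= 5


def _fake_grid(best_by_level):
    rows, models = [], {}
    for level, acc in best_by_level.items():
        rows.append(dict(level=level, algorithm="rf", alpha=0.0, n_genes=3 + 5 * level,
                         cv_accuracy=acc))
        models[(level, "rf", 0.0)] = SimpleNamespace(cv_accuracy_=acc, level=level)
    return GridResult(pd.DataFrame(rows), models, {})


class TestSelectInitialModel:
    def test_smallest_level_within_tolerance(self):
        accs = {1: 0.834, 2: 0.880, 3: 0.879, 4: 0.878, 5: 0.877}
        level, model = select_initial_model(_fake_grid(accs), tolerance=0.005)
        assert level == 2 and model.level == 2

    def test_all_equal_prefers_level_one(self):
        level, _ = select_initial_model(_fake_grid({k: 0.8 for k in range(1, 6)}))
        assert level == 1

    def test_zero_tolerance_strictly_increasing(self):
        accs = {k: 0.7 + 0.01 * k for k in range(1, 6)}
        level, _ = select_initial_model(_fake_grid(accs), tolerance=0.0)
        assert level == 5


def _fake_rf(pair_importances: dict, genes=None):
    names = list(pair_importances)
    if genes is None:
        genes = sorted({g for n in names for g in n.split("/")})
    model = SimpleNamespace(
        genes=genes,
        feature_names_=names,
        feature_importances_=np.array([pair_importances[n] for n in names]),
    )
    return model


class TestGeneImportance:
    def test_sum_over_incident_pairs(self):
        model = _fake_rf({"A/B": 2.0, "A/C": 4.0, "B/C": 6.0})
        imp = gene_importance(model).set_index("gene")
        assert imp.loc["A", "importance"] == 6.0
        assert imp.loc["B", "importance"] == 8.0
        assert imp.loc["C", "importance"] == 10.0
        assert list(gene_importance(model)["gene"]) == ["C", "B", "A"]

    def test_single_pair_tie_breaks_lexicographically(self):
        imp = gene_importance(_fake_rf({"A/B": 5.0}))
        assert list(imp["gene"]) == ["A", "B"]
        assert list(imp["rank"]) == [1, 2]

    def test_all_zero_importances_tied_at_zero(self):
        imp = gene_importance(_fake_rf({"A/B": 0.0, "A/C": 0.0, "B/C": 0.0}))
        assert (imp["importance"] == 0).all()

    def test_conservation_of_total_importance(self):
        vals = {"A/B": 0.1, "A/C": 0.25, "B/C": 0.3, "A/D": 0.05, "B/D": 0.2, "C/D": 0.1}
        model = _fake_rf(vals)
        imp = gene_importance(model)
        assert imp["importance"].sum() == pytest.approx(2 * sum(vals.values()))


class TestImportanceGap:
    def test_two_group_pattern_found(self):
        scores = [60.9, 55, 50, 48, 45, 42, 40.2, 24, 23, 22, 21, 20.5, 20.2]
        imp = pd.DataFrame({"gene": [f"G{i:02d}" for i in range(13)], "importance": scores})
        assert detect_importance_gap(imp) == 7

    def test_linear_decline_gaps_at_first(self):
        imp = pd.DataFrame({"gene": list("ABCDE"), "importance": [5.0, 4, 3, 2, 1]})
        assert detect_importance_gap(imp) == 1

    def test_two_plateaus_split_at_boundary(self):
        imp = pd.DataFrame({"gene": list("ABCDEF"), "importance": [9.0, 9, 9, 2, 2, 2]})
        assert detect_importance_gap(imp) == 3

    def test_override_and_minimum_size(self):
        imp = pd.DataFrame({"gene": list("AB"), "importance": [2.0, 1.0]})
        with pytest.raises(ValueError, match="3 genes"):
            detect_importance_gap(imp)
        assert detect_importance_gap(imp, override=1) == 1


def _mocked_reduction(accuracies, initial_acc=0.8804, n_genes=13, tol=0.005):
    genes = [f"G{i:02d}" for i in range(1, n_genes + 1)]
    importance = pd.DataFrame(
        {"gene": genes, "importance": np.linspace(10.0, 1.0, n_genes)}
    )
    initial = SimpleNamespace(genes=genes, cv_accuracy_=initial_acc)
    acc_iter = iter(accuracies)

    def retrain(panel):
        return SimpleNamespace(genes=list(panel), cv_accuracy_=next(acc_iter))

    return reduce_genes(
        initial,
        None,
        None,
        importance=importance,
        protected_count=7,
        drop_tolerance=tol,
        retrain=retrain,
    )


class TestReduceGenes:
    def test_published_trajectory_returns_eleven_gene_model(self):
        res = _mocked_reduction([0.8826, 0.8824, 0.8412])
        assert len(res.genes) == 11
        assert res.model.cv_accuracy_ == 0.8824
        # the drop that stopped the search is recorded but not kept
        assert list(res.history["kept"]) == [True, True, True, False]

    def test_monotone_increase_runs_to_protected_floor(self):
        res = _mocked_reduction([0.89, 0.90, 0.91, 0.92, 0.93, 0.94])
        assert len(res.genes) == 7
        assert res.model.cv_accuracy_ == 0.94

    def test_immediate_drop_returns_initial_model(self):
        res = _mocked_reduction([0.80])
        assert len(res.genes) == 13
        assert res.model.cv_accuracy_ == 0.8804

    def test_initial_set_must_exceed_protected_count(self):
        initial = SimpleNamespace(genes=list("ABCDEFG"), cv_accuracy_=0.9)
        imp = pd.DataFrame({"gene": list("ABCDEFG"), "importance": np.arange(7.0, 0, -1)})
        with pytest.raises(ValueError, match="protected"):
            reduce_genes(initial, None, None, importance=imp, protected_count=7)


class TestReductionRecovery:
    """Reduction on planted data removes only non-informative genes."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_only_noise_genes_removed(self, seed, pipeline_runs):
        if seed < 3:
            run = pipeline_runs(seed)
            removed = set(run.initial.genes) - set(run.reduction.genes)
        else:
            # cheaper reduction-only runs for the extra seeds
            from miniabs.train import PairRatioClassifier

            mat, labels = make_cohort(
                delta=2.0, sigma=0.7, n_normal_like=60, seed=seed
            )
            X = mat.to_samples_by_genes()
            X_tr, y_tr, _, _ = split_train_test(X, labels, 0.8, seed=seed)
            initial = PairRatioClassifier(
                genes=list(mat.genes), alpha=0.1, algorithm="rf",
                folds=5, repeats=1, tune_grid_size=1, random_state=seed,
            ).fit(X_tr, y_tr)
            res = reduce_genes(initial, X_tr, y_tr, seed=seed)
            removed = set(initial.genes) - set(res.genes)
        assert removed <= set(NOISE_GENES)
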