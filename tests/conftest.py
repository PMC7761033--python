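"""Shared fixtures: small simulated cohorts and the end-to-end pipeline run.

The pipeline fixture is session-scoped and cached per seed because the
construction chain (ssDEG calling, initial CV training, stepwise gene
reduction, slack-margin ensemble) is by far the most expensive thing the
suite does; several tests interrogate different aspects of the same run.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from miniabs import (
    MiniAbsClassifier,
    SimConfig,
    call_ssdegs,
    default_markers,
    detect_importance_gap,
    gene_importance,
    reduce_genes,
    score,
    simulate,
    split_train_test,
)
from miniabs.train import PairRatioClassifier

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: 13-gene study design: 8 informative markers (all five subtypes covered,
#: Normal-like rare and weakly shifted) + 5 pure-noise genes.
NOISE_GENES = ("FOXA1", "MYBL2", "GRB7", "KRT14", "FGFR4")
MAJOR_SUBTYPES = ("Basal-like", "Her2E", "LumA", "LumB")


def make_cohort(
    delta: float = 2.0,
    sigma: float = 0.7,
    n_per_class: int = 60,
    n_normal_like: int = 7,
    seed: int = 0,
):
    sizes = {s: n_per_class for s in MAJOR_SUBTYPES}
    sizes["Normal-like"] = n_normal_like
    cfg = SimConfig(
        class_sizes=sizes,
        markers=default_markers(delta),
        noise_gene_names=NOISE_GENES,
        noise_sd=sigma,
        seed=seed,
    )
    return simulate(cfg)


@dataclass
class PipelineRun:
    """One full construction run on a synthetic cohort."""

    seed: int
    mat: object
    labels: pd.Series
    ssdeg_table: pd.DataFrame
    initial: PairRatioClassifier
    importance: pd.DataFrame
    protected_count: int
    reduction: object
    ensemble: MiniAbsClassifier
    report_major: object
    X_test: pd.DataFrame
    y_test: pd.Series


def _run_pipeline(seed: int) -> PipelineRun:
    mat, labels = make_cohort(delta=2.0, sigma=0.7, n_normal_like=60, seed=seed)
    table = call_ssdegs(mat, labels, gene_universe=list(mat.genes))
    X = mat.to_samples_by_genes()
    X_tr, y_tr, X_te, y_te = split_train_test(X, labels, 0.8, seed=seed)
    initial = PairRatioClassifier(
        genes=list(mat.genes),
        alpha=0.1,
        algorithm="rf",
        folds=5,
        repeats=2,
        tune_grid_size=2,
        random_state=seed,
    ).fit(X_tr, y_tr)
    importance = gene_importance(initial)
    protected = detect_importance_gap(importance)
    reduction = reduce_genes(
        initial,
        X_tr,
        y_tr,
        importance=importance,
        protected_count=protected,
        seed=seed,
    )
    ensemble = MiniAbsClassifier(
        genes=list(reduction.genes),
        algorithm="rf",
        folds=5,
        repeats=2,
        tune_grid_size=2,
        random_state=seed,
    ).fit(X_tr, y_tr)
    report = score(ensemble.predict_result(X_te), y_te, exclude_normal_like=True)
    return PipelineRun(
        seed=seed,
        mat=mat,
        labels=labels,
        ssdeg_table=table,
        initial=initial,
        importance=importance,
        protected_count=protected,
        reduction=reduction,
        ensemble=ensemble,
        report_major=report,
        X_test=X_te,
        y_test=y_te,
    )


@pytest.fixture(scope="session")
def pipeline_runs():
    """Factory with cross-test caching of full pipeline runs per seed."""
    cache: dict[int, PipelineRun] = {}

    def get(seed: int) -> PipelineRun:
        if seed not in cache:
            cache[seed] = _run_pipeline(seed)
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def small_ensemble():
    """A cheap trained ensemble over a well-separated small cohort."""
    mat, labels = make_cohort(delta=3.0, sigma=0.5, n_per_class=12, n_normal_like=6, seed=42)
    X = mat.to_samples_by_genes()
    model = MiniAbsClassifier(
        genes=[g for g in mat.genes if g not in NOISE_GENES],
        algorithm="rf",
        folds=3,
        repeats=1,
        tune_grid_size=1,
        n_estimators=50,
        random_state=42,
    ).fit(X, labels)
    return model, mat, labels


@pytest.fixture(scope="session")
def separable_cohort():
    return make_cohort(delta=3.0, sigma=0.5, n_per_class=30, n_normal_like=8, seed=7)
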