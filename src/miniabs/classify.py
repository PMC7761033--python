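"""The slack-margin ensemble classifier and its model archive format.

The deployed classifier is an ensemble of seven members, one per slack
margin alpha in the grid, all sharing the same gene panel and learning
algorithm. A new sample is featurised once per alpha and classified by the
matching member; the final call is the unique mode of the member votes,
and a tied mode yields the sentinel ``Ambiguous`` (scored as incorrect
downstream). Because PGER features are computed within-sample, a sample's
call is exactly independent of whatever cohort it arrives in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .features import _as_samples_by_genes
from .resources import ALPHA_GRID, AMBIGUOUS, MINIABS_PANEL, SUBTYPES
from .train import PairRatioClassifier, _spawn_seeds

FORMAT_VERSION = 1


@dataclass
class PredictionResult:
    """Per-sample member votes, vote counts and final calls.

    ``votes``: samples x alphas (column names ``"alpha=0.05"`` etc.);
    ``counts``: samples x subtypes vote tallies (rows sum to the ensemble
    size); ``final``: Series of final calls, one of the five subtypes or
    ``Ambiguous`` when the modal count is shared.
    """

    votes: pd.DataFrame
    counts: pd.DataFrame
    final: pd.Series

    @property
    def sample_ids(self) -> pd.Index:
        return self.final.index

    def to_frame(self) -> pd.DataFrame:
        out = self.votes.copy()
        out["final_call"] = self.final
        return out


def majority_call(votes: Sequence[str]) -> str:
    """Unique modal vote, or ``Ambiguous`` on a tied mode."""
    counts = pd.Series(list(votes)).value_counts()
    top = counts.max()
    winners = counts.index[counts == top]
    return str(winners[0]) if len(winners) == 1 else AMBIGUOUS


class MiniAbsClassifier(BaseEstimator, ClassifierMixin):
    """Absolute single-sample subtype classifier over a small gene panel.

    Parameters
    ----------
    genes : panel; defaults to the shipped 11-gene reference panel.
    alphas : slack-margin grid; one ensemble member is trained per value.
    algorithm : base learner for every member ('rf', 'svm', 'cart', 'nb').
    vote : 'hard' counts one vote per member (default); 'proba' averages
        member class probabilities instead (requires a probabilistic
        learner) — ties then only arise on exactly equal probabilities.
    folds, repeats, tune_grid_size, n_estimators, random_state : member
        cross-validation / tuning protocol, as in
        :class:`~miniabs.train.PairRatioClassifier`.
    """

    def __init__(
        self,
        genes: Sequence[str] | None = None,
        alphas: Sequence[float] = ALPHA_GRID,
        algorithm: str = "rf",
        folds: int = 5,
        repeats: int = 10,
        tune_grid_size: int = 3,
        n_estimators: int = 100,
        vote: str = "hard",
        random_state: int | None = None,
    ):
        self.genes = genes
        self.alphas = alphas
        self.algorithm = algorithm
        self.folds = folds
        self.repeats = repeats
        self.tune_grid_size = tune_grid_size
        self.n_estimators = n_estimators
        self.vote = vote
        self.random_state = random_state

    def _panel(self) -> list[str]:
        return list(self.genes) if self.genes is not None else list(MINIABS_PANEL)

    def _alpha_grid(self) -> list[float]:
        alphas = [float(a) for a in self.alphas]
        if len(set(alphas)) != len(alphas):
            raise ValueError("alpha values must be distinct")
        if any(a < 0 for a in alphas):
            raise ValueError("alpha values must be >= 0")
        return sorted(alphas)

    def fit(self, X, y):
        if self.vote not in ("hard", "proba"):
            raise ValueError("vote must be 'hard' or 'proba'")
        panel, alphas = self._panel(), self._alpha_grid()
        seeds = _spawn_seeds(self.random_state, len(alphas))
        self.members_ = {}
        for alpha, seed in zip(alphas, seeds):
            self.members_[alpha] = PairRatioClassifier(
                genes=panel,
                alpha=alpha,
                algorithm=self.algorithm,
                folds=self.folds,
                repeats=self.repeats,
                tune_grid_size=self.tune_grid_size,
                n_estimators=self.n_estimators,
                random_state=seed,
            ).fit(X, y)
        self.panel_ = tuple(panel)
        self.alphas_ = tuple(alphas)
        self.classes_ = next(iter(self.members_.values())).classes_
        self.cv_accuracies_ = {a: m.cv_accuracy_ for a, m in self.members_.items()}
        return self

    def _validate_input(self, X) -> pd.DataFrame:
        check_is_fitted(self, "members_")
        X = _as_samples_by_genes(X)
        missing = sorted(set(self.panel_) - set(X.columns))
        if missing:
            raise KeyError(f"panel genes absent from input: {missing}")
        return X

    def predict_result(self, X) -> PredictionResult:
        """Full prediction record: member votes, tallies, final calls."""
        X = self._validate_input(X)
        votes = pd.DataFrame(index=X.index)
        if self.vote == "hard":
            for alpha in self.alphas_:
                votes[f"alpha={alpha:g}"] = self.members_[alpha].predict(X)
            counts = pd.DataFrame(
                0, index=X.index, columns=list(self.classes_), dtype=int
            )
            for col in votes.columns:
                for cls in self.classes_:
                    counts[cls] += (votes[col] == cls).astype(int)
            final = votes.apply(lambda row: majority_call(row.to_list()), axis=1)
        else:
            proba = np.zeros((len(X), len(self.classes_)))
            for alpha in self.alphas_:
                member = self.members_[alpha]
                p = member.predict_proba(X)
                order = [list(member.classes_).index(c) for c in self.classes_]
                proba += p[:, order]
                votes[f"alpha={alpha:g}"] = member.predict(X)
            proba /= len(self.alphas_)
            counts = pd.DataFrame(proba, index=X.index, columns=list(self.classes_))
            best = proba.max(axis=1, keepdims=True)
            n_top = (proba == best).sum(axis=1)
            calls = np.asarray(self.classes_, dtype=object)[proba.argmax(axis=1)]
            calls[n_top > 1] = AMBIGUOUS
            final = pd.Series(calls, index=X.index)
        final.name = "final_call"
        return PredictionResult(votes=votes, counts=counts, final=final)

    def predict(self, X) -> np.ndarray:
        return self.predict_result(X).final.to_numpy(dtype=object)

    def predict_single(self, expression: Mapping[str, float]) -> PredictionResult:
        """Classify one sample from a gene->linear-expression mapping.

        The single-sample guarantee holds by construction: the result is
        identical to this sample's row when classified inside any cohort.
        """
        check_is_fitted(self, "members_")
        missing = sorted(set(self.panel_) - set(expression))
        if missing:
            raise KeyError(f"panel genes absent from sample: {missing}")
        row = pd.DataFrame(
            [[float(expression[g]) for g in self.panel_]],
            index=pd.Index(["sample"], name="sample_id"),
            columns=list(self.panel_),
        )
        return self.predict_result(row)


def save_model(model: MiniAbsClassifier, out_dir) -> Path:
    """Persist an ensemble as a directory: plain-text manifest + one
    serialized member per alpha."""
    check_is_fitted(model, "members_")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "panel": list(model.panel_),
        "alphas": [float(a) for a in model.alphas_],
        "algorithm": model.algorithm,
        "vote": model.vote,
        "classes": [str(c) for c in model.classes_],
        "cv_accuracies": {f"{a:g}": acc for a, acc in model.cv_accuracies_.items()},
        "hyperparameters": {
            f"{a:g}": model.members_[a].best_params_ for a in model.alphas_
        },
        "folds": model.folds,
        "repeats": model.repeats,
        "tune_grid_size": model.tune_grid_size,
        "n_estimators": model.n_estimators,
        "random_state": model.random_state,
        "members": {f"{a:g}": f"member_alpha_{a:g}.joblib" for a in model.alphas_},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    for a in model.alphas_:
        joblib.dump(model.members_[a], out / manifest["members"][f"{a:g}"])
    return out


def load_model(model_dir) -> MiniAbsClassifier:
    """Load an ensemble saved by :func:`save_model`."""
    model_dir = Path(model_dir)
    manifest = json.loads((model_dir / "manifest.json").read_text())
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported model archive format: {manifest.get('format_version')!r}"
        )
    model = MiniAbsClassifier(
        genes=manifest["panel"],
        alphas=manifest["alphas"],
        algorithm=manifest["algorithm"],
        folds=manifest["folds"],
        repeats=manifest["repeats"],
        tune_grid_size=manifest["tune_grid_size"],
        n_estimators=manifest["n_estimators"],
        vote=manifest["vote"],
        random_state=manifest["random_state"],
    )
    model.members_ = {
        float(a): joblib.load(model_dir / fname)
        for a, fname in manifest["members"].items()
    }
    model.panel_ = tuple(manifest["panel"])
    model.alphas_ = tuple(sorted(model.members_))
    model.classes_ = np.asarray(manifest["classes"], dtype=object)
    model.cv_accuracies_ = {
        float(a): acc for a, acc in manifest["cv_accuracies"].items()
    }
    return model


def predict(model: MiniAbsClassifier, mat) -> PredictionResult:
    """Functional wrapper: classify every sample of an expression matrix."""
    return model.predict_result(mat)


def predict_single(model: MiniAbsClassifier, expression: Mapping[str, float]):
    """Functional wrapper over :meth:`MiniAbsClassifier.predict_single`."""
    return model.predict_single(expression)
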