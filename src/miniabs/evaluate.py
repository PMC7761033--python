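"""Scoring predictions: accuracy, Cohen's kappa, confusion matrices.

Ambiguous calls (tied ensemble votes) always count as incorrect, even when
one of the tied subtypes matches the truth; they appear as an extra
prediction row of the confusion matrix with no truth column. Because the
Normal-like subtype is contested (often attributed to normal-tissue
contamination), every report can be produced with and without the samples
whose *truth* label is Normal-like.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import PredictionResult
from .resources import AMBIGUOUS, SUBTYPES


def cohens_kappa(confusion: np.ndarray) -> tuple[float, float, float, float]:
    """Cohen's kappa with asymptotic 95% CI from a square confusion matrix.

    Returns ``(kappa, se, lo, hi)``. The standard error is the common
    asymptotic approximation ``sqrt(po(1-po)/(n(1-pe)^2))``.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = c.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(c) / n
    pe = float((c.sum(axis=1) / n) @ (c.sum(axis=0) / n))
    if 1.0 - pe < 1e-12:
        # both raters constant on the same category
        return (1.0 if po > 1.0 - 1e-12 else 0.0), 0.0, np.nan, np.nan
    kappa = (po - pe) / (1.0 - pe)
    se = float(np.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2)))
    return float(kappa), se, float(kappa - 1.96 * se), float(kappa + 1.96 * se)


@dataclass
class EvalReport:
    """Scored prediction set.

    ``confusion`` rows are predicted classes (plus ``Ambiguous``), columns
    are truth classes; ``accuracy`` counts Ambiguous as incorrect and its
    denominator includes those samples.
    """

    n_scored: int
    accuracy: float
    kappa: float
    kappa_se: float
    kappa_ci: tuple[float, float]
    confusion: pd.DataFrame
    normal_like_excluded: bool
    n_ambiguous: int

    def to_text(self) -> str:
        lines = [
            f"samples scored      : {self.n_scored}",
            f"accuracy            : {self.accuracy:.4f}",
            f"Cohen's kappa       : {self.kappa:.4f} "
            f"(95% CI {self.kappa_ci[0]:.4f}-{self.kappa_ci[1]:.4f})",
            f"ambiguous calls     : {self.n_ambiguous}",
            f"Normal-like excluded: {self.normal_like_excluded}",
            "",
            "confusion matrix (rows = predicted, columns = truth):",
            self.confusion.to_string(),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        path = Path(path)
        self.confusion.rename_axis("predicted").to_csv(path, sep="\t")
        stats = path.with_name(path.stem + "_stats.tsv")
        pd.DataFrame(
            {
                "metric": [
                    "n_scored",
                    "accuracy",
                    "kappa",
                    "kappa_se",
                    "kappa_ci_low",
                    "kappa_ci_high",
                    "n_ambiguous",
                    "normal_like_excluded",
                ],
                "value": [
                    self.n_scored,
                    self.accuracy,
                    self.kappa,
                    self.kappa_se,
                    self.kappa_ci[0],
                    self.kappa_ci[1],
                    self.n_ambiguous,
                    self.normal_like_excluded,
                ],
            }
        ).to_csv(stats, sep="\t", index=False)


def _calls(pred) -> pd.Series:
    if isinstance(pred, PredictionResult):
        return pred.final
    return pd.Series(pred)


def score(
    pred, truth: pd.Series, exclude_normal_like: bool = False
) -> EvalReport:
    """Score final calls against reference labels.

    ``pred`` is a :class:`~miniabs.classify.PredictionResult` or a Series
    of calls indexed by sample. With ``exclude_normal_like``, samples whose
    truth label is Normal-like are dropped before scoring; predictions of
    Normal-like for other samples still count (as errors).
    """
    calls = _calls(pred)
    common = calls.index.intersection(truth.index)
    if len(common) == 0:
        raise ValueError("no overlap between predictions and truth labels")
    calls, truth = calls.loc[common], truth.loc[common]
    if exclude_normal_like:
        keep = truth != "Normal-like"
        calls, truth = calls[keep], truth[keep]
        if len(calls) == 0:
            raise ValueError("no samples left after excluding Normal-like")
    truth_classes = [s for s in SUBTYPES if not (exclude_normal_like and s == "Normal-like")]
    unknown = sorted(set(truth) - set(truth_classes))
    if unknown:
        raise ValueError(f"truth labels outside the subtype set: {unknown}")
    # predictions may name any subtype (e.g. Normal-like calls on excluded
    # cohorts still count, as errors); Ambiguous is an extra prediction row
    pred_classes = list(SUBTYPES) + [AMBIGUOUS]
    confusion = pd.DataFrame(0, index=pred_classes, columns=truth_classes, dtype=int)
    for p, t in zip(calls, truth):
        row = p if p in pred_classes else AMBIGUOUS
        confusion.loc[row, t] += 1
    n = int(confusion.to_numpy().sum())
    correct = sum(confusion.loc[c, c] for c in truth_classes)
    accuracy = correct / n
    # square matrix for kappa: prediction-only categories (Ambiguous, and
    # Normal-like under exclusion) get all-zero truth columns
    square = confusion.reindex(columns=pred_classes, fill_value=0)
    kappa, se, lo, hi = cohens_kappa(square.to_numpy())
    return EvalReport(
        n_scored=n,
        accuracy=float(accuracy),
        kappa=kappa,
        kappa_se=se,
        kappa_ci=(lo, hi),
        confusion=confusion,
        normal_like_excluded=bool(exclude_normal_like),
        n_ambiguous=int(confusion.loc[AMBIGUOUS].sum()),
    )
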