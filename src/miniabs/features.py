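"""Candidate gene sets and slack-thresholded pairwise expression ratios.

The classifier never sees single-gene expression. For a gene set of size n
it sees the n(n-1)/2 pairwise gene expression ratios (PGER)

    r_ij = log2((e_i + 1) / (e_j + 1)),   1 <= i < j <= n,

computed on raw linear expression, then soft-thresholded by a slack margin
alpha that treats ratios within +/-alpha of zero as experimental noise:

    r'_ij = 0            if |r_ij| <= alpha
          = r_ij - alpha if  r_ij  >  alpha
          = r_ij + alpha if  r_ij  < -alpha

Because both the ratio and the margin live inside one sample, the features
— and everything downstream — are independent of cohort composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix
from .resources import ALPHA_GRID, SEED_GENES, SUBTYPES  # noqa: F401  (re-export)

PAIR_SEP = "/"


@dataclass(frozen=True)
class GeneSet:
    """Ordered, duplicate-free gene panel with provenance.

    ``provenance`` maps each gene to ``"seed"`` or ``"ssDEG(<subtype>, rank
    <r>)"``; ``level`` is the ssDEG depth k the set was built at.
    """

    genes: tuple[str, ...]
    level: int = 0
    provenance: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene set contains duplicates")

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def build_gene_set(
    seeds: Sequence[str], table: pd.DataFrame, k: int
) -> GeneSet:
    """Union of seed genes and the top-k ssDEGs of each subtype.

    Insertion order is seeds first, then subtypes in canonical order by
    ascending rank; duplicates keep their first occurrence. ``table`` needs
    columns ``subtype``, ``rank``, ``gene`` (e.g. the output of
    :func:`miniabs.ssdeg.call_ssdegs` or the bundled reference ranking).
    """
    if k < 0:
        raise ValueError("level k must be >= 0")
    ordered: dict[str, str] = {}
    for g in seeds:
        ordered.setdefault(g, "seed")
    if k > 0:
        for subtype in SUBTYPES:
            sub = table[table["subtype"] == subtype].set_index("rank")["gene"]
            if not set(range(1, k + 1)) <= set(sub.index):
                raise ValueError(
                    f"ssDEG table has fewer than {k} ranked genes for {subtype!r}"
                )
            for r in range(1, k + 1):
                ordered.setdefault(sub.loc[r], f"ssDEG({subtype}, rank {r})")
    return GeneSet(tuple(ordered), level=k, provenance=ordered)


def pger(e_i, e_j):
    """Pairwise gene expression ratio log2((e_i+1)/(e_j+1)), elementwise."""
    e_i = np.asarray(e_i, dtype=float)
    e_j = np.asarray(e_j, dtype=float)
    if (e_i < 0).any() or (e_j < 0).any():
        raise ValueError("expression values must be non-negative (linear scale)")
    out = np.log2(e_i + 1.0) - np.log2(e_j + 1.0)
    return out if out.shape else float(out)


def slack_transform(r, alpha: float):
    """Soft-threshold a ratio by the slack margin alpha (see module docstring)."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    r = np.asarray(r, dtype=float)
    out = np.sign(r) * np.maximum(np.abs(r) - alpha, 0.0)
    return out if out.shape else float(out)


def pair_names(genes: Sequence[str]) -> list[str]:
    """Feature names ``"Gi/Gj"`` for all pairs i<j in gene-set order."""
    return [f"{a}{PAIR_SEP}{b}" for a, b in combinations(genes, 2)]


class PgerTransformer(BaseEstimator, TransformerMixin):
    """Turn a samples-by-genes expression frame into PGER features.

    Parameters
    ----------
    genes:
        Ordered gene panel; pair orientation and feature order follow it.
    alpha:
        Slack margin (log2 units), >= 0.

    The transform of each sample depends only on that sample's values.
    """

    def __init__(self, genes: Sequence[str] | None = None, alpha: float = 0.0):
        self.genes = genes
        self.alpha = alpha

    def _resolved_genes(self) -> list[str]:
        if self.genes is None or len(self.genes) < 2:
            raise ValueError("PgerTransformer needs an ordered panel of >= 2 genes")
        return list(self.genes)

    def fit(self, X, y=None):
        genes = self._resolved_genes()
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        X = _as_samples_by_genes(X)
        missing = sorted(set(genes) - set(X.columns))
        if missing:
            raise KeyError(f"genes absent from expression input: {missing}")
        self.feature_names_out_ = np.asarray(pair_names(genes), dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "feature_names_out_")
        genes = self._resolved_genes()
        X = _as_samples_by_genes(X)
        missing = sorted(set(genes) - set(X.columns))
        if missing:
            raise KeyError(f"genes absent from expression input: {missing}")
        E = X.loc[:, genes].to_numpy(dtype=float)
        if not np.isfinite(E).all():
            raise ValueError("expression values must be finite")
        if (E < 0).any():
            raise ValueError("expression values must be non-negative (linear scale)")
        L = np.log2(E + 1.0)
        i_idx, j_idx = np.triu_indices(len(genes), k=1)
        R = L[:, i_idx] - L[:, j_idx]
        out = pd.DataFrame(
            slack_transform(R, self.alpha), index=X.index, columns=self.feature_names_out_
        )
        out.attrs["alpha"] = self.alpha
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_out_")
        return self.feature_names_out_


def _as_samples_by_genes(X) -> pd.DataFrame:
    """Accept an ExpressionMatrix (genes x samples) or a samples-by-genes frame."""
    if isinstance(X, ExpressionMatrix):
        return X.to_samples_by_genes()
    if not isinstance(X, pd.DataFrame):
        raise TypeError(
            "expression input must be an ExpressionMatrix or a samples-by-genes DataFrame"
        )
    return X


def feature_matrix(mat, genes: Sequence[str] | GeneSet, alpha: float) -> pd.DataFrame:
    """Samples x gene-pair PGER matrix (``.attrs['alpha']`` records alpha)."""
    genes = list(genes)
    return PgerTransformer(genes=genes, alpha=alpha).fit(mat).transform(mat)


def feature_subtype_separation(
    features: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Kruskal–Wallis p-value per PGER column across subtype groups.

    Columns that are constant across all samples carry no rank signal;
    they get p=1 and ``degenerate=True``.
    """
    common = features.index.intersection(labels.index)
    lab = labels.loc[common]
    groups = sorted(set(lab))
    if len(groups) < 2:
        raise ValueError("need at least two classes for separation testing")
    feats = features.loc[common]
    recs = []
    for col in feats.columns:
        vals = [feats.loc[lab == g, col].to_numpy(float) for g in groups]
        if np.ptp(feats[col].to_numpy(float)) == 0:
            recs.append((col, 1.0, True))
            continue
        p = float(stats.kruskal(*vals).pvalue)
        recs.append((col, p, False))
    return pd.DataFrame(recs, columns=["feature", "p_value", "degenerate"]).set_index(
        "feature"
    )
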