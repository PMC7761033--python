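"""Subtype-specific differential expression (ssDEG) calling.

Each gene is tested one-vs-rest per subtype with a two-sided Wilcoxon
rank-sum test; p-values are Benjamini–Hochberg adjusted within each
subtype's family of tests. A gene is *subtype-specific* when it is
up- or down-regulated in exactly one subtype. Deciding that from raw
one-vs-rest significance alone is misleading: a gene strongly shifted in
one subtype contaminates the "rest" group of every other test, so it also
comes out (oppositely) significant there even though only one subtype
moved. The specificity rule therefore works in two stages: a gene's *home*
is the subtype where it is most significant (smallest q, which must clear
the FDR threshold), and the gene is excluded as non-specific only if some
other subtype remains BH-significant after the home subtype's samples are
removed from the comparison — i.e. only when a second subtype is shifted
in its own right. Within a subtype, genes are ranked by ascending q (ties:
ascending p, then symbol); genes clearing the threshold nowhere are still
ranked (under their home subtype) with ``passed_threshold=False``, so a
requested gene-set depth can always be met, flagged rather than silently
truncated.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .resources import SUBTYPES

#: Combined group size at or below which the rank-sum p-value is exact.
EXACT_N_MAX = 25

SSDEG_COLUMNS = (
    "gene",
    "subtype",
    "p_value",
    "q_value",
    "direction",
    "rank",
    "passed_threshold",
)


def _group_values(
    mat: ExpressionMatrix, labels: pd.Series, subtype: str, gene: str
) -> tuple[np.ndarray, np.ndarray]:
    if subtype not in set(labels):
        raise ValueError(f"subtype {subtype!r} absent from labels")
    if gene not in mat.data.index:
        raise KeyError(f"gene {gene!r} absent from matrix")
    common = labels.index.intersection(mat.data.columns)
    lab = labels.loc[common]
    row = mat.data.loc[gene, common]
    return (
        row[lab == subtype].to_numpy(float),
        row[lab != subtype].to_numpy(float),
    )


def wilcoxon_one_vs_rest(
    mat: ExpressionMatrix, labels: pd.Series, subtype: str, gene: str
) -> tuple[float, str]:
    """Two-sided rank-sum p-value and direction for one gene, one subtype.

    Direction is ``up`` when the gene's median in the subtype exceeds its
    median in the remaining samples, ``down`` otherwise (exactly equal
    medians break to ``down``). Exact p when the combined group size is at
    most ``EXACT_N_MAX`` and the data are tie-free, otherwise the
    tie-corrected normal approximation.
    """
    x, y = _group_values(mat, labels, subtype, gene)
    if len(x) < 2 or len(y) < 2:
        raise ValueError(
            f"need >=2 samples per group for {subtype!r} (got {len(x)} vs {len(y)})"
        )
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0, "down"  # no rank signal at all
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_N_MAX and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    direction = "up" if np.median(x) > np.median(y) else "down"
    return float(min(res.pvalue, 1.0)), direction


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_ssdegs(
    mat: ExpressionMatrix,
    labels: pd.Series,
    gene_universe: Sequence[str] | None = None,
    q_threshold: float = 0.005,
) -> pd.DataFrame:
    """Build the ranked per-subtype ssDEG table.

    Returns a DataFrame with columns ``gene, subtype, p_value, q_value,
    direction, rank, passed_threshold``; each gene appears under at most
    one subtype (see module docstring for the assignment rule).
    """
    if gene_universe is None:
        from .resources import load_pam50_genes

        gene_universe = [g for g in load_pam50_genes() if g in set(mat.data.index)]
    gene_universe = list(dict.fromkeys(gene_universe))
    missing = sorted(set(gene_universe) - set(mat.data.index))
    if missing:
        raise KeyError(f"gene universe members absent from matrix: {missing}")
    present = set(labels)
    absent = [s for s in SUBTYPES if s not in present]
    if absent:
        raise ValueError(f"subtypes absent from labels: {absent}")
    counts = labels.value_counts()
    small = [s for s in SUBTYPES if counts.get(s, 0) < 2]
    if small:
        raise ValueError(f"subtypes with fewer than 2 samples: {small}")

    stats_long: dict[str, pd.DataFrame] = {}
    for subtype in SUBTYPES:
        recs = []
        for gene in gene_universe:
            p, direction = wilcoxon_one_vs_rest(mat, labels, subtype, gene)
            recs.append((gene, p, direction))
        df = pd.DataFrame(recs, columns=["gene", "p_value", "direction"])
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
        stats_long[subtype] = df.set_index("gene")

    # conditional q-values for the specificity screen, computed lazily:
    # cond_q[home][secondary] ranks each gene's secondary-vs-rest test with
    # the home subtype's samples excluded (BH within each family)
    cond_cache: dict[str, dict[str, pd.Series]] = {}

    def _conditional_q(home: str) -> dict[str, pd.Series]:
        if home not in cond_cache:
            sub_labels = labels[labels != home]
            sub_mat = mat.subset_samples(
                [s for s in mat.samples if s in set(sub_labels.index)]
            )
            fams: dict[str, pd.Series] = {}
            for other in SUBTYPES:
                if other == home:
                    continue
                ps = [
                    wilcoxon_one_vs_rest(sub_mat, sub_labels, other, g)[0]
                    for g in gene_universe
                ]
                fams[other] = pd.Series(bh_adjust(ps), index=gene_universe)
            cond_cache[home] = fams
        return cond_cache[home]

    rows = []
    for gene in gene_universe:
        qs = {s: stats_long[s].loc[gene, "q_value"] for s in SUBTYPES}
        home = min(
            SUBTYPES, key=lambda s: (qs[s], stats_long[s].loc[gene, "p_value"])
        )
        passed = qs[home] < q_threshold
        if passed:
            cond = _conditional_q(home)
            if any(cond[s].loc[gene] < q_threshold for s in cond):
                continue  # genuinely shifted in more than one subtype
        rec = stats_long[home].loc[gene]
        rows.append(
            dict(
                gene=gene,
                subtype=home,
                p_value=float(rec["p_value"]),
                q_value=float(rec["q_value"]),
                direction=rec["direction"],
                passed_threshold=passed,
            )
        )
    table = pd.DataFrame(rows, columns=[c for c in SSDEG_COLUMNS if c != "rank"])
    if table.empty:
        table["rank"] = pd.Series(dtype=int)
        return table.loc[:, list(SSDEG_COLUMNS)]
    table = table.sort_values(
        ["subtype", "q_value", "p_value", "gene"], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = table.groupby("subtype").cumcount() + 1
    return table.loc[:, list(SSDEG_COLUMNS)]


def significant_ssdegs(table: pd.DataFrame) -> pd.DataFrame:
    """Rows that cleared the FDR threshold in exactly one subtype."""
    return table[table["passed_threshold"]].reset_index(drop=True)


def write_ssdeg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(Path(path), sep="\t", index=False)


def read_ssdeg_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")
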