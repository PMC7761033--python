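"""Expression-matrix, label-table and probe-map I/O with validation.

Expression matrices are delimited text, genes in rows, one header row of
sample identifiers, first column ``gene_id``. Values are non-negative and on
a raw linear scale (RPKM/FPKM-like); log2-encoded files are decoded to the
linear scale on read so that every in-memory matrix speaks linear units.
Microarray probe-level matrices are collapsed to gene level with a
per-sample maximum over each gene's probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .resources import SUBTYPES

ScaleTag = Literal["linear", "log2"]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression on the linear scale.

    Parameters
    ----------
    data:
        DataFrame with unique gene symbols as index and sample identifiers
        as columns; values finite and >= 0 (linear RPKM/FPKM-like units).
    scale_tag:
        The on-disk encoding this matrix was read from. Values are always
        stored linear in memory regardless of the tag.
    """

    data: pd.DataFrame
    scale_tag: ScaleTag = "linear"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (genes x samples)")
        if self.data.index.has_duplicates:
            dups = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValueError(f"duplicate gene identifiers: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if values.size and (values < 0).any():
            raise ValueError("negative expression values on the linear scale")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_samples_by_genes(self) -> pd.DataFrame:
        """Samples-in-rows orientation used by the estimators."""
        return self.data.T

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.scale_tag)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path,
    scale_tag: ScaleTag = "linear",
    pseudocount_floor: float = 0.0,
    allow_duplicate_ids: bool = False,
) -> ExpressionMatrix:
    """Read a delimited expression matrix and return it on the linear scale.

    ``scale_tag='log2'`` decodes each on-disk value ``x`` as
    ``2**x - pseudocount_floor`` (floor 0.1 inverts a log2(FPKM+0.1)
    encoding exactly); decoded values are clipped at zero.
    ``allow_duplicate_ids`` admits probe-level files with several rows per
    gene, pending :func:`collapse_probes`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        raise ValueError(f"non-numeric cells in columns: {list(bad)}")
    df = df.astype(float)
    if scale_tag == "log2":
        df = (np.exp2(df) - pseudocount_floor).clip(lower=0.0)
    elif scale_tag != "linear":
        raise ValueError(f"unknown scale_tag: {scale_tag!r}")
    if allow_duplicate_ids:
        # bypass the uniqueness invariant until probes are collapsed
        if not np.isfinite(df.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if (df.to_numpy() < 0).any():
            raise ValueError("negative expression values on the linear scale")
        mat = ExpressionMatrix.__new__(ExpressionMatrix)
        mat.data = df
        mat.scale_tag = scale_tag
        return mat
    return ExpressionMatrix(df, scale_tag)


def write_expression(mat: ExpressionMatrix, path) -> None:
    """Write the linear-scale matrix as delimited text (full float precision)."""
    path = Path(path)
    mat.data.to_csv(path, sep=_sep_for(path))


def read_labels(path) -> pd.Series:
    """Read a two-column (sample_id, subtype) table into a Series."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=0)
    if df.shape[1] != 2:
        raise ValueError("label table must have exactly two columns")
    labels = pd.Series(
        df.iloc[:, 1].astype(str).to_numpy(),
        index=pd.Index(df.iloc[:, 0].astype(str), name="sample_id"),
        name="subtype",
    )
    return validate_labels(labels)


def validate_labels(labels: pd.Series) -> pd.Series:
    if labels.index.has_duplicates:
        dups = sorted(labels.index[labels.index.duplicated()].unique())
        raise ValueError(f"samples labeled more than once: {dups}")
    unknown = sorted(set(labels) - set(SUBTYPES))
    if unknown:
        raise ValueError(f"unknown subtype labels: {unknown}; expected {SUBTYPES}")
    return labels


def write_labels(labels: pd.Series, path) -> None:
    path = Path(path)
    labels.rename("subtype").rename_axis("sample_id").to_csv(path, sep=_sep_for(path))


def read_probe_map(path) -> pd.Series:
    """Read a two-column (probe_id, gene_symbol) map; many probes per gene."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=0)
    if df.shape[1] != 2:
        raise ValueError("probe map must have exactly two columns")
    probes = pd.Index(df.iloc[:, 0].astype(str), name="probe_id")
    if probes.has_duplicates:
        dups = sorted(probes[probes.duplicated()].unique())
        raise ValueError(f"probes mapped more than once: {dups}")
    return pd.Series(df.iloc[:, 1].astype(str).to_numpy(), index=probes, name="gene")


def collapse_probes(
    mat: ExpressionMatrix,
    probe_map: Mapping[str, str] | pd.Series,
    mode: Literal["per_sample_max", "global_max_probe"] = "per_sample_max",
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    ``per_sample_max`` (default) takes, for each gene and each sample
    independently, the maximum over that gene's probes — a within-sample
    rule that is immune to cohort composition. ``global_max_probe``
    instead keeps the single probe whose maximum across samples is
    largest (ties broken by probe identifier).
    """
    probe_map = pd.Series(probe_map)
    missing = sorted(set(mat.data.index) - set(probe_map.index))
    if missing:
        raise KeyError(f"probes absent from probe map: {missing}")
    genes = probe_map.loc[mat.data.index]
    if mode == "per_sample_max":
        collapsed = mat.data.groupby(genes.to_numpy(), sort=True).max()
    elif mode == "global_max_probe":
        rows = []
        for gene, block in mat.data.groupby(genes.to_numpy(), sort=True):
            peak = block.max(axis=1)
            pick = min(peak.index[peak == peak.max()])
            rows.append(block.loc[pick].rename(gene))
        collapsed = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown collapse mode: {mode!r}")
    collapsed.index.name = "gene_id"
    return ExpressionMatrix(collapsed, mat.scale_tag)
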