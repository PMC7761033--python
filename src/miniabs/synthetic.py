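"""Synthetic subtype-structured expression data with known ground truth.

Each gene g has a baseline log2 expression; marker genes additionally
shift by delta log2 units (up or down) in exactly one designated subtype.
Per-sample log-normal noise is added on the log2 scale and the value is
emitted on the linear (RPKM-like) scale as max(0, 2**x - 1), so that the
log2((e+1)/(e+1)) ratio of two genes recovers their log2 difference up to
the noise. Class sizes default to the imbalanced reference cohort
(76/50/194/105/7), with Normal-like as a rare, weakly shifted class.
Gene-gene correlation and platform batch effects are deliberately not
modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, write_expression, write_labels
from .resources import DEFAULT_CLASS_SIZES, SUBTYPES

#: marker gene -> (subtype, direction, effect size delta in log2 units)
MarkerMap = Mapping[str, tuple[str, int, float]]


def default_markers(delta: float = 3.0, normal_like_scale: float = 0.5) -> dict:
    """Eight informative markers covering all five subtypes.

    Gene names follow the reference panel so that seed-gene based set
    construction works out of the box; the Normal-like marker effect is
    scaled down to reproduce that class's instability.
    """
    return {
        "ESR1": ("LumA", +1, delta),
        "PGR": ("LumA", +1, delta),
        "ERBB2": ("Her2E", +1, delta),
        "MKI67": ("LumB", +1, delta),
        "CEP55": ("LumB", +1, delta),
        "MLPH": ("Basal-like", -1, delta),
        "KRT17": ("Basal-like", +1, delta),
        "SFRP1": ("Normal-like", +1, delta * normal_like_scale),
    }


@dataclass
class SimConfig:
    """Configuration of one simulated cohort."""

    class_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES)
    )
    markers: MarkerMap = field(default_factory=default_markers)
    n_noise_genes: int = 10
    noise_gene_names: tuple[str, ...] | None = None
    baseline_log2: float | Mapping[str, float] = 5.0
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for subtype, n in self.class_sizes.items():
            if subtype not in SUBTYPES:
                raise ValueError(f"unknown subtype in class_sizes: {subtype!r}")
            if n < 0:
                raise ValueError("class sizes must be >= 0")
        for gene, (subtype, direction, delta) in self.markers.items():
            if subtype not in SUBTYPES:
                raise ValueError(f"marker {gene!r} targets unknown subtype {subtype!r}")
            if direction not in (-1, +1):
                raise ValueError(f"marker {gene!r} direction must be +1 or -1")
            if delta < 0:
                raise ValueError(f"marker {gene!r} effect size must be >= 0")
        if set(self.markers) & set(self._noise_names()):
            raise ValueError("marker genes and noise genes must be disjoint")

    def _noise_names(self) -> list[str]:
        if self.noise_gene_names is not None:
            return list(self.noise_gene_names)
        return [f"NOISE{i + 1:03d}" for i in range(self.n_noise_genes)]

    def gene_names(self) -> list[str]:
        return list(self.markers) + self._noise_names()

    def baseline_of(self, gene: str) -> float:
        if isinstance(self.baseline_log2, Mapping):
            return float(self.baseline_log2.get(gene, 5.0))
        return float(self.baseline_log2)


def simulate(cfg: SimConfig) -> tuple[ExpressionMatrix, pd.Series]:
    """Draw one cohort; reproducible given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_names()
    subtype_of_sample: list[str] = []
    for subtype in SUBTYPES:
        subtype_of_sample += [subtype] * int(cfg.class_sizes.get(subtype, 0))
    sample_ids = [f"S{i + 1:04d}" for i in range(len(subtype_of_sample))]
    labels = pd.Series(
        subtype_of_sample, index=pd.Index(sample_ids, name="sample_id"), name="subtype"
    )
    x = np.empty((len(genes), len(sample_ids)))
    for gi, gene in enumerate(genes):
        mean = np.full(len(sample_ids), cfg.baseline_of(gene))
        if gene in cfg.markers:
            subtype, direction, delta = cfg.markers[gene]
            mean = mean + direction * delta * (labels.to_numpy() == subtype)
        x[gi] = mean + rng.normal(0.0, cfg.noise_sd, size=len(sample_ids))
    linear = np.maximum(0.0, np.exp2(x) - 1.0)
    data = pd.DataFrame(
        linear, index=pd.Index(genes, name="gene_id"), columns=sample_ids
    )
    return ExpressionMatrix(data), labels


def make_fixture_suite(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the small canonical fixture set used by tests and docs.

    Produces a separable five-class cohort, a null (no-signal) cohort, a
    probe-level matrix with duplicate probes plus its probe map, and a
    log2-encoded copy of the separable cohort, with labels and a manifest.
    Reruns with the same seed are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    small_sizes = {
        "Basal-like": 12,
        "Her2E": 12,
        "LumA": 12,
        "LumB": 12,
        "Normal-like": 6,
    }
    sep_cfg = SimConfig(class_sizes=small_sizes, markers=default_markers(3.0), seed=seed)
    null_cfg = SimConfig(
        class_sizes=small_sizes, markers=default_markers(0.0), seed=seed + 1
    )
    paths: dict[str, Path] = {}

    def _write(mat: ExpressionMatrix, labels: pd.Series, stem: str) -> None:
        ep, lp = out / f"{stem}_expression.tsv", out / f"{stem}_labels.tsv"
        rounded = ExpressionMatrix(mat.data.round(4), mat.scale_tag)
        write_expression(rounded, ep)
        write_labels(labels, lp)
        paths[f"{stem}_expression"] = ep
        paths[f"{stem}_labels"] = lp

    sep_mat, sep_labels = simulate(sep_cfg)
    _write(sep_mat, sep_labels, "separable")
    null_mat, null_labels = simulate(null_cfg)
    _write(null_mat, null_labels, "null")

    # probe-level fixture: two probes per gene; probe 2 is attenuated so the
    # per-sample maximum recovers the gene-level value
    probe_rows, probe_map_rows = [], []
    for gene in sep_mat.genes[:6]:
        vals = sep_mat.data.loc[gene]
        att = rng.uniform(0.2, 0.8)
        probe_rows.append((f"{gene}_p1", vals))
        probe_rows.append((f"{gene}_p2", (vals * att).round(4)))
        probe_map_rows += [(f"{gene}_p1", gene), (f"{gene}_p2", gene)]
    probe_df = pd.DataFrame(
        {pid: v for pid, v in probe_rows}
    ).T.round(4)
    probe_df.index.name = "gene_id"
    pp = out / "probe_level_expression.tsv"
    probe_df.to_csv(pp, sep="\t")
    paths["probe_level_expression"] = pp
    pm = out / "probe_map.tsv"
    pd.DataFrame(probe_map_rows, columns=["probe_id", "gene_symbol"]).to_csv(
        pm, sep="\t", index=False
    )
    paths["probe_map"] = pm

    log2_df = np.log2(sep_mat.data + 0.1).round(4)
    lp = out / "log2_encoded_expression.tsv"
    log2_df.to_csv(lp, sep="\t")
    paths["log2_encoded_expression"] = lp

    manifest = {
        "seed": seed,
        "separable": {
            "class_sizes": small_sizes,
            "markers": {g: list(m) for g, m in sep_cfg.markers.items()},
            "noise_sd": sep_cfg.noise_sd,
        },
        "null": {"class_sizes": small_sizes, "noise_sd": null_cfg.noise_sd},
        "log2_encoding": "log2(linear + 0.1); decode with pseudocount_floor=0.1",
        "files": {k: p.name for k, p in paths.items()},
    }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = mp
    return paths
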