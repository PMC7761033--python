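"""Package-level constants and bundled reference data.

The five intrinsic breast-cancer subtypes, the four clinical seed marker
genes, the slack-margin grid, the shipped 11-gene panel, and loaders for
the bundled PAM50 gene list and the published per-subtype ssDEG ranking
used to assemble candidate gene sets.
"""

from __future__ import annotations

from importlib import resources as _ires

import pandas as pd

#: Intrinsic subtype labels in canonical order.
SUBTYPES: tuple[str, ...] = ("Basal-like", "Her2E", "LumA", "LumB", "Normal-like")

#: Sentinel prediction emitted when the ensemble vote is tied.
AMBIGUOUS: str = "Ambiguous"

#: Clinically established marker genes pre-included in every candidate set.
SEED_GENES: tuple[str, ...] = ("ESR1", "PGR", "ERBB2", "MKI67")

#: Slack-margin grid (log2 units) over which the ensemble members are trained.
ALPHA_GRID: tuple[float, ...] = (0.00, 0.01, 0.05, 0.10, 0.15, 0.20, 1.00)

#: The shipped 11-gene reference panel (level-2 candidate set minus GRB7 and
#: KRT14, the two genes whose removal does not cost accuracy).
MINIABS_PANEL: tuple[str, ...] = (
    "ESR1",
    "PGR",
    "ERBB2",
    "MKI67",
    "MLPH",
    "FGFR4",
    "CEP55",
    "KRT17",
    "FOXA1",
    "MYBL2",
    "SFRP1",
)

#: Fixed tie-break order between learning algorithms (best average performer first).
ALGORITHM_ORDER: tuple[str, ...] = ("rf", "svm", "cart", "nb")

#: Default class sizes of the reference training cohort (heavily imbalanced,
#: with Normal-like as a rare class).
DEFAULT_CLASS_SIZES: dict[str, int] = {
    "Basal-like": 76,
    "Her2E": 50,
    "LumA": 194,
    "LumB": 105,
    "Normal-like": 7,
}


def load_pam50_genes() -> list[str]:
    """Return the 50-gene PAM50 symbol list (default ssDEG gene universe).

    Symbols follow the original PAM50 publication; CDCA1, KNTC2 and ORC6L
    are the legacy aliases of NUF2, NDC80 and ORC6.
    """
    text = _ires.files("miniabs.data").joinpath("pam50_genes.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def load_reference_ssdegs() -> pd.DataFrame:
    """Return the published top-5 per-subtype ssDEG ranking.

    Columns: ``subtype``, ``rank``, ``gene``, ``p_value``, ``q_value``.
    This is a verbatim transcription of the published reference ranking and,
    unlike tables produced by :func:`miniabs.ssdeg.call_ssdegs`, may list the
    same gene under more than one subtype; gene-set assembly deduplicates.
    """
    with _ires.files("miniabs.data").joinpath("reference_ssdegs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
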