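"""Categorical agreement between CNV calling methods via PABAK.

PABAK (prevalence-adjusted bias-adjusted kappa) for k categories is

    PABAK = (k * Po - 1) / (k - 1)

where Po is the observed proportion of agreement (trace of the contingency
table over its total).  Unlike Cohen's kappa it does not depend on the
marginal category prevalences, which for CNV data are dominated by the
diploid state.  PABAK = 1 is perfect agreement, 0 is chance-level, and the
minimum (-1 for k = 2) is systematic contradiction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import CATEGORICAL, CNCategory, CopyNumberDataset, aligned_calls

CN_ORDER: tuple[CNCategory, ...] = (
    CNCategory.DELETION,
    CNCategory.NORMAL,
    CNCategory.AMPLIFICATION,
)

#: Agreement bands anchored at the conventional 0.61-0.80 "substantial" interval.
BAND_EDGES = (
    (0.80, "near_perfect"),
    (0.60, "substantial"),
    (0.20, "moderate"),
    (0.0, "poor"),
)


def agreement_band(value: float) -> str:
    """Qualitative band for a PABAK value."""
    if value < 0:
        return "negative"
    for edge, name in BAND_EDGES:
        if value > edge:
            return name
    return "poor"


@dataclass(frozen=True)
class ContingencyTable:
    """k x k cross-classification of paired categorical calls.

    Rows index method A's call, columns method B's, in the fixed order
    deletion, normal, amplification (for the default three categories).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] < 2:
            raise ValueError("counts must be a square matrix with k >= 2")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return int(self.counts.shape[0])


def contingency(
    pairs: Iterable[tuple[CNCategory, CNCategory]],
    categories: Sequence[CNCategory] = CN_ORDER,
) -> ContingencyTable:
    """Tally paired calls into a contingency table (fixed category order)."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cannot build a contingency table from no pairs")
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=int)
    for a, b in pairs:
        counts[index[a], index[b]] += 1
    return ContingencyTable(counts)


@dataclass(frozen=True)
class PabakResult:
    """Observed agreement and PABAK for one contingency table."""

    po: float
    pabak: float
    k_categories: int
    n: int
    band: str


def pabak(table: ContingencyTable) -> PabakResult:
    """PABAK of a contingency table.

    ``k`` is the number of *defined* categories (the table dimension), not
    the number observed, so sparse tables keep a stable formula.  A 2x2
    table recovers the binary form 2*Po - 1.
    """
    if table.n < 1:
        raise ValueError("contingency table is empty (n = 0)")
    k = table.k
    po = float(np.trace(table.counts)) / table.n
    value = (k * po - 1.0) / (k - 1.0)
    return PabakResult(po=po, pabak=value, k_categories=k, n=table.n, band=agreement_band(value))


@dataclass
class PabakMatrix:
    """Per-(gene, method-pair) PABAK results with median summaries.

    ``table`` is tidy (gene, method_a, method_b, n, po, pabak, band); cells
    with no aligned calls appear with n = 0 and NaN statistics (missing, not
    zero).  ``gene_medians`` is sorted in decreasing median-PABAK order, the
    canonical display order; ``pair_medians`` summarizes each method pair
    over genes.  Medians are taken over available cells only.
    """

    table: pd.DataFrame
    gene_medians: pd.Series
    pair_medians: pd.Series


def pabak_matrix(
    ds: CopyNumberDataset,
    method_pairs: Sequence[tuple[str, str]],
    genes: Sequence[str] | None = None,
    tissue: str | None = None,
) -> PabakMatrix:
    """PABAK for every (gene, method pair) combination.

    All methods must be categorical (discretize quantitative platforms
    first).  Tumor and normal samples are pooled unless ``tissue`` narrows
    to one compartment.
    """
    for a, b in method_pairs:
        for mid in (a, b):
            if ds.method_kind(mid) != CATEGORICAL:
                raise ValueError(f"method {mid!r} is not categorical")
    if genes is None:
        genes = ds.genes
    rows = []
    for gene in genes:
        for a, b in method_pairs:
            try:
                pairs = aligned_calls(ds, a, b, gene, tissue=tissue)
            except KeyError:
                pairs = []  # gene absent from the dataset: a missing cell
            if not pairs:
                rows.append(
                    {
                        "gene": gene,
                        "method_a": a,
                        "method_b": b,
                        "n": 0,
                        "po": np.nan,
                        "pabak": np.nan,
                        "band": "missing",
                    }
                )
                continue
            res = pabak(contingency(pairs))
            rows.append(
                {
                    "gene": gene,
                    "method_a": a,
                    "method_b": b,
                    "n": res.n,
                    "po": res.po,
                    "pabak": res.pabak,
                    "band": res.band,
                }
            )
    table = pd.DataFrame(
        rows, columns=["gene", "method_a", "method_b", "n", "po", "pabak", "band"]
    )
    gene_medians = (
        table.groupby("gene")["pabak"].median().sort_values(ascending=False)
    )
    pair_key = table["method_a"] + ":" + table["method_b"]
    pair_medians = table.assign(pair=pair_key).groupby("pair")["pabak"].median()
    # emit gene rows in decreasing per-gene median order
    order = {g: i for i, g in enumerate(gene_medians.index)}
    table = table.sort_values(
        ["gene", "method_a", "method_b"],
        key=lambda s: s.map(order) if s.name == "gene" else s,
        kind="stable",
    ).reset_index(drop=True)
    return PabakMatrix(table=table, gene_medians=gene_medians, pair_medians=pair_medians)
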