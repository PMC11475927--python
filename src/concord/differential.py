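"""Per-gene tumor-vs-normal differential copy-number testing.

For each gene, every quantitative platform with paired tumor/normal data
contributes a two-sided paired Wilcoxon signed-rank p-value.  Because the
same biological contrast is tested once per platform, the per-method
p-values are pooled by their plain harmonic mean (dominated by the
smallest p, and equal to the single p when only one method has data), and
the pooled values are corrected across genes by the step-down Holm
procedure, which controls the family-wise error rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import QUANTITATIVE, CopyNumberDataset, paired_values

#: Largest n for which the exact signed-rank null distribution is used
#: (when the absolute differences are tie-free).
EXACT_N_MAX = 25


def paired_wilcoxon(tumor, normal) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are discarded before ranking (classic convention).
    The exact null distribution is used for n <= 25 tie-free absolute
    differences; otherwise the normal approximation with continuity
    correction.  If every difference is zero there is no evidence either
    way: p = 1 is returned with a warning.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape or tumor.ndim != 1 or tumor.size < 1:
        raise ValueError("tumor and normal must be equal-length 1-D arrays, n >= 1")
    diffs = tumor - normal
    nz = diffs[diffs != 0]
    if nz.size == 0:
        warnings.warn(
            "all paired differences are zero; returning p = 1", stacklevel=2
        )
        return 1.0
    abs_nz = np.abs(nz)
    exact = nz.size <= EXACT_N_MAX and np.unique(abs_nz).size == abs_nz.size
    res = stats.wilcoxon(
        nz,
        zero_method="wilcox",
        correction=not exact,
        alternative="two-sided",
        method="exact" if exact else "approx",
    )
    return float(res.pvalue)


def harmonic_mean_p(ps: Sequence[float]) -> float:
    """Plain harmonic mean m / sum(1/p_i) of m p-values in (0, 1]."""
    arr = np.asarray(list(ps), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one p-value")
    if (arr <= 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return float(arr.size / np.sum(1.0 / arr))


def holm_adjust(ps: Sequence[float]) -> np.ndarray:
    """Step-down Holm correction, returned in the input order.

    The i-th smallest of m p-values is multiplied by (m - i + 1), a running
    maximum enforces monotonicity, and values are capped at 1.
    """
    arr = np.asarray(list(ps), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one p-value")
    if (arr <= 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="holm")[1]


def rank_correlation(a, b) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided
    p-value; errors on constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length sequences with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation is undefined for constant input")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def combine_method_pvalues(pvals: pd.DataFrame) -> pd.DataFrame:
    """Pool a gene x method table of p-values and correct across genes.

    ``pvals`` is indexed by gene with one column per method; missing cells
    (no data for that gene on that method) are NaN and are skipped, not
    imputed.  Returns the input plus ``pooled_p`` (harmonic mean over the
    available methods) and ``adjusted_p`` (Holm across genes), sorted by
    gene name.  Genes with no available p-value are dropped.
    """
    pvals = pvals.sort_index()
    pooled = {}
    for gene, row in pvals.iterrows():
        avail = row.dropna()
        if avail.empty:
            continue
        pooled[gene] = harmonic_mean_p(avail.to_numpy())
    if not pooled:
        raise ValueError("no gene has any available p-value")
    out = pvals.loc[list(pooled)].copy()
    out["pooled_p"] = pd.Series(pooled)
    out["adjusted_p"] = holm_adjust(out["pooled_p"].to_numpy())
    return out


@dataclass
class DifferentialResults:
    """Fitted differential table.

    ``table`` is indexed by gene with one ``p_<method>`` column per method,
    plus ``pooled_p``, ``adjusted_p`` and a ``trend`` flag marking pooled
    p-values in the interpretive band (0.05, 0.1) (annotation only; it
    never affects computation).
    """

    table: pd.DataFrame
    methods: tuple[str, ...]
    alpha: float = 0.05

    def summary(self, decimals: int = 3) -> str:
        disp = self.table.copy()
        num = disp.columns.drop("trend")
        disp[num] = disp[num].round(decimals)
        return "Differential copy number (paired Wilcoxon / harmonic mean / Holm)\n" + disp.to_string()

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["adjusted_p"] < self.alpha]


class DifferentialCNV:
    """Per-gene tumor-vs-normal differential model over quantitative methods.

    Parameters
    ----------
    dataset : CopyNumberDataset
    genes : sequence of str, optional
        Gene panel to test (default: all genes in the dataset).
    methods : sequence of str, optional
        Quantitative methods to use (default: all quantitative methods).

    ``fit()`` runs one paired Wilcoxon per (gene, method) with paired data,
    pools per-method p-values by harmonic mean, and applies Holm across the
    genes actually tested.
    """

    def __init__(
        self,
        dataset: CopyNumberDataset,
        genes: Sequence[str] | None = None,
        methods: Sequence[str] | None = None,
    ):
        self.dataset = dataset
        if methods is None:
            methods = [m for m, k in dataset.method_kinds.items() if k == QUANTITATIVE]
        for mid in methods:
            if dataset.method_kind(mid) != QUANTITATIVE:
                raise ValueError(f"method {mid!r} is not quantitative")
        self.methods = tuple(sorted(methods))
        self.genes = tuple(sorted(genes if genes is not None else dataset.genes))

    def fit(self, alpha: float = 0.05) -> DifferentialResults:
        pvals: dict[str, dict[str, float]] = {}
        for gene in self.genes:
            for mid in self.methods:
                try:
                    pairs = paired_values(self.dataset, mid, gene)
                except KeyError:
                    continue
                if not pairs:
                    continue
                tumor = [t for _, t, _ in pairs]
                normal = [n for _, _, n in pairs]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pvals.setdefault(gene, {})[mid] = paired_wilcoxon(tumor, normal)
        if not pvals:
            raise ValueError("no (gene, method) group has paired tumor/normal data")
        frame = pd.DataFrame.from_dict(pvals, orient="index").reindex(
            columns=list(self.methods)
        )
        frame.index.name = "gene"
        combined = combine_method_pvalues(frame)
        combined = combined.rename(columns={m: f"p_{m}" for m in self.methods})
        combined["trend"] = (combined["pooled_p"] > 0.05) & (combined["pooled_p"] < 0.1)
        return DifferentialResults(table=combined, methods=self.methods, alpha=alpha)


def differential_table(
    ds: CopyNumberDataset,
    genes: Sequence[str] | None = None,
    methods: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: ``DifferentialCNV(ds, genes, methods).fit().table``."""
    return DifferentialCNV(ds, genes=genes, methods=methods).fit().table
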