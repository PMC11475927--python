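"""Normal-tissue quality filters for quantitative assays.

Two filters, both driven exclusively by normal-tissue measurements (tumor
values never influence QC):

* per-(method, gene) normal-median window: a group whose normal-tissue
  median copy number falls outside [1.5, 2.5] behaves abnormally (bad
  primers, bad normalization) and is excluded from downstream analysis;
* reference-gene adequacy: a reference-gene configuration (the set of
  methods normalized against one reference, e.g. an ALB-normalized ddPCR
  pair) is dropped wholesale when more than a threshold fraction of its
  normal-tissue values fall outside [1.5, 2.5].
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .data import QUANTITATIVE, CopyNumberDataset, Tissue

NORMAL_LOWER = 1.5
NORMAL_UPPER = 2.5


def _normal_values(ds: CopyNumberDataset, method_id: str, gene: str) -> np.ndarray:
    vals = [
        m.quant_value
        for m in ds.measurements
        if m.method_id == method_id
        and m.gene == gene
        and m.tissue is Tissue.NORMAL
        and m.value_kind == QUANTITATIVE
    ]
    return np.asarray(vals, dtype=float)


def normal_median_filter(
    ds: CopyNumberDataset,
    method_id: str,
    gene: str,
    lower: float = NORMAL_LOWER,
    upper: float = NORMAL_UPPER,
) -> tuple[float, bool]:
    """Median of normal-tissue values for one (method, gene) and whether the
    group is kept (median within [lower, upper], boundaries inclusive).

    The median uses the standard midpoint convention for even counts.
    Raises if the group has no quantitative normal-tissue measurements.
    """
    vals = _normal_values(ds, method_id, gene)
    if vals.size == 0:
        raise ValueError(
            f"no quantitative normal-tissue values for ({method_id!r}, {gene!r})"
        )
    med = float(np.median(vals))
    return med, bool(lower <= med <= upper)


def qc_report(
    ds: CopyNumberDataset,
    methods: Sequence[str] | None = None,
    lower: float = NORMAL_LOWER,
    upper: float = NORMAL_UPPER,
) -> pd.DataFrame:
    """Tidy per-(method, gene) QC table for quantitative methods.

    Columns: method_id, gene, n_normal, normal_median, kept.  Groups with no
    normal-tissue data are reported with n_normal = 0 and kept = False (they
    cannot be vetted, so they are not kept).
    """
    if methods is None:
        methods = [m for m, k in ds.method_kinds.items() if k == QUANTITATIVE]
    rows = []
    for mid in sorted(methods):
        if ds.method_kind(mid) != QUANTITATIVE:
            raise ValueError(f"method {mid!r} is not quantitative")
        present = sorted(
            {m.gene for m in ds.measurements if m.method_id == mid}
        )
        for gene in present:
            vals = _normal_values(ds, mid, gene)
            if vals.size == 0:
                rows.append(
                    {
                        "method_id": mid,
                        "gene": gene,
                        "n_normal": 0,
                        "normal_median": np.nan,
                        "kept": False,
                    }
                )
                continue
            med = float(np.median(vals))
            rows.append(
                {
                    "method_id": mid,
                    "gene": gene,
                    "n_normal": int(vals.size),
                    "normal_median": med,
                    "kept": bool(lower <= med <= upper),
                }
            )
    return pd.DataFrame(
        rows, columns=["method_id", "gene", "n_normal", "normal_median", "kept"]
    )


def apply_qc(
    ds: CopyNumberDataset, report: pd.DataFrame | None = None, **kwargs
) -> CopyNumberDataset:
    """Drop all measurements of (method, gene) groups that failed the
    normal-median filter.  Categorical methods are untouched."""
    if report is None:
        report = qc_report(ds, **kwargs)
    dropped = {
        (r.method_id, r.gene) for r in report.itertuples() if not r.kept
    }
    return ds.subset(lambda m: (m.method_id, m.gene) not in dropped)


def assess_reference_config(
    ds: CopyNumberDataset,
    methods_using_reference: Sequence[str],
    threshold: float = 0.5,
    lower: float = NORMAL_LOWER,
    upper: float = NORMAL_UPPER,
) -> tuple[float, bool]:
    """Adequacy of a reference-gene configuration.

    Pools every quantitative normal-tissue value across the named methods
    (all genes) and reports the fraction falling outside [lower, upper] and
    whether the configuration is flagged (fraction > threshold).  A flagged
    configuration should be dropped wholesale.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    methods = set(methods_using_reference)
    unknown = methods - set(ds.methods)
    if unknown:
        raise KeyError(f"unknown methods {sorted(unknown)}")
    pool = [
        m.quant_value
        for m in ds.measurements
        if m.method_id in methods
        and m.tissue is Tissue.NORMAL
        and m.value_kind == QUANTITATIVE
    ]
    if not pool:
        raise ValueError("no quantitative normal-tissue values in the named methods")
    arr = np.asarray(pool, dtype=float)
    frac = float(np.mean((arr < lower) | (arr > upper)))
    return frac, bool(frac > threshold)
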