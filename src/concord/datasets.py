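"""Small bundled reference tables.

These are published summary statistics (not raw measurements) used to
validate the pooling and correction arithmetic of the differential module
against a known table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Published per-method tumor-vs-normal paired Wilcoxon p-values for the
#: seven-gene high-consistency validation panel of an ovarian-carcinoma
#: multi-platform CNV benchmarking cohort.  Columns are the three
#: quantitative platforms; NaN marks "no data" (the platform had no usable
#: paired measurements for that gene).
_SEVEN_GENE_ROWS = {
    "C8orf4": (0.972, np.nan, 0.807),
    "CCND2": (np.nan, 0.003, 0.092),
    "CDK6": (0.497, 0.216, 1.0),
    "HMGA2": (0.505, np.nan, 0.168),
    "KDR": (0.685, np.nan, 0.363),
    "MET": (0.893, np.nan, 0.421),
    "PAX9": (0.685, 0.542, 0.168),
}

#: Pooled (harmonic-mean) and Holm-corrected columns as printed in the
#: published table, for cross-checking at 3 decimal places.
SEVEN_GENE_PUBLISHED_POOLED = {
    "C8orf4": (0.882, 1.0),
    "CCND2": (0.006, 0.042),
    "CDK6": (0.393, 1.0),
    "HMGA2": (0.252, 1.0),
    "KDR": (0.475, 1.0),
    "MET": (0.573, 1.0),
    "PAX9": (0.324, 1.0),
}


def seven_gene_panel_pvalues() -> pd.DataFrame:
    """Gene x method table of published per-method p-values (NaN = no data)."""
    return pd.DataFrame.from_dict(
        _SEVEN_GENE_ROWS,
        orient="index",
        columns=["pcr_evagreen", "pcr_probes", "nanostring"],
    ).rename_axis("gene")
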