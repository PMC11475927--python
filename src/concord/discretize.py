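"""Conversion of quantitative copy numbers to three-state categorical calls.

Two rules are provided:

``thresholds`` (default)
    Values in [1.5, 2.5] (inclusive) are a conditionally normal diploid
    state; values below 1.5 are deletions; values above 2.5 are
    amplifications.  Total: every finite non-negative value maps to exactly
    one category.

``vendor_band``
    The platform vendor's integer-rounding guideline: a value within +/-0.4
    of an integer maps to that integer (<=1 deletion, 2 normal, >=3
    amplification); values falling in the open bands (n + 0.4, n + 0.6) are
    excluded from categorical analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .data import (
    CATEGORICAL,
    QUANTITATIVE,
    CNCategory,
    CopyNumberDataset,
    Measurement,
)

THRESHOLDS = "thresholds"
VENDOR_BAND = "vendor_band"


@dataclass(frozen=True)
class ConversionRule:
    """Parameters of the quantitative-to-categorical conversion.

    Parameters
    ----------
    mode : {"thresholds", "vendor_band"}
    lower, upper : float
        Normal-state window for ``thresholds`` mode, inclusive on both ends.
    band_halfwidth : float
        Half-width of the integer acceptance band in ``vendor_band`` mode,
        inclusive; must lie in (0, 0.5).
    """

    mode: str = THRESHOLDS
    lower: float = 1.5
    upper: float = 2.5
    band_halfwidth: float = 0.4

    def __post_init__(self) -> None:
        if self.mode not in (THRESHOLDS, VENDOR_BAND):
            raise ValueError(f"mode must be '{THRESHOLDS}' or '{VENDOR_BAND}'")
        if not self.lower < self.upper:
            raise ValueError("lower must be < upper")
        if not 0 < self.band_halfwidth < 0.5:
            raise ValueError("band_halfwidth must be in (0, 0.5)")


def _round_half_away(v: float) -> int:
    # round-half-away-from-zero; v >= 0 here so floor(v + 0.5)
    return int(math.floor(v + 0.5))


def discretize_value(v: float, rule: ConversionRule = ConversionRule()) -> CNCategory | None:
    """Convert one quantitative copy number to a categorical call.

    Returns ``None`` when the value is excluded (``vendor_band`` mode only).
    Raises on negative or non-finite input.
    """
    v = float(v)
    if not math.isfinite(v) or v < 0:
        raise ValueError(f"copy number must be finite and >= 0, got {v!r}")
    if rule.mode == THRESHOLDS:
        if v < rule.lower:
            return CNCategory.DELETION
        if v > rule.upper:
            return CNCategory.AMPLIFICATION
        return CNCategory.NORMAL
    nearest = _round_half_away(v)
    # small tolerance so decimal band boundaries (e.g. 4.4) stay inclusive
    # despite binary float representation
    if abs(v - nearest) > rule.band_halfwidth + 1e-9:
        return None
    if nearest <= 1:
        return CNCategory.DELETION
    if nearest == 2:
        return CNCategory.NORMAL
    return CNCategory.AMPLIFICATION


@dataclass
class DiscretizationResult:
    """Converted dataset plus a per-method conversion log."""

    dataset: CopyNumberDataset
    log: pd.DataFrame = field(repr=False)


def discretize_dataset(
    ds: CopyNumberDataset, rule: ConversionRule = ConversionRule()
) -> DiscretizationResult:
    """Replace every quantitative measurement by its categorical call.

    Categorical inputs pass through unchanged.  In ``vendor_band`` mode,
    excluded values are dropped (row absence).  The log records, per method,
    how many values were converted, excluded, or passed through.
    """
    rows: list[Measurement] = []
    counts: dict[str, dict[str, int]] = {}
    for m in ds.measurements:
        c = counts.setdefault(
            m.method_id, {"converted": 0, "excluded": 0, "passthrough": 0}
        )
        if m.value_kind == CATEGORICAL:
            c["passthrough"] += 1
            rows.append(m)
            continue
        cat = discretize_value(m.quant_value, rule)
        if cat is None:
            c["excluded"] += 1
            continue
        c["converted"] += 1
        rows.append(
            Measurement(
                patient_id=m.patient_id,
                tissue=m.tissue,
                method_id=m.method_id,
                gene=m.gene,
                value_kind=CATEGORICAL,
                call=cat,
            )
        )
    log = (
        pd.DataFrame.from_dict(counts, orient="index")
        .rename_axis("method_id")
        .reset_index()
        .sort_values("method_id", ignore_index=True)
    )
    return DiscretizationResult(dataset=CopyNumberDataset(rows), log=log)
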