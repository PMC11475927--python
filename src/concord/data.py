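"""Data model and I/O for multi-platform paired tumor/normal copy-number data.

The canonical container is :class:`CopyNumberDataset`, a validated long/tidy
table with one row per ``(patient_id, tissue, method_id, gene)`` key.  Each
method (platform) is either *quantitative* — non-negative real copies per
diploid genome — or *categorical* — a three-state call
deletion / normal / amplification.  Missing data is represented by row
absence, never by sentinel values.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("patient_id", "tissue", "method_id", "gene", "value", "value_kind")

QUANTITATIVE = "quantitative"
CATEGORICAL = "categorical"


class Tissue(str, enum.Enum):
    """Tissue compartment of a paired sample."""

    TUMOR = "tumor"
    NORMAL = "normal"

    @classmethod
    def parse(cls, raw: object) -> "Tissue":
        if isinstance(raw, cls):
            return raw
        try:
            return cls(str(raw).strip().lower())
        except ValueError:
            raise ValueError(
                f"tissue must be one of {[t.value for t in cls]}, got {raw!r}"
            ) from None


class CNCategory(enum.IntEnum):
    """Three-state copy-number call.

    The integer codes (1, 2, 3) double as file aliases; the ordering
    deletion < normal < amplification is defined for display and for the
    monotonicity of threshold discretization only.
    """

    DELETION = 1
    NORMAL = 2
    AMPLIFICATION = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def parse(cls, raw: object) -> "CNCategory":
        """Parse a categorical call, case-insensitively, from the category
        name or the integer aliases 1/2/3."""
        if isinstance(raw, CNCategory):
            return raw
        text = str(raw).strip()
        try:
            return cls(int(float(text)))
        except ValueError:
            pass
        try:
            return cls[text.upper()]
        except KeyError:
            raise ValueError(
                f"cannot parse categorical call {raw!r}; expected one of "
                f"{[c.label for c in cls]} or integer aliases 1/2/3"
            ) from None


@dataclass(frozen=True)
class Measurement:
    """One copy-number observation.

    Exactly one of ``quant_value`` / ``call`` is present, selected by
    ``value_kind``.
    """

    patient_id: str
    tissue: Tissue
    method_id: str
    gene: str
    value_kind: str
    quant_value: float | None = None
    call: CNCategory | None = None

    def __post_init__(self) -> None:
        if self.value_kind not in (QUANTITATIVE, CATEGORICAL):
            raise ValueError(f"invalid value_kind {self.value_kind!r}")
        if self.value_kind == QUANTITATIVE:
            if self.quant_value is None or self.call is not None:
                raise ValueError("quantitative measurement must carry quant_value only")
            v = float(self.quant_value)
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"quantitative copy number must be finite and >= 0, got {v!r} "
                    f"for {self.key}"
                )
        else:
            if self.call is None or self.quant_value is not None:
                raise ValueError("categorical measurement must carry call only")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.patient_id, self.tissue.value, self.method_id, self.gene)

    @property
    def value(self) -> float | CNCategory:
        return self.quant_value if self.value_kind == QUANTITATIVE else self.call


class CopyNumberDataset:
    """Validated collection of :class:`Measurement` rows.

    Invariants enforced at construction:

    * at most one measurement per (patient, tissue, method, gene) key;
    * every method has a single consistent value kind across its rows;
    * quantitative values are finite and non-negative.

    Parameters
    ----------
    measurements : iterable of Measurement
    """

    def __init__(self, measurements: Iterable[Measurement]):
        rows = list(measurements)
        seen: dict[tuple, int] = {}
        kinds: dict[str, str] = {}
        for m in rows:
            if m.key in seen:
                raise ValueError(f"duplicate measurement for key {m.key}")
            seen[m.key] = 1
            prev = kinds.setdefault(m.method_id, m.value_kind)
            if prev != m.value_kind:
                raise ValueError(
                    f"method {m.method_id!r} mixes value kinds "
                    f"({prev} and {m.value_kind})"
                )
        self._measurements: tuple[Measurement, ...] = tuple(
            sorted(rows, key=lambda m: m.key)
        )
        self._kinds = kinds

    # -- basic accessors ---------------------------------------------------
    @property
    def measurements(self) -> tuple[Measurement, ...]:
        return self._measurements

    def __len__(self) -> int:
        return len(self._measurements)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CopyNumberDataset):
            return NotImplemented
        return self._measurements == other._measurements

    @property
    def patients(self) -> list[str]:
        return sorted({m.patient_id for m in self._measurements})

    @property
    def methods(self) -> list[str]:
        return sorted(self._kinds)

    @property
    def genes(self) -> list[str]:
        return sorted({m.gene for m in self._measurements})

    @property
    def method_kinds(self) -> dict[str, str]:
        return dict(self._kinds)

    def method_kind(self, method_id: str) -> str:
        try:
            return self._kinds[method_id]
        except KeyError:
            raise KeyError(f"unknown method {method_id!r}") from None

    def subset(self, predicate) -> "CopyNumberDataset":
        """New dataset keeping measurements where ``predicate(m)`` is true."""
        return CopyNumberDataset(m for m in self._measurements if predicate(m))

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame view (categorical calls as labels)."""
        recs = []
        for m in self._measurements:
            recs.append(
                {
                    "patient_id": m.patient_id,
                    "tissue": m.tissue.value,
                    "method_id": m.method_id,
                    "gene": m.gene,
                    "value": m.quant_value
                    if m.value_kind == QUANTITATIVE
                    else m.call.label,
                    "value_kind": m.value_kind,
                }
            )
        return pd.DataFrame(recs, columns=list(REQUIRED_COLUMNS))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CopyNumberDataset":
        """Build from a long-format frame with the six canonical columns."""
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        rows = []
        for i, rec in enumerate(df.itertuples(index=False)):
            try:
                rows.append(_measurement_from_record(rec))
            except ValueError as exc:
                raise ValueError(f"row {i + 1}: {exc}") from None
        return cls(rows)

    def completeness(self) -> pd.DataFrame:
        """Method x gene matrix of observation counts (over patients+tissues)."""
        df = self.to_frame()
        return (
            df.groupby(["method_id", "gene"])
            .size()
            .unstack(fill_value=0)
            .rename_axis(index="method_id", columns="gene")
        )


def _measurement_from_record(rec) -> Measurement:
    kind = str(rec.value_kind).strip().lower()
    if kind not in (QUANTITATIVE, CATEGORICAL):
        raise ValueError(f"invalid value_kind {rec.value_kind!r}")
    if kind == QUANTITATIVE:
        try:
            v = float(rec.value)
        except (TypeError, ValueError):
            raise ValueError(f"unparseable quantitative value {rec.value!r}") from None
        return Measurement(
            patient_id=str(rec.patient_id),
            tissue=Tissue.parse(rec.tissue),
            method_id=str(rec.method_id),
            gene=str(rec.gene),
            value_kind=QUANTITATIVE,
            quant_value=v,
        )
    return Measurement(
        patient_id=str(rec.patient_id),
        tissue=Tissue.parse(rec.tissue),
        method_id=str(rec.method_id),
        gene=str(rec.gene),
        value_kind=CATEGORICAL,
        call=CNCategory.parse(rec.value),
    )


def read_dataset(path: str | Path, format: str | None = None) -> CopyNumberDataset:
    """Read a dataset from a TSV or CSV file.

    The header must name the six canonical columns.  Categorical values are
    parsed case-insensitively from {deletion, normal, amplification} or the
    integer aliases {1, 2, 3}.  Errors carry 1-based data-row numbers.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if format not in ("tsv", "csv"):
        raise ValueError(f"format must be 'tsv' or 'csv', got {format!r}")
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    return CopyNumberDataset.from_frame(df)


def write_dataset(
    ds: CopyNumberDataset, path: str | Path, format: str | None = None
) -> None:
    """Write a dataset as TSV (default) or CSV, round-trippable by
    :func:`read_dataset`."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "\t" if format == "tsv" else ","
    ds.to_frame().to_csv(path, sep=sep, index=False)


def paired_values(
    ds: CopyNumberDataset, method_id: str, gene: str
) -> list[tuple[str, float, float]]:
    """Tumor/normal value pairs for one quantitative (method, gene) group.

    Returns one ``(patient_id, tumor_value, normal_value)`` tuple per patient
    having both tissues measured; patients missing either tissue are omitted.
    Order is ascending patient_id.
    """
    if ds.method_kind(method_id) != QUANTITATIVE:
        raise ValueError(f"method {method_id!r} is not quantitative")
    if gene not in ds.genes:
        raise KeyError(f"unknown gene {gene!r}")
    by_patient: dict[str, dict[str, float]] = {}
    for m in ds.measurements:
        if m.method_id == method_id and m.gene == gene:
            by_patient.setdefault(m.patient_id, {})[m.tissue.value] = m.quant_value
    out = []
    for pid in sorted(by_patient):
        vals = by_patient[pid]
        if "tumor" in vals and "normal" in vals:
            out.append((pid, vals["tumor"], vals["normal"]))
    return out


def aligned_calls(
    ds: CopyNumberDataset,
    method_a: str,
    method_b: str,
    gene: str,
    tissue: str | Tissue | None = None,
) -> list[tuple[CNCategory, CNCategory]]:
    """Categorical call pairs for two methods on one gene.

    One pair per (patient, tissue) sample observed by *both* methods
    (complete-case intersection), ordered by (patient_id, tissue).  Pass
    ``tissue`` to restrict to one compartment; by default tumor and normal
    samples are pooled.
    """
    for mid in (method_a, method_b):
        if ds.method_kind(mid) != CATEGORICAL:
            raise ValueError(
                f"method {mid!r} is not categorical; discretize quantitative "
                "methods first"
            )
    if gene not in ds.genes:
        raise KeyError(f"unknown gene {gene!r}")
    want = Tissue.parse(tissue).value if tissue is not None else None
    calls: dict[str, dict[tuple[str, str], CNCategory]] = {method_a: {}, method_b: {}}
    for m in ds.measurements:
        if m.gene == gene and m.method_id in calls:
            if want is not None and m.tissue.value != want:
                continue
            calls[m.method_id][(m.patient_id, m.tissue.value)] = m.call
    shared = sorted(set(calls[method_a]) & set(calls[method_b]))
    return [(calls[method_a][k], calls[method_b][k]) for k in shared]


def quantitative_pairs(
    ds: CopyNumberDataset,
    method_x: str,
    method_y: str,
    genes: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled quantitative value pairs (x from ``method_x``, y from
    ``method_y``) over all (patient, tissue, gene) samples measured by both
    methods.  Deterministic (gene, patient, tissue) order."""
    for mid in (method_x, method_y):
        if ds.method_kind(mid) != QUANTITATIVE:
            raise ValueError(f"method {mid!r} is not quantitative")
    gene_set = set(genes) if genes is not None else None
    vals: dict[str, dict[tuple[str, str, str], float]] = {method_x: {}, method_y: {}}
    for m in ds.measurements:
        if m.method_id in vals and (gene_set is None or m.gene in gene_set):
            vals[m.method_id][(m.gene, m.patient_id, m.tissue.value)] = m.quant_value
    shared = sorted(set(vals[method_x]) & set(vals[method_y]))
    x = np.array([vals[method_x][k] for k in shared], dtype=float)
    y = np.array([vals[method_y][k] for k in shared], dtype=float)
    return x, y
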