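"""End-to-end orchestration: QC -> discretize -> agreement -> differential.

``run_pipeline`` reproduces the full benchmarking analysis on one dataset
and writes every summary surface as a tidy TSV: the QC report, the
per-(gene, method-pair) PABAK matrix with median orderings, the pairwise
median-PABAK summary, Passing-Bablok fits with bias flags and discrepancy
quartiles, the differential (Wilcoxon / harmonic mean / Holm) table, the
per-gene deletion/amplification tallies, and a run log.  Outputs are
byte-reproducible from input + config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (
    CATEGORICAL,
    QUANTITATIVE,
    CNCategory,
    CopyNumberDataset,
    Tissue,
    read_dataset,
)
from .differential import DifferentialCNV
from .discretize import ConversionRule, discretize_dataset
from .qc import apply_qc, qc_report
from .agreement import pabak_matrix
from .regression import quantitative_panel


@dataclass
class CnvCountSummary:
    """Per-gene deletion/amplification tallies over tumor samples."""

    per_gene: pd.DataFrame
    total_deletions: int
    total_amplifications: int

    @property
    def ratio(self) -> float:
        """Deletions per amplification; NaN when no amplifications."""
        if self.total_amplifications == 0:
            return float("nan")
        return self.total_deletions / self.total_amplifications


def cnv_count_summary(
    ds: CopyNumberDataset,
    method_id: str,
    genes: Sequence[str] | None = None,
    tissue: str | Tissue = Tissue.TUMOR,
) -> CnvCountSummary:
    """Count deletion and amplification calls per gene for one categorical
    method, across patients of one tissue (tumor by default)."""
    if ds.method_kind(method_id) != CATEGORICAL:
        raise ValueError(f"method {method_id!r} is not categorical")
    tissue = Tissue.parse(tissue)
    gene_list = sorted(genes) if genes is not None else ds.genes
    counts = {g: {"n_deletion": 0, "n_amplification": 0} for g in gene_list}
    for m in ds.measurements:
        if m.method_id != method_id or m.tissue is not tissue or m.gene not in counts:
            continue
        if m.call is CNCategory.DELETION:
            counts[m.gene]["n_deletion"] += 1
        elif m.call is CNCategory.AMPLIFICATION:
            counts[m.gene]["n_amplification"] += 1
    per_gene = (
        pd.DataFrame.from_dict(counts, orient="index")
        .rename_axis("gene")
        .reset_index()
    )
    return CnvCountSummary(
        per_gene=per_gene,
        total_deletions=int(per_gene["n_deletion"].sum()),
        total_amplifications=int(per_gene["n_amplification"].sum()),
    )


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``cat_method_pairs`` are compared after discretization (quantitative
    members are converted by ``rule``); ``quant_method_pairs`` are compared
    on the QC-filtered quantitative values.
    """

    input: str | Path
    output_dir: str | Path
    rule: ConversionRule = field(default_factory=ConversionRule)
    cat_method_pairs: Sequence[tuple[str, str]] = ()
    quant_method_pairs: Sequence[tuple[str, str]] = ()
    genes: Sequence[str] | None = None
    differential_genes: Sequence[str] | None = None
    count_method: str | None = None
    alpha: float = 0.05
    qc_threshold: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        rule = ConversionRule(**raw.pop("rule", {}))
        pairs = {
            k: [tuple(p) for p in raw.pop(k, [])]
            for k in ("cat_method_pairs", "quant_method_pairs")
        }
        return cls(rule=rule, **pairs, **raw)


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run (mirrors the written TSVs)."""

    qc: pd.DataFrame
    pabak: pd.DataFrame
    pabak_pair_medians: pd.Series
    passing_bablok: pd.DataFrame
    differential: pd.DataFrame
    cnv_counts: pd.DataFrame
    log: dict


class PipelineError(RuntimeError):
    """Raised with the failing stage's name; no partial silent output."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def _validate_config(cfg: RunConfig, ds: CopyNumberDataset) -> None:
    if cfg.genes is not None and len(cfg.genes) == 0:
        raise ValueError("config field 'genes' is an empty panel")
    if cfg.differential_genes is not None and len(cfg.differential_genes) == 0:
        raise ValueError("config field 'differential_genes' is an empty panel")
    known_genes = set(ds.genes)
    for fieldname, panel in (("genes", cfg.genes), ("differential_genes", cfg.differential_genes)):
        if panel is not None:
            missing = sorted(set(panel) - known_genes)
            if missing:
                raise ValueError(f"config field {fieldname!r} names unknown genes {missing}")
    known = set(ds.methods)
    for fieldname, pairs in (
        ("cat_method_pairs", cfg.cat_method_pairs),
        ("quant_method_pairs", cfg.quant_method_pairs),
    ):
        for pair in pairs:
            missing = sorted(set(pair) - known)
            if missing:
                raise ValueError(f"config field {fieldname!r} names unknown methods {missing}")


def run_pipeline(cfg: RunConfig, dataset: CopyNumberDataset | None = None) -> ReportBundle:
    """Run QC, discretization, both agreement analyses, differential
    testing and CNV counting; write all tables under ``cfg.output_dir``."""
    ds = dataset if dataset is not None else read_dataset(cfg.input)
    _stage("config")(_validate_config)(cfg, ds)

    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    qc = _stage("qc")(qc_report)(ds)
    filtered = _stage("qc")(apply_qc)(ds, qc)

    disc = _stage("discretize")(discretize_dataset)(filtered, cfg.rule)

    if cfg.cat_method_pairs:
        pm = _stage("categorical_agreement")(pabak_matrix)(
            disc.dataset, cfg.cat_method_pairs, genes=cfg.genes
        )
        pabak_table, pair_medians = pm.table, pm.pair_medians
    else:
        pabak_table = pd.DataFrame(
            columns=["gene", "method_a", "method_b", "n", "po", "pabak", "band"]
        )
        pair_medians = pd.Series(dtype=float, name="pabak")

    if cfg.quant_method_pairs:
        pb = _stage("quantitative_agreement")(quantitative_panel)(
            filtered, cfg.quant_method_pairs, genes=cfg.genes, alpha=cfg.alpha
        )
    else:
        pb = pd.DataFrame()

    diff = _stage("differential")(
        lambda: DifferentialCNV(
            filtered, genes=cfg.differential_genes, methods=None
        ).fit(alpha=cfg.alpha).table.reset_index()
    )()

    count_method = cfg.count_method
    if count_method is None:
        cats = [m for m, k in disc.dataset.method_kinds.items() if k == CATEGORICAL]
        count_method = sorted(cats)[0] if cats else None
    if count_method is not None:
        counts = _stage("counts")(cnv_count_summary)(
            disc.dataset, count_method, genes=cfg.genes
        )
        counts_table = counts.per_gene.assign(method_id=count_method)
        totals = {
            "deletions": counts.total_deletions,
            "amplifications": counts.total_amplifications,
            "ratio": None if np.isnan(counts.ratio) else round(counts.ratio, 4),
        }
    else:
        counts_table = pd.DataFrame(columns=["gene", "n_deletion", "n_amplification", "method_id"])
        totals = {"deletions": 0, "amplifications": 0, "ratio": None}

    from . import __version__

    log = {
        "version": __version__,
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "qc_threshold": cfg.qc_threshold,
        "rule": {
            "mode": cfg.rule.mode,
            "lower": cfg.rule.lower,
            "upper": cfg.rule.upper,
            "band_halfwidth": cfg.rule.band_halfwidth,
        },
        "n_measurements": len(ds),
        "n_after_qc": len(filtered),
        "discretization": disc.log.to_dict(orient="records"),
        "cnv_totals": totals,
    }

    _stage("write")(_write_outputs)(
        outdir, qc, pabak_table, pair_medians, pb, diff, counts_table, log
    )
    return ReportBundle(
        qc=qc,
        pabak=pabak_table,
        pabak_pair_medians=pair_medians,
        passing_bablok=pb,
        differential=diff,
        cnv_counts=counts_table,
        log=log,
    )


def _write_outputs(outdir, qc, pabak_table, pair_medians, pb, diff, counts, log):
    qc.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    pabak_table.to_csv(outdir / "pabak_matrix.tsv", sep="\t", index=False)
    pair_medians.rename("median_pabak").to_csv(outdir / "pabak_pair_summary.tsv", sep="\t")
    pb.to_csv(outdir / "passing_bablok.tsv", sep="\t", index=False)
    # 3-decimal display columns alongside full precision
    disp = diff.copy()
    for col in disp.columns:
        if col.startswith("p_") or col in ("pooled_p", "adjusted_p"):
            disp[f"{col}_3dp"] = disp[col].round(3)
    disp.to_csv(outdir / "differential.tsv", sep="\t", index=False)
    counts.to_csv(outdir / "cnv_counts.tsv", sep="\t", index=False)
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
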