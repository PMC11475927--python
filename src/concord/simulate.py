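"""Seeded synthetic multi-platform paired tumor/normal cohort generator.

Emulates the structure of a small clinical benchmarking cohort: ~13
patients each contributing a tumor and a matched normal tissue sample,
assayed for a panel of up to 87 cancer genes by five platforms — two
categorical callers operating on one shared microarray signal, one
quantitative hybridization panel with a positive constant bias, and two
near-identity quantitative digital-PCR chemistries.

The latent truth per (patient, gene) is an integer tumor copy number;
normal tissue is diploid (CN = 2).  Bulk tumor measurements are diluted by
tumor purity p via linear mixing of the tumor and diploid compartments:

    effective CN = p * CN + (1 - p) * 2

so non-integer observed values arise exactly as intratumor admixture
produces them in real bulk assays.  Quantitative platforms add a linear
distortion a + b * effective CN plus Gaussian noise truncated at zero;
categorical callers discretize the (optionally jointly perturbed) shared
signal by the 1.5/2.5 threshold rule and then push the call through a
row-stochastic misclassification channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    CATEGORICAL,
    QUANTITATIVE,
    CNCategory,
    CopyNumberDataset,
    Measurement,
    Tissue,
)
from .discretize import ConversionRule, discretize_value

#: Cancer-associated gene panel used by default (87 genes, mirroring the
#: size of a commercial targeted CNV panel).
DEFAULT_GENE_PANEL: tuple[str, ...] = (
    "AKT1", "AKT2", "AKT3", "ALK", "AR", "ATM", "AURKA", "BBC3", "BCL2L1",
    "BRAF", "BRCA1", "BRCA2", "C8orf4", "CCND1", "CCND2", "CCNE1", "CDK4",
    "CDK6", "CDKN2A", "CHEK1", "CHEK2", "CRKL", "DDR2", "EGFR", "ERBB2",
    "ERBB3", "ESR1", "EZH2", "FGF19", "FGF3", "FGF4", "FGFR1", "FGFR2",
    "FGFR3", "FGFR4", "FLT3", "GATA3", "HMGA2", "IGF1R", "ITGB4", "JAK2",
    "KDR", "KIT", "KRAS", "MAGI3", "MAP2K1", "MAP2K2", "MAPK1", "MAPK7",
    "MCL1", "MDM2", "MDM4", "MET", "MITF", "MYC", "MYCL", "MYCN", "NF1",
    "NKX2-1", "NOTCH1", "NRAS", "PAX9", "PDGFRA", "PDGFRB", "PIK3CA",
    "PIK3CB", "PIK3R1", "PPARG", "PTEN", "PTPRD", "RAF1", "RB1", "RET",
    "RICTOR", "RPS6KB1", "SMAD4", "SMO", "SOX2", "STK11", "TERT", "TOP2A",
    "TP53", "TSC1", "TSC2", "TYMS", "VEGFA", "ZNF217",
)

#: Default latent tumor copy-number distribution: mostly diploid, with
#: deletions ~1.6x more frequent than amplifications, as targeted CNV
#: panels typically observe in high-grade serous tumors.
DEFAULT_TRUTH_MODEL: dict[int, float] = {0: 0.03, 1: 0.13, 2: 0.74, 3: 0.07, 4: 0.03}


def caller_confusion(rate: float) -> np.ndarray:
    """Symmetric 3x3 misclassification channel: total error ``rate`` per
    true category, split evenly over the two wrong categories."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    m = np.full((3, 3), rate / 2.0)
    np.fill_diagonal(m, 1.0 - rate)
    return m


@dataclass(frozen=True)
class PlatformSpec:
    """One simulated platform.

    Quantitative platforms emit ``a + b * effective_cn + N(0, noise_sd)``
    truncated at 0.  Categorical platforms discretize the effective copy
    number (1.5/2.5 thresholds) and sample from the misclassification
    matrix row of the true call; platforms sharing a ``signal_group`` also
    share one Gaussian perturbation of the signal before discretization
    (correlated caller noise on the same raw data).
    """

    method_id: str
    kind: str
    constant_bias: float = 0.0
    proportional_bias: float = 1.0
    noise_sd: float = 0.0
    misclassification: np.ndarray | None = None
    signal_group: str | None = None

    def __post_init__(self) -> None:
        problems = []
        if self.kind not in (QUANTITATIVE, CATEGORICAL):
            problems.append(f"kind must be quantitative or categorical, got {self.kind!r}")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        if self.kind == CATEGORICAL:
            m = self.misclassification
            if m is None:
                m = np.eye(3)
            m = np.asarray(m, dtype=float)
            if m.shape != (3, 3) or (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0):
                problems.append("misclassification must be a 3x3 row-stochastic matrix")
            object.__setattr__(self, "misclassification", m)
        if problems:
            raise ValueError(f"invalid PlatformSpec {self.method_id!r}: " + "; ".join(problems))


def default_platforms(include_alb: bool = False) -> list[PlatformSpec]:
    """The default five-platform roster.

    Two categorical callers share the microarray signal; the hybridization
    panel reads high by a constant +0.3 copies (a positive bias small
    enough that its normal-tissue medians survive the [1.5, 2.5] QC
    window); the two PCR chemistries are near-identity.  ``include_alb`` adds two ALB-normalized PCR variants
    with a strong proportional distortion (an inadequate reference gene),
    for exercising the reference-gene QC filter.
    """
    roster = [
        PlatformSpec(
            "microarray_bcftools", CATEGORICAL,
            misclassification=caller_confusion(0.10), signal_group="microarray",
        ),
        PlatformSpec(
            "microarray_cnvpartition", CATEGORICAL,
            misclassification=caller_confusion(0.10), signal_group="microarray",
        ),
        PlatformSpec("nanostring", QUANTITATIVE, constant_bias=0.3, noise_sd=0.2),
        PlatformSpec("ddpcr_probes_rpp30", QUANTITATIVE, noise_sd=0.15),
        PlatformSpec("ddpcr_evagreen_rpp30", QUANTITATIVE, noise_sd=0.15),
    ]
    if include_alb:
        roster += [
            PlatformSpec(
                "ddpcr_probes_alb", QUANTITATIVE, proportional_bias=0.6, noise_sd=0.15
            ),
            PlatformSpec(
                "ddpcr_evagreen_alb", QUANTITATIVE, proportional_bias=0.6, noise_sd=0.15
            ),
        ]
    return roster


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic cohort.

    Parameters
    ----------
    n_patients : int
        Cohort size (default 13 paired tumor/normal sample sets).
    genes : sequence of str
        Gene panel (default: the 87-gene cancer panel).
    tumor_purity : float, sequence, or None
        Per-patient fraction of neoplastic cells.  A scalar applies to all
        patients; None draws each from Uniform(0.5, 0.9).
    truth_model : mapping
        Either {cn: prob} applied to every gene, or {gene: {cn: prob}}.
    platforms : list of PlatformSpec
    shared_noise_sd : float
        SD of the signal perturbation shared within each categorical
        signal group (0 disables it).
    seed : int
    """

    n_patients: int = 13
    genes: Sequence[str] = DEFAULT_GENE_PANEL
    tumor_purity: object = None
    truth_model: Mapping = field(default_factory=lambda: dict(DEFAULT_TRUTH_MODEL))
    platforms: Sequence[PlatformSpec] = field(default_factory=default_platforms)
    shared_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_patients < 1:
            problems.append("n_patients must be >= 1")
        if not self.genes:
            problems.append("genes must be non-empty")
        if self.shared_noise_sd < 0:
            problems.append("shared_noise_sd must be >= 0")
        if not self.platforms:
            problems.append("platforms must be non-empty")
        ids = [p.method_id for p in self.platforms]
        if len(set(ids)) != len(ids):
            problems.append("platform method_ids must be unique")
        for gene, dist in self._per_gene_truth().items():
            probs = np.array(list(dist.values()), dtype=float)
            if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
                problems.append(f"truth probabilities for {gene} must be >= 0 and sum to 1")
                break
        purity = self._purities(np.random.default_rng(0))
        if ((purity <= 0) | (purity > 1)).any():
            problems.append("tumor_purity must lie in (0, 1]")
        if problems:
            raise ValueError("invalid GeneratorConfig: " + "; ".join(problems))

    def _per_gene_truth(self) -> dict[str, dict[int, float]]:
        tm = self.truth_model
        if tm and all(isinstance(k, (int, np.integer)) for k in tm):
            return {g: dict(tm) for g in self.genes}
        out = {}
        for g in self.genes:
            out[g] = dict(tm.get(g, DEFAULT_TRUTH_MODEL))
        return out

    def _purities(self, rng: np.random.Generator) -> np.ndarray:
        if self.tumor_purity is None:
            return rng.uniform(0.5, 0.9, size=self.n_patients)
        arr = np.atleast_1d(np.asarray(self.tumor_purity, dtype=float))
        if arr.size == 1:
            return np.full(self.n_patients, float(arr[0]))
        if arr.size != self.n_patients:
            raise ValueError("tumor_purity length must equal n_patients")
        return arr


@dataclass
class SyntheticTruth:
    """Latent per-(patient, gene) truth of a generated cohort.

    ``frame`` columns: patient_id, gene, purity, latent_tumor_cn,
    effective_tumor_cn (= purity*CN + (1-purity)*2; equal to 2 whenever the
    latent CN is 2, for any purity).
    """

    frame: pd.DataFrame


def generate_cohort(cfg: GeneratorConfig) -> tuple[CopyNumberDataset, SyntheticTruth]:
    """Generate a cohort; deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    patients = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]
    genes = list(cfg.genes)
    purity = cfg._purities(rng)
    truth_dists = cfg._per_gene_truth()

    latent = np.empty((cfg.n_patients, len(genes)), dtype=int)
    for j, gene in enumerate(genes):
        states = np.array(sorted(truth_dists[gene]), dtype=int)
        probs = np.array([truth_dists[gene][s] for s in states], dtype=float)
        latent[:, j] = rng.choice(states, size=cfg.n_patients, p=probs)

    eff_tumor = purity[:, None] * latent + (1.0 - purity[:, None]) * 2.0
    eff_normal = np.full_like(eff_tumor, 2.0)

    # one shared signal perturbation per (signal_group, tissue, patient, gene)
    groups = sorted({p.signal_group for p in cfg.platforms if p.signal_group})
    shared: dict[tuple[str, str], np.ndarray] = {}
    for grp in groups:
        for tissue in ("tumor", "normal"):
            shared[(grp, tissue)] = (
                rng.normal(0.0, cfg.shared_noise_sd, size=eff_tumor.shape)
                if cfg.shared_noise_sd > 0
                else np.zeros_like(eff_tumor)
            )

    rule = ConversionRule()
    rows: list[Measurement] = []
    for spec in cfg.platforms:
        for tissue, eff in (("tumor", eff_tumor), ("normal", eff_normal)):
            if spec.kind == QUANTITATIVE:
                noise = (
                    rng.normal(0.0, spec.noise_sd, size=eff.shape)
                    if spec.noise_sd > 0
                    else np.zeros_like(eff)
                )
                values = np.maximum(
                    0.0, spec.constant_bias + spec.proportional_bias * eff + noise
                )
                for i, pid in enumerate(patients):
                    for j, gene in enumerate(genes):
                        rows.append(
                            Measurement(
                                patient_id=pid,
                                tissue=Tissue(tissue),
                                method_id=spec.method_id,
                                gene=gene,
                                value_kind=QUANTITATIVE,
                                quant_value=float(values[i, j]),
                            )
                        )
            else:
                signal = eff
                if spec.signal_group:
                    signal = np.maximum(0.0, eff + shared[(spec.signal_group, tissue)])
                u = rng.random(size=eff.shape)
                for i, pid in enumerate(patients):
                    for j, gene in enumerate(genes):
                        true_call = discretize_value(signal[i, j], rule)
                        row_probs = spec.misclassification[int(true_call) - 1]
                        emitted = int(np.searchsorted(np.cumsum(row_probs), u[i, j])) + 1
                        rows.append(
                            Measurement(
                                patient_id=pid,
                                tissue=Tissue(tissue),
                                method_id=spec.method_id,
                                gene=gene,
                                value_kind=CATEGORICAL,
                                call=CNCategory(min(emitted, 3)),
                            )
                        )

    truth = pd.DataFrame(
        {
            "patient_id": np.repeat(patients, len(genes)),
            "gene": np.tile(genes, cfg.n_patients),
            "purity": np.repeat(purity, len(genes)),
            "latent_tumor_cn": latent.ravel(),
            "effective_tumor_cn": eff_tumor.ravel(),
        }
    )
    return CopyNumberDataset(rows), SyntheticTruth(frame=truth)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write the latent truth as a tidy TSV."""
    truth.frame.to_csv(Path(path), sep="\t", index=False)


def read_truth(path: str | Path) -> SyntheticTruth:
    """Read a truth TSV written by :func:`write_truth`."""
    return SyntheticTruth(frame=pd.read_csv(Path(path), sep="\t"))
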