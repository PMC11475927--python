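"""Paired Wilcoxon, harmonic-mean pooling, Holm correction, rank correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concord.data import CopyNumberDataset
from concord.datasets import SEVEN_GENE_PUBLISHED_POOLED, seven_gene_panel_pvalues
from concord.differential import (
    DifferentialCNV,
    combine_method_pvalues,
    differential_table,
    harmonic_mean_p,
    holm_adjust,
    paired_wilcoxon,
    rank_correlation,
)
from concord.simulate import GeneratorConfig, PlatformSpec, generate_cohort
from conftest import quant

positive_p = st.floats(min_value=1e-6, max_value=1.0)


def holm_oracle(ps):
    """Step-down Holm written out longhand: sort, multiply the i-th smallest
    of m by (m - i + 1), running maximum, cap at 1, restore input order."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * ps[i]))
        adjusted[i] = running
    return adjusted


class TestPairedWilcoxon:
    def test_no_signal_gives_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            assert paired_wilcoxon([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_all_positive_differences_exact_enumeration(self):
        # differences (1..6): the most extreme of 2^6 equally likely sign
        # assignments, two-sided -> p = 2/64
        tumor = np.array([2, 3, 4, 5, 6, 7], dtype=float)
        normal = np.ones(6)
        expected = 2 / 2**6
        assert paired_wilcoxon(tumor, normal + 0) == pytest.approx(expected)
        # independent check by direct enumeration of the signed-rank null
        diffs = tumor - normal
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        w_obs = ranks[diffs > 0].sum()
        stats = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product((False, True), repeat=6)
        ]
        w_max = sum(ranks)
        p_enum = np.mean(
            [min(w, w_max - w) <= min(w_obs, w_max - w_obs) for w in stats]
        )
        assert paired_wilcoxon(tumor, normal) == pytest.approx(p_enum)

    def test_detects_one_copy_shift(self):
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(100):
            normal = 2.0 + rng.normal(0, 0.2, size=12)
            tumor = 3.0 + rng.normal(0, 0.2, size=12)
            if paired_wilcoxon(tumor, normal) < 0.05:
                hits += 1
        assert hits >= 95

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1.0, 2.0], [1.0])


class TestHarmonicMean:
    @pytest.mark.parametrize(
        "ps,expected",
        [
            ([0.003, 0.092], 0.006),
            ([0.497, 0.216, 1.0], 0.393),
            ([0.685, 0.542, 0.168], 0.324),
            ([0.972, 0.807], 0.882),
            ([0.505, 0.168], 0.252),
            ([0.685, 0.363], 0.475),
        ],
    )
    def test_published_panel_values(self, ps, expected):
        assert round(harmonic_mean_p(ps), 3) == expected

    def test_single_value_identity(self):
        assert harmonic_mean_p([0.37]) == pytest.approx(0.37)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(positive_p, min_size=1, max_size=10))
    def test_bounded_by_extremes_and_arithmetic_mean(self, ps):
        hm = harmonic_mean_p(ps)
        assert min(ps) - 1e-12 <= hm <= max(ps) + 1e-12
        assert hm <= np.mean(ps) + 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            harmonic_mean_p([])
        with pytest.raises(ValueError):
            harmonic_mean_p([0.0, 0.5])


class TestHolm:
    def test_published_panel_correction(self):
        pooled = [0.882, 0.006, 0.393, 0.252, 0.475, 0.573, 0.324]
        adjusted = holm_adjust(pooled)
        assert adjusted == pytest.approx([1, 0.042, 1, 1, 1, 1, 1])

    def test_running_maximum_lifts_large_p_to_one(self):
        # 0.882 alone times its factor (1) would stay 0.882; the running
        # maximum from earlier ranks must lift it to 1
        pooled = [0.882, 0.006, 0.393, 0.252, 0.475, 0.573, 0.324]
        assert holm_adjust(pooled)[0] == 1.0

    def test_single_p_unchanged_and_all_ones(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])
        assert holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(positive_p, min_size=1, max_size=12))
    def test_matches_longhand_oracle(self, ps):
        assert holm_adjust(ps) == pytest.approx(holm_oracle(ps))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(positive_p, min_size=2, max_size=10), st.randoms())
    def test_permutation_equivariance_and_bonferroni_dominance(self, ps, rnd):
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        adjusted = holm_adjust(ps)
        permuted = holm_adjust([ps[i] for i in perm])
        assert [adjusted[i] for i in perm] == pytest.approx(list(permuted))
        bonferroni = np.minimum(1.0, len(ps) * np.asarray(ps))
        assert (adjusted <= bonferroni + 1e-12).all()
        assert (adjusted >= np.asarray(ps) - 1e-12).all()


class TestCombine:
    def test_published_table_reproduction(self):
        combined = combine_method_pvalues(seven_gene_panel_pvalues())
        for gene, (pooled, corrected) in SEVEN_GENE_PUBLISHED_POOLED.items():
            assert combined.loc[gene, "pooled_p"] == pytest.approx(pooled, abs=1e-3)
        # Holm of the display-rounded pooled column reproduces the printed
        # corrected column; full-precision pooling keeps CCND2 significant
        adjusted = holm_adjust(combined["pooled_p"].round(3).to_numpy())
        assert adjusted == pytest.approx(
            [SEVEN_GENE_PUBLISHED_POOLED[g][1] for g in combined.index]
        )
        assert combined.loc["CCND2", "adjusted_p"] < 0.05

    def test_missing_methods_skipped_not_imputed(self):
        df = pd.DataFrame(
            {"m1": [0.2, np.nan], "m2": [np.nan, 0.4]}, index=["g1", "g2"]
        )
        out = combine_method_pvalues(df)
        assert out.loc["g1", "pooled_p"] == pytest.approx(0.2)
        assert out.loc["g2", "pooled_p"] == pytest.approx(0.4)

    def test_pooled_between_min_and_max_of_available(self):
        df = seven_gene_panel_pvalues()
        out = combine_method_pvalues(df)
        for gene, row in df.iterrows():
            avail = row.dropna()
            assert avail.min() <= out.loc[gene, "pooled_p"] <= avail.max()


class TestDifferentialModel:
    def test_single_gene_single_method(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(8):
            rows.append(quant(f"P{i}", "tumor", "q", "G", 3.0 + rng.normal(0, 0.1)))
            rows.append(quant(f"P{i}", "normal", "q", "G", 2.0 + rng.normal(0, 0.1)))
        res = DifferentialCNV(CopyNumberDataset(rows)).fit()
        row = res.table.iloc[0]
        assert row["pooled_p"] == row["p_q"]
        assert row["adjusted_p"] == row["p_q"]

    def test_amplified_gene_wins_among_nulls(self):
        genes = [f"N{i}" for i in range(6)] + ["AMP"]
        truth = {g: {2: 1.0} for g in genes}
        truth["AMP"] = {4: 1.0}
        platforms = [
            PlatformSpec("q1", "quantitative", noise_sd=0.2),
            PlatformSpec("q2", "quantitative", noise_sd=0.2),
        ]
        wins = 0
        for seed in range(100):
            cfg = GeneratorConfig(
                n_patients=12,
                genes=genes,
                tumor_purity=0.8,
                truth_model=truth,
                platforms=platforms,
                seed=seed,
            )
            ds, _ = generate_cohort(cfg)
            table = differential_table(ds)
            if table["adjusted_p"].idxmin() == "AMP":
                wins += 1
        assert wins >= 90

    def test_summary_mentions_columns(self, tiny_quant_dataset):
        rows = list(tiny_quant_dataset.measurements) + [
            quant("P3", "tumor", "ddpcr", "CCND2", 2.6),
            quant("P3", "normal", "ddpcr", "CCND2", 2.0),
        ]
        res = DifferentialCNV(CopyNumberDataset(rows)).fit()
        text = res.summary()
        assert "pooled_p" in text and "adjusted_p" in text


class TestRankCorrelation:
    def test_monotone_pairs(self):
        assert rank_correlation([1, 2, 3, 4], [10, 20, 30, 40])[0] == 1.0
        assert rank_correlation([1, 2, 3, 4], [40, 30, 20, 10])[0] == -1.0

    def test_partially_ordered_pair(self):
        rho, _ = rank_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rank_correlation([1, 1, 1], [1, 2, 3])
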