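"""Passing-Bablok regression and relative discrepancy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concord.regression import (
    PassingBablok,
    passing_bablok,
    quantitative_panel,
    relative_discrepancy,
)
from concord.simulate import GeneratorConfig, PlatformSpec, generate_cohort


def oracle_slope_intercept(x, y):
    """Brute-force shifted-median estimate, written to the published recipe:
    enumerate every pairwise slope with explicit loops, drop undefined and
    exactly -1 slopes, sort, shift the median rank by the count below -1."""
    x, y = list(map(float, x)), list(map(float, y))
    slopes = []
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            if x[j] == x[i]:
                continue
            s = (y[j] - y[i]) / (x[j] - x[i])
            if s != -1.0:
                slopes.append(s)
    slopes.sort()
    n = len(slopes)
    k = sum(1 for s in slopes if s < -1.0)
    if n % 2 == 1:
        slope = slopes[(n + 1) // 2 + k - 1]
    else:
        slope = 0.5 * (slopes[n // 2 + k - 1] + slopes[n // 2 + k])
    residuals = sorted(yi - slope * xi for xi, yi in zip(x, y))
    m = len(residuals)
    if m % 2 == 1:
        intercept = residuals[m // 2]
    else:
        intercept = 0.5 * (residuals[m // 2 - 1] + residuals[m // 2])
    return slope, intercept


class TestPassingBablok:
    def test_identity_line_has_no_bias(self):
        fit = passing_bablok([1, 2, 3, 4], [1, 2, 3, 4])
        assert fit.slope == 1.0 and fit.intercept == 0.0
        assert not fit.proportional_bias and not fit.constant_bias

    def test_exact_linear_data(self):
        x = np.arange(1.0, 6.0)
        fit = passing_bablok(x, 2 * x + 1)
        assert fit.slope == 2.0 and fit.intercept == pytest.approx(1.0)
        assert fit.ci_slope == (2.0, 2.0)  # all pairwise slopes identical
        assert fit.proportional_bias and fit.constant_bias

    def test_known_noisy_example(self):
        x = [1, 2, 3, 4, 5]
        y = [2.1, 3.9, 6.2, 8.0, 9.9]
        fit = passing_bablok(x, y)
        exp_slope, exp_intercept = oracle_slope_intercept(x, y)
        assert fit.slope == pytest.approx(exp_slope)
        assert fit.slope == pytest.approx((1.95 + 59 / 30) / 2)  # mean of 5th, 6th of 10
        assert fit.intercept == pytest.approx(exp_intercept)
        assert round(fit.slope, 3) == 1.958
        assert round(fit.intercept, 3) == 0.142

    def test_preconditions(self):
        with pytest.raises(ValueError):
            PassingBablok([1, 2], [1, 2])
        with pytest.raises(ValueError):
            PassingBablok([2, 2, 2], [1, 2, 3])

    def test_matches_oracle_on_random_data(self):
        rng = np.random.default_rng(20240901)
        checked = 0
        while checked < 500:
            n = int(rng.integers(3, 9))
            if rng.random() < 0.5:  # integer-valued x to exercise tied x
                x = rng.integers(0, 5, size=n).astype(float)
            else:
                x = rng.uniform(0, 5, size=n)
            y = rng.uniform(0, 5, size=n)
            try:
                fit = passing_bablok(x, y)
            except ValueError:
                continue
            exp_slope, exp_intercept = oracle_slope_intercept(x, y)
            assert fit.slope == pytest.approx(exp_slope), (x, y)
            assert fit.intercept == pytest.approx(exp_intercept), (x, y)
            checked += 1

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.floats(min_value=0.1, max_value=10),
        st.integers(0, 2**16),
    )
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.5, 5, size=8)
        y = 1.4 * x + 0.2 + rng.normal(0, 0.1, size=8)
        base = passing_bablok(x, y)
        scaled = passing_bablok(c * x, c * y)
        assert scaled.slope == pytest.approx(base.slope, rel=1e-9)
        assert scaled.intercept == pytest.approx(c * base.intercept, rel=1e-6, abs=1e-9)

    def test_noise_free_flags_match_injected_bias(self):
        x = np.linspace(0.5, 4.5, 30)
        with_offset = passing_bablok(x, x + 0.5)
        assert with_offset.constant_bias and not with_offset.proportional_bias
        with_factor = passing_bablok(x, 1.3 * x)
        assert with_factor.proportional_bias and not with_factor.constant_bias

    def test_ci_width_shrinks_with_vanishing_noise(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0.5, 4.5, 40)
        widths = []
        for sd in (0.5, 0.05, 0.005):
            y = 1.2 * x + 0.3 + rng.normal(0, sd, size=x.size)
            fit = passing_bablok(x, y)
            widths.append(fit.ci_slope[1] - fit.ci_slope[0])
        assert widths[0] > widths[1] > widths[2]


class TestRelativeDiscrepancy:
    def test_examples(self):
        assert relative_discrepancy([2.0], [2.0]).d_values[0] == 0.0
        assert relative_discrepancy([2.0], [4.0]).d_values[0] == pytest.approx(0.5)
        summ = relative_discrepancy([2, 2, 2], [2, 3, 4])
        assert summ.d_values == pytest.approx([0, 1 / 3, 1 / 2])
        assert summ.median == pytest.approx(1 / 3)

    def test_double_zero_defined_as_zero(self):
        assert relative_discrepancy([0.0], [0.0]).d_values[0] == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            relative_discrepancy([-1.0], [1.0])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(min_value=0, max_value=50), min_size=1, max_size=20),
        st.lists(st.floats(min_value=0, max_value=50), min_size=1, max_size=20),
        st.floats(min_value=0.01, max_value=100),
    )
    def test_symmetry_scaling_and_range(self, xs, ys, c):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        d_xy = relative_discrepancy(x, y).d_values
        d_yx = relative_discrepancy(y, x).d_values
        d_scaled = relative_discrepancy(c * x, c * y).d_values
        assert np.allclose(d_xy, d_yx)
        assert np.allclose(d_xy, d_scaled)
        assert ((d_xy >= 0) & (d_xy <= 1)).all()
        assert np.array_equal(d_xy == 0, x == y)


class TestQuantitativePanel:
    def test_self_comparison_is_identity(self):
        cfg = GeneratorConfig(
            n_patients=6,
            genes=["G1", "G2", "G3"],
            tumor_purity=1.0,
            truth_model={1: 0.3, 2: 0.4, 3: 0.3},
            platforms=[
                PlatformSpec("q1", "quantitative"),
                PlatformSpec("q2", "quantitative"),
            ],
            seed=7,
        )
        ds, _ = generate_cohort(cfg)
        row = quantitative_panel(ds, [("q1", "q2")]).iloc[0]
        assert row["slope"] == 1.0 and row["intercept"] == 0.0
        assert row["d_median"] == 0.0
        assert not row["prop_bias"] and not row["const_bias"]

    @pytest.mark.parametrize(
        "spec_kwargs,expect",
        [
            ({"constant_bias": 0.5}, ("const_bias", "prop_bias")),
            ({"proportional_bias": 1.3}, ("prop_bias", "const_bias")),
        ],
    )
    def test_noise_free_injected_bias_flags(self, spec_kwargs, expect):
        flag_on, flag_off = expect
        cfg = GeneratorConfig(
            n_patients=8,
            genes=["G1", "G2", "G3"],
            tumor_purity=1.0,
            truth_model={0: 0.1, 1: 0.2, 2: 0.4, 3: 0.2, 4: 0.1},
            platforms=[
                PlatformSpec("qx", "quantitative"),
                PlatformSpec("qy", "quantitative", **spec_kwargs),
            ],
            seed=21,
        )
        ds, _ = generate_cohort(cfg)
        row = quantitative_panel(ds, [("qx", "qy")]).iloc[0]
        assert row[flag_on] and not row[flag_off]

    def test_too_few_shared_points_is_error(self):
        from concord.data import CopyNumberDataset
        from conftest import quant

        ds = CopyNumberDataset(
            [
                quant("P1", "tumor", "a", "G", 2.0),
                quant("P1", "normal", "a", "G", 2.1),
                quant("P2", "tumor", "a", "G", 3.0),
                quant("P1", "tumor", "b", "G", 2.2),
                quant("P1", "normal", "b", "G", 2.0),
            ]
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            quantitative_panel(ds, [("a", "b")])
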