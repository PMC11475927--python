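"""Passing-Bablok regression and the relative-discrepancy statistic.

Passing-Bablok regression is the standard nonparametric method-comparison
fit: the slope is a shifted median of all pairwise slopes
S_ij = (y_j - y_i) / (x_j - x_i), making it robust to outliers and to
measurement error in both variables.  The fitted line y = k*x + b is read
as: k != 1 indicates a proportional bias between the two methods, b != 0 a
constant bias, each judged by whether the 95% confidence interval covers
the null value.

Because two methods can scatter widely around y = x without triggering
either bias flag, the per-observation relative discrepancy

    d_i = |y_i - x_i| / max(x_i, y_i)     (in [0, 1])

is summarized alongside the fit; the closer its median and quartiles are
to zero, the better the agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import CopyNumberDataset, quantitative_pairs


class PassingBablok:
    """Passing-Bablok method-comparison model.

    Parameters
    ----------
    x, y : array-like
        Paired measurements of the same samples by two methods, equal
        length n >= 3, with x not all identical.

    Examples
    --------
    >>> fit = PassingBablok([1, 2, 3, 4, 5], [3, 5, 7, 9, 11]).fit()
    >>> round(fit.slope, 6), round(fit.intercept, 6)
    (2.0, 1.0)
    """

    def __init__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size < 3:
            raise ValueError(f"need at least 3 points, got {x.size}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("x and y must be finite")
        if np.ptp(x) == 0:
            raise ValueError("all x values are identical; slope is undefined")
        self.x = x
        self.y = y
        self.nobs = int(x.size)

    def _pairwise_slopes(self) -> np.ndarray:
        i, j = np.triu_indices(self.nobs, k=1)
        dx = self.x[j] - self.x[i]
        dy = self.y[j] - self.y[i]
        keep = dx != 0
        s = dy[keep] / dx[keep]
        # slopes of exactly -1 carry no information about the shifted median
        return s[s != -1.0]

    def fit(self, alpha: float = 0.05) -> "PassingBablokResults":
        """Estimate slope, intercept and their (1 - alpha) confidence
        intervals.

        The slope is the K-shifted median of the N sorted pairwise slopes,
        K being the number of slopes below -1; the intercept is
        median(y - slope*x).  Slope CI bounds are the order statistics at
        ranks M1 + K and M2 + K with M1 = round((N - C)/2) (half-to-even),
        M2 = N - M1 + 1 and C = z_{1-alpha/2} * sqrt(n(n-1)(2n+5)/18).
        Ranks falling outside [1, N] are clamped to the extreme order
        statistics (conservative full-range CI) and ``ci_clamped`` is set.
        """
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        s = np.sort(self._pairwise_slopes())
        n_slopes = s.size
        if n_slopes == 0:
            raise ValueError("all pairwise slopes are undefined (tied x values)")
        shift = int(np.sum(s < -1.0))

        slope = _shifted_median(s, shift)

        n = self.nobs
        z = stats.norm.ppf(1 - alpha / 2)
        c = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
        m1 = round((n_slopes - c) / 2)  # round-half-to-even
        m2 = n_slopes - m1 + 1
        lo_rank, hi_rank = m1 + shift, m2 + shift
        clamped = lo_rank < 1 or hi_rank > n_slopes
        lo_rank = min(max(lo_rank, 1), n_slopes)
        hi_rank = min(max(hi_rank, 1), n_slopes)
        slope_lo = float(s[lo_rank - 1])
        slope_hi = float(s[hi_rank - 1])

        intercept = float(np.median(self.y - slope * self.x))
        # intercept bounds pair with the opposite slope bounds
        intercept_lo = float(np.median(self.y - slope_hi * self.x))
        intercept_hi = float(np.median(self.y - slope_lo * self.x))

        return PassingBablokResults(
            model=self,
            alpha=alpha,
            slope=float(slope),
            intercept=intercept,
            ci_slope=(slope_lo, slope_hi),
            ci_intercept=(intercept_lo, intercept_hi),
            n_points=n,
            n_slopes=int(n_slopes),
            ci_clamped=bool(clamped),
        )


def _shifted_median(sorted_slopes: np.ndarray, shift: int) -> float:
    """K-shifted median (1-based ranks (N+1)/2 + K, or the mean of ranks
    N/2 + K and N/2 + 1 + K for even N)."""
    n = sorted_slopes.size
    if n % 2 == 1:
        idx = (n + 1) // 2 + shift
        if not 1 <= idx <= n:
            raise ValueError("shifted median rank out of range; need more points")
        return float(sorted_slopes[idx - 1])
    i1, i2 = n // 2 + shift, n // 2 + 1 + shift
    if not (1 <= i1 <= n and 1 <= i2 <= n):
        raise ValueError("shifted median rank out of range; need more points")
    return float(0.5 * (sorted_slopes[i1 - 1] + sorted_slopes[i2 - 1]))


@dataclass
class PassingBablokResults:
    """Fitted Passing-Bablok regression.

    ``proportional_bias`` is true when the slope CI excludes 1;
    ``constant_bias`` when the intercept CI excludes 0.
    """

    model: PassingBablok
    alpha: float
    slope: float
    intercept: float
    ci_slope: tuple[float, float]
    ci_intercept: tuple[float, float]
    n_points: int
    n_slopes: int
    ci_clamped: bool = False

    @property
    def proportional_bias(self) -> bool:
        return not (self.ci_slope[0] <= 1.0 <= self.ci_slope[1])

    @property
    def constant_bias(self) -> bool:
        return not (self.ci_intercept[0] <= 0.0 <= self.ci_intercept[1])

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def summary(self) -> str:
        conf = int(round(100 * (1 - self.alpha)))
        lines = [
            "Passing-Bablok regression",
            f"  n points            : {self.n_points}",
            f"  n pairwise slopes   : {self.n_slopes}",
            f"  slope k             : {self.slope:.4f}  "
            f"[{self.ci_slope[0]:.4f}, {self.ci_slope[1]:.4f}] ({conf}% CI)",
            f"  intercept b         : {self.intercept:.4f}  "
            f"[{self.ci_intercept[0]:.4f}, {self.ci_intercept[1]:.4f}] ({conf}% CI)",
            "  proportional bias   : "
            + ("yes (slope CI excludes 1)" if self.proportional_bias else "no"),
            "  constant bias       : "
            + ("yes (intercept CI excludes 0)" if self.constant_bias else "no"),
        ]
        if self.ci_clamped:
            lines.append("  note: CI ranks clamped to the slope range (small n)")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of the paired values with the fitted line and y = x."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.model.x, self.model.y
        ax.scatter(x, y, s=18, alpha=0.7)
        grid = np.linspace(min(x.min(), y.min()), max(x.max(), y.max()), 50)
        ax.plot(grid, grid, linestyle="--", color="grey", label="y = x")
        ax.plot(grid, self.predict(grid), color="C1", label="fit")
        ax.set_xlabel("method x")
        ax.set_ylabel("method y")
        ax.legend()
        return ax


def passing_bablok(x, y, alpha: float = 0.05) -> PassingBablokResults:
    """Convenience wrapper: ``PassingBablok(x, y).fit(alpha)``."""
    return PassingBablok(x, y).fit(alpha=alpha)


@dataclass
class DiscrepancySummary:
    """Relative discrepancies d_i = |y - x| / max(x, y) with quartiles."""

    d_values: np.ndarray
    median: float
    q1: float
    q3: float


def relative_discrepancy(x, y) -> DiscrepancySummary:
    """Per-observation relative discrepancy and its quartile summary.

    d_i lies in [0, 1], is zero iff the two measurements agree, is
    symmetric in x and y, and is invariant to common positive scaling.
    x_i = y_i = 0 yields d_i = 0.  Quartiles use linear interpolation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("copy-number values must be non-negative")
    denom = np.maximum(x, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, np.abs(y - x) / np.where(denom > 0, denom, 1.0), 0.0)
    q1, med, q3 = (float(q) for q in np.quantile(d, [0.25, 0.5, 0.75]))
    return DiscrepancySummary(d_values=d, median=med, q1=q1, q3=q3)


def quantitative_panel(
    ds: CopyNumberDataset,
    method_pairs: Sequence[tuple[str, str]],
    genes: Sequence[str] | None = None,
    alpha: float = 0.05,
    per_gene: bool = False,
) -> pd.DataFrame:
    """Passing-Bablok fits plus discrepancy summaries for method pairs.

    Points are pooled across genes and (patient, tissue) samples measured by
    both methods; pass ``per_gene=True`` for one fit per gene instead.
    Output columns: method_x, method_y, [gene], n, slope, slope_lo,
    slope_hi, intercept, intercept_lo, intercept_hi, prop_bias, const_bias,
    d_median, d_q1, d_q3.
    """
    rows = []
    for mx, my in method_pairs:
        if per_gene:
            pool = genes if genes is not None else ds.genes
            groups = [(g, [g]) for g in pool]
        else:
            groups = [(None, genes)]
        for label, gene_subset in groups:
            x, y = quantitative_pairs(ds, mx, my, genes=gene_subset)
            if x.size < 3:
                raise ValueError(
                    f"fewer than 3 shared points for pair ({mx!r}, {my!r})"
                    + (f" gene {label!r}" if label else "")
                )
            res = PassingBablok(x, y).fit(alpha=alpha)
            disc = relative_discrepancy(x, y)
            row = {
                "method_x": mx,
                "method_y": my,
                "n": res.n_points,
                "slope": res.slope,
                "slope_lo": res.ci_slope[0],
                "slope_hi": res.ci_slope[1],
                "intercept": res.intercept,
                "intercept_lo": res.ci_intercept[0],
                "intercept_hi": res.ci_intercept[1],
                "prop_bias": res.proportional_bias,
                "const_bias": res.constant_bias,
                "d_median": disc.median,
                "d_q1": disc.q1,
                "d_q3": disc.q3,
            }
            if per_gene:
                row = {"method_x": mx, "method_y": my, "gene": label, **{
                    k: v for k, v in row.items() if k not in ("method_x", "method_y")
                }}
            rows.append(row)
    return pd.DataFrame(rows)
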