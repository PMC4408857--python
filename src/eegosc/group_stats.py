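"""Group comparison of fitted oscillator parameters and power analysis.

For each of the seven model parameters two groups of per-block fits are
compared with a two-sided unpaired t-test (pooled variance by default)
and a two-sided Wilcoxon rank-sum test (exact enumeration when both
groups have at most 10 observations, otherwise the normal approximation
with tie correction).  Both raw p-values are Bonferroni-adjusted by the
number of simultaneous comparisons (7, one per parameter).

Sample-size adequacy is quantified by the minimum detectable mean
difference of the two-sample normal-approximation power formula

.. math::

    \\Delta_{min} = (z_{1-\\alpha/2} + z_{power})\\, s_{pooled}
                    \\sqrt{1/n_a + 1/n_b}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import PARAM_NAMES

__all__ = [
    "ParamSample",
    "GroupComparisonTable",
    "compare_groups",
    "min_detectable_difference",
]

N_COMPARISONS = len(PARAM_NAMES)


@dataclass
class ParamSample:
    """Fitted parameter values for one group: one row per block."""

    label: str
    values: pd.DataFrame  # columns = the 7 parameter names

    def __post_init__(self) -> None:
        missing = [c for c in PARAM_NAMES if c not in self.values.columns]
        if missing:
            raise ValueError(f"missing parameter columns: {missing}")
        if len(self.values) < 2:
            raise ValueError("need at least 2 fitted blocks per group")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class GroupComparisonTable:
    """Per-parameter means +- SD and the three p-value columns."""

    label_a: str
    label_b: str
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _bonferroni(p: float, n: int = N_COMPARISONS) -> float:
    return min(1.0, p * n)


def compare_groups(a: ParamSample, b: ParamSample,
                   welch: bool = False) -> GroupComparisonTable:
    """Compare the 7 fitted parameters between two groups.

    Returns a table with group means +- SD, raw t-test and rank-sum
    p-values, and their Bonferroni adjustments (factor 7, capped at 1).
    Zero variance in both groups with equal means yields p = 1 with a
    warning instead of an undefined statistic.
    """
    rows = []
    for name in PARAM_NAMES:
        xa = a.values[name].to_numpy(dtype=float)
        xb = b.values[name].to_numpy(dtype=float)
        degenerate = xa.std() == 0 and xb.std() == 0
        if degenerate and xa.mean() == xb.mean():
            warnings.warn(
                f"{name}: zero variance in both groups with equal means; p=1"
            )
            t_p, w_p = 1.0, 1.0
        else:
            t_p = float(stats.ttest_ind(xa, xb, equal_var=not welch).pvalue)
            method = "exact" if (len(xa) <= 10 and len(xb) <= 10) else "asymptotic"
            w_p = float(stats.mannwhitneyu(
                xa, xb, alternative="two-sided", method=method).pvalue)
            if np.isnan(t_p):
                warnings.warn(f"{name}: degenerate t-test; p set to 1")
                t_p = 1.0
        rows.append({
            "parameter": name,
            f"mean_{a.label}": xa.mean(), f"sd_{a.label}": xa.std(ddof=1),
            f"mean_{b.label}": xb.mean(), f"sd_{b.label}": xb.std(ddof=1),
            "t_p": t_p,
            "wilcoxon_p": w_p,
            "t_p_bonferroni": _bonferroni(t_p),
            "wilcoxon_p_bonferroni": _bonferroni(w_p),
        })
    table = pd.DataFrame(rows).set_index("parameter")
    return GroupComparisonTable(a.label, b.label, table)


def ttest_from_summary(n_a: int, mean_a: float, sd_a: float,
                       n_b: int, mean_b: float, sd_b: float,
                       welch: bool = False) -> float:
    """Two-sided unpaired t-test p-value from (n, mean, sd) summaries."""
    res = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                     equal_var=not welch)
    return float(res.pvalue)


def min_detectable_difference(a_summary: tuple[int, float],
                              b_summary: tuple[int, float],
                              power_levels=(0.90, 0.95, 0.99, 0.999),
                              alpha: float = 0.05) -> pd.DataFrame:
    """Minimum detectable mean difference at the requested power levels.

    ``a_summary`` and ``b_summary`` are ``(n, sd)`` pairs; the pooled SD
    combines them with ``n-1`` weights.  Returns one row per power level.
    """
    n_a, sd_a = a_summary
    n_b, sd_b = b_summary
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    for p in power_levels:
        if not 0 < p < 1:
            raise ValueError(f"power level {p} outside (0, 1)")
    s_pooled = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2)
                       / (n_a + n_b - 2))
    z_alpha = stats.norm.ppf(1 - alpha / 2)
    rows = [{
        "power": p,
        "min_difference": float(
            (z_alpha + stats.norm.ppf(p)) * s_pooled
            * np.sqrt(1 / n_a + 1 / n_b)
        ),
    } for p in power_levels]
    return pd.DataFrame(rows).set_index("power")
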