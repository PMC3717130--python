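"""Goodness-of-fit of a weighted virtual population against trial targets.

Three statistics compare each therapy/timepoint to its target: a two-sided
Welch t-test on the means, a two-sided variance-ratio F-test on the SDs, and
a chi-squared test on the binned response distribution (expected counts
N_T * f_b from the population's weighted bin fractions). The weighted
population enters the t/F tests with the Kish effective sample size by
default (configurable to the trial's N on both sides).

Fisher's method aggregates the individual p-values into the composite
goodness-of-fit: X = -2 sum ln p ~ chi^2 with 2k degrees of freedom under the
null. The optimization objective is the sum of log p-values, a strictly
increasing function of the composite for a fixed statistic count. p-values
are floored at 1e-300 before taking logs so the objective stays finite (and
worst-scoring) away from the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import TrialTarget
from .errors import DegenerateVarianceError, MapelError

__all__ = [
    "GofReport",
    "StatResult",
    "mean_pvalue",
    "sd_pvalue",
    "bins_pvalue",
    "composite_gof",
    "write_gof_report",
]

P_FLOOR = 1e-300


def mean_pvalue(
    vpop_mean: float,
    vpop_sd: float,
    n_eff: float,
    trial_mean: float,
    trial_sd: float,
    n_trial: float,
) -> float:
    """Two-sided Welch t-test p-value from summary statistics.

    Convention: when both SDs are zero the p-value is 1 for equal means and
    0 for differing means (no exception, so the optimizer can keep moving).
    """
    if n_eff <= 1 or n_trial <= 1:
        raise MapelError("both sample sizes must exceed 1")
    if vpop_sd == 0.0 and trial_sd == 0.0:
        return 1.0 if vpop_mean == trial_mean else 0.0
    res = stats.ttest_ind_from_stats(
        vpop_mean, vpop_sd, n_eff, trial_mean, trial_sd, n_trial, equal_var=False
    )
    return float(res.pvalue)


def sd_pvalue(
    vpop_sd: float,
    n_eff: float,
    trial_sd: float,
    n_trial: float,
    two_sided: bool = True,
) -> float:
    """Variance-ratio F-test p-value, two-sided by doubling the smaller tail."""
    if n_eff <= 1 or n_trial <= 1:
        raise MapelError("both sample sizes must exceed 1")
    if vpop_sd <= 0.0 or trial_sd <= 0.0:
        raise DegenerateVarianceError("F-test requires strictly positive SDs")
    f = (vpop_sd / trial_sd) ** 2
    d1, d2 = n_eff - 1.0, n_trial - 1.0
    upper = float(stats.f.sf(f, d1, d2))
    if not two_sided:
        return upper
    lower = float(stats.f.cdf(f, d1, d2))
    return min(1.0, 2.0 * min(upper, lower))


def bins_pvalue(
    fractions: np.ndarray, target: TrialTarget, floor_scale: float = 1e-6
) -> float:
    """Chi-squared p-value of observed bin counts against weighted fractions.

    Expected counts are N_T * f_b, floored at ``floor_scale * N_T`` and
    renormalized to sum N_T (so an empty population bin cannot divide by
    zero); the statistic uses B - 1 degrees of freedom.
    """
    fractions = np.asarray(fractions, dtype=float)
    counts = np.array([b.count for b in target.bins], dtype=float)
    if len(counts) < 2:
        raise MapelError("chi-squared test needs at least 2 bins")
    if len(fractions) != len(counts):
        raise MapelError("fraction/bin length mismatch")
    n = float(target.n_trial)
    expected = n * fractions
    expected = np.maximum(expected, floor_scale * n)
    expected *= n / expected.sum()
    statistic = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(statistic, len(counts) - 1))


def composite_gof(p_values: Sequence[float]) -> tuple[float, float]:
    """Fisher's-method composite p-value and the log-sum objective.

    Returns ``(composite, objective)`` with objective = sum ln p (p floored
    at 1e-300) and composite = P(chi^2_{2k} >= -2 * objective). A single
    p-value passes through unchanged; all-ones give (1, 0).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise MapelError("composite_gof requires at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise MapelError("p-values must lie in [0, 1]")
    objective = float(np.log(np.clip(p, P_FLOOR, 1.0)).sum())
    composite = float(stats.chi2.sf(-2.0 * objective, 2 * p.size))
    return composite, objective


@dataclass(frozen=True)
class StatResult:
    therapy: str
    months: float
    statistic: str  # "mean" | "sd" | "bins"
    pvalue: float
    included: bool = True


@dataclass
class GofReport:
    """Per-statistic p-values plus the Fisher composite for one VPop."""

    results: list[StatResult] = field(default_factory=list)
    composite: float = 1.0
    objective: float = 0.0

    def included_pvalues(self) -> list[float]:
        return [r.pvalue for r in self.results if r.included]

    def finalize(self) -> "GofReport":
        self.composite, self.objective = composite_gof(self.included_pvalues())
        return self

    def pvalue(self, therapy: str, months: float, statistic: str) -> float:
        for r in self.results:
            if (r.therapy, r.months, r.statistic) == (therapy, float(months), statistic):
                return r.pvalue
        raise KeyError((therapy, months, statistic))

    def accepted(self, threshold: float = 0.05) -> bool:
        """Validity rule: composite goodness-of-fit must exceed the threshold."""
        return self.composite > threshold

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "therapy": r.therapy,
                "months": r.months,
                "statistic": r.statistic,
                "p_value": r.pvalue,
                "included": r.included,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)


def write_gof_report(report: GofReport, path: str | Path) -> None:
    frame = report.to_frame()
    summary = pd.DataFrame(
        [
            {"therapy": "", "months": "", "statistic": "composite",
             "p_value": report.composite, "included": True},
            {"therapy": "", "months": "", "statistic": "objective",
             "p_value": report.objective, "included": True},
        ]
    )
    pd.concat([frame, summary], ignore_index=True).to_csv(path, index=False)
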