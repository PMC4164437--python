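"""Univariate reference tests on the 2x3 case-control genotype table.

These are the standard single-trait association tests the proportional-odds
score test is benchmarked against: the Cochran-Armitage trend test (1 df,
linear trend in case proportion across ordered genotype scores) and
Pearson's chi-square test of independence (2 df). Both are asymptotic, with
no continuity correction.

Tables are oriented rows = (control, case), columns = genotype 0/1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, chi2_contingency

__all__ = ["ContingencyTable2x3", "trend_test", "pearson_chisq", "TestOutcome"]


@dataclass(frozen=True)
class TestOutcome:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ContingencyTable2x3:
    """2x3 genotype table; rows (control, case), columns genotype 0/1/2."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (2, 3):
            raise ValueError(f"expected a 2x3 table, got shape {c.shape}")
        if np.any(c < 0) or c.sum() <= 0:
            raise ValueError("counts must be nonnegative with positive total")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_counts(cls, controls, cases) -> "ContingencyTable2x3":
        return cls(np.array([controls, cases], dtype=float))


def _as_table(table) -> np.ndarray:
    if isinstance(table, ContingencyTable2x3):
        return table.counts
    return ContingencyTable2x3(np.asarray(table)).counts


def trend_test(table, scores=(0.0, 1.0, 2.0)) -> TestOutcome:
    """Cochran-Armitage trend test.

    With column scores s_j, column totals n_j, case totals r_j, R = sum r_j
    and N the grand total, the statistic is

        chi2_1 = [sum_j s_j (r_j - (R/N) n_j)]^2
                 / [ (R/N)(1 - R/N) (sum_j s_j^2 n_j - (sum_j s_j n_j)^2 / N) ].

    Scores must be strictly monotone; the statistic is invariant to affine
    transformations of the scores.
    """
    t = _as_table(table)
    s = np.asarray(scores, dtype=float)
    if s.shape != (3,) or not (np.all(np.diff(s) > 0) or np.all(np.diff(s) < 0)):
        raise ValueError("scores must be three strictly monotone values")
    controls, cases = t[0], t[1]
    if cases.sum() <= 0 or controls.sum() <= 0:
        raise ValueError("both case and control rows must have positive totals")
    n_col = t.sum(axis=0)
    N = n_col.sum()
    rbar = cases.sum() / N
    num = float(s @ (cases - rbar * n_col)) ** 2
    var = rbar * (1 - rbar) * (float(s ** 2 @ n_col) - float(s @ n_col) ** 2 / N)
    if var <= 0:
        raise ValueError("zero trend variance (all mass in one genotype column)")
    stat = num / var
    return TestOutcome(statistic=stat, df=1, p_value=float(chi2.sf(stat, 1)))


def pearson_chisq(table) -> TestOutcome:
    """Pearson's chi-square test of the 2x3 table (no continuity correction).

    Genotype columns with zero margin are dropped and the degrees of freedom
    reduced accordingly, so monomorphic-in-sample tables still yield a test.
    """
    t = _as_table(table)
    keep = t.sum(axis=0) > 0
    t = t[:, keep]
    if t.shape[1] < 2:
        raise ValueError("fewer than two genotype columns with observations")
    if np.any(t.sum(axis=1) <= 0):
        raise ValueError("both case and control rows must have positive totals")
    res = chi2_contingency(t, correction=False)
    return TestOutcome(statistic=float(res.statistic), df=int(res.dof),
                       p_value=float(res.pvalue))
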