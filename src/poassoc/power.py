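"""Analytic power machinery for case-control designs.

A Mendelian disease model is parameterised by the risk-allele frequency p
(HWE genotype frequencies q = ((1-p)^2, 2p(1-p), p^2)), the population
prevalence K, and genotype relative risks (R0=1, R1, R2). Penetrances
follow as f_j = R_j * f0 with f0 = K / sum_j q_j R_j, and the genotype
distributions in cases and controls are

    g_j(case)    = q_j f_j / K,
    g_j(control) = q_j (1 - f_j) / (1 - K).

For a sample of n subjects with case fraction phi, the score statistic of
the proportional-odds reverse regression (phenotype = case indicator) is
asymptotically noncentral chi-square with 1 df and noncentrality

    lambda = n phi (1 - phi) * Delta^2 / wbar,

where the pooled genotype distribution is p_j = phi g_j(case) +
(1-phi) g_j(control), the score weights c and wbar derive from p_j exactly
as in :mod:`poassoc.ordinal`, and Delta = sum_j (g_j(case) - g_j(control)) c_j.
Power at level alpha is the upper tail of the noncentral chi-square beyond
the central critical value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, ncx2

__all__ = [
    "GeneticModel",
    "CaseControlDesign",
    "GenotypeDistributionPair",
    "PowerResult",
    "MODE_PRESETS",
    "hwe_genotype_freqs",
    "penetrances",
    "case_control_geno_dists",
    "ncp_case_control",
    "power_from_ncp",
    "power_table",
]

# Relative risks (R1, R2) of genotypes 1 and 2 versus genotype 0.
MODE_PRESETS: dict[str, tuple[float, float]] = {
    "recessive": (1.0, 1.5),
    "additive": (1.25, 1.5),
    "dominant": (1.5, 1.5),
}


@dataclass(frozen=True)
class GeneticModel:
    """Single-locus disease model: allele frequency, prevalence, relative risks."""

    p: float
    K: float
    risks: tuple[float, float]
    mode: str = "custom"

    def __post_init__(self):
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"allele frequency p must be in (0,1), got {self.p}")
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"prevalence K must be in (0,1), got {self.K}")
        if len(self.risks) != 2 or any(r <= 0 for r in self.risks):
            raise ValueError("risks must be two positive relative risks (R1, R2)")

    @classmethod
    def preset(cls, mode: str, p: float, K: float) -> "GeneticModel":
        """Model with the standard recessive/additive/dominant risk presets."""
        if mode not in MODE_PRESETS:
            raise ValueError(f"unknown mode {mode!r}; choose from {sorted(MODE_PRESETS)}")
        return cls(p=p, K=K, risks=MODE_PRESETS[mode], mode=mode)


@dataclass(frozen=True)
class CaseControlDesign:
    """Total sample size and case fraction."""

    n: int
    phi: float = 0.5

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be positive")
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must be in (0,1)")

    @property
    def n_cases(self) -> int:
        n_ca = self.n * self.phi
        if abs(n_ca - round(n_ca)) > 1e-9:
            raise ValueError(f"n*phi = {n_ca} is not integral; cannot simulate")
        return int(round(n_ca))

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases


@dataclass(frozen=True)
class GenotypeDistributionPair:
    """Genotype distributions (simplexes over 0/1/2) in cases and controls."""

    g_case: tuple[float, float, float]
    g_control: tuple[float, float, float]


@dataclass(frozen=True)
class PowerResult:
    ncp: float
    alpha: float
    df: int
    power: float


def hwe_genotype_freqs(p: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies ((1-p)^2, 2p(1-p), p^2)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0,1), got {p}")
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])


def penetrances(model: GeneticModel) -> tuple[float, float, float]:
    """Penetrances (f0, f1, f2) implied by prevalence and relative risks."""
    q = hwe_genotype_freqs(model.p)
    R = np.array([1.0, *model.risks])
    f0 = model.K / float(q @ R)
    f = f0 * R
    if f[-1] > 1.0 + 1e-12:
        raise ValueError(
            f"inconsistent model: implied penetrance f2 = {f[-1]:.4g} > 1 "
            f"for K={model.K}, p={model.p}, risks={model.risks}"
        )
    return tuple(float(x) for x in f)


def case_control_geno_dists(model: GeneticModel) -> GenotypeDistributionPair:
    """Genotype distributions in cases (q_j f_j / K) and controls (q_j(1-f_j)/(1-K))."""
    q = hwe_genotype_freqs(model.p)
    f = np.array(penetrances(model))
    g_case = q * f / model.K
    g_control = q * (1.0 - f) / (1.0 - model.K)
    return GenotypeDistributionPair(
        g_case=tuple(float(x) for x in g_case),
        g_control=tuple(float(x) for x in g_control),
    )


def ncp_case_control(model: GeneticModel, design: CaseControlDesign) -> float:
    """Noncentrality of the score statistic under the case-control alternative."""
    dists = case_control_geno_dists(model)
    g_ca = np.array(dists.g_case)
    g_co = np.array(dists.g_control)
    phi = design.phi
    pooled = phi * g_ca + (1 - phi) * g_co
    g1 = pooled[0]
    g2 = pooled[0] + pooled[1]
    c = np.array([1 - g1, 1 - g1 - g2, -g2])
    wbar = float(pooled @ c ** 2)
    if wbar <= 0:
        raise ValueError("degenerate pooled genotype distribution (wbar = 0)")
    delta = float((g_ca - g_co) @ c)
    return design.n * phi * (1 - phi) * delta ** 2 / wbar


def power_from_ncp(ncp: float, alpha: float, df: int = 1) -> float:
    """P(chi2_df(ncp) > central chi2_df critical value at level alpha)."""
    if ncp < 0:
        raise ValueError("noncentrality must be nonnegative")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    crit = chi2.isf(alpha, df)
    if ncp == 0.0:
        return float(alpha)
    return float(ncx2.sf(crit, df, ncp))


def analytic_power(model: GeneticModel, design: CaseControlDesign,
                   alpha: float) -> PowerResult:
    """NCP and analytic power for one model/design (1-df score test)."""
    lam = ncp_case_control(model, design)
    return PowerResult(ncp=lam, alpha=alpha, df=1,
                       power=power_from_ncp(lam, alpha, 1))


def power_table(models, design: CaseControlDesign, alpha: float) -> pd.DataFrame:
    """Tabulate (model, lambda, power) for a list of genetic models."""
    rows = []
    for m in models:
        res = analytic_power(m, design, alpha)
        rows.append({
            "K": m.K, "p": m.p, "mode": m.mode,
            "R1": m.risks[0], "R2": m.risks[1],
            "n": design.n, "phi": design.phi, "alpha": alpha,
            "ncp": res.ncp, "power": res.power,
        })
    return pd.DataFrame(
        rows, columns=["K", "p", "mode", "R1", "R2", "n", "phi", "alpha",
                       "ncp", "power"])
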