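"""Seedable simulators for case-control and multivariate-phenotype designs.

Two generators cover every experiment the package's study harness runs:

* :func:`simulate_case_control` — a Mendelian disease locus. Case genotypes
  are multinomial draws from the case genotype distribution, controls from
  the control distribution (both implied by allele frequency, prevalence and
  genotype relative risks); the phenotype is the binary case indicator.

* :func:`simulate_multiphen` — a random cohort with one quantitative trait
  locus (QTL) and three phenotypes. Genotype G ~ Binomial(2, q) under HWE;
  residuals are trivariate normal with unit variances and a common pairwise
  (equicorrelated) residual correlation rE; each associated phenotype k gets
  b_k * beta * (G - 2q) added, with b1 = b2 = +1 and b3 = ±1 switching the
  direction of the third phenotype's effect. Centring G lets the effect size
  be specified exactly as the fraction of phenotype variance explained:
  beta^2 = ev / ((1 - ev) * 2q(1-q)).

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .power import CaseControlDesign, GeneticModel, case_control_geno_dists

__all__ = ["SimScenario", "SimDataset", "simulate_case_control",
           "simulate_multiphen", "simulate_case_control_tables"]

#: Defaults for the three-phenotype QTL scenarios. The companion design this
#: emulates does not travel with its effect size and sample size, so these
#: are package choices, documented in docs/methods.md: n = 1000 subjects and
#: a QTL explaining 0.5% of each associated phenotype's variance, which puts
#: single-trait power in the moderate range where method differences show.
DEFAULT_MULTIPHEN_N = 1000
DEFAULT_EFFECT_VAR = 0.005


@dataclass(frozen=True)
class SimScenario:
    """One multivariate-phenotype simulation scenario.

    ``associated`` lists which of the three phenotypes carry the QTL effect:
    scenario I = {1}, II = {1, 2}, III = {1, 2, 3}.
    """

    associated: frozenset[int]
    rE: float = 0.0
    b3: int = +1
    maf: float = 0.01
    effect_var: float = DEFAULT_EFFECT_VAR
    n: int = DEFAULT_MULTIPHEN_N

    def __post_init__(self):
        object.__setattr__(self, "associated", frozenset(self.associated))
        if not self.associated <= {1, 2, 3} or not self.associated:
            raise ValueError("associated must be a nonempty subset of {1,2,3}")
        if self.b3 not in (+1, -1):
            raise ValueError("b3 must be +1 or -1")
        if not 0.0 <= self.effect_var < 1.0:
            raise ValueError("effect_var must be in [0, 1)")
        if not 0.0 < self.maf < 1.0:
            raise ValueError("maf must be in (0,1)")
        # equicorrelation is positive definite for rE in (-1/2, 1) at q=3
        if not -0.5 < self.rE < 1.0:
            raise ValueError(f"residual equicorrelation {self.rE} is not "
                             "positive definite for three phenotypes")

    @classmethod
    def numbered(cls, scenario: int, **kw) -> "SimScenario":
        """Scenario by Roman-numeral index: 1 -> {1}, 2 -> {1,2}, 3 -> {1,2,3}."""
        if scenario not in (1, 2, 3):
            raise ValueError("scenario must be 1, 2 or 3")
        return cls(associated=frozenset(range(1, scenario + 1)), **kw)


@dataclass(frozen=True)
class SimDataset:
    """A simulated dataset with its generating provenance."""

    genotype: np.ndarray
    phenotypes: np.ndarray
    labels: np.ndarray | None
    seed: int | None
    provenance: dict = field(default_factory=dict)


def simulate_case_control(model: GeneticModel, design: CaseControlDesign,
                          seed=None) -> SimDataset:
    """Draw a case-control dataset; phenotype is the 0/1 case indicator."""
    rng = np.random.default_rng(seed)
    dists = case_control_geno_dists(model)
    n_ca, n_co = design.n_cases, design.n_controls
    counts_ca = rng.multinomial(n_ca, dists.g_case)
    counts_co = rng.multinomial(n_co, dists.g_control)
    g = np.concatenate([np.repeat([0, 1, 2], counts_co),
                        np.repeat([0, 1, 2], counts_ca)])
    y = np.concatenate([np.zeros(n_co), np.ones(n_ca)])
    return SimDataset(
        genotype=g.astype(float), phenotypes=y[:, None], labels=y.astype(int),
        seed=seed,
        provenance={"model": model, "design": design, "kind": "case_control"},
    )


def simulate_case_control_tables(model: GeneticModel, design: CaseControlDesign,
                                 replicates: int, rng) -> np.ndarray:
    """Stack of (replicates, 2, 3) genotype tables, rows (control, case).

    Same law as expanding :func:`simulate_case_control` replicate by
    replicate; the binary-phenotype tests depend on the data only through
    these six counts, so studies run on tables without loss.
    """
    dists = case_control_geno_dists(model)
    ca = rng.multinomial(design.n_cases, dists.g_case, size=replicates)
    co = rng.multinomial(design.n_controls, dists.g_control, size=replicates)
    return np.stack([co, ca], axis=1).astype(float)


def _qtl_slope(effect_var: float, maf: float) -> float:
    """beta with Var(beta * G_centred) / Var(y) = effect_var, unit residuals."""
    var_g = 2.0 * maf * (1.0 - maf)
    return np.sqrt(effect_var / ((1.0 - effect_var) * var_g))


def simulate_multiphen(scenario: SimScenario, seed=None) -> SimDataset:
    """Cohort with one QTL and three equicorrelated phenotypes."""
    rng = np.random.default_rng(seed)
    n, q3 = scenario.n, 3
    g = rng.binomial(2, scenario.maf, size=n).astype(float)
    R = np.full((q3, q3), scenario.rE)
    np.fill_diagonal(R, 1.0)
    L = np.linalg.cholesky(R)
    e = rng.standard_normal((n, q3)) @ L.T
    beta = _qtl_slope(scenario.effect_var, scenario.maf)
    direction = {1: 1.0, 2: 1.0, 3: float(scenario.b3)}
    y = e.copy()
    gc = g - 2.0 * scenario.maf
    for k in scenario.associated:
        y[:, k - 1] += direction[k] * beta * gc
    return SimDataset(
        genotype=g, phenotypes=y, labels=None, seed=seed,
        provenance={"scenario": scenario, "kind": "multiphen", "beta": beta},
    )
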