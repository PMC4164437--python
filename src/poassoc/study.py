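"""Config-driven regeneration of the package's benchmark studies.

Four studies characterise the proportional-odds score test:

* :func:`reproduce_table1` — the analytic surface: noncentrality and power
  for the twelve case-control disease models (prevalence x allele frequency
  x recessive/additive/dominant risk presets).
* :func:`type1_study` — empirical type-I error of Score, LRT, trend and
  Pearson chi-square under null case-control models.
* :func:`power_study` — empirical power under the alternative models, with
  the analytic score power alongside.
* :func:`multiphen_power_study` — Score vs LRT power on the three-phenotype
  QTL scenarios (scenario I/II/III x residual correlation x effect
  direction x MAF).

Every study is a pure function of (configuration, seed): replicate streams
are spawned from a single ``SeedSequence`` so the output tables are
reproducible cell by cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .comparators import pearson_chisq, trend_test
from .ordinal import (GenotypePOModel, lrt_test_from_table,
                      score_test_from_table)
from .power import (CaseControlDesign, GeneticModel, ncp_case_control,
                    power_from_ncp)
from .simulate import SimScenario, simulate_case_control_tables, simulate_multiphen

__all__ = [
    "TABLE1_CELLS", "NULL_GRID", "MULTIPHEN_GRID",
    "reproduce_table1", "type1_study", "power_study",
    "multiphen_power_study", "write_tsv",
]

#: The populated (K, p, mode) cells of the analytic power surface.
TABLE1_CELLS: list[tuple[float, float, str]] = [
    (0.01, 0.1, "additive"), (0.01, 0.1, "dominant"),
    (0.01, 0.3, "recessive"), (0.01, 0.3, "additive"), (0.01, 0.3, "dominant"),
    (0.01, 0.4, "recessive"),
    (0.1, 0.1, "additive"), (0.1, 0.1, "dominant"),
    (0.1, 0.3, "recessive"), (0.1, 0.3, "additive"), (0.1, 0.3, "dominant"),
    (0.1, 0.4, "recessive"),
]

#: (K, p) grid for the null (type-I error) study.
NULL_GRID: list[tuple[float, float]] = [(0.01, 0.1), (0.01, 0.3),
                                        (0.1, 0.1), (0.1, 0.3)]

#: Scenario grid for the multiphenotype study: scenario I once (the third
#: phenotype carries no effect, so its direction switch is inert), scenarios
#: II and III under both effect directions.
MULTIPHEN_GRID: list[tuple[int, int, float, float]] = [
    (scen, b3, rE, maf)
    for scen in (1, 2, 3)
    for b3 in ((+1,) if scen == 1 else (+1, -1))
    for rE in (0.0, 0.3, 0.7)
    for maf in (0.01, 0.40)
]


def reproduce_table1(alpha: float = 0.005, n: int = 2000,
                     phi: float = 0.5) -> pd.DataFrame:
    """Analytic NCP and power for the twelve preset disease models."""
    design = CaseControlDesign(n=n, phi=phi)
    rows = []
    for K, p, mode in TABLE1_CELLS:
        model = GeneticModel.preset(mode, p=p, K=K)
        lam = ncp_case_control(model, design)
        rows.append({"K": K, "p": p, "mode": mode, "ncp": lam,
                     "power": power_from_ncp(lam, alpha, 1)})
    return pd.DataFrame(rows)


def _table_pvalues(table, tests):
    out = {}
    if "trend" in tests:
        out["trend"] = trend_test(table).p_value
    if "chisq" in tests:
        out["chisq"] = pearson_chisq(table).p_value
    if "score" in tests:
        res = score_test_from_table(table)
        out["score"] = res.p_value if res.status == "ok" else np.nan
    if "lrt" in tests:
        out["lrt"] = lrt_test_from_table(table).p_value
    return out


def _case_control_pvalues(model, design, replicates, rng, tests):
    """Per-replicate p-values, one column per test, for one disease model."""
    tables = simulate_case_control_tables(model, design, replicates, rng)
    rows = [_table_pvalues(t, tests) for t in tables]
    return pd.DataFrame(rows)


def type1_study(replicates: int = 2000, seed: int = 0,
                grid=NULL_GRID, alpha_levels=(0.1, 0.01, 0.005),
                n: int = 2000, phi: float = 0.5,
                tests=("trend", "chisq", "lrt", "score")) -> pd.DataFrame:
    """Empirical rejection rates under null models (all relative risks 1)."""
    design = CaseControlDesign(n=n, phi=phi)
    streams = np.random.SeedSequence(seed).spawn(len(grid))
    rows = []
    for (K, p), ss in zip(grid, streams):
        model = GeneticModel(p=p, K=K, risks=(1.0, 1.0), mode="null")
        pvals = _case_control_pvalues(model, design, replicates,
                                      np.random.default_rng(ss), tests)
        for level in alpha_levels:
            row = {"K": K, "p": p, "level": level, "replicates": replicates}
            for t in tests:
                row[t] = float((pvals[t] < level).mean())
            rows.append(row)
    return pd.DataFrame(rows)


def power_study(replicates: int = 2000, seed: int = 0, alpha: float = 0.005,
                cells=TABLE1_CELLS, n: int = 2000, phi: float = 0.5,
                tests=("trend", "chisq", "lrt", "score")) -> pd.DataFrame:
    """Empirical power under the preset alternatives, with analytic reference."""
    design = CaseControlDesign(n=n, phi=phi)
    streams = np.random.SeedSequence(seed).spawn(len(cells))
    rows = []
    for (K, p, mode), ss in zip(cells, streams):
        model = GeneticModel.preset(mode, p=p, K=K)
        lam = ncp_case_control(model, design)
        pvals = _case_control_pvalues(model, design, replicates,
                                      np.random.default_rng(ss), tests)
        row = {"K": K, "p": p, "mode": mode, "alpha": alpha,
               "replicates": replicates, "ncp": lam,
               "analytic_score_power": power_from_ncp(lam, alpha, 1)}
        for t in tests:
            row[t] = float((pvals[t] < alpha).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def multiphen_power_study(replicates: int = 1000, seed: int = 0,
                          alpha: float = 0.005, grid=MULTIPHEN_GRID,
                          n: int | None = None,
                          effect_var: float | None = None) -> pd.DataFrame:
    """Score vs LRT empirical power over the three-phenotype QTL scenarios."""
    rows = []
    for scen, b3, rE, maf in grid:
        # stream keyed by the parameters that matter: the direction switch
        # b3 is inert unless phenotype 3 carries an effect (scenario III),
        # so inert-b3 cells share a stream and are exactly identical
        b3_eff = b3 if scen == 3 else +1
        ss = np.random.SeedSequence(
            entropy=(seed, scen, b3_eff + 2, int(round(rE * 100)),
                     int(round(maf * 1000))))
        kw = {}
        if n is not None:
            kw["n"] = n
        if effect_var is not None:
            kw["effect_var"] = effect_var
        scenario = SimScenario.numbered(scen, b3=b3, rE=rE, maf=maf, **kw)
        rng = np.random.default_rng(ss)
        rej_score = rej_lrt = 0
        used = 0
        for _ in range(replicates):
            data = simulate_multiphen(scenario, rng)
            model = GenotypePOModel(data.genotype, data.phenotypes)
            sc = model.score_test()
            if sc.status != "ok":
                continue  # monomorphic draw (possible at maf=0.01)
            used += 1
            rej_score += sc.p_value < alpha
            rej_lrt += model.lrt().p_value < alpha
        rows.append({"scenario": scen, "b3": b3, "rE": rE, "maf": maf,
                     "n": scenario.n, "effect_var": scenario.effect_var,
                     "alpha": alpha, "replicates_used": used,
                     "score": rej_score / used, "lrt": rej_lrt / used})
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path, seed=None, config=None) -> None:
    """Write a study table as TSV with a provenance comment header."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if config:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in config.items()) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
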