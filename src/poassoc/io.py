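"""Reading genotype/phenotype files and streaming a genome scan.

Supported inputs:

* VCF (plain or bgzipped, via cyvcf2): biallelic diploid sites with a GT
  field; the genotype code is the ALT-allele count (``--count-ref`` in the
  CLI flips it, which leaves the test statistic unchanged). ``./.`` is
  missing; multiallelic and non-diploid sites are skipped with a warning.
* Genotype TSV: a variants x samples integer matrix, first column variant
  IDs, header row of sample IDs; cells are 0/1/2 with ``NA``/blank missing.
* Phenotype TSV: first column sample IDs, remaining columns numeric traits
  (binary traits as 0/1); non-numeric cells become missing.

Samples are aligned by ID intersection, so row order in the phenotype file
never affects results. The scan emits one row per variant and never aborts
on a degenerate marker — a status flag marks it instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .comparators import pearson_chisq, trend_test
from .ordinal import CollinearPhenotypesError, GenotypePOModel

logger = logging.getLogger("poassoc")

__all__ = ["VariantRecord", "read_genotypes", "read_vcf", "read_genotype_tsv",
           "read_phenotypes", "scan", "write_results", "write_genotype_tsv"]


@dataclass
class VariantRecord:
    """One variant's genotype calls across samples (NaN = missing)."""

    id: str
    genotypes: np.ndarray
    chrom: str | None = None
    pos: int | None = None


def read_vcf(path) -> tuple[list[str], Iterator[VariantRecord]]:
    """Sample names and a variant stream from a VCF (ALT-allele counts)."""
    from cyvcf2 import VCF  # deferred: only scan paths need it

    vcf = VCF(str(path))
    samples = list(vcf.samples)

    def _iter():
        for var in vcf:
            if len(var.ALT) != 1:
                logger.warning("skipping multiallelic site %s:%s", var.CHROM, var.POS)
                continue
            calls = np.full(len(samples), np.nan)
            ok = True
            for i, gt in enumerate(var.genotypes):
                alleles = [a for a in gt[:-1] if a is not None]
                if len(alleles) != 2:
                    logger.warning("skipping non-diploid GT at %s:%s",
                                   var.CHROM, var.POS)
                    ok = False
                    break
                if min(alleles) < 0:
                    continue  # ./. stays missing
                calls[i] = sum(1 for a in alleles if a > 0)
            if not ok:
                continue
            vid = var.ID or f"{var.CHROM}:{var.POS}"
            yield VariantRecord(id=vid, genotypes=calls,
                                chrom=var.CHROM, pos=var.POS)

    return samples, _iter()


def read_genotype_tsv(path) -> tuple[list[str], Iterator[VariantRecord]]:
    """Sample names and variant stream from a variants x samples TSV matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ".", ""])
    samples = [str(c) for c in df.columns]
    mat = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    obs = mat[~np.isnan(mat)]
    if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
        raise ValueError(
            f"{path}: genotype matrix must contain only 0/1/2 codes "
            "(fractional dosages are not supported)"
        )

    def _iter():
        for vid, row in zip(df.index.astype(str), mat):
            yield VariantRecord(id=vid, genotypes=row.copy())

    return samples, _iter()


def read_genotypes(path, fmt: str | None = None):
    """Dispatch on format: 'vcf' or 'tsv' (inferred from the suffix)."""
    if fmt is None:
        name = str(path).lower()
        fmt = "vcf" if name.endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "tsv":
        return read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_genotype_tsv(path, sample_names, variants: Iterable[VariantRecord]) -> None:
    """Inverse of :func:`read_genotype_tsv` (NaN written as NA)."""
    rows = {v.id: v.genotypes for v in variants}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=sample_names)
    df = df.astype("Int64")  # keeps 0/1/2 integral, NA for missing
    df.index.name = "variant"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype table indexed by sample ID; non-numeric cells become NaN."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ".", ""])
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][:3].tolist()
        raise ValueError(f"duplicate sample IDs in phenotype file: {dup}")
    if df.shape[1] < 1:
        raise ValueError("phenotype file has no phenotype columns")
    return df.apply(pd.to_numeric, errors="coerce")


def scan(sample_names, variants: Iterable[VariantRecord], phenotypes: pd.DataFrame,
         also=(), pseudo_inverse: bool = False,
         count_ref: bool = False) -> Iterator[dict]:
    """Per-variant association rows for a stream of variants.

    ``also`` may include 'lrt' and, for a single binary phenotype,
    'trend' and 'chisq'.
    """
    common = [s for s in sample_names if s in phenotypes.index]
    if not common:
        raise ValueError("no overlapping sample IDs between genotype and "
                         "phenotype files")
    col_idx = [sample_names.index(s) for s in common]
    Y = phenotypes.loc[common]
    pheno_names = list(Y.columns)
    ymat = Y.to_numpy(dtype=float)
    univariate_binary = (ymat.shape[1] == 1 and
                         np.all(np.isin(ymat[~np.isnan(ymat)], (0.0, 1.0))))

    for var in variants:
        g = var.genotypes[col_idx]
        if count_ref:
            g = 2.0 - g
        row = {"variant": var.id, "chrom": var.chrom, "pos": var.pos}
        try:
            model = GenotypePOModel(g, ymat, phenotype_names=pheno_names)
        except ValueError as exc:
            row.update({"status": "no_data", "reason": str(exc), "n_used": 0})
            yield row
            continue
        row["n_used"] = model.nobs
        row["n_dropped"] = model.n_dropped
        if model.n_dropped:
            logger.info("%s: dropped %d incomplete cases", var.id, model.n_dropped)
        try:
            res = model.score_test(pseudo_inverse=pseudo_inverse)
        except CollinearPhenotypesError as exc:
            row.update({"status": "collinear", "reason": str(exc)})
            yield row
            continue
        if res.status != "ok":
            row.update({"status": res.status, "reason": res.reason})
            yield row
            continue
        nf = model.fit_null()
        row.update({
            "status": "ok",
            "p0": nf.proportions[0], "p1": nf.proportions[1],
            "p2": nf.proportions[2],
            "T": res.statistic, "df": res.df, "p_value": res.p_value,
        })
        if "lrt" in also:
            lrt = model.lrt()
            row["lrt_stat"] = lrt.statistic
            row["lrt_p"] = lrt.p_value
        if ("trend" in also or "chisq" in also) and univariate_binary:
            table = _binary_table(model)
            if "trend" in also:
                tr = trend_test(table)
                row["trend_stat"] = tr.statistic
                row["trend_p"] = tr.p_value
            if "chisq" in also:
                cs = pearson_chisq(table)
                row["chisq_stat"] = cs.statistic
                row["chisq_p"] = cs.p_value
        yield row


def _binary_table(model: GenotypePOModel) -> np.ndarray:
    """2x3 (control, case) x genotype table from a fitted univariate model."""
    y = model.exog[:, 0].astype(int)
    t = np.zeros((2, 3))
    np.add.at(t, (y, model.endog), model.freq_weights)
    return t


def write_results(rows: Iterable[dict], path, bonferroni: bool = False) -> None:
    """Write scan rows as a stable-ordered TSV; optional Bonferroni column."""
    df = pd.DataFrame(list(rows))
    if bonferroni and "p_value" in df:
        m = int(df["p_value"].notna().sum())
        df["p_bonferroni"] = (df["p_value"] * m).clip(upper=1.0)
    lead = [c for c in ("variant", "chrom", "pos", "status", "n_used",
                        "p0", "p1", "p2", "T", "df", "p_value") if c in df.columns]
    rest = [c for c in df.columns if c not in lead]
    df[lead + rest].to_csv(path, sep="\t", index=False, float_format="%.6g")
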