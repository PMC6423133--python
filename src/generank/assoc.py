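"""Per-SNP additive linear regression with covariates.

Each SNP is tested by ordinary least squares of the phenotype on its 0/1/2
dosage plus the configured covariates (sex, age, 10 PCs, optionally the other
rumination subscale).  Betas are per-allele (no dosage standardization) so
their sign is directly comparable across cohorts.  Two paths are provided:
:func:`run_gwas` (per-SNP full OLS) and :func:`residualized_fast_gwas`, the
Frisch-Waugh-Lovell equivalent that residualizes the phenotype and all dosage
columns against the covariates once and is cheap enough to sit inside a
permutation loop.  The module also computes the genomic inflation factor and
Bonferroni thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import RunConfig
from .synth import PHENOTYPES, GenotypeMatrix

logger = logging.getLogger("generank")

__all__ = [
    "AssocTable",
    "run_gwas",
    "residualized_fast_gwas",
    "genomic_lambda",
    "bonferroni_threshold",
    "SUGGESTIVE_THRESHOLD",
]

#: Threshold for suggestive significance at the SNP level.
SUGGESTIVE_THRESHOLD = 1e-5

#: Median of the 1-df chi-square distribution.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))

_MONO_VAR = 1e-12


@dataclass
class AssocTable:
    """Per-SNP regression results aligned to the SNP map order."""

    table: pd.DataFrame  # snp_id, chrom, pos, beta, se, t, p, n_used, tested
    phenotype_name: str
    covariate_names: list[str] = field(default_factory=list)
    lambda_gc: float = float("nan")

    def tested_p(self) -> pd.Series:
        return self.table.loc[self.table["tested"], "p"]

    def header_lines(self) -> list[str]:
        return [
            f"phenotype: {self.phenotype_name}",
            f"covariates: {','.join(self.covariate_names)}",
            f"lambda_gc: {self.lambda_gc:.6g}",
        ]


def _covariate_names(ph: pd.DataFrame, cfg: RunConfig) -> list[str]:
    names = list(cfg.covariate_names)
    if cfg.include_other_subscale:
        if cfg.phenotype_name == "brooding":
            names.append("reflection")
        elif cfg.phenotype_name == "reflection":
            names.append("brooding")
        elif cfg.phenotype_name in PHENOTYPES:
            raise ValueError("include_other_subscale applies only to brooding/reflection")
    missing = [c for c in names + [cfg.phenotype_name] if c not in ph.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    return names


def _aligned_design(g: GenotypeMatrix, ph: pd.DataFrame, cfg: RunConfig):
    """Align phenotype rows to genotype order, drop incomplete rows."""
    names = _covariate_names(ph, cfg)
    ph_idx = ph.set_index("individual_id")
    if not set(g.individual_ids).issubset(ph_idx.index):
        raise ValueError("phenotype table is missing genotyped individuals")
    ph_al = ph_idx.loc[g.individual_ids]
    cols = [cfg.phenotype_name] + names
    keep = ~ph_al[cols].isna().any(axis=1).to_numpy()
    y = ph_al[cfg.phenotype_name].to_numpy(dtype=float)[keep]
    c = np.column_stack(
        [np.ones(keep.sum())] + [ph_al[c].to_numpy(dtype=float)[keep] for c in names]
    )
    dosages = g.dosages[keep].astype(float)
    n, k = len(y), len(names)
    if n <= k + 2:
        raise ValueError(f"n={n} too small for {k} covariates plus dosage")
    if np.linalg.matrix_rank(c) < c.shape[1]:
        logger.warning("collinear covariate design; using least-squares pseudo-inverse")
    if keep.sum() < len(keep):
        logger.info("listwise deletion dropped %d individuals", len(keep) - keep.sum())
    return y, c, dosages, names


def _finalize(g, beta, se, t, p, tested, n_used, cfg, names) -> AssocTable:
    table = pd.DataFrame(
        {
            "snp_id": g.snp_map["snp_id"],
            "chrom": g.snp_map["chrom"],
            "pos": g.snp_map["pos"],
            "beta": beta,
            "se": se,
            "t": t,
            "p": p,
            "n_used": n_used,
            "tested": tested,
        }
    )
    lam = genomic_lambda(p[tested]) if tested.any() else float("nan")
    n_mono = int((~tested).sum())
    if n_mono:
        logger.info("flagged %d monomorphic SNPs as untested", n_mono)
    return AssocTable(
        table=table, phenotype_name=cfg.phenotype_name, covariate_names=names, lambda_gc=lam
    )


def run_gwas(g: GenotypeMatrix, ph: pd.DataFrame, cfg: RunConfig) -> AssocTable:
    """Full per-SNP OLS: phenotype ~ dosage + covariates.

    Two-sided p from the t distribution with n - k - 2 df (k covariates,
    plus intercept and dosage).  Monomorphic SNPs (dosage variance < 1e-12)
    are flagged untested with NaN statistics, not dropped.
    """
    y, c, dosages, names = _aligned_design(g, ph, cfg)
    n, m = dosages.shape
    df = n - len(names) - 2
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tval = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    tested = dosages.var(axis=0) > _MONO_VAR
    for j in np.flatnonzero(tested):
        x = np.column_stack([c, dosages[:, j]])
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        s2 = resid @ resid / df
        xtx_inv = np.linalg.pinv(x.T @ x)
        beta[j] = coef[-1]
        se[j] = np.sqrt(s2 * xtx_inv[-1, -1])
        tval[j] = beta[j] / se[j] if se[j] > 0 else np.inf * np.sign(beta[j])
        pval[j] = _t_two_sided(tval[j], df)
    return _finalize(g, beta, se, tval, pval, tested, np.full(m, n), cfg, names)


def _t_two_sided(t, df):
    """Two-sided p from the t distribution, floored at the smallest positive float."""
    p = 2.0 * special.stdtr(df, -np.abs(t))
    return np.maximum(p, np.finfo(float).tiny)


def residualized_fast_gwas(g: GenotypeMatrix, ph: pd.DataFrame, cfg: RunConfig) -> AssocTable:
    """Fast path: residualize y and dosages against covariates once.

    By Frisch-Waugh-Lovell this matches :func:`run_gwas` t and p within
    numerical tolerance; betas and SEs are identical to the full fit.
    """
    y, c, dosages, names = _aligned_design(g, ph, cfg)
    n = len(y)
    df = n - len(names) - 2
    q, _ = np.linalg.qr(c)
    y_t = y - q @ (q.T @ y)
    g_t = dosages - q @ (q.T @ dosages)
    tested = dosages.var(axis=0) > _MONO_VAR

    gg = np.einsum("ij,ij->j", g_t, g_t)
    gy = g_t.T @ y_t
    yy = y_t @ y_t
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        s2 = (yy - beta * gy) / df
        se = np.sqrt(s2 / gg)
        tval = beta / se
    pval = _t_two_sided(tval, df)
    beta[~tested] = se[~tested] = tval[~tested] = pval[~tested] = np.nan
    return _finalize(g, beta, se, tval, pval, tested, np.full(dosages.shape[1], n), cfg, names)


def write_assoc(assoc: AssocTable, path) -> None:
    """Association TSV with phenotype/covariates/lambda header metadata."""
    from .io import write_table

    write_table(assoc.table, path, header_lines=assoc.header_lines())


def read_assoc(path) -> AssocTable:
    from .io import read_table

    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
    table = read_table(path)
    table["tested"] = table["tested"].astype(bool)
    cov = [c for c in meta.get("covariates", "").split(",") if c]
    return AssocTable(
        table=table,
        phenotype_name=meta.get("phenotype", ""),
        covariate_names=cov,
        lambda_gc=float(meta.get("lambda_gc", "nan")),
    )


def genomic_lambda(pvals) -> float:
    """Genomic inflation factor: median observed 1-df chi-square / 0.4549."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / CHI2_1DF_MEDIAN)


def bonferroni_threshold(m_snps: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / m."""
    if m_snps < 1:
        raise ValueError("m_snps must be >= 1")
    return alpha / m_snps
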