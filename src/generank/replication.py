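"""Cross-cohort sign-test replication of independent lead SNPs.

Following the study design: SNPs are filtered by their combined-sample
association p-value at a threshold (0.05, 1e-3, 1e-5), greedily LD-clumped
(r2 >= 0.5 with a more significant SNP removes a variant), and for the
surviving lead SNPs the sign of the regression beta is compared between the
two cohorts.  The concordance rate is reported with an exact Clopper-Pearson
95% interval and a right-tailed exact binomial sign test against 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .assoc import AssocTable
from .synth import GenotypeMatrix

logger = logging.getLogger("generank")

__all__ = [
    "LDMatrix",
    "ConcordanceResult",
    "ld_matrix",
    "ld_clump",
    "sign_concordance",
    "clopper_pearson",
    "sign_test_right",
    "concordance_table",
]


@dataclass
class LDMatrix:
    """Signed pairwise dosage correlation matrix over a SNP universe."""

    snp_ids: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (len(self.snp_ids),) * 2:
            raise ValueError("r must be square and conformable with snp_ids")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-8:
            raise ValueError("|r| must be <= 1")

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    def index(self, snp_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        return np.array([lookup[s] for s in snp_ids], dtype=int)


@dataclass
class ConcordanceResult:
    """One row of the sign-test replication table."""

    p_threshold: float
    n_lead: int
    k_concordant: int
    rate: float
    ci_low: float
    ci_high: float
    sign_test_p: float


def ld_matrix(g: GenotypeMatrix) -> LDMatrix:
    """Pearson dosage correlation on the (combined) analysis sample.

    Monomorphic SNPs get zero off-diagonal correlation and unit diagonal.
    """
    x = g.dosages.astype(float)
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 0
    x[:, ok] /= sd[ok]
    x[:, ~ok] = 0.0
    r = (x.T @ x) / x.shape[0]
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return LDMatrix(snp_ids=g.snp_map["snp_id"].to_numpy(), r=r)


def ld_clump(assoc: AssocTable, ld: LDMatrix, p_threshold: float, r2_cut: float = 0.5) -> list[str]:
    """Greedy LD clumping: return independent lead SNP ids.

    Among tested SNPs with p strictly below the threshold, repeatedly take
    the most significant as a lead and remove remaining candidates with
    r2 >= r2_cut to it; returned leads are pairwise r2 < r2_cut.
    """
    if ld.r.size == 0:
        raise ValueError("empty LD matrix")
    tab = assoc.table
    cand = tab[(tab["tested"]) & (tab["p"] < p_threshold)]
    idx = ld.index(cand["snp_id"])
    order = np.argsort(cand["p"].to_numpy(), kind="stable")
    r2 = ld.r2
    alive = np.ones(len(cand), dtype=bool)
    leads: list[str] = []
    snp_ids = cand["snp_id"].to_numpy()
    for o in order:
        if not alive[o]:
            continue
        leads.append(snp_ids[o])
        alive &= r2[idx[o], idx] < r2_cut
    return leads


def sign_concordance(leads: list[str], assoc_a: AssocTable, assoc_b: AssocTable) -> tuple[int, int]:
    """Count leads whose beta sign agrees between the two cohorts.

    Leads missing (or untested/zero-beta) in either cohort are excluded with
    a warning, reducing n.
    """
    k = n = 0
    a = assoc_a.table.set_index("snp_id")
    b = assoc_b.table.set_index("snp_id")
    excluded = []
    for snp in leads:
        if snp not in a.index or snp not in b.index:
            excluded.append(snp)
            continue
        ba, bb = a.at[snp, "beta"], b.at[snp, "beta"]
        if not (np.isfinite(ba) and np.isfinite(bb)) or ba == 0 or bb == 0:
            excluded.append(snp)
            continue
        n += 1
        if np.sign(ba) == np.sign(bb):
            k += 1
    if excluded:
        logger.warning("%d lead SNPs excluded from sign comparison: %s", len(excluded), excluded[:5])
    return k, n


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via beta quantiles."""
    if n < 1 or not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n and n >= 1")
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def sign_test_right(k: int, n: int) -> float:
    """Right-tailed exact sign test: P(X >= k) for X ~ Binomial(n, 1/2)."""
    if n < 1 or not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n and n >= 1")
    return float(stats.binom.sf(k - 1, n, 0.5))


def concordance_table(
    assoc_combined: AssocTable,
    ld: LDMatrix,
    assoc_a: AssocTable,
    assoc_b: AssocTable,
    p_thresholds=(0.05, 1e-3, 1e-5),
    r2_cut: float = 0.5,
) -> list[ConcordanceResult]:
    """Full replication analysis: one ConcordanceResult per p threshold."""
    results = []
    for thr in p_thresholds:
        leads = ld_clump(assoc_combined, ld, thr, r2_cut)
        k, n = sign_concordance(leads, assoc_a, assoc_b)
        if n == 0:
            results.append(ConcordanceResult(thr, 0, 0, float("nan"), float("nan"), float("nan"), float("nan")))
            continue
        lo, hi = clopper_pearson(k, n)
        results.append(
            ConcordanceResult(
                p_threshold=thr,
                n_lead=n,
                k_concordant=k,
                rate=k / n,
                ci_low=lo,
                ci_high=hi,
                sign_test_p=sign_test_right(k, n),
            )
        )
    return results
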