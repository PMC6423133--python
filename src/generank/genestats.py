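"""Gene-level aggregation of SNP p-values under LD.

SNPs are mapped to genes (gene bounds extended by a 10 kb flank, inclusive),
and each gene's SNP p-values are combined by eight statistics that account
for the LD correlation between its SNPs:

1. ``minp``       uncorrected minimum p
2. ``sidak``      Sidak-adjusted minimum p, 1 - (1 - min p)^k
3. ``km_fisher``  Fisher's combined statistic for correlated tests with the
                  Kost-McDermott covariance approximation
                  cov(-2 ln p_i, -2 ln p_j) ~ 3.263 r + 0.710 r^2 + 0.027 r^3,
                  referred to a moment-matched scaled chi-square (Brown's
                  method with the KM polynomial)
4. ``stouffer``   fixed-effect z-score sum with variance 1' R 1
5. ``makambi``    weighted Fisher statistic (equal weights by default) with
                  the same covariance polynomial and scaled chi-square
6. ``method6``    decorrelated z-score test: whiten the z vector by R^(-1/2)
                  (a pluggable slot; see ``stat_method6``)
7. ``gates``      extended Simes with effective numbers of tests from the
                  eigenvalues of the p-value correlation matrix (approximated
                  by r^2)
8. ``ecs``        effective chi-squared: sum of 1-df chi-square deviates with
                  LD-adjusted effective degrees of freedom

Every statistic reduces to the single SNP p when a gene holds one SNP, and
``km_fisher``/``gates``/``ecs``/``stouffer`` are invariant to duplicating a
SNP in perfect LD (the KM polynomial sums to exactly 4 at r = 1).

:class:`GeneScorer` precomputes all per-gene LD structure once so the eight
statistics can be re-evaluated cheaply for thousands of permuted p-vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .assoc import AssocTable
from .replication import LDMatrix

logger = logging.getLogger("generank")

__all__ = [
    "GeneSnpMap",
    "map_snps_to_genes",
    "stat_minp",
    "stat_sidak",
    "stat_km_fisher",
    "stat_stouffer_fixed",
    "stat_makambi",
    "stat_method6",
    "stat_gates",
    "stat_ecs",
    "GeneScorer",
    "gene_stat_table",
    "METHODS",
]

METHODS = ("minp", "sidak", "km_fisher", "stouffer", "makambi", "method6", "gates", "ecs")

P_FLOOR = 1e-300
EIG_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# SNP -> gene mapping


@dataclass
class GeneSnpMap:
    """gene_id -> ordered SNP indices; genes with no SNPs kept separately."""

    genes: dict[str, np.ndarray]
    untestable: list[str] = field(default_factory=list)
    flank_bp: int = 10_000


def map_snps_to_genes(snp_map: pd.DataFrame, annotation: pd.DataFrame, flank_bp: int = 10_000) -> GeneSnpMap:
    """Assign SNPs to genes within [start - flank, end + flank], inclusive.

    A SNP may belong to several overlapping genes; genes that catch no SNP
    are recorded as untestable.
    """
    genes: dict[str, np.ndarray] = {}
    untestable: list[str] = []
    by_chrom = {c: grp for c, grp in snp_map.reset_index(drop=True).groupby("chrom", sort=False)}
    for row in annotation.itertuples(index=False):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            untestable.append(row.gene_id)
            continue
        pos = grp["pos"].to_numpy()
        lo = max(1, row.start - flank_bp)
        hi = row.end + flank_bp
        a, b = np.searchsorted(pos, [lo, hi + 1])
        if a == b:
            untestable.append(row.gene_id)
        else:
            genes[row.gene_id] = grp.index.to_numpy()[a:b]
    if untestable:
        logger.info("%d genes have no mapped SNPs (untestable)", len(untestable))
    return GeneSnpMap(genes=genes, untestable=untestable, flank_bp=flank_bp)


# ---------------------------------------------------------------------------
# shared machinery


def _clean_p(p_vector) -> np.ndarray:
    p = np.asarray(p_vector, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector (untestable unit)")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be in [0, 1]")
    return np.clip(p, P_FLOOR, 1.0)


def _check_corr(r, k: int) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (k, k):
        raise ValueError("correlation matrix not conformable with p-vector")
    if np.any(np.abs(r) > 1 + 1e-8):
        raise ValueError("|r| must be <= 1")
    return np.clip(r, -1.0, 1.0)


def km_covariance(r):
    """Kost-McDermott approximation to cov(-2 ln p_i, -2 ln p_j)."""
    r = np.asarray(r, dtype=float)
    return 3.263 * r + 0.710 * r**2 + 0.027 * r**3


def _km_pair_sum(r: np.ndarray, weights: np.ndarray | None = None) -> float:
    """sum over i<j of w_i w_j c(r_ij) (unit weights by default)."""
    c = km_covariance(r)
    if weights is not None:
        c = c * np.outer(weights, weights)
    iu = np.triu_indices(r.shape[0], k=1)
    return float(c[iu].sum())


def _scaled_chi2_sf(t, e, var):
    """Upper tail of the moment-matched scaled chi-square (Brown's method)."""
    t, e, var = np.asarray(t, float), np.asarray(e, float), np.asarray(var, float)
    if np.any(var <= 0):
        raise ValueError("non-positive variance in scaled chi-square match")
    scale = var / (2.0 * e)
    df = 2.0 * e**2 / var
    return np.maximum(special.chdtrc(df, t / scale), P_FLOOR)


def effective_tests(eigvals, m) -> float:
    """Effective number of tests: m - sum(lambda - 1 over lambda > 1)."""
    lam = np.asarray(eigvals, dtype=float)
    me = m - float(lam[lam > 1].sum() - (lam > 1).sum())
    return float(np.clip(me, 1.0, m))


def _me_prefix(r2: np.ndarray, order: np.ndarray, j: int) -> float:
    """Effective tests among the first j SNPs of ``order``."""
    if j == 1:
        return 1.0
    if j == 2:
        # eigenvalues of [[1, a], [a, 1]] are 1 +/- a with a = r^2 >= 0
        a = r2[order[0], order[1]]
        return float(np.clip(2.0 - a, 1.0, 2.0))
    sub = r2[np.ix_(order[:j], order[:j])]
    return effective_tests(np.linalg.eigvalsh(sub), j)


def _gates(p_sorted: np.ndarray, r2: np.ndarray, order: np.ndarray) -> float:
    m = len(p_sorted)
    me_full = _me_prefix(r2, order, m)
    best = np.inf
    for j in range(1, m + 1):
        best = min(best, me_full * p_sorted[j - 1] / _me_prefix(r2, order, j))
    return float(np.clip(best, P_FLOOR, 1.0))


def _gates_kernel_py(p_all, concat, starts, ks, r2_flat, r2_off, out):
    """GATES for every unit; reference implementation of the jitted kernel."""
    for u in range(len(ks)):
        k = ks[u]
        idx = concat[starts[u] : starts[u] + k]
        p_sub = p_all[idx]
        r2 = r2_flat[r2_off[u] : r2_off[u] + k * k].reshape(k, k)
        order = np.argsort(p_sub, kind="stable")
        out[u] = _gates(p_sub[order], r2, order)


try:  # optional speedup: the prefix-eigenvalue scan is the hot loop
    import numba

    @numba.njit(cache=True)
    def _gates_kernel_jit(p_all, concat, starts, ks, r2_flat, r2_off, out):  # pragma: no cover
        for u in range(len(ks)):
            k = ks[u]
            s = starts[u]
            p_sub = np.empty(k)
            for a in range(k):
                p_sub[a] = p_all[concat[s + a]]
            order = np.argsort(p_sub)
            ro = np.empty((k, k))
            base = r2_off[u]
            for a in range(k):
                for b in range(k):
                    ro[a, b] = r2_flat[base + order[a] * k + order[b]]
            # effective tests among the top-j SNPs for every prefix j
            me = np.empty(k)
            me[0] = 1.0
            if k > 1:
                a2 = ro[0, 1]
                me[1] = min(max(2.0 - a2, 1.0), 2.0)
            for j in range(3, k + 1):
                lam = np.linalg.eigvalsh(np.ascontiguousarray(ro[:j, :j]))
                excess = 0.0
                for v in lam:
                    if v > 1.0:
                        excess += v - 1.0
                me[j - 1] = min(max(j - excess, 1.0), float(j))
            me_full = me[k - 1]
            p_sorted = np.sort(p_sub)
            best = 1e300
            for j in range(k):
                cand = me_full * p_sorted[j] / me[j]
                if cand < best:
                    best = cand
            out[u] = min(max(best, P_FLOOR), 1.0)

    _GATES_KERNEL = _gates_kernel_jit
except ImportError:  # pragma: no cover
    _GATES_KERNEL = _gates_kernel_py


# ---------------------------------------------------------------------------
# the eight statistics (scalar surface)


def stat_minp(p_vector) -> float:
    """Uncorrected minimum p within the gene."""
    return float(_clean_p(p_vector).min())


def stat_sidak(p_vector) -> float:
    """Sidak-adjusted minimum: 1 - (1 - min p)^k."""
    p = _clean_p(p_vector)
    return float(-np.expm1(len(p) * np.log1p(-p.min()))) if p.min() < 1 else 1.0


def stat_km_fisher(p_vector, r) -> float:
    """Fisher's method for correlated p-values (Kost-McDermott covariance)."""
    p = _clean_p(p_vector)
    k = len(p)
    r = _check_corr(r, k)
    t = -2.0 * np.log(p).sum()
    e = 2.0 * k
    var = 4.0 * k + 2.0 * _km_pair_sum(r)
    return float(_scaled_chi2_sf(t, e, var))


def stat_stouffer_fixed(p_vector, r) -> float:
    """Fixed-effect z-score statistic: Z = sum(z_i) / sqrt(1' R 1).

    The z-score correlation is taken equal to the genotype correlation r.
    """
    p = _clean_p(p_vector)
    r = _check_corr(r, len(p))
    denom = float(r.sum())
    if denom <= 0:
        raise ValueError("non-positive z-score variance (1'R1 <= 0)")
    z = special.ndtri(1.0 - p)  # upper-tail quantiles
    zsum = float(z.sum()) / np.sqrt(denom)
    return float(max(special.ndtr(-zsum), P_FLOOR))


def stat_makambi(p_vector, r, weights=None) -> float:
    """Makambi's weighted Fisher statistic with scaled chi-square calibration."""
    p = _clean_p(p_vector)
    k = len(p)
    r = _check_corr(r, k)
    if weights is None:
        w = np.full(k, 1.0 / k)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (k,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be non-negative and sum to 1")
    m_stat = float(w @ (-2.0 * np.log(p)))
    e = 2.0
    var = 4.0 * float(w @ w) + 2.0 * _km_pair_sum(r, w)
    return float(_scaled_chi2_sf(m_stat, e, var))


def stat_method6(p_vector, r) -> float:
    """Decorrelated z-score test (pluggable slot).

    Whitens the upper-tail z vector by R^(-1/2) (symmetric eigendecomposition,
    eigenvalues floored at 1e-8), sums the whitened scores and refers
    sum / sqrt(k) to the standard normal.  Reduces to the fixed-effect z-score
    test under independence and collapses duplicated tests.
    """
    p = _clean_p(p_vector)
    k = len(p)
    r = _check_corr(r, k)
    lam, vec = np.linalg.eigh(r)
    if np.any(lam < -1e-6):
        raise ValueError("correlation matrix not positive semi-definite")
    lam = np.maximum(lam, EIG_FLOOR)
    z = special.ndtri(1.0 - p)
    w = vec @ ((vec.T @ z) / np.sqrt(lam))
    zsum = float(w.sum()) / np.sqrt(k)
    return float(max(special.ndtr(-zsum), P_FLOOR))


def stat_gates(p_vector, r) -> float:
    """GATES: extended Simes with effective numbers of tests.

    The p-value correlation matrix is approximated by r^2 of the dosage
    correlation; m_e = m - sum(lambda - 1 over lambda > 1).
    """
    p = _clean_p(p_vector)
    r = _check_corr(r, len(p))
    order = np.argsort(p, kind="stable")
    return _gates(p[order], r**2, order)


def stat_ecs(p_vector, r) -> float:
    """Effective chi-squared: LD-rescaled sum of 1-df chi-square deviates."""
    p = _clean_p(p_vector)
    m = len(p)
    r = _check_corr(r, m)
    q = stats.chi2.isf(p, df=1)
    me = effective_tests(np.linalg.eigvalsh(r**2), m)
    t_e = q.sum() * me / m
    return float(max(special.chdtrc(me, t_e), P_FLOOR))


_SCALAR_STATS = {
    "minp": lambda p, r: stat_minp(p),
    "sidak": lambda p, r: stat_sidak(p),
    "km_fisher": stat_km_fisher,
    "stouffer": stat_stouffer_fixed,
    "makambi": stat_makambi,
    "method6": stat_method6,
    "gates": stat_gates,
    "ecs": stat_ecs,
}


# ---------------------------------------------------------------------------
# vectorized scorer for permutation loops


class GeneScorer:
    """Evaluate the eight statistics for many units over repeated p-vectors.

    All LD-dependent quantities (KM variance constants, Stouffer denominators,
    whitening row-sums, effective test numbers) are precomputed per unit;
    per evaluation only segment reductions and the GATES prefix scan remain.

    ``methods`` selects which statistics to compute (gene sets use the first
    six only).
    """

    def __init__(
        self,
        ld: LDMatrix | np.ndarray,
        unit_indices: dict[str, np.ndarray],
        methods: tuple[str, ...] = METHODS,
    ) -> None:
        r_full = ld.r if isinstance(ld, LDMatrix) else np.asarray(ld, dtype=float)
        self.methods = tuple(methods)
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        self.unit_ids = list(unit_indices)
        if not self.unit_ids:
            raise ValueError("no testable units")
        self._idx_list = [np.asarray(unit_indices[u], dtype=int) for u in self.unit_ids]
        if any(len(i) == 0 for i in self._idx_list):
            raise ValueError("units must have at least one SNP")
        self.k = np.array([len(i) for i in self._idx_list])
        self._concat = np.concatenate(self._idx_list)
        self._starts = np.concatenate([[0], np.cumsum(self.k)[:-1]])

        need_r = set(self.methods) - {"minp", "sidak"}
        self._r_sub = [r_full[np.ix_(i, i)] for i in self._idx_list] if need_r else None

        if "km_fisher" in self.methods:
            self._km_e = 2.0 * self.k
            self._km_var = np.array(
                [4.0 * k + 2.0 * _km_pair_sum(r) for k, r in zip(self.k, self._r_sub)]
            )
        if "makambi" in self.methods:
            self._mak_var = np.array(
                [4.0 / k + 2.0 * _km_pair_sum(r, np.full(k, 1.0 / k)) for k, r in zip(self.k, self._r_sub)]
            )
        if "stouffer" in self.methods:
            denom = np.array([r.sum() for r in self._r_sub])
            if np.any(denom <= 0):
                raise ValueError("non-positive z-score variance (1'R1 <= 0)")
            self._stouffer_denom = np.sqrt(denom)
        if "method6" in self.methods:
            rows = []
            for r in self._r_sub:
                lam, vec = np.linalg.eigh(r)
                lam = np.maximum(lam, EIG_FLOOR)
                # row-sum vector a with a' z = 1' R^(-1/2) z
                rows.append(vec @ (vec.sum(axis=0) / np.sqrt(lam)))
            self._m6_a = np.concatenate(rows)
        if "gates" in self.methods or "ecs" in self.methods:
            self._r2_sub = [r**2 for r in self._r_sub]
            self._me = np.array(
                [effective_tests(np.linalg.eigvalsh(r2), k) for k, r2 in zip(self.k, self._r2_sub)]
            )
        if "gates" in self.methods:
            self._r2_flat = np.concatenate([r2.ravel() for r2 in self._r2_sub])
            self._r2_off = np.concatenate([[0], np.cumsum(self.k**2)[:-1]]).astype(np.int64)

    def _segment_sum(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self._starts)

    def scores(self, p_all: np.ndarray) -> dict[str, np.ndarray]:
        """Eight (or selected) p-value arrays, one entry per unit.

        ``p_all`` is the full per-SNP p vector the unit indices point into.
        """
        p = np.clip(np.asarray(p_all, dtype=float), P_FLOOR, 1.0)
        pc = p[self._concat]
        out: dict[str, np.ndarray] = {}
        minp = np.minimum.reduceat(pc, self._starts)
        if "minp" in self.methods:
            out["minp"] = minp
        if "sidak" in self.methods:
            out["sidak"] = -np.expm1(self.k * np.log1p(-np.minimum(minp, 1 - 1e-16)))
        neg2ln = None
        if "km_fisher" in self.methods or "makambi" in self.methods:
            neg2ln = self._segment_sum(-2.0 * np.log(pc))
        if "km_fisher" in self.methods:
            out["km_fisher"] = _scaled_chi2_sf(neg2ln, self._km_e, self._km_var)
        if "makambi" in self.methods:
            out["makambi"] = _scaled_chi2_sf(neg2ln / self.k, 2.0, self._mak_var)
        z = None
        if "stouffer" in self.methods or "method6" in self.methods:
            z = special.ndtri(1.0 - pc)
        if "stouffer" in self.methods:
            zs = self._segment_sum(z) / self._stouffer_denom
            out["stouffer"] = np.maximum(special.ndtr(-zs), P_FLOOR)
        if "method6" in self.methods:
            zw = self._segment_sum(self._m6_a * z) / np.sqrt(self.k)
            out["method6"] = np.maximum(special.ndtr(-zw), P_FLOOR)
        if "ecs" in self.methods:
            q = self._segment_sum(special.chdtri(np.ones_like(pc), pc))
            out["ecs"] = np.maximum(special.chdtrc(self._me, q * self._me / self.k), P_FLOOR)
        if "gates" in self.methods:
            gates = np.empty(len(self.unit_ids))
            _GATES_KERNEL(
                p, self._concat, self._starts.astype(np.int64),
                self.k.astype(np.int64), self._r2_flat, self._r2_off, gates,
            )
            out["gates"] = gates
        return out

    def score_matrix(self, p_all: np.ndarray) -> np.ndarray:
        """Units x methods matrix in the order of ``self.methods``."""
        s = self.scores(p_all)
        return np.column_stack([s[m] for m in self.methods])


def gene_stat_table(assoc: AssocTable, gene_snp_map: GeneSnpMap, ld: LDMatrix) -> pd.DataFrame:
    """One row per testable gene with the eight aggregation p-values.

    Only tested (polymorphic) SNPs enter; genes left with no tested SNP are
    excluded with a logged count.
    """
    tab = assoc.table
    tested = tab["tested"].to_numpy()
    p_all = tab["p"].to_numpy(dtype=float).copy()
    p_all[~tested] = 1.0  # placeholder, never selected below
    usable: dict[str, np.ndarray] = {}
    dropped = 0
    for gene, idx in gene_snp_map.genes.items():
        keep = idx[tested[idx]]
        if len(keep):
            usable[gene] = keep
        else:
            dropped += 1
    if dropped:
        logger.info("%d genes excluded: no tested SNPs", dropped)
    scorer = GeneScorer(ld, usable)
    scores = scorer.scores(p_all)
    table = pd.DataFrame({"gene_id": scorer.unit_ids, "n_snps": scorer.k})
    for m in METHODS:
        table[f"p_{m}"] = scores[m]
    return table
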