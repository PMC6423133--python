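"""Rank-averaging permutation omnibus over the eight aggregation methods.

For each unit (gene or gene set) the eight method p-values are converted to
within-method ranks (smallest p = rank 1, midranks for ties) and averaged.
The null distribution of the average rank is built by re-running the whole
chain -- fast residualized GWAS, gene statistics, set statistics -- on
phenotypes permuted under the Freedman-Lane scheme (covariate-residualized
phenotype permuted, covariate fit preserved).  The empirical p-value uses the
add-one estimator, (1 + #{avg_rank_perm <= avg_rank_obs}) / (B + 1), and
Benjamini-Hochberg q-values are computed separately per category (genes; each
gene-set collection); units with q below the configured threshold (0.1) are
flagged significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .assoc import _aligned_design, _t_two_sided, genomic_lambda
from .genestats import METHODS, GeneScorer, GeneSnpMap, map_snps_to_genes, P_FLOOR, _km_pair_sum, _scaled_chi2_sf
from .io import RunConfig
from .replication import LDMatrix, ld_matrix
from .setstats import SET_SNP_METHODS, gene_cross_ld, pool_set_snps, HYST_R_CUT
from .synth import GenotypeMatrix, _substream

logger = logging.getLogger("generank")

__all__ = [
    "OmnibusTables",
    "rank_average",
    "bh_fdr",
    "call_significant",
    "permutation_omnibus",
]

SET_METHODS = SET_SNP_METHODS + ("wilcoxon", "hyst")


def rank_average(p_matrix: np.ndarray) -> np.ndarray:
    """Average within-method rank per unit (rows: units, columns: methods)."""
    p = np.asarray(p_matrix, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ValueError("need a units x methods matrix with at least 2 units")
    return stats.rankdata(p, axis=0).mean(axis=1)


def bh_fdr(p_vector) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone from the largest p)."""
    p = np.asarray(p_vector, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_significant(table: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Flag rows with q strictly below the threshold."""
    out = table.copy()
    out["significant"] = out["q_value"] < threshold
    return out


# ---------------------------------------------------------------------------
# permutation engine


def _fast_ranksum_p(ranks: np.ndarray, tie_term: float, in_idx: np.ndarray) -> float:
    """One-sided (in-set smaller) rank-sum p via the tie/continuity-corrected
    normal approximation, computed from precomputed midranks."""
    n = ranks.size
    n_in = in_idx.size
    n_out = n - n_in
    w = ranks[in_idx].sum()
    mean = n_in * (n + 1) / 2.0
    var = n_in * n_out * (n + 1) / 12.0 - n_in * n_out * tie_term / (12.0 * n * (n - 1))
    if var <= 0:
        return 0.5
    z = (w - mean + 0.5) / np.sqrt(var)
    return float(max(special.ndtr(z), P_FLOOR))


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float((counts**3 - counts).sum())


class _SetEval:
    """Per-collection precomputation for set-level statistics."""

    def __init__(self, name, collection, gene_snp_map, ld, tested, gene_ids):
        self.name = name
        gene_pos = {gene: i for i, gene in enumerate(gene_ids)}
        pooled_idx: dict[str, np.ndarray] = {}
        self.members: dict[str, list[str]] = {}
        self.member_pos: dict[str, np.ndarray] = {}
        self.cross: dict[str, np.ndarray] = {}
        self.n_genes: dict[str, int] = {}
        for set_name, genes in collection.items():
            pooled = pool_set_snps(genes, gene_snp_map)
            pooled = pooled[tested[pooled]]
            members = [gene for gene in genes if gene in gene_pos]
            if pooled.size == 0 or not members or len(members) >= len(gene_ids):
                logger.info("collection %r: set %r untestable, skipped", name, set_name)
                continue
            pooled_idx[set_name] = pooled
            self.members[set_name] = members
            self.member_pos[set_name] = np.array([gene_pos[gene] for gene in members])
            self.cross[set_name] = gene_cross_ld(gene_snp_map, ld, members).to_numpy()
            self.n_genes[set_name] = len(members)
        if not pooled_idx:
            raise ValueError(f"collection {name!r} has no testable sets")
        self.scorer = GeneScorer(ld, pooled_idx, methods=SET_SNP_METHODS)
        self.set_names = self.scorer.unit_ids

    def score_matrix(self, p_all: np.ndarray, gene_gates: np.ndarray) -> np.ndarray:
        """Sets x 8 matrix: six pooled-SNP methods + wilcoxon + hyst."""
        snp_part = self.scorer.score_matrix(p_all)
        ranks = stats.rankdata(gene_gates)
        tie = _tie_term(gene_gates)
        wil = np.empty(len(self.set_names))
        hy = np.empty(len(self.set_names))
        for i, set_name in enumerate(self.set_names):
            pos = self.member_pos[set_name]
            wil[i] = _fast_ranksum_p(ranks, tie, pos)
            hy[i] = self._hyst(gene_gates[pos], self.cross[set_name])
        return np.column_stack([snp_part, wil, hy])

    @staticmethod
    def _hyst(gates_p: np.ndarray, cross: np.ndarray) -> float:
        order = np.argsort(gates_p, kind="stable")
        retained: list[int] = []
        for o in order:
            if all(cross[o, r] < HYST_R_CUT for r in retained):
                retained.append(o)
        p = np.clip(gates_p[retained], P_FLOOR, 1.0)
        k = len(retained)
        t = -2.0 * np.log(p).sum()
        var = 4.0 * k + 2.0 * _km_pair_sum(cross[np.ix_(retained, retained)])
        return float(_scaled_chi2_sf(t, 2.0 * k, var))


@dataclass
class OmnibusTables:
    """Observed method p-values plus omnibus empirical p and q per unit."""

    genes: pd.DataFrame
    sets: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_permutations: int = 0
    lambda_gc: float = float("nan")


def permutation_omnibus(
    g: GenotypeMatrix,
    ph: pd.DataFrame,
    cfg: RunConfig,
    annotation: pd.DataFrame,
    collections: dict[str, dict[str, list[str]]] | None = None,
    ld: LDMatrix | None = None,
    gene_snp_map: GeneSnpMap | None = None,
) -> OmnibusTables:
    """Run the full observed + permutation chain and assemble omnibus tables.

    ``collections`` maps collection name -> {set name -> gene ids}; sets are
    expected to be size-filtered already.  The same seeded permutation
    sequence drives every unit; B = ``cfg.n_permutations``.
    """
    if cfg.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y, c, dosages, _names = _aligned_design(g, ph, cfg)
    n, m = dosages.shape
    df = n - (c.shape[1] - 1) - 2

    q_mat, _ = np.linalg.qr(c)
    y_resid = y - q_mat @ (q_mat.T @ y)
    g_resid = dosages - q_mat @ (q_mat.T @ dosages)
    tested = dosages.var(axis=0) > 1e-12
    gg = np.einsum("ij,ij->j", g_resid, g_resid)

    def snp_p(y_t: np.ndarray) -> np.ndarray:
        """Per-SNP two-sided p for a residualized phenotype vector."""
        dots = g_resid.T @ y_t
        yy = y_t @ y_t
        p = np.ones(m)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = gg[tested] * yy - dots[tested] ** 2
            t = dots[tested] * np.sqrt(df) / np.sqrt(np.maximum(denom, 0))
            t[~np.isfinite(t)] = 0.0
        p[tested] = _t_two_sided(t, df)
        return p

    if ld is None:
        ld = ld_matrix(g)
    if gene_snp_map is None:
        gene_snp_map = map_snps_to_genes(g.snp_map, annotation, cfg.flank_bp)
    usable = {
        gene: idx[tested[idx]]
        for gene, idx in gene_snp_map.genes.items()
        if tested[idx].any()
    }
    gene_scorer = GeneScorer(ld, usable, methods=METHODS)
    gene_ids = gene_scorer.unit_ids
    gates_col = METHODS.index("gates")

    set_evals = []
    for name, coll in (collections or {}).items():
        if not coll:
            logger.warning("collection %r is empty (after filtering?), skipped", name)
            continue
        set_evals.append(_SetEval(name, coll, gene_snp_map, ld, tested, gene_ids))

    p_obs = snp_p(y_resid)
    lam = genomic_lambda(p_obs[tested])
    gene_obs = gene_scorer.score_matrix(p_obs)
    gene_rank_obs = rank_average(gene_obs)
    set_obs = [se.score_matrix(p_obs, gene_obs[:, gates_col]) for se in set_evals]
    set_rank_obs = [rank_average(s) for s in set_obs]

    rng = _substream(cfg.seed, "permutations")
    b_total = cfg.n_permutations
    gene_counts = np.zeros(len(gene_ids), dtype=int)
    set_counts = [np.zeros(len(se.set_names), dtype=int) for se in set_evals]
    logger.info(
        "omnibus: %d genes, %d collections, B=%d, seed=%d",
        len(gene_ids), len(set_evals), b_total, cfg.seed,
    )
    for _b in range(b_total):
        perm = rng.permutation(n)
        y_b = y_resid[perm]
        y_b = y_b - q_mat @ (q_mat.T @ y_b)  # Freedman-Lane re-residualization
        p_b = snp_p(y_b)
        gene_b = gene_scorer.score_matrix(p_b)
        gene_counts += rank_average(gene_b) <= gene_rank_obs
        for s, se in enumerate(set_evals):
            set_b = se.score_matrix(p_b, gene_b[:, gates_col])
            set_counts[s] += rank_average(set_b) <= set_rank_obs[s]

    def assemble(ids, n_snps, obs, ranks, counts, methods, id_col) -> pd.DataFrame:
        emp = (1.0 + counts) / (b_total + 1.0)
        table = pd.DataFrame({id_col: ids, "n_snps": n_snps})
        for j, meth in enumerate(methods):
            table[f"p_{meth}"] = obs[:, j]
        table["avg_rank"] = ranks
        table["empirical_p"] = emp
        table["q_value"] = bh_fdr(emp)
        return call_significant(table, cfg.fdr_threshold)

    genes_out = assemble(
        gene_ids, gene_scorer.k, gene_obs, gene_rank_obs, gene_counts, METHODS, "gene_id"
    )
    sets_out = {
        se.name: assemble(
            se.set_names, se.scorer.k, set_obs[s], set_rank_obs[s], set_counts[s],
            SET_METHODS, "set_name",
        )
        for s, se in enumerate(set_evals)
    }
    return OmnibusTables(genes=genes_out, sets=sets_out, n_permutations=b_total, lambda_gc=lam)
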