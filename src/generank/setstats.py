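"""Gene-set level statistics.

Sets are size-filtered after intersection with the annotation (15-300 genes
by default).  Each surviving set gets eight p-values: the six SNP-aggregation
methods applied to the deduplicated union of its member genes' SNPs, a
one-sided Wilcoxon rank-sum test that in-set genes have smaller gene-level
GATES p-values than the remaining testable genes, and HYST, which combines
the GATES p-values of a greedily pruned quasi-independent subset of member
genes by the scaled chi-square machinery.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .assoc import AssocTable
from .genestats import (
    GeneScorer,
    GeneSnpMap,
    _km_pair_sum,
    _scaled_chi2_sf,
    P_FLOOR,
)
from .replication import LDMatrix

logger = logging.getLogger("generank")

__all__ = [
    "filter_gene_sets",
    "pool_set_snps",
    "set_snp_stats",
    "wilcoxon_set_test",
    "gene_cross_ld",
    "hyst",
    "set_stat_table",
    "SET_SNP_METHODS",
]

SET_SNP_METHODS = ("minp", "sidak", "km_fisher", "stouffer", "makambi", "method6")
HYST_R_CUT = 0.5


def filter_gene_sets(
    collection: dict[str, list[str]],
    annotation: pd.DataFrame,
    min_size: int = 15,
    max_size: int = 300,
) -> dict[str, list[str]]:
    """Keep sets whose size, after intersection with the annotation, lies in
    [min_size, max_size] (bounds inclusive)."""
    known = set(annotation["gene_id"])
    out: dict[str, list[str]] = {}
    for name, genes in collection.items():
        members = [g for g in genes if g in known]
        if min_size <= len(members) <= max_size:
            out[name] = members
    logger.info("size filter kept %d of %d gene sets", len(out), len(collection))
    return out


def pool_set_snps(genes: list[str], gene_snp_map: GeneSnpMap) -> np.ndarray:
    """Deduplicated, ordered union of member genes' SNP indices."""
    idx = [gene_snp_map.genes[g] for g in genes if g in gene_snp_map.genes]
    if not idx:
        return np.array([], dtype=int)
    return np.unique(np.concatenate(idx))


def set_snp_stats(
    genes: list[str],
    gene_snp_map: GeneSnpMap,
    assoc: AssocTable,
    ld: LDMatrix,
) -> dict[str, float]:
    """The six SNP-aggregation statistics on a set's pooled SNP vector."""
    pooled = pool_set_snps(genes, gene_snp_map)
    tested = assoc.table["tested"].to_numpy()
    pooled = pooled[tested[pooled]]
    if pooled.size == 0:
        raise ValueError("gene set has no tested SNPs (untestable)")
    p_all = assoc.table["p"].to_numpy(dtype=float)
    scorer = GeneScorer(ld, {"set": pooled}, methods=SET_SNP_METHODS)
    return {m: float(v[0]) for m, v in scorer.scores(np.nan_to_num(p_all, nan=1.0)).items()}


def wilcoxon_set_test(in_p, out_p) -> float:
    """One-sided rank-sum test that in-set values are smaller than out-set.

    Exact enumeration when min(n_in, n_out) <= 10 and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(in_p, dtype=float)
    y = np.asarray(out_p, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("need at least one gene inside and outside the set")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return 0.5  # no separation at all
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="less", method=method, use_continuity=True)
    return float(res.pvalue)


def gene_cross_ld(gene_snp_map: GeneSnpMap, ld: LDMatrix, genes: list[str]) -> pd.DataFrame:
    """Max |r| between the SNP sets of each gene pair (diagonal 1)."""
    k = len(genes)
    out = np.eye(k)
    abs_r = np.abs(ld.r)
    idx = [gene_snp_map.genes[g] for g in genes]
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = abs_r[np.ix_(idx[i], idx[j])].max()
    return pd.DataFrame(out, index=genes, columns=genes)


def hyst(
    genes: list[str],
    gene_gates_p: dict[str, float],
    gene_snp_map: GeneSnpMap,
    ld: LDMatrix,
    r_cut: float = HYST_R_CUT,
) -> float:
    """Hybrid set-based test on gene-level GATES p-values.

    Member genes are greedily pruned (best GATES p first) so retained genes
    are quasi-independent (max inter-gene SNP |r| < r_cut); the retained
    GATES p-values are combined by the Kost-McDermott scaled chi-square with
    the inter-gene correlation summarized as that max |r|.
    """
    testable = [g for g in genes if g in gene_gates_p and g in gene_snp_map.genes]
    if not testable:
        raise ValueError("gene set has no testable genes")
    cross = gene_cross_ld(gene_snp_map, ld, testable).to_numpy()
    order = np.argsort([gene_gates_p[g] for g in testable], kind="stable")
    retained: list[int] = []
    for o in order:
        if all(cross[o, r] < r_cut for r in retained):
            retained.append(o)
    p = np.array([gene_gates_p[testable[i]] for i in retained])
    p = np.clip(p, P_FLOOR, 1.0)
    r_genes = cross[np.ix_(retained, retained)]
    k = len(retained)
    t = -2.0 * np.log(p).sum()
    var = 4.0 * k + 2.0 * _km_pair_sum(r_genes)
    return float(_scaled_chi2_sf(t, 2.0 * k, var))


def set_stat_table(
    collection: dict[str, list[str]],
    gene_snp_map: GeneSnpMap,
    assoc: AssocTable,
    ld: LDMatrix,
    gene_table: pd.DataFrame,
) -> pd.DataFrame:
    """One row per testable set: six pooled-SNP p-values, Wilcoxon, HYST.

    ``gene_table`` is the output of :func:`generank.genestats.gene_stat_table`
    (supplies the gene-level GATES p-values).
    """
    gates = dict(zip(gene_table["gene_id"], gene_table["p_gates"]))
    tested = assoc.table["tested"].to_numpy()
    p_all = np.nan_to_num(assoc.table["p"].to_numpy(dtype=float), nan=1.0)

    pooled_idx: dict[str, np.ndarray] = {}
    meta: dict[str, tuple[list[str], int]] = {}
    for name, genes in collection.items():
        pooled = pool_set_snps(genes, gene_snp_map)
        pooled = pooled[tested[pooled]]
        members = [g for g in genes if g in gates]
        if pooled.size == 0 or not members:
            logger.info("set %r untestable (no tested SNPs or genes)", name)
            continue
        pooled_idx[name] = pooled
        meta[name] = (members, len(genes))
    if not pooled_idx:
        return pd.DataFrame(
            columns=["set_name", "n_genes", "n_snps"]
            + [f"p_{m}" for m in SET_SNP_METHODS]
            + ["p_wilcoxon", "p_hyst"]
        )

    scorer = GeneScorer(ld, pooled_idx, methods=SET_SNP_METHODS)
    snp_scores = scorer.scores(p_all)

    all_genes = gene_table["gene_id"].to_numpy()
    all_gates = gene_table["p_gates"].to_numpy()
    rows = []
    for i, name in enumerate(scorer.unit_ids):
        members, n_genes = meta[name]
        in_mask = np.isin(all_genes, members)
        row = {"set_name": name, "n_genes": n_genes, "n_snps": int(scorer.k[i])}
        for m in SET_SNP_METHODS:
            row[f"p_{m}"] = float(snp_scores[m][i])
        row["p_wilcoxon"] = wilcoxon_set_test(all_gates[in_mask], all_gates[~in_mask])
        row["p_hyst"] = hyst(members, gates, gene_snp_map, ld)
        rows.append(row)
    return pd.DataFrame(rows)
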