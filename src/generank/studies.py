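"""Desk-scale reference simulation studies.

These functions define the package's standard calibration and recovery
experiments: a synthetic-null omnibus run (type-I error, empirical-p
uniformity, genomic inflation), planted-causal-gene recovery across seeds,
planted-set Wilcoxon enrichment, and the two-subsample phenotype-correlation
check.  They are used by the test suite and by ``scripts/acceptance.py``;
problem sizes are fixed here so results are comparable across runs.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .assoc import residualized_fast_gwas
from .genestats import gene_stat_table, map_snps_to_genes
from .io import RunConfig
from .omnibus import permutation_omnibus
from .replication import ld_matrix
from .setstats import set_stat_table
from .synth import (
    LDBlockSpec,
    SyntheticTruth,
    make_annotation_and_sets,
    plant_causal_genes,
    plant_causal_set,
    simulate_genotypes,
    simulate_phenotypes,
)

logger = logging.getLogger("generank")

__all__ = [
    "null_calibration_study",
    "gene_recovery_study",
    "set_enrichment_study",
    "subscale_correlation_study",
]


def null_calibration_study(
    seed: int,
    n_individuals: int = 1000,
    n_blocks: int = 500,
    n_genes: int = 200,
    n_permutations: int = 500,
) -> dict:
    """Omnibus under the global null: 5000 SNPs, 200 genes, B permutations.

    Returns lambda_gc, the fraction of genes with empirical p < 0.05, a
    chi-square goodness-of-fit p-value for decile uniformity of the empirical
    p's, and the Monte-Carlo standard deviation of the type-I estimate.
    """
    spec = LDBlockSpec(n_snps_per_block=10, n_blocks=n_blocks, within_block_rho=0.8)
    g = simulate_genotypes(spec, n_individuals, seed=seed)
    annotation, _ = make_annotation_and_sets(
        g, genes_per_chrom=n_genes, set_sizes=[15], seed=seed, gene_span_snps=10
    )
    ph = simulate_phenotypes(g, SyntheticTruth(), seed=seed + 1)
    cfg = RunConfig(n_permutations=n_permutations, seed=seed + 2)
    res = permutation_omnibus(g, ph, cfg, annotation)
    emp = res.genes["empirical_p"].to_numpy()
    counts, _ = np.histogram(emp, bins=np.linspace(0, 1, 11))
    gof = stats.chisquare(counts).pvalue
    return {
        "n_genes": len(emp),
        "m_snps": g.m_snps,
        "lambda_gc": res.lambda_gc,
        "type1_rate_at_0.05": float((emp < 0.05).mean()),
        "type1_mc_sd": float(np.sqrt(0.05 * 0.95 / len(emp))),
        "uniformity_gof_p": float(gof),
    }


def gene_recovery_study(
    seed: int,
    n_seeds: int = 20,
    n_individuals: int = 2000,
    n_blocks: int = 100,
    n_genes: int = 50,
    h2_target: float = 0.03,
    n_permutations: int = 500,
    empirical_p_cut: float = 0.01,
) -> dict:
    """Planted-causal-gene recovery across seeded replicates.

    One causal gene (h2 = 0.03 by default) per replicate; success means its
    omnibus empirical p is at or below ``empirical_p_cut``.
    """
    spec = LDBlockSpec(n_snps_per_block=10, n_blocks=n_blocks, within_block_rho=0.8)
    hits = 0
    for rep in range(n_seeds):
        s = seed + 1000 * (rep + 1)
        g = simulate_genotypes(spec, n_individuals, seed=s)
        annotation, _ = make_annotation_and_sets(
            g, genes_per_chrom=n_genes, set_sizes=[15], seed=s, gene_span_snps=10
        )
        truth = plant_causal_genes(g, annotation, 1, seed=s)
        ph = simulate_phenotypes(g, truth, h2_target=h2_target, seed=s + 1)
        cfg = RunConfig(n_permutations=n_permutations, seed=s + 2)
        res = permutation_omnibus(g, ph, cfg, annotation)
        row = res.genes[res.genes["gene_id"] == truth.causal_genes[0]]
        hit = len(row) == 1 and row["empirical_p"].iloc[0] <= empirical_p_cut
        hits += hit
        logger.info("recovery replicate %d: %s", rep, "hit" if hit else "miss")
    return {"n_seeds": n_seeds, "n_hits": hits, "recovery_rate": hits / n_seeds}


def set_enrichment_study(
    seed: int,
    n_individuals: int = 2000,
    n_blocks: int = 200,
    n_genes: int = 100,
    n_null_sets: int = 60,
    set_size: int = 15,
    h2_target: float = 0.05,
) -> dict:
    """Planted 3-causal-gene set versus null sets on the Wilcoxon column.

    Reports the fraction of null sets whose Wilcoxon enrichment p exceeds the
    planted set's (the planted set "wins" against that fraction).
    """
    spec = LDBlockSpec(n_snps_per_block=10, n_blocks=n_blocks, within_block_rho=0.8)
    g = simulate_genotypes(spec, n_individuals, seed=seed)
    annotation, _ = make_annotation_and_sets(
        g, genes_per_chrom=n_genes, set_sizes=[set_size], seed=seed, gene_span_snps=10
    )
    truth = plant_causal_genes(g, annotation, 3, seed=seed)
    rng = np.random.default_rng(seed + 9)
    null_pool = [gid for gid in annotation["gene_id"] if gid not in truth.causal_genes]
    sets = {
        f"NULL{i:03d}": sorted(rng.choice(null_pool, size=set_size, replace=False))
        for i in range(n_null_sets)
    }
    sets = plant_causal_set(sets, truth, annotation, size=set_size, seed=seed)
    ph = simulate_phenotypes(g, truth, h2_target=h2_target, seed=seed + 1)
    cfg = RunConfig(seed=seed + 2)
    assoc = residualized_fast_gwas(g, ph, cfg)
    ld = ld_matrix(g)
    gmap = map_snps_to_genes(g.snp_map, annotation, cfg.flank_bp)
    gene_table = gene_stat_table(assoc, gmap, ld)
    table = set_stat_table(sets, gmap, assoc, ld, gene_table).set_index("set_name")
    planted = table.loc["SET_CAUSAL", "p_wilcoxon"]
    null_p = table.drop("SET_CAUSAL")["p_wilcoxon"].to_numpy()
    return {
        "n_null_sets": len(null_p),
        "planted_wilcoxon_p": float(planted),
        "win_fraction": float((null_p > planted).mean()),
    }


def subscale_correlation_study(seed: int, n_individuals: int = 1758) -> dict:
    """Empirical brooding-reflection correlation at the two-cohort sample size."""
    spec = LDBlockSpec(n_snps_per_block=10, n_blocks=50, within_block_rho=0.8)
    g = simulate_genotypes(spec, n_individuals, seed=seed)
    ph = simulate_phenotypes(g, SyntheticTruth(target_subscale_corr=0.488), seed=seed + 1)
    corr = float(np.corrcoef(ph["brooding"], ph["reflection"])[0, 1])
    return {"n_individuals": n_individuals, "target": 0.488, "correlation": corr}
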