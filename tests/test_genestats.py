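"""Gene-level statistics: mapping rules, closed-form oracles, invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from generank import RunConfig, SyntheticTruth, ld_matrix, residualized_fast_gwas, simulate_phenotypes
from generank.genestats import (
    METHODS,
    GeneScorer,
    _SCALAR_STATS,
    gene_stat_table,
    km_covariance,
    map_snps_to_genes,
    stat_ecs,
    stat_gates,
    stat_km_fisher,
    stat_makambi,
    stat_method6,
    stat_minp,
    stat_sidak,
    stat_stouffer_fixed,
)
from generank.synth import LDBlockSpec, make_annotation_and_sets, plant_causal_genes, simulate_genotypes

from conftest import random_corr


# ---------------------------------------------------------------------------
# SNP -> gene mapping


def test_flank_boundary_inclusive():
    snp_map = pd.DataFrame(
        {
            "snp_id": ["a", "b", "c"],
            "chrom": "1",
            "pos": [60_000, 70_000, 70_001],
            "a1": "A",
            "a2": "G",
        }
    )
    ann = pd.DataFrame({"gene_id": ["G1"], "chrom": ["1"], "start": [40_000], "end": [60_000]})
    gmap = map_snps_to_genes(snp_map, ann, flank_bp=10_000)
    # pos = end + 10000 included; end + 10001 excluded
    assert list(gmap.genes["G1"]) == [0, 1]


def test_snp_in_two_overlapping_genes():
    snp_map = pd.DataFrame(
        {"snp_id": ["a"], "chrom": "1", "pos": [50_000], "a1": "A", "a2": "G"}
    )
    ann = pd.DataFrame(
        {
            "gene_id": ["G1", "G2"],
            "chrom": ["1", "1"],
            "start": [40_000, 45_000],
            "end": [55_000, 60_000],
        }
    )
    gmap = map_snps_to_genes(snp_map, ann, flank_bp=0)
    assert list(gmap.genes["G1"]) == [0]
    assert list(gmap.genes["G2"]) == [0]


def test_empty_genes_recorded_untestable():
    snp_map = pd.DataFrame(
        {"snp_id": ["a"], "chrom": "1", "pos": [50_000], "a1": "A", "a2": "G"}
    )
    ann = pd.DataFrame(
        {"gene_id": ["G1", "G2"], "chrom": ["1", "2"], "start": [1, 1], "end": [100, 100]}
    )
    gmap = map_snps_to_genes(snp_map, ann, flank_bp=0)
    assert sorted(gmap.untestable) == ["G1", "G2"]


# ---------------------------------------------------------------------------
# closed-form examples


def test_minp_and_sidak_examples():
    assert stat_minp([0.3, 0.01, 0.5]) == 0.01
    assert stat_minp([0.7]) == 0.7
    assert stat_sidak([0.01]) == pytest.approx(0.01, abs=1e-15)
    p10 = np.concatenate([[0.01], np.full(9, 0.9)])
    assert stat_sidak(p10) == pytest.approx(1 - 0.99**10, rel=1e-10)
    assert stat_sidak(p10) == pytest.approx(0.0956179, abs=1e-7)


def test_km_fisher_examples():
    # independent pair: 4-df chi-square survival e^(-T/2)(1 + T/2)
    t = -2 * (np.log(0.05) + np.log(0.05))
    expected = np.exp(-t / 2) * (1 + t / 2)
    assert stat_km_fisher([0.05, 0.05], np.eye(2)) == pytest.approx(expected, rel=1e-10)
    assert stat_km_fisher([0.05, 0.05], np.eye(2)) == pytest.approx(0.01748, abs=5e-5)
    # perfect LD collapses to the single test; c(1) = 4 exactly
    assert km_covariance(1.0) == pytest.approx(4.0, abs=1e-12)
    assert stat_km_fisher([0.05, 0.05], np.ones((2, 2))) == pytest.approx(0.05, rel=1e-10)


def test_stouffer_examples():
    z = stats.norm.isf(0.05)
    expected = stats.norm.sf(2 * z / np.sqrt(2))
    assert stat_stouffer_fixed([0.05, 0.05], np.eye(2)) == pytest.approx(expected, rel=1e-10)
    assert stat_stouffer_fixed([0.05, 0.05], np.eye(2)) == pytest.approx(0.01000, abs=1e-4)
    assert stat_stouffer_fixed([0.05, 0.05], np.ones((2, 2))) == pytest.approx(0.05, rel=1e-10)
    with pytest.raises(ValueError, match="variance"):
        stat_stouffer_fixed([0.05, 0.05], np.array([[1.0, -1.0], [-1.0, 1.0]]))


def test_makambi_reduces_to_km_fisher_with_equal_weights():
    rng = np.random.default_rng(0)
    for k in (2, 4, 7):
        p = rng.uniform(0.001, 0.999, size=k)
        r = random_corr(rng, k)
        assert stat_makambi(p, r) == pytest.approx(stat_km_fisher(p, r), rel=1e-12)
    # duplicated pair collapse
    assert stat_makambi([0.05, 0.05], np.ones((2, 2))) == pytest.approx(0.05, rel=1e-10)
    with pytest.raises(ValueError, match="weights"):
        stat_makambi([0.1, 0.2], np.eye(2), weights=[0.9, 0.9])


def test_method6_limits():
    rng = np.random.default_rng(1)
    p = rng.uniform(0.01, 0.99, size=5)
    # independence: whitening is the identity, equals fixed-effect z-score test
    assert stat_method6(p, np.eye(5)) == pytest.approx(stat_stouffer_fixed(p, np.eye(5)), abs=1e-10)
    # rank-1 duplicated pair collapses after eigenvalue flooring
    assert stat_method6([0.05, 0.05], np.ones((2, 2))) == pytest.approx(0.05, abs=1e-6)


def test_gates_examples():
    # independence reduces to Simes
    assert stat_gates([0.01, 0.02, 0.9], np.eye(3)) == pytest.approx(0.03, rel=1e-10)
    # perfect LD pair: m_e = 1
    assert stat_gates([0.05, 0.05], np.ones((2, 2))) == pytest.approx(0.05, rel=1e-10)


def test_ecs_examples():
    rng = np.random.default_rng(2)
    p = rng.uniform(0.01, 0.99, size=4)
    plain = stats.chi2.sf(stats.chi2.isf(p, 1).sum(), 4)
    assert stat_ecs(p, np.eye(4)) == pytest.approx(plain, abs=1e-10)
    assert stat_ecs([0.05, 0.05], np.ones((2, 2))) == pytest.approx(0.05, rel=1e-8)


# ---------------------------------------------------------------------------
# invariants


def test_single_snp_reduction_all_methods():
    rng = np.random.default_rng(3)
    r1 = np.eye(1)
    for _ in range(100):
        p = rng.uniform(1e-6, 1.0)
        for name, fn in _SCALAR_STATS.items():
            assert fn([p], r1) == pytest.approx(p, abs=1e-10), name


def test_monotone_in_each_p():
    rng = np.random.default_rng(4)
    monotone = {
        "minp": stat_minp,
        "sidak": stat_sidak,
        "km_fisher": stat_km_fisher,
        "stouffer": stat_stouffer_fixed,
        "makambi": stat_makambi,
    }
    for _ in range(20):
        k = rng.integers(2, 8)
        p = rng.uniform(0.05, 0.95, size=k)
        r = random_corr(rng, k)
        j = rng.integers(k)
        smaller = p.copy()
        smaller[j] *= rng.uniform(0.1, 0.9)
        for name, fn in monotone.items():
            if name in ("minp", "sidak"):
                assert fn(smaller) <= fn(p) + 1e-12, name
            else:
                assert fn(smaller, r) <= fn(p, r) + 1e-12, name


def test_perfect_ld_pair_collapses_to_single_test():
    # A test duplicated at r=1 is statistically one test: the pair must
    # reproduce the single p exactly.  (Appending a duplicate to a larger
    # gene is NOT an invariant of the moment-matched approximations.)
    rng = np.random.default_rng(5)
    r_pair = np.ones((2, 2))
    for _ in range(20):
        p = rng.uniform(1e-4, 1.0)
        pair = [p, p]
        assert stat_km_fisher(pair, r_pair) == pytest.approx(p, abs=1e-10)
        assert stat_gates(pair, r_pair) == pytest.approx(p, abs=1e-10)
        assert stat_ecs(pair, r_pair) == pytest.approx(p, abs=1e-8)
        assert stat_stouffer_fixed(pair, r_pair) == pytest.approx(p, abs=1e-10)
        assert stat_makambi(pair, r_pair) == pytest.approx(p, abs=1e-10)
        assert stat_method6(pair, r_pair) == pytest.approx(p, abs=1e-6)


def test_sidak_bounds_vs_minp():
    rng = np.random.default_rng(6)
    for _ in range(50):
        k = rng.integers(1, 20)
        p = rng.uniform(1e-4, 1.0, size=k)
        lo, si = stat_minp(p), stat_sidak(p)
        assert si >= lo - 1e-15
        assert si <= k * lo + 1e-12  # Bonferroni dominance


def test_outputs_in_unit_interval_no_nan():
    rng = np.random.default_rng(7)
    for _ in range(30):
        k = rng.integers(1, 9)
        p = rng.uniform(1e-12, 1.0, size=k)
        r = random_corr(rng, k) if k > 1 else np.eye(1)
        for name, fn in _SCALAR_STATS.items():
            v = fn(p, r)
            assert 0.0 < v <= 1.0, (name, v)


# ---------------------------------------------------------------------------
# scorer and table


def test_scorer_matches_scalar_functions(assoc_null, ld_small, geno_small, annotation_sets):
    annotation, _ = annotation_sets
    gmap = map_snps_to_genes(geno_small.snp_map, annotation)
    p_all = np.nan_to_num(assoc_null.table["p"].to_numpy(), nan=1.0)
    scorer = GeneScorer(ld_small, gmap.genes)
    scores = scorer.scores(p_all)
    for u, gene in enumerate(scorer.unit_ids):
        idx = gmap.genes[gene]
        r = ld_small.r[np.ix_(idx, idx)]
        for name in METHODS:
            ref = _SCALAR_STATS[name](p_all[idx], r)
            assert scores[name][u] == pytest.approx(ref, abs=1e-10), (name, gene)


def test_gates_kernel_paths_agree(ld_small, geno_small, annotation_sets):
    """The compiled GATES kernel and the pure-numpy reference are identical."""
    from generank.genestats import _GATES_KERNEL, _gates_kernel_py

    annotation, _ = annotation_sets
    gmap = map_snps_to_genes(geno_small.snp_map, annotation)
    scorer = GeneScorer(ld_small, gmap.genes, methods=("gates",))
    rng = np.random.default_rng(17)
    p = rng.uniform(1e-6, 1.0, size=geno_small.m_snps)
    args = (
        p, scorer._concat, scorer._starts.astype(np.int64),
        scorer.k.astype(np.int64), scorer._r2_flat, scorer._r2_off,
    )
    out_active = np.empty(len(scorer.unit_ids))
    out_ref = np.empty(len(scorer.unit_ids))
    _GATES_KERNEL(*args, out_active)
    _gates_kernel_py(*args, out_ref)
    np.testing.assert_allclose(out_active, out_ref, atol=1e-12)


def test_gene_table_single_snp_gene_returns_snp_p(assoc_null, ld_small, geno_small):
    pos = int(geno_small.snp_map["pos"].iloc[7])
    ann = pd.DataFrame({"gene_id": ["solo"], "chrom": ["1"], "start": [pos], "end": [pos]})
    gmap = map_snps_to_genes(geno_small.snp_map, ann, flank_bp=0)
    table = gene_stat_table(assoc_null, gmap, ld_small)
    snp_p = assoc_null.table["p"].iloc[7]
    for m in METHODS:
        assert table[f"p_{m}"].iloc[0] == pytest.approx(snp_p, abs=1e-10)


def test_null_calibration_gene_columns_uniform():
    """Under a null phenotype the adjusted gene-level columns are ~Uniform(0,1)
    in the weak-LD regime where the covariance approximations are accurate.

    The raw minimum p is excluded by construction (min of k p-values is
    stochastically small); under strong LD the moment-matched methods are
    deliberately conservative and are recalibrated by the permutation omnibus
    rather than asserted uniform here.
    """
    spec = LDBlockSpec(n_snps_per_block=10, n_blocks=200, within_block_rho=0.3)
    g = simulate_genotypes(spec, 800, seed=61)
    ann, _ = make_annotation_and_sets(g, genes_per_chrom=200, set_sizes=[3], seed=61, gene_span_snps=8)
    ph = simulate_phenotypes(g, SyntheticTruth(), seed=62)
    assoc = residualized_fast_gwas(g, ph, RunConfig())
    gmap = map_snps_to_genes(g.snp_map, ann)
    table = gene_stat_table(assoc, gmap, ld_matrix(g))
    assert len(table) == 200
    for m in METHODS:
        if m == "minp":
            assert np.median(table["p_minp"]) < 0.3  # min of ~10 p-values
            continue
        ks = stats.kstest(table[f"p_{m}"], "uniform")
        assert ks.pvalue > 0.01, (m, ks.pvalue)


def test_planted_gene_wins_gates_column():
    """A causal gene attains the best GATES p in most seeded replicates."""
    wins = 0
    n_rep = 10
    for rep in range(n_rep):
        spec = LDBlockSpec(n_snps_per_block=10, n_blocks=50, within_block_rho=0.8)
        g = simulate_genotypes(spec, 2000, seed=400 + rep)
        ann, _ = make_annotation_and_sets(g, genes_per_chrom=50, set_sizes=[3], seed=400 + rep, gene_span_snps=8)
        truth = plant_causal_genes(g, ann, 1, seed=400 + rep)
        ph = simulate_phenotypes(g, truth, h2_target=0.02, seed=500 + rep)
        assoc = residualized_fast_gwas(g, ph, RunConfig())
        gmap = map_snps_to_genes(g.snp_map, ann)
        table = gene_stat_table(assoc, gmap, ld_matrix(g))
        best = table.loc[table["p_gates"].idxmin(), "gene_id"]
        wins += best == truth.causal_genes[0]
    assert wins >= 0.8 * n_rep
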