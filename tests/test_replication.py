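"""LD clumping, sign concordance, exact binomial CI and sign test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from generank import (
    RunConfig,
    SyntheticTruth,
    clopper_pearson,
    ld_clump,
    ld_matrix,
    residualized_fast_gwas,
    sign_concordance,
    sign_test_right,
    simulate_genotypes,
    simulate_phenotypes,
)
from generank.assoc import AssocTable
from generank.replication import LDMatrix, concordance_table
from generank.synth import LDBlockSpec, plant_causal_genes, make_annotation_and_sets


def _assoc(snp_ids, p, beta=None, tested=None):
    m = len(snp_ids)
    table = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": np.arange(1, m + 1),
            "beta": beta if beta is not None else np.ones(m),
            "se": 1.0,
            "t": 1.0,
            "p": p,
            "n_used": 100,
            "tested": tested if tested is not None else [True] * m,
        }
    )
    return AssocTable(table=table, phenotype_name="rumination")


def _ld(snp_ids, r):
    return LDMatrix(snp_ids=np.array(snp_ids), r=np.asarray(r, dtype=float))


def test_full_ld_collapses_to_best_snp():
    ids = ["s1", "s2", "s3"]
    ld = _ld(ids, np.ones((3, 3)))
    leads = ld_clump(_assoc(ids, [1e-6, 1e-5, 1e-4]), ld, p_threshold=1e-3)
    assert leads == ["s1"]


def test_no_ld_keeps_all_subthreshold_snps():
    ids = ["s1", "s2", "s3"]
    leads = ld_clump(_assoc(ids, [1e-6, 1e-5, 0.5]), _ld(ids, np.eye(3)), p_threshold=1e-3)
    assert sorted(leads) == ["s1", "s2"]


def test_greedy_chain_hand_trace():
    # A-B r2=0.6, B-C r2=0.6, A-C r2=0.1; A most significant -> leads [A, C]
    ids = ["A", "B", "C"]
    r = np.array(
        [
            [1.0, np.sqrt(0.6), np.sqrt(0.1)],
            [np.sqrt(0.6), 1.0, np.sqrt(0.6)],
            [np.sqrt(0.1), np.sqrt(0.6), 1.0],
        ]
    )
    leads = ld_clump(_assoc(ids, [1e-6, 1e-5, 1e-4]), _ld(ids, r), p_threshold=1e-3)
    assert leads == ["A", "C"]


def test_clump_output_pairwise_independent(ld_small, assoc_null):
    rng = np.random.default_rng(0)
    for _ in range(20):
        thr = rng.uniform(0.05, 0.9)
        leads = ld_clump(assoc_null, ld_small, thr, r2_cut=0.5)
        idx = ld_small.index(leads)
        sub = ld_small.r2[np.ix_(idx, idx)]
        off = sub[np.triu_indices(len(idx), k=1)]
        assert off.size == 0 or off.max() < 0.5


def test_sign_concordance_counting():
    leads = ["s1", "s2", "s3"]
    a = _assoc(leads, [0.1] * 3, beta=[1.0, -2.0, 3.0])
    b = _assoc(leads, [0.1] * 3, beta=[0.5, -1.0, -4.0])
    assert sign_concordance(leads, a, b) == (2, 3)
    assert sign_concordance(leads, a, a) == (3, 3)


def test_missing_and_zero_beta_leads_excluded():
    a = _assoc(["s1", "s2"], [0.1, 0.1], beta=[1.0, 0.0])
    b = _assoc(["s1"], [0.1], beta=[1.0])
    k, n = sign_concordance(["s1", "s2", "s9"], a, b)
    assert (k, n) == (1, 1)


@pytest.mark.parametrize(
    "k,n,low,high",
    [
        (1, 1, 0.02500, 1.0),
        (2, 2, 0.15811, 1.0),
        (0, 5, 0.0, 0.52182),
    ],
)
def test_clopper_pearson_published_values(k, n, low, high):
    lo, hi = clopper_pearson(k, n)
    assert lo == pytest.approx(low, abs=5e-6)
    assert hi == pytest.approx(high, abs=5e-6)


def test_clopper_pearson_degenerate_closed_forms():
    # k=n: lower bound (alpha/2)^(1/n); k=0: upper bound 1-(alpha/2)^(1/n)
    for n in (1, 2, 5, 10):
        lo, hi = clopper_pearson(n, n)
        assert lo == pytest.approx(0.025 ** (1 / n), rel=1e-10)
        assert hi == 1.0
        lo0, hi0 = clopper_pearson(0, n)
        assert lo0 == 0.0
        assert hi0 == pytest.approx(1 - 0.025 ** (1 / n), rel=1e-10)


@given(st.integers(min_value=1, max_value=200), st.data())
@settings(max_examples=50, derandomize=True, deadline=None)
def test_clopper_pearson_contains_estimate(n, data):
    k = data.draw(st.integers(min_value=0, max_value=n))
    lo, hi = clopper_pearson(k, n)
    assert lo <= k / n <= hi
    # widening coverage: the 99% interval contains the 95% one
    lo99, hi99 = clopper_pearson(k, n, conf=0.99)
    assert lo99 <= lo and hi <= hi99


@pytest.mark.parametrize("k,n,expected", [(1, 1, 0.5), (2, 2, 0.25), (7, 10, 0.171875)])
def test_sign_test_exact_values(k, n, expected):
    assert sign_test_right(k, n) == pytest.approx(expected, rel=1e-12)


@given(st.integers(min_value=1, max_value=20), st.data())
@settings(max_examples=60, derandomize=True, deadline=None)
def test_sign_test_matches_pmf_enumeration(n, data):
    k = data.draw(st.integers(min_value=0, max_value=n))
    brute = sum(stats.binom.pmf(j, n, 0.5) for j in range(k, n + 1))
    assert sign_test_right(k, n) == pytest.approx(brute, rel=1e-9)


def test_invalid_inputs_raise():
    with pytest.raises(ValueError):
        clopper_pearson(3, 2)
    with pytest.raises(ValueError):
        sign_test_right(-1, 5)
    with pytest.raises(ValueError):
        ld_clump(_assoc(["s1"], [0.1]), LDMatrix(snp_ids=np.array([]), r=np.empty((0, 0))), 0.05)


def _two_cohort_setup(seed, n_causal, h2):
    spec = LDBlockSpec(n_snps_per_block=5, n_blocks=60, within_block_rho=0.6)
    g = simulate_genotypes(spec, 1000, seed=seed)
    if n_causal:
        ann, _ = make_annotation_and_sets(g, genes_per_chrom=20, set_sizes=[3], seed=seed, gene_span_snps=4)
        truth = plant_causal_genes(g, ann, n_causal, seed=seed)
    else:
        truth = SyntheticTruth()
    ph = simulate_phenotypes(g, truth, h2_target=h2, seed=seed + 1)
    cfg = RunConfig()
    ga, gb = g.subset(g.site == "A"), g.subset(g.site == "B")
    assoc = residualized_fast_gwas(g, ph, cfg)
    assoc_a = residualized_fast_gwas(ga, ph[ph["individual_id"].isin(ga.individual_ids)], cfg)
    assoc_b = residualized_fast_gwas(gb, ph[ph["individual_id"].isin(gb.individual_ids)], cfg)
    return g, assoc, assoc_a, assoc_b


def test_shared_effects_give_concordance_above_half():
    g, assoc, assoc_a, assoc_b = _two_cohort_setup(seed=31, n_causal=4, h2=0.08)
    rows = concordance_table(assoc, ld_matrix(g), assoc_a, assoc_b, p_thresholds=[0.05])
    row = rows[0]
    assert row.n_lead > 0
    assert row.rate > 0.5
    assert row.ci_low <= row.rate <= row.ci_high


def test_selection_free_null_concordance_is_half():
    # Lead selection at threshold 1.0 is independent of both cohorts, so the
    # null concordance rate is ~0.5 (selecting on the combined p would not be:
    # that conditioning itself favours concordant subsample signs).
    rates = []
    for seed in (41, 42, 43):
        g, assoc, assoc_a, assoc_b = _two_cohort_setup(seed=seed, n_causal=0, h2=0.0)
        leads = ld_clump(assoc, ld_matrix(g), p_threshold=1.0, r2_cut=0.5)
        k, n = sign_concordance(leads, assoc_a, assoc_b)
        rates.append(k / n)
    mean = np.mean(rates)
    n_tot = 3 * 150  # >= 150 leads per replicate
    assert abs(mean - 0.5) < 4 * np.sqrt(0.25 / n_tot)
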