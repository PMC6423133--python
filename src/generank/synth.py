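"""Synthetic GWAS data generator.

Produces genotype matrices with block LD structure (Gaussian-copula
haplotypes with an AR(1) latent correlation within each block), covariates,
correlated continuous phenotypes with planted per-gene effects, BED-like gene
annotations and GMT gene-set collections.  The generator emulates the data
layout of a two-site general-population GWAS of continuous questionnaire
phenotypes (rumination and its brooding / reflection subscales): two
subsamples, weighted item-mean scores, sex/age/10-PC covariates, and a target
brooding-reflection correlation.

The LD model is deliberately minimal: within a block the latent Gaussian
correlation between SNPs i and j is rho**|i-j| and blocks are mutually
independent.  Thresholding the latent variable at each SNP's MAF quantile
yields haplotypes; the dosage is the sum of two independent haplotypes.  The
genotype-scale r2 is an attenuated, monotone function of the latent rho,
which is all the downstream clumping and aggregation machinery needs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LDBlockSpec",
    "GenotypeMatrix",
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "make_annotation_and_sets",
    "plant_causal_genes",
    "plant_causal_set",
    "PHENOTYPES",
    "COVARIATE_COLUMNS",
]

PHENOTYPES = ("rumination", "brooding", "reflection")
COVARIATE_COLUMNS = ("sex", "age") + tuple(f"pc{i}" for i in range(1, 11))

#: Budapest / Manchester subsample proportions (773 and 985 of 1758).
SITE_A_FRACTION = 773 / 1758


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from a single seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class LDBlockSpec:
    """Geometry and correlation of the simulated LD blocks."""

    n_snps_per_block: int = 10
    within_block_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_blocks: int = 50
    inter_block_gap_bp: int = 100_000
    snp_spacing_bp: int = 2_000

    def __post_init__(self) -> None:
        if self.n_snps_per_block < 1 or self.n_blocks < 1:
            raise ValueError("n_snps_per_block and n_blocks must be positive")
        if not (0.0 <= self.within_block_rho < 1.0):
            raise ValueError("within_block_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.inter_block_gap_bp < 1 or self.snp_spacing_bp < 1:
            raise ValueError("bp spacings must be positive")

    @property
    def m_snps(self) -> int:
        return self.n_snps_per_block * self.n_blocks


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix plus SNP map and sample labels."""

    dosages: np.ndarray  # (n, m) values in {0,1,2}
    snp_map: pd.DataFrame  # snp_id, chrom, pos, a1, a2
    individual_ids: np.ndarray
    site: np.ndarray  # per-individual label in {"A","B"}

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.individual_ids = np.asarray(self.individual_ids)
        self.site = np.asarray(self.site)
        self.validate()

    def validate(self) -> None:
        n, m = self.dosages.shape
        if len(self.individual_ids) != n or len(self.site) != n:
            raise ValueError("individual_ids/site length must match dosage rows")
        if len(self.snp_map) != m:
            raise ValueError("snp_map rows must match dosage columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual_ids")
        if self.snp_map["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_ids in map")
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"dosage outside {{0,1,2}} at row {i}, column {j}")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def m_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Row-subset (e.g. one recruitment site) preserving the SNP map."""
        mask = np.asarray(mask)
        return GenotypeMatrix(
            dosages=self.dosages[mask],
            snp_map=self.snp_map.reset_index(drop=True),
            individual_ids=self.individual_ids[mask],
            site=self.site[mask],
        )

    def snp_index(self, snp_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_map["snp_id"])}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown snp_id {exc.args[0]!r}") from None


@dataclass
class SyntheticTruth:
    """Planted signal: which SNPs/genes/sets carry effects, and how strong.

    ``causal_snps`` maps snp_id -> {phenotype: relative beta}; betas act on
    standardized dosages and are rescaled jointly so the causal SNPs explain
    ``h2_target`` of the phenotypic variance (see :func:`simulate_phenotypes`).
    """

    causal_snps: dict[str, dict[str, float]] = field(default_factory=dict)
    causal_genes: list[str] = field(default_factory=list)
    causal_sets: list[str] = field(default_factory=list)
    target_subscale_corr: float = 0.488
    seed: int = 0


def simulate_genotypes(
    spec: LDBlockSpec,
    n_individuals: int,
    seed: int,
    n_chromosomes: int = 1,
    site_counts: tuple[int, int] | None = None,
) -> GenotypeMatrix:
    """Draw a dosage matrix with block-AR(1) LD via a Gaussian copula.

    Each of the two haplotypes per individual thresholds a latent multivariate
    normal (AR(1) within block, independent across blocks) at the normal
    quantile of each SNP's MAF; dosage is the haplotype sum.  Deterministic
    given ``seed``.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    if n_chromosomes < 1 or n_chromosomes > spec.n_blocks:
        raise ValueError("n_chromosomes must be in [1, n_blocks]")

    rng = _substream(seed, "genotypes")
    m = spec.m_snps
    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    thresholds = stats.norm.ppf(mafs)

    k = spec.n_snps_per_block
    rho = spec.within_block_rho
    innov = np.sqrt(1.0 - rho**2)
    # Two haplotypes per individual, all blocks at once: AR(1) recursion
    # column-wise within each block.
    z = rng.standard_normal((2 * n_individuals, m))
    for b in range(spec.n_blocks):
        s = b * k
        for j in range(s + 1, s + k):
            z[:, j] = rho * z[:, j - 1] + innov * z[:, j]
    haps = (z < thresholds).astype(np.uint8)
    dosages = haps[:n_individuals] + haps[n_individuals:]

    # Map: blocks split contiguously across chromosomes, positions restart
    # at 1 on each chromosome.
    chrom_of_block = np.array_split(np.arange(spec.n_blocks), n_chromosomes)
    chroms, positions = [], []
    for c, blocks in enumerate(chrom_of_block, start=1):
        pos = 0
        for _ in blocks:
            pos += spec.inter_block_gap_bp
            for _ in range(k):
                positions.append(pos)
                chroms.append(str(c))
                pos += spec.snp_spacing_bp
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(m)],
            "chrom": chroms,
            "pos": np.asarray(positions, dtype=np.int64),
            "a1": "A",
            "a2": "G",
        }
    )

    if site_counts is None:
        n_a = int(round(n_individuals * SITE_A_FRACTION))
        site_counts = (n_a, n_individuals - n_a)
    if sum(site_counts) != n_individuals:
        raise ValueError("site_counts must sum to n_individuals")
    site = np.array(["A"] * site_counts[0] + ["B"] * site_counts[1])
    ids = np.array([f"ind{i:05d}" for i in range(n_individuals)])
    return GenotypeMatrix(dosages=dosages, snp_map=snp_map, individual_ids=ids, site=site)


def _genotype_pcs(dosages: np.ndarray, n_components: int, seed: int) -> np.ndarray:
    """Top principal components of the standardized dosage matrix."""
    from sklearn.utils.extmath import randomized_svd

    x = dosages.astype(float)
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x /= sd
    u, s, _ = randomized_svd(x, n_components=n_components, random_state=seed & 0x7FFFFFFF)
    return u * s  # individual scores


def simulate_phenotypes(
    g: GenotypeMatrix,
    truth: SyntheticTruth,
    h2_target: float = 0.0,
    cov_effects: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    site_pheno_shift: float = 0.1,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Generate the phenotype/covariate table for a genotype matrix.

    phenotype = intercept + sum(beta * standardized dosage) + covariate
    effects + Gaussian noise.  Causal betas are rescaled so the causal SNPs
    jointly explain ``h2_target`` of the phenotypic variance; the
    brooding/reflection noise correlation is solved so the empirical subscale
    correlation approaches ``truth.target_subscale_corr``.

    ``cov_effects`` is a length-12 vector of effects on (sex, age, pc1..pc10)
    applied identically to all three phenotypes; ``missing_rate`` optionally
    blanks phenotype cells at random (off by default).
    """
    if not (0.0 <= h2_target < 1.0):
        raise ValueError("h2_target must be in [0, 1)")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    missing = set(truth.causal_snps) - set(g.snp_map["snp_id"])
    if missing:
        raise ValueError(f"causal SNPs not in genotype matrix: {sorted(missing)[:3]}")

    n = g.n_individuals
    rng = _substream(seed, "phenotypes")
    is_b = g.site == "B"

    sex = rng.integers(0, 2, size=n).astype(float)
    # Site-specific age distributions (recruitment windows differ slightly).
    age = rng.uniform(18.0, 60.0, size=n) + np.where(is_b, 1.5, 0.0)
    pcs = _genotype_pcs(g.dosages, 10, seed)

    cov = np.column_stack([sex, age - age.mean()] + [pcs[:, i] for i in range(10)])
    if cov_effects is None:
        cov_effects = np.array([0.2, 0.01] + [0.0] * 10)
    cov_effects = np.asarray(cov_effects, dtype=float)
    if cov_effects.shape != (12,):
        raise ValueError("cov_effects must have length 12 (sex, age, pc1..pc10)")
    cov_part = cov @ cov_effects

    # Genetic parts on standardized dosages, per phenotype.
    genetic = {ph: np.zeros(n) for ph in PHENOTYPES}
    if truth.causal_snps:
        idx = g.snp_index(list(truth.causal_snps))
        x = g.dosages[:, idx].astype(float)
        x -= x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x /= sd
        for ph in PHENOTYPES:
            beta = np.array([truth.causal_snps[s].get(ph, 0.0) for s in truth.causal_snps])
            if np.any(beta != 0) and h2_target > 0:
                raw = x @ beta
                v_raw = raw.var()
                if v_raw > 0:
                    v_other = cov_part.var() + noise_sd**2
                    v_target = h2_target * v_other / (1.0 - h2_target)
                    genetic[ph] = raw * np.sqrt(v_target / v_raw)

    # Noise: rumination independent; brooding/reflection bivariate with the
    # correlation solved so the total empirical correlation hits the target.
    fixed = {ph: genetic[ph] + cov_part for ph in PHENOTYPES}
    vb = fixed["brooding"].var() + noise_sd**2
    vr = fixed["reflection"].var() + noise_sd**2
    cov_fixed = np.cov(fixed["brooding"], fixed["reflection"])[0, 1]
    rho_e = (truth.target_subscale_corr * np.sqrt(vb * vr) - cov_fixed) / noise_sd**2
    rho_e = float(np.clip(rho_e, -0.99, 0.99))

    e_rum = rng.standard_normal(n)
    e_shared = rng.standard_normal(n)
    e_b = np.sqrt(abs(rho_e)) * e_shared + np.sqrt(1 - abs(rho_e)) * rng.standard_normal(n)
    e_r = np.sign(rho_e) * np.sqrt(abs(rho_e)) * e_shared + np.sqrt(1 - abs(rho_e)) * rng.standard_normal(n)

    intercept = 2.0
    site_term = np.where(is_b, site_pheno_shift, 0.0)
    table = pd.DataFrame({"individual_id": g.individual_ids})
    table["rumination"] = intercept + fixed["rumination"] + site_term + noise_sd * e_rum
    table["brooding"] = intercept + fixed["brooding"] + site_term + noise_sd * e_b
    table["reflection"] = intercept + fixed["reflection"] + site_term + noise_sd * e_r
    table["sex"] = sex.astype(int)
    table["age"] = age
    for i in range(10):
        table[f"pc{i + 1}"] = pcs[:, i]
    table["site"] = g.site

    if missing_rate > 0:
        mask = rng.random((n, 3)) < missing_rate
        for j, ph in enumerate(PHENOTYPES):
            table.loc[mask[:, j], ph] = np.nan
    return table


def plant_causal_genes(
    g: GenotypeMatrix,
    annotation: pd.DataFrame,
    n_causal_genes: int,
    snps_per_gene: int = 3,
    seed: int = 0,
    target_subscale_corr: float = 0.488,
    phenotypes: tuple[str, ...] = PHENOTYPES,
) -> SyntheticTruth:
    """Choose causal genes and place causal SNPs strictly inside their bounds.

    Every causal SNP gets the same relative beta (1.0) for each phenotype in
    ``phenotypes``; :func:`simulate_phenotypes` rescales jointly to the h2
    target.
    """
    rng = _substream(seed, "truth")
    ann = annotation.reset_index(drop=True)
    eligible = []
    snp_choices = {}
    for row in ann.itertuples(index=False):
        in_gene = g.snp_map[
            (g.snp_map["chrom"] == row.chrom)
            & (g.snp_map["pos"] >= row.start)
            & (g.snp_map["pos"] <= row.end)
        ]["snp_id"].to_list()
        if in_gene:
            eligible.append(row.gene_id)
            snp_choices[row.gene_id] = in_gene
    if len(eligible) < n_causal_genes:
        raise ValueError("not enough genes containing SNPs to plant effects")
    causal_genes = sorted(rng.choice(eligible, size=n_causal_genes, replace=False))
    causal_snps: dict[str, dict[str, float]] = {}
    for gene in causal_genes:
        snps = snp_choices[gene]
        take = np.linspace(0, len(snps) - 1, min(snps_per_gene, len(snps))).astype(int)
        for t in np.unique(take):
            causal_snps[snps[t]] = {ph: 1.0 for ph in phenotypes}
    return SyntheticTruth(
        causal_snps=causal_snps,
        causal_genes=list(causal_genes),
        target_subscale_corr=target_subscale_corr,
        seed=seed,
    )


def plant_causal_set(
    sets: dict[str, list[str]],
    truth: SyntheticTruth,
    annotation: pd.DataFrame,
    size: int = 15,
    seed: int = 0,
    name: str = "SET_CAUSAL",
) -> dict[str, list[str]]:
    """Add a gene set containing all causal genes, padded to ``size``."""
    rng = _substream(seed, "causal_set")
    pool = [gid for gid in annotation["gene_id"] if gid not in truth.causal_genes]
    pad = size - len(truth.causal_genes)
    if pad < 0:
        raise ValueError("size smaller than the number of causal genes")
    members = sorted(truth.causal_genes) + sorted(rng.choice(pool, size=pad, replace=False))
    out = dict(sets)
    out[name] = members
    truth.causal_sets = list(dict.fromkeys(truth.causal_sets + [name]))
    return out


def make_annotation_and_sets(
    g: GenotypeMatrix,
    genes_per_chrom: int,
    set_sizes: list[int],
    overlap_policy: str = "disjoint",
    seed: int = 0,
    gene_span_snps: int | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Tile genes over the simulated coordinates and sample gene sets.

    Genes are placed per chromosome on a regular stride over SNP positions;
    ``overlap_policy`` "disjoint" leaves intergenic gaps, "overlapping" makes
    adjacent genes share SNPs.  For each requested size a gene set is sampled
    uniformly without replacement; output is a BED-like annotation DataFrame
    (1-based inclusive bounds) and a set-name -> gene-id mapping.
    """
    if overlap_policy not in ("disjoint", "overlapping"):
        raise ValueError("overlap_policy must be 'disjoint' or 'overlapping'")
    if genes_per_chrom < 1:
        raise ValueError("genes_per_chrom must be positive")

    rng = _substream(seed, "annotation")
    rows = []
    gid = 0
    for chrom, grp in g.snp_map.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        m_c = len(pos)
        stride = max(1, m_c // genes_per_chrom)
        if gene_span_snps is None:
            span = max(1, stride // 2) if overlap_policy == "disjoint" else min(m_c, stride + max(1, stride // 2))
        else:
            span = max(1, gene_span_snps)
        for i in range(genes_per_chrom):
            lo = min(i * stride, m_c - 1)
            hi = min(lo + span - 1, m_c - 1)
            rows.append(
                {
                    "gene_id": f"GENE{gid:05d}",
                    "chrom": chrom,
                    "start": int(pos[lo]),
                    "end": int(pos[hi]),
                }
            )
            gid += 1
    annotation = pd.DataFrame(rows)

    genes = annotation["gene_id"].to_list()
    sets: dict[str, list[str]] = {}
    for i, size in enumerate(set_sizes):
        if size > len(genes):
            raise ValueError(f"set size {size} exceeds number of genes {len(genes)}")
        members = sorted(rng.choice(genes, size=size, replace=False))
        sets[f"SET{i:03d}_n{size}"] = members
    return annotation, sets
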