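"""Readers/writers for the on-disk formats and the run configuration.

Formats are deliberately plain text at desk scale: genotype TSV
(individual_id, site, one column per SNP) + map TSV (snp_id, chrom, pos, a1,
a2), phenotype TSV, BED-like annotation TSV (1-based inclusive bounds), GMT
gene sets, results TSVs, and a YAML run configuration.  All writers use a
stable column order and fixed float formatting so write -> read -> write is
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import GenotypeMatrix

logger = logging.getLogger("generank")

__all__ = [
    "FormatError",
    "ConfigError",
    "RunConfig",
    "load_config",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_annotation",
    "write_annotation",
    "read_gmt",
    "write_gmt",
    "write_table",
    "read_table",
]

FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """Malformed input file."""


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Pipeline configuration; defaults follow the study's analysis choices."""

    phenotype_name: str = "rumination"
    covariate_names: list[str] = field(
        default_factory=lambda: ["sex", "age"] + [f"pc{i}" for i in range(1, 11)]
    )
    include_other_subscale: bool = False
    p_thresholds: list[float] = field(default_factory=lambda: [0.05, 1e-3, 1e-5])
    clump_r2: float = 0.5
    flank_bp: int = 10_000
    set_size_min: int = 15
    set_size_max: int = 300
    n_permutations: int = 1000
    fdr_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0.0 < t <= 1.0 for t in self.p_thresholds):
            raise ConfigError("p_thresholds must be in (0, 1]")
        if not (0.0 < self.clump_r2 <= 1.0):
            raise ConfigError("clump_r2 must be in (0, 1]")
        if self.flank_bp < 0:
            raise ConfigError("flank_bp must be non-negative")
        if self.set_size_min > self.set_size_max:
            raise ConfigError("set_size_min must be <= set_size_max")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not (0.0 < self.fdr_threshold <= 1.0):
            raise ConfigError("fdr_threshold must be in (0, 1]")


def load_config(path) -> RunConfig:
    """Load a YAML config; unspecified fields take the defaults above."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes(g: GenotypeMatrix, path_matrix, path_map) -> None:
    mat = pd.DataFrame(g.dosages, columns=g.snp_map["snp_id"].to_list())
    mat.insert(0, "individual_id", g.individual_ids)
    mat.insert(1, "site", g.site)
    mat.to_csv(path_matrix, sep="\t", index=False)
    g.snp_map.to_csv(path_map, sep="\t", index=False)
    logger.info("wrote genotypes: %d individuals x %d SNPs", g.n_individuals, g.m_snps)


def read_genotypes(path_matrix, path_map) -> GenotypeMatrix:
    """Read and validate the genotype TSV pair; row order is preserved."""
    snp_map = pd.read_csv(path_map, sep="\t", dtype={"chrom": str})
    required = ["snp_id", "chrom", "pos", "a1", "a2"]
    if list(snp_map.columns) != required:
        raise FormatError(f"map columns must be {required}, got {list(snp_map.columns)}")
    mat = pd.read_csv(path_matrix, sep="\t")
    if list(mat.columns[:2]) != ["individual_id", "site"]:
        raise FormatError("genotype matrix must start with individual_id, site columns")
    snp_cols = list(mat.columns[2:])
    if len(snp_cols) != len(snp_map):
        raise FormatError(
            f"map has {len(snp_map)} SNPs but matrix has {len(snp_cols)} dosage columns"
        )
    if snp_cols != snp_map["snp_id"].to_list():
        raise FormatError("SNP column order differs between matrix and map")
    dosages = mat[snp_cols].to_numpy()
    bad = ~np.isin(dosages, (0, 1, 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"dosage {dosages[i, j]!r} outside {{0,1,2}} at row {i} "
            f"(individual {mat['individual_id'].iloc[i]!r}), column {snp_cols[j]!r}"
        )
    return GenotypeMatrix(
        dosages=dosages.astype(np.uint8),
        snp_map=snp_map,
        individual_ids=mat["individual_id"].to_numpy(),
        site=mat["site"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# phenotype / annotation tables


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_phenotypes(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"site": str})
    if "individual_id" not in table.columns:
        raise FormatError("phenotype table must contain an individual_id column")
    return table


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[["gene_id", "chrom", "start", "end"]].to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["gene_id", "chrom", "start", "end"]
    if list(ann.columns) != required:
        raise FormatError(f"annotation columns must be {required}")
    if (ann["start"] > ann["end"]).any():
        raise FormatError("annotation has start > end")
    return ann


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file into set-name -> unique gene ids (order preserved)."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {lineno} has fewer than 3 tab-separated fields")
        name, _desc, *genes = parts
        genes = [gene for gene in genes if gene]
        unique = list(dict.fromkeys(genes))
        if len(unique) != len(genes):
            logger.warning("GMT set %r: %d duplicate gene ids removed", name, len(genes) - len(unique))
        sets[name] = unique
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "synthetic") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# generic result tables


def write_table(table: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    """Write a results TSV with optional '#'-prefixed header metadata.

    Floats use 6 significant digits; p-value columns (names starting with
    'p' or equal to 'empirical_p'/'q_value') are written in scientific
    notation.
    """
    out = table.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            sci = col.startswith("p") or col in ("empirical_p", "q_value", "sign_test_p")
            fmt = "%.6e" if sci else FLOAT_FMT
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else fmt % v)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
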