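"""Reading and writing the package's delimited-text formats.

All tables are tab-separated text: a cohort table (``id, group, sex,
height_cm`` plus covariates), a genotype dosage matrix (individuals x SNPs,
header row of SNP ids), a variant weight table (``snp_id, effect_allele,
other_allele, weight, p_value, locus_id, ...``) and population summary
tables (``population_id, sex, mean_height, sd_height, n``).  Generator
configurations round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import GenerativeConfig, SyntheticCohort

__all__ = [
    "write_cohort_bundle",
    "read_cohort_table",
    "read_genotypes",
    "read_weight_table",
    "read_population_summaries",
    "config_to_yaml",
    "config_from_yaml",
]


def config_to_yaml(config: GenerativeConfig, path) -> None:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = [float(x) for x in v]
        elif isinstance(v, tuple):
            d[k] = list(v)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path) -> GenerativeConfig:
    d = yaml.safe_load(Path(path).read_text())
    if d.get("maf_range") is not None:
        d["maf_range"] = tuple(d["maf_range"])
    return GenerativeConfig(**d)


def write_cohort_bundle(sim: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write cohort, genotypes, weights and config echo into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out / "cohort.tsv",
        "genotypes": out / "genotypes.tsv",
        "weights": out / "weights.tsv",
        "config": out / "config.yaml",
        "mafs": out / "mafs.tsv",
    }
    sim.cohort.to_csv(paths["cohort"], sep="\t", index=False, float_format="%.6g")
    sim.genotypes.to_csv(paths["genotypes"], sep="\t", index=False)
    sim.weights.to_csv(paths["weights"], sep="\t", index=False, float_format="%.8g")
    pd.DataFrame({"snp_id": sim.genotypes.columns, "maf": sim.mafs}).to_csv(
        paths["mafs"], sep="\t", index=False, float_format="%.6g"
    )
    config_to_yaml(sim.truth, paths["config"])
    return paths


def read_cohort_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_genotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_weight_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_population_summaries(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a population summary table, optionally renaming columns.

    ``column_map`` maps file column names to the canonical names
    ``population_id, sex, mean_height, sd_height, n`` (and any metadata
    columns used by the pairing rules).
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    return df
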