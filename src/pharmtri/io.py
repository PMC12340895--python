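"""Readers, writers, annotation filters, configuration, run manifests.

Coordinate conventions are fixed and asserted at the boundaries: BED is
0-based half-open; GWAS and dosage positions are 1-based.  Every reader
validates its schema and fails with the offending line/row identified.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_gwas", "write_gwas",
    "read_dosages", "write_dosages",
    "read_bed", "write_bed",
    "read_gmt", "write_gmt",
    "read_phenotypes", "write_phenotypes",
    "read_ld_matrix", "write_ld_matrix",
    "filter_interactions", "lof_phewas_filter",
    "RunManifest", "load_config",
]

GWAS_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

ATC_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}(\d{2})?$")  # level 4 or 5


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required columns {missing}")


def read_gwas(path: str | Path) -> pd.DataFrame:
    """Read and validate a GWAS summary-statistic TSV (1-based positions)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, GWAS_COLUMNS, f"GWAS file {path}")
    df["CHR"] = df["CHR"].astype(str)
    df["EA"] = df["EA"].str.upper()
    df["OA"] = df["OA"].str.upper()
    dup = df["SNP"].duplicated()
    if dup.any():
        raise ValueError(
            f"GWAS file {path}: duplicated variant ids at rows "
            f"{(df.index[dup] + 2).tolist()[:5]}")
    bad_se = df["SE"] <= 0
    if bad_se.any():
        raise ValueError(
            f"GWAS file {path}: non-positive SE at row {int(df.index[bad_se][0]) + 2}")
    bad_p = ~df["P"].between(0, 1) | (df["P"] == 0)
    if bad_p.any():
        raise ValueError(
            f"GWAS file {path}: P outside (0, 1] at row {int(df.index[bad_p][0]) + 2}")
    return df


def write_gwas(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, GWAS_COLUMNS, "GWAS frame")
    df[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_dosages(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Dosage TSV: variant metadata columns then one column per individual.

    Returns (individuals x variants dosage matrix, variant metadata frame).
    """
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["SNP", "CHR", "POS", "EA", "OA"]
    _require_columns(df, meta_cols, f"dosage file {path}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise ValueError(f"dosage file {path}: no individual columns")
    dos = df[sample_cols].to_numpy(dtype=float).T
    if dos.min() < 0 or dos.max() > 2:
        raise ValueError(f"dosage file {path}: dosages outside [0, 2]")
    return dos, df[meta_cols]


def write_dosages(
    dosages: np.ndarray, meta: pd.DataFrame, path: str | Path,
    sample_ids: list[str] | None = None,
) -> None:
    n = dosages.shape[0]
    sample_ids = sample_ids or [f"I{i + 1}" for i in range(n)]
    out = meta[["SNP", "CHR", "POS", "EA", "OA"]].copy()
    for i, sid in enumerate(sample_ids):
        out[sid] = dosages[i]
    out.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED (0-based half-open) -> 1-based inclusive gene annotation frame."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{i}: expected >= 4 BED columns")
            chrom, start, end, name = parts[:4]
            strand = parts[5] if len(parts) > 5 else "+"
            start, end = int(start), int(end)
            if end <= start:
                raise ValueError(f"{path}:{i}: BED end <= start")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{i}: bad strand {strand!r}")
            rows.append({"gene": name, "chrom": chrom,
                         "start": start + 1, "end": end, "strand": strand})
    return pd.DataFrame(rows)


def write_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    """1-based inclusive annotation -> BED (0-based half-open)."""
    with open(path, "w") as fh:
        for _, r in annotation.iterrows():
            fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t"
                     f"{r['gene']}\t0\t{r.get('strand', '+')}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: GMT line needs name, desc, >=1 gene")
            sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na"] + list(genes)) + "\n")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["individual_id"], f"phenotype file {path}")
    if df["individual_id"].duplicated().any():
        raise ValueError(f"phenotype file {path}: duplicated individual ids")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"LD matrix {path} is not square")
    return df


def write_ld_matrix(ld: pd.DataFrame, path: str | Path) -> None:
    ld.to_csv(path, sep="\t")


def filter_interactions(
    table: pd.DataFrame,
    pct_list: list[str],
    min_score: float = 0.0,
) -> pd.DataFrame:
    """Drug-gene interactions for the prioritized targets, by ATC class.

    Restricts a DGIdb-like table (gene, drug_name, atc_code,
    interaction_type, interaction_score) to PCT genes with score strictly
    above ``min_score``, groups by the 4th-level ATC prefix (first five
    characters), and ranks by score descending within and across groups.
    """
    _require_columns(table, ["gene", "drug_name", "atc_code",
                             "interaction_type", "interaction_score"],
                     "interaction table")
    bad = ~table["atc_code"].astype(str).str.match(ATC_PATTERN)
    if bad.any():
        raise ValueError(
            f"invalid ATC code(s): {table.loc[bad, 'atc_code'].tolist()[:5]}")
    if (table["interaction_score"] < 0).any():
        raise ValueError("interaction scores must be non-negative")
    out = table.loc[table["gene"].isin(pct_list)
                    & (table["interaction_score"] > min_score)].copy()
    out["atc_class"] = out["atc_code"].str[:5]
    return out.sort_values(["interaction_score", "gene", "drug_name"],
                           ascending=[False, True, True]).reset_index(drop=True)


def lof_phewas_filter(
    table: pd.DataFrame,
    *,
    primary_threshold: float = 2.75e-6,
    subthreshold: float = 1e-4,
) -> pd.DataFrame:
    """Tier gene-based LoF burden associations by significance.

    ``significant`` for p strictly below the primary threshold (default
    2.75e-6, a configurable constant), ``subthreshold`` for p strictly
    below 1e-4 but not primary; other rows are dropped.
    """
    _require_columns(table, ["gene", "phenotype", "p"], "PheWAS table")
    out = table.copy()
    out["tier"] = np.where(out["p"] < primary_threshold, "significant",
                           np.where(out["p"] < subthreshold, "subthreshold", ""))
    return out.loc[out["tier"] != ""].sort_values("p").reset_index(drop=True)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Traceability record written alongside every pipeline output."""

    root_seed: int
    config_hash: str = ""
    stage_versions: dict[str, str] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def add_input(self, name: str, path: str | Path) -> None:
        self.input_digests[name] = _sha256(path)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def load_config(path: str | Path, allowed_keys: set[str]) -> dict:
    """Strict flat YAML config: unknown keys are rejected."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    unknown = set(cfg) - set(allowed_keys)
    if unknown:
        raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
    return cfg
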