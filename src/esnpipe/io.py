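"""Readers and writers for the plain-text formats used across the pipeline.

Everything here is deliberately simple: tab-separated tables via pandas and
the GMT gene-set format (one set per line: name, description, member genes).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

GWAS_COLUMNS = [
    "snp", "allele1", "allele2", "beta", "se", "pvalue",
    "maf", "hwe_pvalue", "info", "call_rate",
]
EQTL_COLUMNS = ["snp", "gene", "tissue", "study", "expr_pvalue", "cis_trans"]
LD_COLUMNS = ["snp_a", "snp_b", "r2"]


class FormatError(ValueError):
    """A required column is missing or a file is malformed."""


def require_columns(df: pd.DataFrame, columns: Sequence[str], what: str = "table") -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_tsv(path: str | Path, columns: Sequence[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if columns is not None:
        require_columns(df, columns, what=str(path))
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered {set_name: [genes]} mapping.

    Duplicate genes within a line are dropped (first occurrence kept).
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name = parts[0]
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
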