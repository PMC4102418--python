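"""Tissue-specific, LD-pruned eSNP backgrounds and gene-set → eSNP mapping.

Expression-association p-values are rank-scaled to [0, 1] within each eQTL
study before pooling, so that studies of different sizes and designs are
comparable. Pooled eSNPs are then greedily pruned so that no two retained
SNPs are in strong LD (r² >= threshold), preferring SNPs with the strongest
(scaled) expression association. Gene sets are mapped to eSNP sets by
intersecting their member genes' eSNPs with the pruned tissue background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import require_columns

R2_MAX_DEFAULT = 0.7
ALL_TISSUES = "all"


@dataclass
class EsnpSet:
    name: str
    tissue: str
    snp_ids: frozenset[str]
    coverage: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snp_ids)


def rank_scale(records: pd.DataFrame) -> pd.DataFrame:
    """Attach ``scaled_rank`` in [0, 1] per study.

    Within each study, ranks of ``expr_pvalue`` (ascending, ties averaged)
    are scaled as (rank - 1) / (n - 1); a single-record study gets 0.
    """
    require_columns(records, ["study", "expr_pvalue"], what="eQTL table")
    out = records.copy()

    def _scale(p: pd.Series) -> np.ndarray:
        n = len(p)
        if n == 1:
            return np.zeros(1)
        ranks = rankdata(p.to_numpy(), method="average")
        return (ranks - 1.0) / (n - 1.0)

    out["scaled_rank"] = (
        out.groupby("study", sort=False)["expr_pvalue"].transform(_scale)
    )
    return out


def _neighbors(ld: pd.DataFrame, known_snps: set[str], r2_max: float) -> dict[str, set[str]]:
    """Symmetric adjacency over pairs with r² >= r2_max, restricted to known SNPs."""
    require_columns(ld, ["snp_a", "snp_b", "r2"], what="LD table")
    strong = ld[ld["r2"] >= r2_max]
    unknown = set(strong["snp_a"]) | set(strong["snp_b"])
    unknown -= known_snps
    if unknown:
        warnings.warn(
            f"LD table references {len(unknown)} SNP(s) absent from the eSNP "
            "records; those pairs are ignored", stacklevel=2)
    adj: dict[str, set[str]] = {}
    for a, b in zip(strong["snp_a"], strong["snp_b"]):
        if a in known_snps and b in known_snps:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    return adj


def ld_prune(records: pd.DataFrame, ld: pd.DataFrame,
             r2_max: float = R2_MAX_DEFAULT) -> list[str]:
    """Greedy LD pruning, keeping the best-associated SNP of each LD clump.

    SNP priority is its minimum ``scaled_rank`` over all of its records
    (a SNP may be an eSNP for several genes/studies); SNPs are visited by
    ascending priority (ties broken by snp_id) and kept iff no previously
    kept SNP has r² >= ``r2_max`` with them. The result is an independent
    set of the r² >= r2_max graph.
    """
    if "scaled_rank" not in records.columns:
        records = rank_scale(records)
    best = records.groupby("snp", sort=False)["scaled_rank"].min()
    snps = set(best.index)
    adj = _neighbors(ld, snps, r2_max)
    order = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
    kept: list[str] = []
    kept_set: set[str] = set()
    for snp, _ in order:
        if not (adj.get(snp, set()) & kept_set):
            kept.append(snp)
            kept_set.add(snp)
    return sorted(kept)


def build_background(records: pd.DataFrame, ld: pd.DataFrame, tissue: str,
                     r2_max: float = R2_MAX_DEFAULT) -> EsnpSet:
    """LD-pruned union of a tissue's eSNPs (``tissue="all"`` pools tissues)."""
    if tissue != ALL_TISSUES:
        records = records[records["tissue"] == tissue]
    if records.empty:
        raise ValueError(f"no eSNP records for tissue {tissue!r}")
    if "scaled_rank" not in records.columns:
        records = rank_scale(records)
    kept = ld_prune(records, ld, r2_max=r2_max)
    return EsnpSet(name="background", tissue=tissue, snp_ids=frozenset(kept))


def build_gene_index(records: pd.DataFrame, tissue: str) -> dict[str, set[str]]:
    """gene -> set of eSNP ids for one tissue (or all tissues pooled)."""
    if tissue != ALL_TISSUES:
        records = records[records["tissue"] == tissue]
    index: dict[str, set[str]] = {}
    for gene, snp in zip(records["gene"], records["snp"]):
        index.setdefault(gene, set()).add(snp)
    return index


def _map_one(name: str, genes, index: dict[str, set[str]],
             background: EsnpSet) -> EsnpSet:
    genes = set(genes)
    snps: set[str] = set()
    covered = 0
    for g in genes:
        gene_snps = index.get(g)
        if gene_snps:
            covered += 1
            snps |= gene_snps
    snps &= background.snp_ids
    coverage = {
        "n_genes": len(genes),
        "n_genes_with_esnps": covered,
        "n_genes_unknown": len(genes - index.keys()),
        "empty": len(snps) == 0,
    }
    return EsnpSet(name=name, tissue=background.tissue,
                   snp_ids=frozenset(snps), coverage=coverage)


def map_gene_set(name: str, genes, records: pd.DataFrame,
                 background: EsnpSet) -> EsnpSet:
    """eSNP set of a gene set: background SNPs with a record to a member gene.

    Gene ids absent from the records are silently ignored but counted in the
    ``coverage`` metadata. An empty result is allowed (flagged in coverage).
    """
    index = build_gene_index(records, background.tissue)
    return _map_one(name, genes, index, background)


def map_gene_sets(gene_sets: dict, records: pd.DataFrame,
                  background: EsnpSet) -> dict[str, EsnpSet]:
    index = build_gene_index(records, background.tissue)
    return {name: _map_one(name, genes, index, background)
            for name, genes in gene_sets.items()}
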