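"""Synthetic-data generators with planted ground truth.

Every downstream stage of the pipeline (meta-analysis, eSNP mapping,
set enrichment, superset merging, key-driver detection) is exercised on
data produced here, with the causal structure recorded in :class:`SimTruth`:

* gene sets, some of which are flagged causal;
* an eSNP catalog mapping SNPs to genes per tissue/study;
* a block-constant LD table;
* per-study GWAS summary statistics in which the eSNPs of causal gene
  sets receive left-skewed (Beta(a, 1)) p-values while everything else
  is uniform;
* directed acyclic gene networks containing planted hub drivers whose
  out-neighborhoods are enriched for a chosen gene set.

All generators are deterministic for a fixed :attr:`SimConfig.seed`; each
generator consumes an independent, named random stream derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import io

# Stream ids keep the per-generator RNGs independent of each other.
_STREAM_GENE_SETS = 1
_STREAM_CATALOG = 2
_STREAM_GWAS = 3
_STREAM_NETWORK = 4


class ConfigurationError(ValueError):
    """Raised when a SimConfig is internally inconsistent."""


@dataclass(frozen=True)
class OverlapRequest:
    """A pair of gene sets with prescribed directional overlap fractions."""

    size_a: int
    size_b: int
    r_ab: float  # |A∩B| / |A|
    r_ba: float  # |A∩B| / |B|

    def shared(self) -> int:
        shared_a = self.r_ab * self.size_a
        shared_b = self.r_ba * self.size_b
        if not np.isclose(shared_a, shared_b):
            raise ConfigurationError(
                f"inconsistent overlap request: r_ab*|A|={shared_a} != r_ba*|B|={shared_b}"
            )
        shared = round(shared_a)
        if not np.isclose(shared_a, shared):
            raise ConfigurationError(
                f"overlap request implies non-integer shared gene count {shared_a}"
            )
        if shared > min(self.size_a, self.size_b):
            raise ConfigurationError("requested overlap exceeds the smaller set size")
        return shared


@dataclass
class SimConfig:
    n_snps: int = 2000
    n_genes: int = 400
    n_studies_stage1: int = 3
    n_studies_stage2: int = 5
    n_gene_sets: int = 50
    set_size_range: tuple[int, int] = (10, 50)
    planted_set_ids: tuple[str, ...] = ()
    signal_strength: float = 1.0
    ld_block_size: int = 5
    within_block_r2: float = 0.9
    tissues: tuple[str, ...] = ("adipose",)
    network_n_nodes: int = 300
    planted_driver_ids: tuple[str, ...] = ()
    hub_degree: int = 30
    seed: int = 0
    # knobs beyond the core dimensions
    mean_esnps_per_gene: float = 3.0
    cis_fraction: float = 0.8
    driver_superset_fraction: float = 0.5
    overlap_requests: tuple[OverlapRequest, ...] = ()

    def __post_init__(self) -> None:
        counts = {
            "n_snps": self.n_snps, "n_genes": self.n_genes,
            "n_studies_stage1": self.n_studies_stage1,
            "n_studies_stage2": self.n_studies_stage2,
            "n_gene_sets": self.n_gene_sets,
            "ld_block_size": self.ld_block_size,
            "network_n_nodes": self.network_n_nodes,
            "hub_degree": self.hub_degree,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if not 0.0 < self.signal_strength <= 1.0:
            raise ConfigurationError("signal_strength must be in (0, 1]")
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise ConfigurationError("within_block_r2 must be in [0, 1]")
        lo, hi = self.set_size_range
        if not (0 < lo <= hi <= self.n_genes):
            raise ConfigurationError("set_size_range must fit inside the gene universe")
        if self.hub_degree >= self.network_n_nodes:
            raise ConfigurationError("hub_degree must be smaller than network_n_nodes")
        if not self.tissues:
            raise ConfigurationError("at least one tissue label is required")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    @property
    def snp_ids(self) -> list[str]:
        return [f"rs{i:06d}" for i in range(self.n_snps)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    @property
    def study_ids(self) -> list[str]:
        n = self.n_studies_stage1 + self.n_studies_stage2
        return [f"study{i:02d}" for i in range(n)]

    def stage_of(self, study_id: str) -> int:
        return 1 if self.study_ids.index(study_id) < self.n_studies_stage1 else 2


@dataclass
class SimTruth:
    causal_gene_sets: list[str] = field(default_factory=list)
    causal_esnps: list[str] = field(default_factory=list)
    planted_key_drivers: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "causal_gene_sets": sorted(self.causal_gene_sets),
            "causal_esnps": sorted(self.causal_esnps),
            "planted_key_drivers": {k: sorted(v) for k, v in self.planted_key_drivers.items()},
        }


def simulate_gene_sets(config: SimConfig) -> dict[str, list[str]]:
    """Draw ``n_gene_sets`` random gene sets plus any requested overlap pairs.

    Requested pairs are appended with ids ``pair<k>_a`` / ``pair<k>_b`` and
    realize exact shared-gene counts; infeasible requests raise
    :class:`ConfigurationError`.
    """
    rng = config.rng(_STREAM_GENE_SETS)
    genes = np.asarray(config.gene_ids)
    lo, hi = config.set_size_range
    sets: dict[str, list[str]] = {}
    for i in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"set_{i:04d}"] = sorted(members.tolist())
    for k, req in enumerate(config.overlap_requests):
        shared = req.shared()
        need = req.size_a + req.size_b - shared
        if need > config.n_genes:
            raise ConfigurationError("overlap request does not fit in the gene universe")
        pool = rng.choice(genes, size=need, replace=False).tolist()
        common = pool[:shared]
        a_only = pool[shared:shared + (req.size_a - shared)]
        b_only = pool[shared + (req.size_a - shared):]
        sets[f"pair{k}_a"] = sorted(common + a_only)
        sets[f"pair{k}_b"] = sorted(common + b_only)
    missing = set(config.planted_set_ids) - set(sets)
    if missing:
        raise ConfigurationError(f"planted set ids not generated: {sorted(missing)}")
    return sets


def simulate_esnp_catalog(config: SimConfig) -> pd.DataFrame:
    """Generate the eSNP catalog: one row per (snp, gene, tissue, study).

    Per tissue there is one eQTL study (``eqtl_<tissue>``). Each gene draws
    a Poisson number of eSNPs (at least across tissues possibly zero) from
    the SNP universe; expression p-values are uniform; the cis/trans flag
    is Bernoulli(``cis_fraction``).
    """
    rng = config.rng(_STREAM_CATALOG)
    snps = np.asarray(config.snp_ids)
    rows: list[tuple] = []
    for tissue in config.tissues:
        study = f"eqtl_{tissue}"
        for gene in config.gene_ids:
            k = int(rng.poisson(config.mean_esnps_per_gene))
            if k == 0:
                continue
            k = min(k, config.n_snps)
            chosen = rng.choice(snps, size=k, replace=False)
            pvals = rng.uniform(0.0, 1.0, size=k)
            cis = rng.uniform(size=k) < config.cis_fraction
            for s, p, c in zip(chosen, pvals, cis):
                rows.append((s, gene, tissue, study, float(p), "cis" if c else "trans"))
    df = pd.DataFrame(rows, columns=io.EQTL_COLUMNS)
    return df.sort_values(["tissue", "gene", "snp"], kind="stable").reset_index(drop=True)


def simulate_ld_table(config: SimConfig) -> pd.DataFrame:
    """Block-constant LD: consecutive SNPs form blocks of ``ld_block_size``.

    Every within-block pair gets r² = ``within_block_r2``; cross-block pairs
    are absent. Each pair is emitted once (snp_a < snp_b); zero-r² entries
    are dropped.
    """
    if config.within_block_r2 == 0.0:
        return pd.DataFrame(columns=io.LD_COLUMNS)
    snps = config.snp_ids
    rows = []
    for start in range(0, config.n_snps, config.ld_block_size):
        block = snps[start:start + config.ld_block_size]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                rows.append((block[i], block[j], config.within_block_r2))
    return pd.DataFrame(rows, columns=io.LD_COLUMNS)


def causal_esnps(catalog: pd.DataFrame, gene_sets: Mapping[str, Sequence[str]],
                 planted_set_ids: Iterable[str]) -> set[str]:
    """eSNPs mapped (in any tissue/study) to a member gene of a planted set."""
    causal_genes: set[str] = set()
    for sid in planted_set_ids:
        causal_genes.update(gene_sets[sid])
    mask = catalog["gene"].isin(causal_genes)
    return set(catalog.loc[mask, "snp"])


def simulate_gwas_studies(
    config: SimConfig,
    catalog: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, SimTruth]:
    """Per-study GWAS summary statistics with planted enrichment.

    Non-causal SNPs get per-study Uniform(0,1) two-sided p-values; eSNPs of
    planted causal sets get Beta(signal_strength, 1) p-values (uniform when
    signal_strength == 1). (beta, se) pairs are synthesized so the Wald
    two-sided normal p-value reproduces the emitted p exactly.

    Returns (studies, stage_map, truth).
    """
    missing = set(config.planted_set_ids) - set(gene_sets)
    if missing:
        raise ConfigurationError(f"planted set ids absent from gene sets: {sorted(missing)}")
    rng = config.rng(_STREAM_GWAS)
    truth = SimTruth(
        causal_gene_sets=sorted(config.planted_set_ids),
        causal_esnps=sorted(causal_esnps(catalog, gene_sets, config.planted_set_ids)),
    )
    snps = np.asarray(config.snp_ids)
    is_causal = np.isin(snps, np.asarray(sorted(truth.causal_esnps), dtype=object))
    n = config.n_snps
    n_causal = int(is_causal.sum())
    alleles = np.array(["A", "C", "G", "T"])
    # causal SNPs keep one effect direction across studies so the signal
    # survives meta-analysis; null SNPs re-draw the sign per study, which
    # leaves their per-study and meta z-scores exactly standard normal
    causal_sign = rng.choice([-1.0, 1.0], size=n)
    studies: dict[str, pd.DataFrame] = {}
    for study in config.study_ids:
        p = rng.uniform(0.0, 1.0, size=n)
        sign = rng.choice([-1.0, 1.0], size=n)
        if n_causal and config.signal_strength < 1.0:
            p[is_causal] = rng.beta(config.signal_strength, 1.0, size=n_causal)
            sign[is_causal] = causal_sign[is_causal]
        z = stats.norm.isf(p / 2.0)
        se = rng.uniform(0.02, 0.10, size=n)
        beta = sign * z * se
        a1 = rng.choice(alleles, size=n)
        a2 = rng.choice(alleles, size=n)
        studies[study] = pd.DataFrame({
            "snp": snps,
            "allele1": a1,
            "allele2": a2,
            "beta": beta,
            "se": se,
            "pvalue": p,
            "maf": rng.uniform(0.05, 0.5, size=n),
            "hwe_pvalue": rng.uniform(0.01, 1.0, size=n),
            "info": rng.uniform(0.6, 1.0, size=n),
            "call_rate": rng.uniform(0.8, 1.0, size=n),
        })
    stage_map = pd.DataFrame({
        "study": config.study_ids,
        "stage": [config.stage_of(s) for s in config.study_ids],
    })
    return studies, stage_map, truth


def simulate_network(
    config: SimConfig,
    superset_genes: Iterable[str],
    network_id: str = "net1",
    stream: int = 0,
) -> tuple[nx.DiGraph, SimTruth]:
    """A random DAG with planted hub drivers wired into ``superset_genes``.

    Nodes are laid out in a topological order with the planted drivers first;
    edges only ever point forward, so acyclicity holds by construction (and
    is re-checked before returning). Each planted driver receives
    ``hub_degree`` out-edges, a ``driver_superset_fraction`` share of which
    target superset genes; remaining nodes get sparse background wiring.
    """
    rng = config.rng(_STREAM_NETWORK + 100 * stream)
    if config.network_n_nodes > config.n_genes:
        raise ConfigurationError("network_n_nodes cannot exceed n_genes")
    superset_genes = set(superset_genes)
    drivers = list(config.planted_driver_ids)
    universe = [g for g in config.gene_ids if g not in drivers]
    in_superset = [g for g in universe if g in superset_genes]
    out_superset = [g for g in universe if g not in superset_genes]
    n_others = config.network_n_nodes - len(drivers)
    if n_others < 0:
        raise ConfigurationError("more planted drivers than network nodes")
    # include every available superset gene, fill the rest at random
    take_sup = in_superset[:n_others]
    n_fill = n_others - len(take_sup)
    pool = [g for g in out_superset] + in_superset[n_others:]
    fill = rng.choice(np.asarray(pool, dtype=object), size=n_fill,
                      replace=False).tolist() if n_fill else []
    others = take_sup + fill
    rng.shuffle(others)
    order = drivers + others

    graph = nx.DiGraph(network_id=network_id)
    graph.add_nodes_from(order)
    pos = {g: i for i, g in enumerate(order)}
    sup_later = np.asarray([g for g in others if g in superset_genes], dtype=object)
    bg_later = np.asarray([g for g in others if g not in superset_genes], dtype=object)
    for d in drivers:
        k_sup = min(int(round(config.hub_degree * config.driver_superset_fraction)),
                    len(sup_later))
        k_bg = min(config.hub_degree - k_sup, len(bg_later))
        targets = list(rng.choice(sup_later, size=k_sup, replace=False)) + \
            list(rng.choice(bg_later, size=k_bg, replace=False))
        graph.add_edges_from((d, t) for t in targets)
    for g in others:
        i = pos[g]
        later = order[i + 1:]
        if not later:
            continue
        k = min(int(rng.poisson(2.0)), len(later))
        if k:
            targets = rng.choice(np.asarray(later, dtype=object), size=k, replace=False)
            graph.add_edges_from((g, t) for t in targets)
    if not nx.is_directed_acyclic_graph(graph):  # pragma: no cover - by construction
        raise RuntimeError("internal error: generated network contains a cycle")
    truth = SimTruth(planted_key_drivers={network_id: list(drivers)})
    return graph, truth


def simulate_all(config: SimConfig, n_networks: int = 1) -> dict:
    """Run every generator and assemble a consistent bundle + SimTruth.

    Networks are planted around the first causal gene set when one exists,
    otherwise around the first generated set.
    """
    gene_sets = simulate_gene_sets(config)
    catalog = simulate_esnp_catalog(config)
    ld = simulate_ld_table(config)
    studies, stage_map, truth = simulate_gwas_studies(config, catalog, gene_sets)
    target_set = (config.planted_set_ids or tuple(gene_sets))[0]
    networks: dict[str, nx.DiGraph] = {}
    for i in range(n_networks):
        net_id = f"net{i + 1}"
        graph, net_truth = simulate_network(config, gene_sets[target_set], net_id, stream=i)
        networks[net_id] = graph
        truth.planted_key_drivers.update(net_truth.planted_key_drivers)
    return {
        "gene_sets": gene_sets,
        "catalog": catalog,
        "ld": ld,
        "studies": studies,
        "stage_map": stage_map,
        "networks": networks,
        "truth": truth,
    }


def write_simulation(bundle: dict, outdir: str | Path) -> None:
    """Serialize a simulate_all bundle to plain-text files under ``outdir``."""
    outdir = Path(outdir)
    io.write_gmt(bundle["gene_sets"], outdir / "gene_sets.gmt")
    io.write_tsv(bundle["catalog"], outdir / "eqtl.tsv")
    io.write_tsv(bundle["ld"], outdir / "ld.tsv")
    io.write_tsv(bundle["stage_map"], outdir / "stage_map.tsv")
    for study, df in bundle["studies"].items():
        io.write_tsv(df, outdir / "gwas" / f"{study}.tsv")
    for net_id, graph in bundle["networks"].items():
        edges = pd.DataFrame(graph.edges(), columns=["source", "target"])
        io.write_tsv(edges, outdir / "networks" / f"{net_id}.tsv")
    io.write_json(bundle["truth"].to_dict(), outdir / "truth.json")
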