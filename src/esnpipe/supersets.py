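"""Merging of overlapping gene sets into non-overlapping, trimmed supersets.

Pairwise overlap is measured by r = sqrt(r_AB * r_BA), the geometric mean of
the two directional shared-gene fractions; the geometric mean stays small
for nested sets of very different sizes, which discourages merging a small
set into a much larger one. Pairs must also share significantly more genes
than chance (one-sided Fisher test, Bonferroni-corrected). Significantly
overlapping sets are clustered (connected components, equivalent to
single-linkage at the zero-overlap cutoff), merged, and trimmed to a core
of the most-shared genes; the procedure runs for a fixed number of rounds
to push the maximum pairwise overlap below a threshold.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

SIZE_LIMIT = 200
MAX_OVERLAP = 0.20
N_ROUNDS = 2
OVERLAP_ALPHA = 0.05


@dataclass(frozen=True)
class OverlapRecord:
    set_a: str
    set_b: str
    r_ab: float
    r_ba: float
    p_overlap: float = 1.0
    significant_overlap: bool = False

    @property
    def r(self) -> float:
        return math.sqrt(self.r_ab * self.r_ba)

    @property
    def d(self) -> float:
        return 1.0 - self.r


@dataclass
class Superset:
    superset_id: str
    member_genes: list[str]
    constituent_sets: list[str]
    share_counts: dict[str, int] = field(default_factory=dict)
    annotation: list[str] = field(default_factory=lambda: ["Unknown"])


def overlap_ratio(genes_a, genes_b) -> tuple[float, float, float]:
    """(r_ab, r_ba, r) for two non-empty gene sets."""
    a, b = set(genes_a), set(genes_b)
    if not a or not b:
        raise ValueError("overlap_ratio requires non-empty gene sets")
    shared = len(a & b)
    r_ab = shared / len(a)
    r_ba = shared / len(b)
    return r_ab, r_ba, math.sqrt(r_ab * r_ba)


def overlap_significance(genes_a, genes_b, universe_size: int,
                         m_tests: int = 1,
                         alpha: float = OVERLAP_ALPHA) -> tuple[float, bool]:
    """One-sided hypergeometric p for the shared-gene count, Bonferroni-gated."""
    a, b = set(genes_a), set(genes_b)
    if universe_size < len(a | b):
        raise ValueError("universe smaller than the union of the two sets")
    shared = len(a & b)
    p = float(stats.hypergeom.sf(shared - 1, universe_size, len(a), len(b)))
    return p, p < alpha / max(m_tests, 1)


def compute_overlaps(gene_sets: dict, universe_size: int,
                     alpha: float = OVERLAP_ALPHA) -> list[OverlapRecord]:
    """All-pairs overlap records; Bonferroni m = number of pairs tested."""
    names = list(gene_sets)
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        r_ab, r_ba, _ = overlap_ratio(gene_sets[a], gene_sets[b])
        p, sig = overlap_significance(gene_sets[a], gene_sets[b],
                                      universe_size, m_tests=m, alpha=alpha)
        out.append(OverlapRecord(a, b, r_ab, r_ba, p, sig))
    return out


def cluster_overlaps(records: list[OverlapRecord],
                     names=None) -> list[set[str]]:
    """Connected components of the significant-overlap graph.

    Non-significant overlaps count as zero; an edge requires r > 0 and a
    significant Fisher test. Single-linkage clustering cut at the
    zero-overlap distance yields exactly these components. ``names`` may
    supply set labels that appear in no record (returned as singletons).
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for name in names or ():
        find(name)
    for rec in records:
        find(rec.set_a), find(rec.set_b)
        if rec.significant_overlap and rec.r > 0:
            parent[find(rec.set_a)] = find(rec.set_b)
    clusters: dict[str, set[str]] = {}
    for name in parent:
        clusters.setdefault(find(name), set()).add(name)
    return sorted(clusters.values(), key=lambda c: sorted(c)[0])


def trim_core(share_counts: dict[str, int], size_limit: int = SIZE_LIMIT,
              per_gene: bool = False) -> list[str]:
    """Keep the most-shared genes, trimming whole low-share strata.

    Strata (all genes at the current minimum share count) are removed as long
    as the remaining size stays >= size_limit; the removal that would drop
    below the limit is not performed. With ``per_gene=True`` genes are removed
    one at a time instead (lexicographic tie-break within a stratum), stopping
    exactly at the limit.
    """
    if any(c < 1 for c in share_counts.values()):
        raise ValueError("share counts must be >= 1")
    remaining = dict(share_counts)
    if len(remaining) <= size_limit:
        return sorted(remaining)
    if per_gene:
        order = sorted(remaining, key=lambda g: (remaining[g], g))
        return sorted(order[len(remaining) - size_limit:])
    while True:
        low = min(remaining.values())
        stratum = [g for g, c in remaining.items() if c == low]
        if len(remaining) - len(stratum) < size_limit:
            break
        for g in stratum:
            del remaining[g]
    return sorted(remaining)


def _share_counts(member_sets: list[set[str]]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for genes in member_sets:
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return counts


def build_supersets(
    gene_sets: dict,
    universe_size: int,
    size_limit: int = SIZE_LIMIT,
    max_overlap: float = MAX_OVERLAP,
    n_rounds: int = N_ROUNDS,
    alpha: float = OVERLAP_ALPHA,
) -> list[Superset]:
    """Iteratively merge/trim overlapping gene sets into supersets.

    Each round recomputes pairwise overlaps among the current sets, clusters
    the significantly overlapping ones, merges each cluster and trims it to
    ``size_limit`` genes by share count (counted over the original
    constituent sets). A warning is emitted if the maximum pairwise overlap
    is still >= ``max_overlap`` after ``n_rounds`` rounds.
    """
    if not gene_sets:
        raise ValueError("build_supersets needs at least one input set")
    originals = {name: set(genes) for name, genes in gene_sets.items()}
    current: dict[str, Superset] = {
        name: Superset(name, sorted(genes), [name],
                       share_counts={g: 1 for g in genes})
        for name, genes in originals.items()
    }
    for _ in range(n_rounds):
        sets_now = {name: set(ss.member_genes) for name, ss in current.items()}
        records = compute_overlaps(sets_now, universe_size, alpha=alpha)
        clusters = cluster_overlaps(records, names=sets_now)
        merged: dict[str, Superset] = {}
        for i, cluster in enumerate(clusters):
            members = sorted(cluster)
            if len(members) == 1:
                ss = current[members[0]]
                merged[ss.superset_id] = ss
                continue
            constituents = sorted({
                c for name in members for c in current[name].constituent_sets})
            pool = set().union(*(set(current[m].member_genes) for m in members))
            counts = _share_counts([originals[c] & pool for c in constituents])
            core = trim_core(counts, size_limit=size_limit)
            sid = f"superset_{members[0]}"
            merged[sid] = Superset(sid, core, constituents,
                                   share_counts={g: counts[g] for g in core})
        current = merged
    supersets = sorted(current.values(), key=lambda s: s.superset_id)
    worst = 0.0
    for a, b in itertools.combinations(supersets, 2):
        _, _, r = overlap_ratio(a.member_genes, b.member_genes)
        worst = max(worst, r)
    if worst >= max_overlap:
        warnings.warn(
            f"maximum pairwise overlap {worst:.3f} still >= {max_overlap} "
            f"after {n_rounds} round(s)", stacklevel=2)
    return supersets


def annotate_superset(superset: Superset, reference_categories: dict,
                      universe_size: int | None = None,
                      alpha: float = OVERLAP_ALPHA) -> list[str]:
    """Bonferroni-significant over-represented categories, else ["Unknown"].

    The default annotation universe is the union of all category genes.
    """
    if not reference_categories:
        raise ValueError("reference categories must be non-empty")
    if universe_size is None:
        universe = set().union(*(set(g) for g in reference_categories.values()))
        universe_size = len(universe | set(superset.member_genes))
    m = len(reference_categories)
    genes = set(superset.member_genes)
    hits = []
    for name, cat in reference_categories.items():
        cat = set(cat)
        shared = len(genes & cat)
        p = float(stats.hypergeom.sf(shared - 1, universe_size, len(cat), len(genes)))
        if p < alpha / m:
            hits.append((p, name))
    labels = [name for _, name in sorted(hits)] or ["Unknown"]
    superset.annotation = labels
    return labels
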