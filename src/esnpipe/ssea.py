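"""SNP-set enrichment analysis (SSEA) of GWAS p-values over eSNP sets.

Each gene set's eSNPs are compared against the LD-pruned tissue background:
a one-sided Kolmogorov-Smirnov test on the background-rank fractions of the
set members (sensitive to many weak signals) and a one-sided Fisher exact
test for over-representation among the top 5% of background SNPs (sensitive
to a few strong signals). The enrichment score is the mean of the two
-log10 p-values. False discovery rates are estimated by permuting the
assignment of GWAS p-values across the background while keeping set
memberships intact, and a set is called significant when FDR < 20% in both
independent stages and < 5% in the combined stage.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .esnp_catalog import EsnpSet, build_background, map_gene_sets

TOP_FRACTION = 0.05
STAGE_FDR_MAX = 0.20
COMBINED_FDR_MAX = 0.05
N_PERM_DEFAULT = 1000
P_FLOOR = 1e-300
BONFERRONI_M_CONFIRM = 3539  # original gene-set count used for the confirmatory round

STAGES = ("stage1", "stage2", "combined")


def expected_combined_fdr(stage_fdr_1: float = STAGE_FDR_MAX,
                          stage_fdr_2: float = STAGE_FDR_MAX) -> float:
    """Expected FDR when two independent stages are thresholded separately.

    Independence makes the combined rate the product of the two stage-level
    thresholds (0.20 * 0.20 = 0.04).
    """
    return stage_fdr_1 * stage_fdr_2


def _as_snp_set(obj) -> frozenset:
    return obj.snp_ids if isinstance(obj, EsnpSet) else frozenset(obj)


def _background_fracs(background_snps: list[str], gwas_p: dict) -> np.ndarray:
    p = np.array([gwas_p[s] for s in background_snps], dtype=float)
    ranks = stats.rankdata(p, method="average")
    return ranks / len(p)


def ks_enrichment(set_snps, gwas_p, background, mode: str = "one_sample") -> float:
    """One-sided K-S p-value for set members having low GWAS p-values.

    Set members are placed on the background p-value ranking; their rank
    fractions (in (0, 1]) are tested against Uniform(0, 1) with the
    alternative that they are stochastically smaller. ``mode="two_sample"``
    instead compares the set fractions against the background complement.
    Sets with fewer than 2 SNPs return 1.0 with a warning.
    """
    bg = sorted(_as_snp_set(background))
    members = _as_snp_set(set_snps)
    if not members <= set(bg):
        raise ValueError("set SNPs must be a subset of the background")
    fracs = _background_fracs(bg, gwas_p)
    in_set = np.array([s in members for s in bg])
    sample = fracs[in_set]
    if sample.size < 2:
        warnings.warn("eSNP set has fewer than 2 SNPs; K-S p set to 1", stacklevel=2)
        return 1.0
    if mode == "one_sample":
        res = stats.ks_1samp(sample, stats.uniform.cdf, alternative="greater")
    elif mode == "two_sample":
        rest = fracs[~in_set]
        res = stats.ks_2samp(sample, rest, alternative="greater")
    else:
        raise ValueError(f"unknown K-S mode {mode!r}")
    return float(res.pvalue)


def _top_set(background_snps: list[str], gwas_p: dict, top_fraction: float) -> set[str]:
    n_top = math.ceil(top_fraction * len(background_snps))
    order = sorted(background_snps, key=lambda s: (gwas_p[s], s))
    return set(order[:n_top])


def fisher_top_enrichment(set_snps, gwas_p, background,
                          top_fraction: float = TOP_FRACTION) -> float:
    """One-sided Fisher exact p for over-representation in the top stratum.

    The top stratum T holds the ceil(top_fraction * N) background SNPs with
    the smallest GWAS p (ties broken by snp_id); the returned p-value is the
    hypergeometric upper tail P(X >= |set ∩ T|).
    """
    bg = sorted(_as_snp_set(background))
    members = _as_snp_set(set_snps)
    if not members <= set(bg):
        raise ValueError("set SNPs must be a subset of the background")
    top = _top_set(bg, gwas_p, top_fraction)
    hits = len(members & top)
    return float(stats.hypergeom.sf(hits - 1, len(bg), len(top), len(members)))


def enrichment_score(p_ks: float, p_fisher: float) -> float:
    """Mean of the two -log10 p-values; p <= 0 is clamped to 1e-300."""
    ps = []
    for p in (p_ks, p_fisher):
        if p <= 0:
            warnings.warn("p-value of 0 clamped to 1e-300 before log", stacklevel=2)
            p = P_FLOOR
        ps.append(max(p, P_FLOOR))
    return float(0.5 * (-np.log10(ps[0]) - np.log10(ps[1])))


def multi_stage_call(fdr1: float, fdr2: float, fdr12: float) -> bool:
    """Strict thresholds: FDR < 20% in each stage and < 5% combined."""
    return fdr1 < STAGE_FDR_MAX and fdr2 < STAGE_FDR_MAX and fdr12 < COMBINED_FDR_MAX


def _hypergeom_sf(hits: np.ndarray, n_total: int, n_top: int,
                  sizes: np.ndarray) -> np.ndarray:
    """Vectorized exact P(X >= hits) for X ~ Hypergeom(n_total, n_top, size).

    Builds one tail table per distinct set size from log-gamma pmf terms
    (summed from the largest support value down, so small tail terms
    accumulate accurately). Much faster than scipy's hypergeom.sf when
    called thousands of times per permutation with shared margins.
    """
    hits = np.asarray(hits, dtype=np.intp)
    sizes = np.asarray(sizes, dtype=np.intp)
    out = np.ones(len(sizes))
    uniq = np.unique(sizes)
    kmax = int(min(n_top, uniq.max() if uniq.size else 0))
    ks = np.arange(kmax + 1)
    for n in uniq:
        hi = min(n, n_top)
        lo = max(0, n_top + n - n_total)
        k = ks[: hi + 1]
        logpmf = (special.gammaln(n_top + 1) - special.gammaln(k + 1)
                  - special.gammaln(n_top - k + 1)
                  + special.gammaln(n_total - n_top + 1)
                  - special.gammaln(n - k + 1)
                  - special.gammaln(n_total - n_top - (n - k) + 1)
                  - special.gammaln(n_total + 1) + special.gammaln(n + 1)
                  + special.gammaln(n_total - n + 1))
        pmf = np.exp(logpmf)
        if lo > 0:
            pmf[:lo] = 0.0
        sf = np.cumsum(pmf[::-1])[::-1]  # sf[k] = P(X >= k)
        mask = sizes == n
        # hits can never exceed min(size, n_top); clip guards k = 0 only
        h = np.clip(hits[mask], 0, hi)
        out[mask] = np.minimum(sf[h], 1.0)
    return out


class SseaIndex:
    """Flat membership index over a fixed background for batch scoring.

    Holds set memberships as index arrays into the sorted background so that
    the scores of every set can be recomputed for a permuted p-assignment
    with a handful of vectorized operations (used by the permutation FDR,
    where thousands of set scores are needed per permutation).
    """

    def __init__(self, background, esnp_sets: dict):
        self.background = sorted(_as_snp_set(background))
        self.n_background = len(self.background)
        pos = {s: i for i, s in enumerate(self.background)}
        self.set_names = list(esnp_sets)
        members = []
        for name in self.set_names:
            snps = _as_snp_set(esnp_sets[name])
            if not snps <= pos.keys():
                raise ValueError(f"set {name!r} has SNPs outside the background")
            members.append(np.array(sorted(pos[s] for s in snps), dtype=np.intp))
        self.sizes = np.array([m.size for m in members], dtype=np.intp)
        self.offsets = np.concatenate([[0], np.cumsum(self.sizes)])
        self.flat = (np.concatenate(members) if members else
                     np.empty(0, dtype=np.intp))
        self._scorable = self.sizes >= 2
        nz = self._scorable.nonzero()[0]
        self._nz_sizes = self.sizes[nz]
        self._nz_offsets = np.concatenate([[0], np.cumsum(self._nz_sizes)])
        self._nz_flat = (np.concatenate([members[i] for i in nz]) if nz.size else
                         np.empty(0, dtype=np.intp))
        self._nz_pos_frac = (
            (np.arange(self._nz_flat.size) -
             np.repeat(self._nz_offsets[:-1], self._nz_sizes) + 1.0) /
            np.repeat(self._nz_sizes, self._nz_sizes)
        ) if self._nz_flat.size else np.empty(0)
        self._nz_keys = 2.0 * np.repeat(np.arange(nz.size), self._nz_sizes)

    def stats_for(self, gwas_p: dict, top_fraction: float = TOP_FRACTION):
        """(rank fractions, top-stratum mask, |T|) aligned to the background."""
        fracs = _background_fracs(self.background, gwas_p)
        top = _top_set(self.background, gwas_p, top_fraction)
        mask = np.array([s in top for s in self.background])
        return fracs, mask, len(top)

    def batch_scores(self, fracs: np.ndarray, top_mask: np.ndarray,
                     n_top: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(p_ks, p_fisher, score) per set for one p-value assignment."""
        n_sets = len(self.set_names)
        p_ks = np.ones(n_sets)
        if self._nz_flat.size:
            vals = fracs[self._nz_flat]
            order = np.argsort(self._nz_keys + vals, kind="stable")
            dplus_elem = self._nz_pos_frac - vals[order]
            dplus = np.maximum.reduceat(dplus_elem, self._nz_offsets[:-1])
            p = special.smirnov(self._nz_sizes, np.clip(dplus, 0.0, 1.0))
            p_ks[self._scorable] = p
        hits = np.zeros(n_sets, dtype=np.intp)
        if self.flat.size:
            contrib = top_mask[self.flat].astype(np.intp)
            nonempty = self.sizes > 0
            hits[nonempty] = np.add.reduceat(
                contrib, self.offsets[:-1][nonempty])
        p_fisher = _hypergeom_sf(hits, self.n_background, n_top, self.sizes)
        scores = 0.5 * (-np.log10(np.maximum(p_ks, P_FLOOR))
                        - np.log10(np.maximum(p_fisher, P_FLOOR)))
        return p_ks, p_fisher, scores


def permutation_fdr(
    observed_scores: np.ndarray,
    index: SseaIndex,
    gwas_p: dict,
    n_perm: int = N_PERM_DEFAULT,
    seed: int | np.random.Generator = 0,
    permute: bool = True,
    top_fraction: float = TOP_FRACTION,
) -> np.ndarray:
    """Permutation FDR at each observed score, pooled across the run's sets.

    Per permutation the GWAS p-values are reassigned uniformly at random
    across the background SNPs and all set scores are recomputed; the FDR at
    threshold s is mean_perm[#permuted scores >= s] / [#observed scores >= s],
    capped at 1. A monotone (running-minimum over laxer thresholds) envelope
    is applied so the estimate is non-increasing in the score threshold.
    ``permute=False`` keeps the identity assignment (useful for calibration
    checks: every achieved score then gets FDR 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = np.asarray(observed_scores, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fracs, top_mask, n_top = index.stats_for(gwas_p, top_fraction)
    order = np.argsort(observed, kind="stable")
    thresholds = observed[order]
    # observed count at >= s_i over the ascending thresholds
    denom = len(observed) - np.searchsorted(thresholds, thresholds, side="left")
    num = np.zeros(len(observed))
    for _ in range(n_perm):
        perm = rng.permutation(index.n_background) if permute \
            else np.arange(index.n_background)
        _, _, scores = index.batch_scores(fracs[perm], top_mask[perm], n_top)
        scores.sort()
        num += len(scores) - np.searchsorted(scores, thresholds, side="left")
    raw = np.minimum((num / n_perm) / denom, 1.0)
    mono = np.minimum.accumulate(raw)
    fdr = np.empty_like(mono)
    fdr[order] = mono
    return fdr


def run_ssea(
    gene_sets: dict,
    records: pd.DataFrame,
    ld: pd.DataFrame,
    meta_tables: dict[str, pd.DataFrame],
    tissues=("all",),
    n_perm: int = N_PERM_DEFAULT,
    seed: int = 0,
    r2_max: float = 0.7,
    top_fraction: float = TOP_FRACTION,
    ks_mode: str = "one_sample",
) -> pd.DataFrame:
    """Full SSEA over (gene set, tissue) pairs and all three GWAS stages.

    ``meta_tables`` must provide "stage1", "stage2" and "combined" tables
    (columns snp, pvalue). The background per tissue is the LD-pruned eSNP
    pool restricted to SNPs with a meta p-value in all three stages; the
    reported p_ks/p_fisher/score come from the combined stage, with one FDR
    column per stage and the multi-stage significance call.
    """
    for stage in STAGES:
        if stage not in meta_tables:
            raise ValueError(f"missing meta table for {stage!r}")
    stage_p = {
        stage: dict(zip(meta_tables[stage]["snp"], meta_tables[stage]["pvalue"]))
        for stage in STAGES
    }
    covered = set.intersection(*(set(p) for p in stage_p.values()))
    rows = []
    for t_i, tissue in enumerate(tissues):
        background = build_background(records, ld, tissue, r2_max=r2_max)
        bg_snps = background.snp_ids & covered
        if not bg_snps:
            raise ValueError(f"no background eSNPs with GWAS coverage for {tissue!r}")
        esnp_sets = {
            name: _as_snp_set(s) & bg_snps
            for name, s in map_gene_sets(gene_sets, records, background).items()
        }
        index = SseaIndex(bg_snps, esnp_sets)
        stage_scores = {}
        stage_fdr = {}
        for s_i, stage in enumerate(STAGES):
            fracs, mask, n_top = index.stats_for(stage_p[stage], top_fraction)
            p_ks, p_fisher, scores = index.batch_scores(fracs, mask, n_top)
            stage_scores[stage] = (p_ks, p_fisher, scores)
            rng = np.random.default_rng([seed, t_i, s_i])
            stage_fdr[stage] = permutation_fdr(
                scores, index, stage_p[stage], n_perm=n_perm, seed=rng,
                top_fraction=top_fraction)
        p_ks, p_fisher, scores = stage_scores["combined"]
        for i, name in enumerate(index.set_names):
            fdr1 = stage_fdr["stage1"][i]
            fdr2 = stage_fdr["stage2"][i]
            fdr12 = stage_fdr["combined"][i]
            rows.append({
                "set": name,
                "tissue": tissue,
                "n_esnps": int(index.sizes[i]),
                "p_ks": p_ks[i],
                "p_fisher": p_fisher[i],
                "score": scores[i],
                "fdr_stage1": fdr1,
                "fdr_stage2": fdr2,
                "fdr_combined": fdr12,
                "significant": multi_stage_call(fdr1, fdr2, fdr12),
            })
    return pd.DataFrame(rows)


def bonferroni_confirm(pvalues, m: int = BONFERRONI_M_CONFIRM) -> np.ndarray:
    """Significance mask for the confirmatory superset round (p < 0.05/m)."""
    return np.asarray(pvalues, dtype=float) < 0.05 / m
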