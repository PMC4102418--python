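"""Independent brute-force oracles shared across test modules.

These deliberately avoid the code paths they are used to check: tail sums
are computed by direct enumeration with exact binomial coefficients.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd


def hypergeom_upper_tail(k: int, n_total: int, n_marked: int, n_drawn: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N=n_total, K=n_marked, n=n_drawn).

    Exact enumeration over the support using integer binomials.
    """
    lo = max(k, 0, n_marked + n_drawn - n_total)
    hi = min(n_marked, n_drawn)
    if lo > hi:
        return 0.0
    total = comb(n_total, n_drawn)
    acc = 0
    for x in range(lo, hi + 1):
        acc += comb(n_marked, x) * comb(n_total - n_marked, n_drawn - x)
    return acc / total


def fixed_effect_loop(betas, ses) -> tuple[float, float]:
    """Plain-loop inverse-variance weighted mean and its standard error."""
    num = 0.0
    den = 0.0
    for b, s in zip(betas, ses):
        w = 1.0 / (s * s)
        num += w * b
        den += w
    return num / den, den ** -0.5


def dl_tau2_two_study(b1, b2, s1, s2) -> float:
    """Closed-form DerSimonian-Laird tau^2 for exactly two studies."""
    w1, w2 = 1.0 / s1**2, 1.0 / s2**2
    fe = (w1 * b1 + w2 * b2) / (w1 + w2)
    q = w1 * (b1 - fe) ** 2 + w2 * (b2 - fe) ** 2
    denom = (w1 + w2) - (w1**2 + w2**2) / (w1 + w2)
    return max(0.0, (q - 1.0) / denom)


def toy_study(snps, maf=0.3, hwe=0.5, info=0.9, call_rate=0.95,
              beta=0.1, se=0.1, pvalue=0.5) -> pd.DataFrame:
    """A well-formed single-study GWAS table with uniform defaults."""
    n = len(snps)

    def col(v):
        return list(v) if np.ndim(v) else [v] * n

    return pd.DataFrame({
        "snp": list(snps),
        "allele1": ["A"] * n,
        "allele2": ["C"] * n,
        "beta": col(beta),
        "se": col(se),
        "pvalue": col(pvalue),
        "maf": col(maf),
        "hwe_pvalue": col(hwe),
        "info": col(info),
        "call_rate": col(call_rate),
    })


def eqtl_records(rows) -> pd.DataFrame:
    """Rows of (snp, gene, tissue, study, expr_pvalue, cis_trans)."""
    return pd.DataFrame(
        rows, columns=["snp", "gene", "tissue", "study", "expr_pvalue", "cis_trans"])


def ld_table(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])
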