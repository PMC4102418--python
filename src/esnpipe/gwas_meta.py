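"""QC filtering and staged inverse-variance meta-analysis of GWAS summaries.

Per-study records are filtered on MAF, Hardy-Weinberg p, imputation quality
and call rate; SNPs must additionally be present in a minimum number of
studies per stage. Each stage (1, 2 and the combined 1+2 meta-cohort) is
then meta-analyzed with a fixed-effect inverse-variance model, switching to
DerSimonian-Laird random effects for SNPs whose Cochran Q heterogeneity
p-value falls below a gate (default 1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FormatError, require_columns

QC_COLUMNS = ["snp", "beta", "se", "pvalue", "maf", "hwe_pvalue", "info", "call_rate"]

MAF_MIN = 0.01
HWE_P_MIN = 1e-4
INFO_MIN = 0.5
CALL_RATE_MIN = 0.75
HET_GATE_P = 1e-4
STAGE_MIN_COUNTS = (3, 5)


@dataclass
class QCResult:
    records: pd.DataFrame          # long table (study, stage, snp, beta, se, ...)
    stage_snps: dict[int, set[str]]  # SNPs passing the per-stage presence filter
    exclusions: pd.DataFrame       # (study, snp, reason)

    @property
    def combined_snps(self) -> set[str]:
        """Union semantics for the Stage 1+2 meta-cohort."""
        return self.stage_snps[1] | self.stage_snps[2]


def qc_filter_snps(
    studies: dict[str, pd.DataFrame],
    stage_map: dict[str, int],
    stage_min_counts: tuple[int, int] = STAGE_MIN_COUNTS,
    maf_min: float = MAF_MIN,
    hwe_p_min: float = HWE_P_MIN,
    info_min: float = INFO_MIN,
    call_rate_min: float = CALL_RATE_MIN,
) -> QCResult:
    """Apply per-record QC thresholds and per-stage presence filters.

    Records with maf < maf_min, hwe_pvalue < hwe_p_min, info < info_min or
    call_rate < call_rate_min are dropped (first failing rule recorded as the
    exclusion reason). A SNP is then kept for a stage only if it survives in
    at least ``stage_min_counts[stage-1]`` of that stage's studies.
    """
    frames = []
    excluded = []
    for study_id, df in studies.items():
        require_columns(df, QC_COLUMNS, what=f"study {study_id}")
        if study_id not in stage_map:
            raise FormatError(f"study {study_id} missing from the stage map")
        df = df.copy()
        reasons = pd.Series("", index=df.index, dtype=object)
        for reason, bad in [
            ("maf", df["maf"] < maf_min),
            ("hwe", df["hwe_pvalue"] < hwe_p_min),
            ("info", df["info"] < info_min),
            ("call_rate", df["call_rate"] < call_rate_min),
        ]:
            reasons[bad & (reasons == "")] = reason
        bad_mask = reasons != ""
        for snp, reason in zip(df.loc[bad_mask, "snp"], reasons[bad_mask]):
            excluded.append((study_id, snp, reason))
        df = df[~bad_mask].copy()
        df["study"] = study_id
        df["stage"] = stage_map[study_id]
        frames.append(df)
    records = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=QC_COLUMNS + ["study", "stage"])

    stage_snps: dict[int, set[str]] = {}
    for stage, min_count in zip((1, 2), stage_min_counts):
        sub = records[records["stage"] == stage]
        counts = sub.groupby("snp", sort=False).size()
        keep = set(counts[counts >= min_count].index)
        stage_snps[stage] = keep
        for snp in set(counts.index) - keep:
            excluded.append((f"stage{stage}", snp, "presence"))
    exclusions = pd.DataFrame(excluded, columns=["study", "snp", "reason"])
    return QCResult(records=records, stage_snps=stage_snps, exclusions=exclusions)


def fixed_effect_meta(betas, ses) -> tuple[float, float, float]:
    """Inverse-variance weighted fixed-effect pooling.

    Returns (beta_meta, se_meta, two-sided normal p).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("fixed_effect_meta needs at least one study")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta_meta = float(np.sum(w * betas) / np.sum(w))
    se_meta = float(np.sum(w) ** -0.5)
    z = beta_meta / se_meta
    pvalue = float(2.0 * stats.norm.sf(abs(z)))
    return beta_meta, se_meta, pvalue


def heterogeneity_stats(betas, ses) -> tuple[float, int, float, float]:
    """Cochran's Q, its degrees of freedom and p-value, and I².

    I² = max(0, (Q - df) / Q), the proportion of variation attributed to
    between-study heterogeneity (0 when Q == 0).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size < 2:
        raise ValueError("heterogeneity requires at least two studies")
    beta_fe, _, _ = fixed_effect_meta(betas, ses)
    w = 1.0 / ses**2
    q = float(np.sum(w * (betas - beta_fe) ** 2))
    df = betas.size - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return q, df, p_q, i2


def random_effects_meta(betas, ses) -> tuple[float, float, float, float]:
    """DerSimonian-Laird random-effects pooling.

    τ² = max(0, (Q - df) / (Σw - Σw²/Σw)) with fixed-effect weights w;
    pooling then uses weights 1 / (se² + τ²). Returns
    (beta_meta, se_meta, pvalue, tau2).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size < 2:
        raise ValueError("random_effects_meta requires at least two studies")
    q, df, _, _ = heterogeneity_stats(betas, ses)
    w = 1.0 / ses**2
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (ses**2 + tau2)
    beta_meta = float(np.sum(w_star * betas) / np.sum(w_star))
    se_meta = float(np.sum(w_star) ** -0.5)
    pvalue = float(2.0 * stats.norm.sf(abs(beta_meta / se_meta)))
    return beta_meta, se_meta, pvalue, tau2


def _meta_table(records: pd.DataFrame, snps: set[str], het_gate_p: float) -> pd.DataFrame:
    """Vectorized per-SNP meta over a long record table restricted to ``snps``."""
    sub = records[records["snp"].isin(snps)]
    if sub.empty:
        return pd.DataFrame(columns=[
            "snp", "n_studies", "beta", "se", "pvalue", "q", "i2", "tau2", "model"])
    beta = sub.pivot(index="snp", columns="study", values="beta")
    se = sub.pivot(index="snp", columns="study", values="se")
    b = beta.to_numpy(dtype=float)
    s = se.to_numpy(dtype=float)
    present = ~np.isnan(b)
    k = present.sum(axis=1)
    w = np.where(present, 1.0 / s**2, 0.0)
    sw = w.sum(axis=1)
    bm = np.nansum(np.where(present, w * b, 0.0), axis=1) / sw
    sem = sw**-0.5
    diff = np.where(present, b - bm[:, None], 0.0)
    q = np.sum(w * diff**2, axis=1)
    df_ = k - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        p_q = np.where(k >= 2, stats.chi2.sf(q, np.maximum(df_, 1)), np.nan)
        i2 = np.where((k >= 2) & (q > 0), np.maximum(0.0, (q - df_) / q), 0.0)
    # DerSimonian-Laird for SNPs behind the heterogeneity gate
    random_mask = (k >= 2) & (p_q < het_gate_p)
    tau2 = np.zeros(len(bm))
    if random_mask.any():
        sw2 = (w**2).sum(axis=1)
        denom = sw - sw2 / sw
        with np.errstate(divide="ignore", invalid="ignore"):
            t2 = np.where(denom > 0, np.maximum(0.0, (q - df_) / denom), 0.0)
        tau2[random_mask] = t2[random_mask]
        w_star = np.where(present, 1.0 / (s**2 + tau2[:, None]), 0.0)
        sw_star = w_star.sum(axis=1)
        bm_star = np.nansum(np.where(present, w_star * b, 0.0), axis=1) / sw_star
        sem_star = sw_star**-0.5
        bm = np.where(random_mask, bm_star, bm)
        sem = np.where(random_mask, sem_star, sem)
    pvalue = 2.0 * stats.norm.sf(np.abs(bm / sem))
    out = pd.DataFrame({
        "snp": beta.index,
        "n_studies": k,
        "beta": bm,
        "se": sem,
        "pvalue": pvalue,
        "q": np.where(k >= 2, q, np.nan),
        "i2": np.where(k >= 2, i2, np.nan),
        "tau2": tau2,
        "model": np.where(random_mask, "random", "fixed"),
    })
    return out.sort_values("snp", kind="stable").reset_index(drop=True)


def run_stage_meta(
    studies: dict[str, pd.DataFrame],
    stage_map: dict[str, int],
    het_gate_p: float = HET_GATE_P,
    stage_min_counts: tuple[int, int] = STAGE_MIN_COUNTS,
    qc: QCResult | None = None,
) -> dict[str, pd.DataFrame]:
    """Produce meta tables for "stage1", "stage2" and "combined".

    QC (per-record thresholds + stage presence counts) is applied first
    unless a precomputed :class:`QCResult` is given. The combined table
    covers the union of SNPs passing the presence filter in either stage,
    pooling the records of every stage in which the SNP passed.
    """
    if qc is None:
        qc = qc_filter_snps(studies, stage_map, stage_min_counts=stage_min_counts)
    records = qc.records
    tables = {}
    for stage in (1, 2):
        sub = records[records["stage"] == stage]
        tables[f"stage{stage}"] = _meta_table(sub, qc.stage_snps[stage], het_gate_p)
    # combined: per stage, keep only records of SNPs that passed that stage
    keep = pd.Series(False, index=records.index)
    for stage in (1, 2):
        keep |= (records["stage"] == stage) & records["snp"].isin(qc.stage_snps[stage])
    tables["combined"] = _meta_table(records[keep], qc.combined_snps, het_gate_p)
    return tables
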