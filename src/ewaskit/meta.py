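"""Fixed-effects inverse-variance meta-analysis across cohorts.

Per probe: pooled estimate beta = sum(w_i b_i) / sum(w_i) with weights
w_i = 1 / se_i^2, pooled SE = sum(w_i)^(-1/2), two-sided p from the
standard normal z. Heterogeneity via Cochran's Q (chi-square tail on k-1
df) and I^2 = max(0, (Q - (k-1)) / Q) * 100; probes with strong evidence
for heterogeneity (Qp below a cutoff AND I^2 above a cutoff) are flagged
and excluded from the significance calls. Multiple testing uses both a
Bonferroni threshold and the Benjamini-Hochberg FDR; calibration of the
scan is summarised by the genomic inflation factor lambda, the ratio of
the median observed chi-square(1) statistic to its null median 0.4549364.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ProbeManifest, ValidationError
from .ewas import CohortResult

logger = logging.getLogger(__name__)

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...

META_COLUMNS = [
    "beta_meta",
    "se_meta",
    "z",
    "p",
    "k",
    "Q",
    "Qp",
    "I2",
    "het_excluded",
    "bonferroni_sig",
    "fdr_q",
    "fdr_sig",
    "novel_epic_only",
    "novel_gene",
]


@dataclass
class MetaResult:
    """Pooled per-probe results plus scan-level summary numbers."""

    table: pd.DataFrame
    lambda_inflation: float
    bonferroni_threshold: float
    fdr_level: float
    n_meta_analyzed: int

    @property
    def dmp_probes(self) -> pd.Index:
        """Bonferroni-significant, heterogeneity-clean probes."""
        t = self.table
        return t.index[t["bonferroni_sig"] & ~t["het_excluded"]]

    @property
    def fdr_probes(self) -> pd.Index:
        t = self.table
        return t.index[t["fdr_sig"] & ~t["het_excluded"]]

    def summary(self) -> dict:
        t = self.table
        return {
            "n_meta_analyzed": int(self.n_meta_analyzed),
            "lambda": float(self.lambda_inflation),
            "bonferroni_threshold": float(self.bonferroni_threshold),
            "n_bonferroni_dmps": int(len(self.dmp_probes)),
            "n_fdr_dmps": int(len(self.fdr_probes)),
            "n_het_excluded": int(t["het_excluded"].sum()),
            "n_novel_epic_only_dmps": int(
                t.loc[self.dmp_probes, "novel_epic_only"].sum()
            ),
        }


def ivw_pool(estimates, ses):
    """Inverse-variance weighted fixed-effects pooling of one probe.

    Returns (beta_meta, se_meta, z, p). All SEs must be positive and
    finite; a single study passes through unchanged.
    """
    b = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValidationError("nothing to pool")
    if not (np.isfinite(b).all() and np.isfinite(s).all() and (s > 0).all()):
        raise ValidationError("non-finite estimate or non-positive SE")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return beta, se, z, max(p, np.nextafter(0, 1))


def heterogeneity(estimates, ses, beta_meta: float):
    """Cochran's Q, its chi-square tail p on k-1 df, and I^2 (percent)."""
    b = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    k = b.size
    if k < 2:
        return np.nan, np.nan, np.nan
    w = 1.0 / s**2
    q = float(np.sum(w * (b - beta_meta) ** 2))
    qp = float(stats.chi2.sf(q, k - 1))
    i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    return q, qp, i2


def genomic_lambda(pvalues) -> float:
    """Genomic inflation factor from a vector of at least 100 p-values."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 100:
        raise ValidationError(f"need >= 100 p-values, got {p.size}")
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_1_MEDIAN)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test p threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return alpha / m


def run_meta(
    cohort_results: list[CohortResult],
    manifest: ProbeManifest,
    het_qp: float = 0.10,
    het_i2: float = 50.0,
    alpha: float = 0.05,
    fdr_level: float = 0.01,
    nominal_m: int | None = None,
) -> MetaResult:
    """Pool per-cohort scans into a MetaResult.

    Probes are pooled over the cohorts where they were successfully fitted;
    probes present in fewer than two cohorts are reported with k = 1 but
    carry no heterogeneity statistics. The Bonferroni denominator defaults
    to the realized number of pooled probes; ``nominal_m`` forces a nominal
    count (e.g. a round array size) instead. Novelty flags come from the
    manifest: ``novel_epic_only`` marks probes absent from the older array,
    and ``novel_gene`` additionally requires the probe's gene to carry no
    previously reported signal.
    """
    if len(cohort_results) < 2:
        raise ValidationError("need >= 2 cohort results")
    est = pd.concat(
        [r.table["estimate"].rename(i) for i, r in enumerate(cohort_results)], axis=1
    )
    ses = pd.concat(
        [r.table["se"].rename(i) for i, r in enumerate(cohort_results)], axis=1
    )
    valid = est.notna() & ses.notna() & (ses > 0)
    k = valid.sum(axis=1)
    if (k >= 2).sum() == 0:
        raise ValidationError("no probe is shared by >= 2 cohorts")

    b = est.to_numpy(dtype=float)
    s = ses.to_numpy(dtype=float)
    w = np.where(valid.to_numpy(), 1.0 / s**2, 0.0)
    bw = np.where(valid.to_numpy(), b, 0.0)
    wsum = w.sum(axis=1)
    beta_meta = np.where(wsum > 0, (w * bw).sum(axis=1) / np.where(wsum > 0, wsum, 1), np.nan)
    se_meta = np.where(wsum > 0, 1.0 / np.sqrt(np.where(wsum > 0, wsum, 1)), np.nan)
    z = beta_meta / se_meta
    p = np.clip(2 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)

    q = (w * (bw - beta_meta[:, None]) ** 2).sum(axis=1)
    kv = k.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        qp = np.where(kv >= 2, stats.chi2.sf(q, np.maximum(kv - 1, 1)), np.nan)
        i2 = np.where(
            kv >= 2, np.maximum(0.0, (q - (kv - 1)) / np.where(q > 0, q, 1)) * 100.0, np.nan
        )
    q = np.where(kv >= 2, q, np.nan)

    het_excluded = (qp < het_qp) & (i2 > het_i2)
    het_excluded = np.where(np.isnan(qp), False, het_excluded)

    table = pd.DataFrame(
        {
            "beta_meta": beta_meta,
            "se_meta": se_meta,
            "z": z,
            "p": p,
            "k": kv,
            "Q": q,
            "Qp": qp,
            "I2": i2,
            "het_excluded": het_excluded.astype(bool),
        },
        index=est.index,
    )
    table = table.loc[table["k"] >= 1].copy()
    if (table["k"] == 1).any():
        logger.info(
            "%d probes present in a single cohort are reported but flagged",
            int((table["k"] == 1).sum()),
        )

    m = int(nominal_m) if nominal_m else len(table)
    thr = bonferroni_threshold(alpha, m)
    table["bonferroni_sig"] = table["p"] < thr
    table["fdr_q"] = bh_fdr(table["p"].to_numpy())
    table["fdr_sig"] = table["fdr_q"] <= fdr_level

    ann = manifest.table.reindex(table.index)
    table["novel_epic_only"] = ann["epic_only"].astype(bool)
    reported_genes = set(
        manifest.table.loc[manifest.table["previously_reported"], "gene"]
    ) - {""}
    table["novel_gene"] = (
        table["novel_epic_only"]
        & (ann["gene"] != "")
        & ~ann["gene"].isin(reported_genes)
    )

    lam = genomic_lambda(table["p"].to_numpy()) if len(table) >= 100 else float("nan")
    return MetaResult(
        table=table,
        lambda_inflation=lam,
        bonferroni_threshold=thr,
        fdr_level=fdr_level,
        n_meta_analyzed=len(table),
    )
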