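"""Probe-level preprocessing ahead of association analysis.

Three pieces: the beta-value formula (methylated / (methylated +
unmethylated + 100)), probe-level QC filters (cross-reactive probes,
polymorphic CpGs with MAF > 5%, probes with > 5% missingness — strict
inequalities, applied in that order), and a rank-based inverse-normal
transform (Blom offset 3/8, average ranks for ties) used to normalize
per-probe methylation to N(0, 1) before linear modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .datatypes import MethylationDataset, ValidationError

logger = logging.getLogger(__name__)


def compute_beta(meth, unmeth, offset: float = 100.0):
    """Beta value = meth / (meth + unmeth + offset), always in [0, 1).

    ``meth`` and ``unmeth`` are non-negative bead intensities; the offset
    (default 100) regularises low-intensity probes.
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if (meth < 0).any() or (unmeth < 0).any():
        raise ValidationError("negative bead intensity")
    out = meth / (meth + unmeth + offset)
    return float(out) if out.ndim == 0 else out


@dataclass
class FilterReport:
    """Per-stage probe removal counts; a probe failing several filters is
    attributed to the first stage that removes it."""

    n_input: int
    n_crossreactive_removed: int
    n_polymorphic_removed: int
    n_missingness_removed: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = (
            self.n_crossreactive_removed
            + self.n_polymorphic_removed
            + self.n_missingness_removed
        )
        assert self.n_retained == self.n_input - removed

    def to_dict(self) -> dict:
        return asdict(self)


def filter_probes(
    ds: MethylationDataset,
    maf_threshold: float = 0.05,
    missingness_threshold: float = 0.05,
) -> tuple[MethylationDataset, FilterReport]:
    """Remove QC-failing probes; order: cross-reactive, polymorphic, missingness.

    Thresholds are strict: a probe is dropped when its MAF exceeds
    ``maf_threshold`` or its missing fraction exceeds
    ``missingness_threshold`` (values exactly at the threshold are kept).
    Idempotent: filtering a filtered dataset removes nothing further.
    """
    ann = ds.manifest.table.reindex(ds.betas.index)
    n_input = len(ds.betas)

    cross = ann["cross_reactive"].to_numpy(dtype=bool)
    poly = (ann["polymorphic_maf"].to_numpy(dtype=float) > maf_threshold) & ~cross
    miss_frac = ds.betas.isna().mean(axis=1).to_numpy()
    miss = (miss_frac > missingness_threshold) & ~cross & ~poly

    keep = ~(cross | poly | miss)
    report = FilterReport(
        n_input=n_input,
        n_crossreactive_removed=int(cross.sum()),
        n_polymorphic_removed=int(poly.sum()),
        n_missingness_removed=int(miss.sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        logger.warning("all %d probes removed by QC filters", n_input)
    filtered = MethylationDataset(
        betas=ds.betas.loc[keep],
        samples=ds.samples,
        manifest=ds.manifest,
        name=ds.name,
    )
    return filtered, report


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Non-missing entries are replaced by Phi^-1((r - 3/8) / (n + 1/4)) where
    r is the average rank (ties share ranks) and n the non-missing count;
    missing entries stay missing. Invariant to strictly monotone transforms
    of the input. Requires at least 3 non-missing values.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    n = int(ok.sum())
    if n < 3:
        raise ValidationError(f"need >= 3 non-missing values, got {n}")
    ranks = rankdata(v[ok], method="average")
    out[ok] = ndtri((ranks - 0.375) / (n + 0.25))
    return out


def transform_matrix(betas: pd.DataFrame) -> pd.DataFrame:
    """Apply the inverse-normal transform probe-wise (rows) to a beta matrix."""
    vals = betas.to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    n_ok = ok.sum(axis=1)
    if (n_ok < 3).any():
        bad = betas.index[n_ok < 3][:5].tolist()
        raise ValidationError(f"probes with < 3 non-missing values: {bad}")
    out = np.full_like(vals, np.nan)
    if ok.all():
        ranks = rankdata(vals, method="average", axis=1)
        out = ndtri((ranks - 0.375) / (vals.shape[1] + 0.25))
    else:
        for i in range(vals.shape[0]):
            row_ok = ok[i]
            ranks = rankdata(vals[i, row_ok], method="average")
            out[i, row_ok] = ndtri((ranks - 0.375) / (row_ok.sum() + 0.25))
    return pd.DataFrame(out, index=betas.index, columns=betas.columns)


def zscore_transform(values) -> np.ndarray:
    """Plain z-score alternative to the rank-based transform (config switch)."""
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 3:
        raise ValidationError("need >= 3 non-missing values")
    mu = v[ok].mean()
    sd = v[ok].std(ddof=1)
    if sd == 0:
        raise ValidationError("zero variance input")
    out = np.full(v.shape, np.nan)
    out[ok] = (v[ok] - mu) / sd
    return out
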