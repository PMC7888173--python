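"""Replication of novel DMPs and persistence after smoking cessation.

Replication: novel discovery DMPs are tested in one or more independent
cohorts; multiple replication cohorts are first pooled with the same
inverse-variance meta-analysis as the discovery stage. A probe replicates
at the Bonferroni level when its pooled replication p falls below
alpha / (number of probes actually tested) *and* the replication estimate
has the same sign as the discovery estimate; zero estimates never count
as agreeing. Probes missing from a replication cohort's QC'd results
shrink the Bonferroni denominator.

Persistence: discovery DMPs are re-tested in the former-versus-never
contrast, pooled across cohorts; a DMP is persistent when its pooled p
falls below alpha / (number of DMPs tested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ValidationError
from .ewas import CohortResult
from .meta import MetaResult, bonferroni_threshold, ivw_pool

logger = logging.getLogger(__name__)


@dataclass
class ReplicationReport:
    """Per-probe replication outcomes plus summary counts and rates."""

    table: pd.DataFrame
    alpha: float
    bonferroni_threshold: float

    def summary(self) -> dict:
        t = self.table
        n = len(t)
        nb = int(t["replicated_bonf"].sum())
        nn = int(t["replicated_nominal"].sum())
        return {
            "n_tested": n,
            "n_replicated_bonf": nb,
            "n_replicated_nominal": nn,
            "rate_bonf": nb / n if n else float("nan"),
            "rate_nominal": nn / n if n else float("nan"),
            "bonferroni_threshold": self.bonferroni_threshold,
        }


@dataclass
class PersistenceReport:
    """Former-versus-never outcomes at the discovery DMPs."""

    table: pd.DataFrame
    alpha: float
    bonferroni_threshold: float

    def summary(self) -> dict:
        t = self.table
        return {
            "n_dmps_tested": len(t),
            "n_persistent": int(t["persistent"].sum()),
            "bonferroni_threshold": self.bonferroni_threshold,
        }


def _pool_tables(tables: list[pd.DataFrame], probes: pd.Index) -> pd.DataFrame:
    """IVW-pool estimate/se across result tables at the given probes."""
    rows = {}
    for pid in probes:
        bs, ss = [], []
        for t in tables:
            if pid in t.index:
                b, s = t.at[pid, "estimate"], t.at[pid, "se"]
                if np.isfinite(b) and np.isfinite(s) and s > 0:
                    bs.append(b)
                    ss.append(s)
        if bs:
            beta, se, z, p = ivw_pool(bs, ss)
            rows[pid] = (beta, se, p, len(bs))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["estimate", "se", "p", "k"]
    )


def test_replication(
    discovery: MetaResult,
    replication_results: list,
    alpha: float = 0.05,
    probes: pd.Index | None = None,
) -> ReplicationReport:
    """Test novel discovery DMPs in independent replication cohorts.

    ``probes`` defaults to the discovery's Bonferroni DMPs restricted to
    probes only present on the newer array (the novel set). Replication
    inputs may be :class:`CohortResult` or :class:`MetaResult` objects.
    """
    if probes is None:
        d = discovery.table
        probes = d.index[
            d["bonferroni_sig"] & ~d["het_excluded"] & d["novel_epic_only"]
        ]
    probes = pd.Index(probes)
    if len(probes) == 0:
        raise ValidationError("no probes to replicate")

    tables = []
    for r in replication_results:
        t = r.table
        if "estimate" not in t.columns:  # MetaResult input
            t = t.rename(columns={"beta_meta": "estimate", "se_meta": "se"})
        tables.append(t[["estimate", "se"]].join(t.filter(["p"])))
    pooled = _pool_tables(tables, probes)
    if pooled.empty:
        raise ValidationError("replication results cover none of the tested probes")
    n_tested = len(pooled)
    if n_tested < len(probes):
        logger.info(
            "%d of %d probes unavailable in replication; Bonferroni denominator "
            "shrunk to %d",
            len(probes) - n_tested,
            len(probes),
            n_tested,
        )
    thr = bonferroni_threshold(alpha, n_tested)

    disc_sign = np.sign(discovery.table["beta_meta"].reindex(pooled.index))
    rep_sign = np.sign(pooled["estimate"])
    same_dir = (disc_sign * rep_sign) > 0  # zero estimates never agree

    out = pd.DataFrame(
        {
            "discovery_direction": disc_sign,
            "replication_estimate": pooled["estimate"],
            "replication_se": pooled["se"],
            "replication_p": pooled["p"],
            "k": pooled["k"],
            "same_direction": same_dir,
            "replicated_bonf": same_dir & (pooled["p"] < thr),
            "replicated_nominal": same_dir & (pooled["p"] < alpha),
        }
    )
    return ReplicationReport(table=out, alpha=alpha, bonferroni_threshold=thr)


def persistence_analysis(
    dmp_list,
    former_results: list[CohortResult],
    discovery: MetaResult | None = None,
    alpha: float = 0.05,
) -> PersistenceReport:
    """Classify discovery DMPs as persistent or reversed after cessation.

    Pools former-versus-never estimates across cohorts per probe and calls
    a DMP persistent when the pooled p is below alpha / (DMPs tested).
    When a discovery MetaResult is supplied, each probe also records
    whether the former-smoker effect has the same direction as discovery.
    """
    probes = pd.Index(dmp_list)
    if len(probes) == 0:
        raise ValidationError("dmp_list is empty")
    pooled = _pool_tables([r.table for r in former_results], probes)
    if pooled.empty:
        raise ValidationError("former-vs-never results cover none of the DMPs")
    n_tested = len(pooled)
    thr = bonferroni_threshold(alpha, n_tested)

    out = pd.DataFrame(
        {
            "former_estimate": pooled["estimate"],
            "former_se": pooled["se"],
            "former_p": pooled["p"],
            "k": pooled["k"],
            "persistent": pooled["p"] < thr,
        }
    )
    if discovery is not None:
        disc = np.sign(discovery.table["beta_meta"].reindex(pooled.index))
        out["direction_vs_discovery"] = np.where(
            disc * np.sign(pooled["estimate"]) > 0, "same", "opposite"
        )
    return PersistenceReport(table=out, alpha=alpha, bonferroni_threshold=thr)
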