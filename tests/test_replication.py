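"""Replication direction/threshold rules and cessation-persistence calls."""

import numpy as np
import pandas as pd
import pytest

from ewaskit.datatypes import ValidationError
from ewaskit.ewas import CohortResult, run_cohort_ewas
from ewaskit.meta import MetaResult, run_meta
from ewaskit.replication import persistence_analysis
from ewaskit.replication import test_replication as check_replication
from ewaskit.simulate import SimulationConfig, generate_cohorts, generate_manifest

from conftest import two_cohort_config


def _meta_stub(probe_ids, betas):
    t = pd.DataFrame(
        {
            "beta_meta": betas,
            "se_meta": 0.1,
            "p": 1e-12,
            "bonferroni_sig": True,
            "het_excluded": False,
            "novel_epic_only": True,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return MetaResult(t, float("nan"), 1e-8, 0.01, len(t))


def _cohort_stub(probe_ids, est, se, p):
    t = pd.DataFrame(
        {"estimate": est, "se": se, "p": p},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return CohortResult("rep", "current_vs_never", t)


class TestReplicationRules:
    def test_same_sign_small_p_replicates(self):
        disc = _meta_stub(["cg1"], [-0.5])
        rep = _cohort_stub(["cg1"], [-0.3], [0.05], [1e-8])
        out = check_replication(disc, [rep], probes=pd.Index(["cg1"]))
        assert out.table.at["cg1", "replicated_bonf"]

    def test_opposite_sign_never_replicates(self):
        disc = _meta_stub(["cg1"], [-0.5])
        rep = _cohort_stub(["cg1"], [0.6], [0.01], [1e-30])
        out = check_replication(disc, [rep], probes=pd.Index(["cg1"]))
        row = out.table.loc["cg1"]
        assert not row["replicated_bonf"] and not row["replicated_nominal"]

    def test_zero_estimate_counts_as_disagreement(self):
        disc = _meta_stub(["cg1"], [-0.5])
        rep = _cohort_stub(["cg1"], [0.0], [0.01], [1e-10])
        out = check_replication(disc, [rep], probes=pd.Index(["cg1"]))
        assert not out.table.at["cg1", "same_direction"]

    def test_bonferroni_denominator_shrinks_to_probes_tested(self):
        disc = _meta_stub(["cg1", "cg2"], [-0.5, 0.4])
        rep = _cohort_stub(["cg1"], [-0.3], [0.05], [1e-8])  # cg2 failed QC
        out = check_replication(disc, [rep], probes=pd.Index(["cg1", "cg2"]))
        assert out.bonferroni_threshold == pytest.approx(0.05 / 1)

    def test_bonferroni_implies_nominal(self, rng):
        probes = [f"cg{i}" for i in range(50)]
        disc = _meta_stub(probes, rng.standard_normal(50))
        rep = _cohort_stub(
            probes, rng.standard_normal(50), rng.uniform(0.01, 1, 50),
            rng.uniform(size=50) ** 3,
        )
        out = check_replication(disc, [rep], probes=pd.Index(probes))
        t = out.table
        assert (t["replicated_bonf"] <= t["replicated_nominal"]).all()
        assert out.summary()["n_replicated_nominal"] >= out.summary()["n_replicated_bonf"]

    def test_zero_overlap_rejected(self):
        disc = _meta_stub(["cg1"], [-0.5])
        rep = _cohort_stub(["other"], [-0.3], [0.05], [1e-8])
        with pytest.raises(ValidationError):
            check_replication(disc, [rep], probes=pd.Index(["cg1"]))


@pytest.fixture(scope="module")
def replication_power_sim():
    """Discovery + same-truth replication: 100 spiked probes, 1000/cohort."""
    man = generate_manifest(600, seed=13)
    cfg = two_cohort_config(
        n_probes=600, n_spiked=100, seed=13,
        cohort_names=("D1", "D2"), cohort_sizes=(1000, 1000),
    )
    dds, truth = generate_cohorts(cfg, man)
    dres = [run_cohort_ewas(d, "current_vs_never") for d in dds]
    dmeta = run_meta(dres, manifest=man)
    rcfg = SimulationConfig(
        **{**cfg.__dict__, "seed": 14, "cohort_names": ("R1", "R2")}
    )
    rds, _ = generate_cohorts(rcfg, man, truth=truth)
    rres = [run_cohort_ewas(d, "current_vs_never") for d in rds]
    return dmeta, rres, truth


class TestReplicationPower:
    def test_spiked_probes_replicate_at_bonferroni(self, replication_power_sim):
        dmeta, rres, truth = replication_power_sim
        out = check_replication(dmeta, rres, probes=truth.spiked.index)
        assert out.summary()["rate_bonf"] >= 0.90

    def test_nominal_rate_at_least_bonferroni_rate(self, replication_power_sim):
        dmeta, rres, truth = replication_power_sim
        out = check_replication(dmeta, rres, probes=truth.spiked.index)
        s = out.summary()
        assert s["rate_nominal"] >= s["rate_bonf"]


@pytest.fixture(scope="module")
def persistence_sim():
    """Two 1200-sample cohorts; 40 spiked probes at effect -0.10 with
    persistence fractions cycling through {0, 0.25, 0.5, 1}."""
    man = generate_manifest(300, seed=21)
    cfg = two_cohort_config(
        n_probes=300, n_spiked=40, seed=21,
        effect_range=(0.10, 0.100001), hypomethylated_fraction=1.0,
        persistence_fractions=(0.0, 0.25, 0.5, 1.0),
        cohort_names=("P1", "P2"), cohort_sizes=(1200, 1200),
        smoking_fractions=((0.25, 0.35, 0.40),) * 2,
    )
    ds, truth = generate_cohorts(cfg, man)
    former = [
        run_cohort_ewas(d.subset_probes(truth.spiked.index), "former_vs_never")
        for d in ds
    ]
    report = persistence_analysis(truth.spiked.index, former)
    return truth, report


class TestPersistence:
    def test_threshold_for_952_dmps(self):
        from ewaskit.meta import bonferroni_threshold

        assert bonferroni_threshold(0.05, 952) == pytest.approx(5.25e-5, rel=1e-3)

    def test_full_reversal_called_non_persistent(self, persistence_sim):
        truth, report = persistence_sim
        reversed_ = truth.spiked.query("persistence_fraction == 0").index
        assert (~report.table.loc[reversed_, "persistent"]).mean() >= 0.95

    def test_fully_persistent_called_persistent(self, persistence_sim):
        truth, report = persistence_sim
        persistent = truth.spiked.query("persistence_fraction == 1").index
        assert report.table.loc[persistent, "persistent"].all()

    def test_detection_monotone_in_persistence_fraction(self, persistence_sim):
        truth, report = persistence_sim
        tab = report.table.join(truth.spiked)
        rates = tab.groupby("persistence_fraction")["persistent"].mean()
        assert (rates.sort_index().diff().dropna() >= 0).all()

    def test_empty_dmp_list_rejected(self, persistence_sim):
        with pytest.raises(ValidationError):
            persistence_analysis([], [], alpha=0.05)
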