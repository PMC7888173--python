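"""IVW pooling, heterogeneity statistics, inflation lambda, multiple testing."""

import numpy as np
import pytest
from scipy import stats

from ewaskit.datatypes import ValidationError
from ewaskit.meta import (
    bh_fdr,
    bonferroni_threshold,
    genomic_lambda,
    heterogeneity,
    ivw_pool,
    run_meta,
)


class TestIvwPool:
    def test_single_study_identity(self):
        b, s, z, p = ivw_pool([1.7], [0.4])
        assert (b, s) == pytest.approx((1.7, 0.4))

    def test_hand_case_two_studies(self):
        b, s, z, p = ivw_pool([1.0, 3.0], [1.0, 1.0])
        assert b == pytest.approx(2.0, abs=1e-12)
        assert s == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-12)

    def test_identical_studies_symmetry(self):
        b, s, z, p = ivw_pool([0.8, 0.8], [0.3, 0.3])
        assert b == pytest.approx(0.8, abs=1e-12)
        assert s == pytest.approx(0.3 / np.sqrt(2.0), abs=1e-12)

    def test_matches_weighted_least_squares_intercept(self, rng):
        """Brute-force WLS intercept fit agrees to 1e-10 on random instances."""
        import statsmodels.api as sm

        for _ in range(20):
            k = rng.integers(2, 8)
            b = rng.standard_normal(k)
            s = rng.uniform(0.1, 2.0, k)
            beta, se, _, _ = ivw_pool(b, s)
            wls = sm.WLS(b, np.ones(k), weights=1.0 / s**2).fit()
            assert beta == pytest.approx(float(wls.params[0]), abs=1e-10)

    def test_pooled_se_never_exceeds_best_cohort(self, rng):
        for _ in range(20):
            k = rng.integers(1, 6)
            s = rng.uniform(0.05, 1.0, k)
            _, se, _, _ = ivw_pool(rng.standard_normal(k), s)
            assert se <= s.min() + 1e-12

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            ivw_pool([1.0, np.nan], [1.0, 1.0])
        with pytest.raises(ValidationError):
            ivw_pool([1.0], [0.0])


class TestHeterogeneity:
    def test_identical_estimates(self):
        q, qp, i2 = heterogeneity([1.0, 1.0, 1.0], [0.5, 0.5, 0.5], 1.0)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert qp == pytest.approx(1.0)
        assert i2 == 0.0

    def test_hand_case(self):
        beta, _, _, _ = ivw_pool([0.0, 2.0], [1.0, 1.0])
        q, qp, i2 = heterogeneity([0.0, 2.0], [1.0, 1.0], beta)
        assert beta == pytest.approx(1.0)
        assert q == pytest.approx(2.0, abs=1e-12)
        assert qp == pytest.approx(stats.chi2.sf(2.0, 1), abs=1e-12)
        assert i2 == pytest.approx(50.0, abs=1e-9)

    def test_single_study_missing(self):
        q, qp, i2 = heterogeneity([1.0], [0.5], 1.0)
        assert np.isnan(q) and np.isnan(qp) and np.isnan(i2)

    def test_null_calibration_qp_uniform(self, rng):
        """Common-effect simulation: Qp < 0.10 for ~10% of probes."""
        hits = 0
        n_probes = 1000
        for _ in range(n_probes):
            s = rng.uniform(0.2, 0.5, 5)
            b = 0.3 + rng.standard_normal(5) * s
            beta, _, _, _ = ivw_pool(b, s)
            _, qp, _ = heterogeneity(b, s, beta)
            hits += qp < 0.10
        assert abs(hits / n_probes - 0.10) < 0.03


class TestGenomicLambda:
    def test_all_half(self):
        assert genomic_lambda(np.full(200, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_p(self):
        p = np.random.default_rng(5).uniform(size=10_000)
        assert 0.97 < genomic_lambda(p) < 1.03

    def test_scale_equivariance(self):
        chi = stats.chi2.rvs(1, size=10_000, random_state=6) * 1.3
        lam = genomic_lambda(stats.chi2.sf(chi, 1))
        assert lam == pytest.approx(1.3, abs=0.05)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            genomic_lambda(np.full(200, 0.0))
        with pytest.raises(ValidationError):
            genomic_lambda([0.5] * 10)


class TestBhFdr:
    def test_hand_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_manual_step_up(self, rng):
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        m = len(p)
        order = np.argsort(p)
        manual = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, m * p[i] / rank)
            manual[i] = prev
        assert np.allclose(q, manual, atol=1e-12)


class TestBonferroniThreshold:
    @pytest.mark.parametrize(
        "m,expected,sig",
        [(800_000, 6.25e-8, 3), (952, 5.25e-5, 3), (525, 9.5e-5, 2)],
    )
    def test_printed_thresholds(self, m, expected, sig):
        thr = bonferroni_threshold(0.05, m)
        assert float(f"%.{sig - 1}e" % thr) == pytest.approx(expected, rel=1e-9)

    def test_zero_m_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.0, 10)


class TestRunMeta:
    def test_spiked_probes_recovered(self, study):
        """Non-heterogeneous strong spikes reach Bonferroni significance and
        the pooled raw effect lands within 2 pooled SEs of truth."""
        truth, meta, results = (
            study["truth"],
            study["meta"],
            study["cohort_results"],
        )
        strong = truth.spiked[
            (truth.spiked["true_effect"].abs() >= 0.1)
            & ~truth.spiked["heterogeneous"]
        ]
        assert meta.table.loc[strong.index, "bonferroni_sig"].all()

    def test_engineered_heterogeneous_probes_flagged(self, study):
        het = study["truth"].spiked.query("heterogeneous").index
        assert study["meta"].table.loc[het, "het_excluded"].all()

    def test_bonferroni_subset_of_fdr(self, study, null_run):
        for m in (study["meta"], null_run["meta"]):
            assert set(m.dmp_probes) <= set(m.fdr_probes)

    def test_nominal_m_option(self, study):
        from ewaskit.meta import run_meta

        m = run_meta(
            study["cohort_results"],
            manifest=study["manifest"],
            nominal_m=800_000,
        )
        assert m.bonferroni_threshold == pytest.approx(6.25e-8)

    def test_novelty_flags_follow_manifest(self, study):
        meta, man = study["meta"], study["manifest"]
        ann = man.table.reindex(meta.table.index)
        assert (meta.table["novel_epic_only"] == ann["epic_only"]).all()
        assert not (meta.table["novel_gene"] & ~meta.table["novel_epic_only"]).any()

    def test_summary_counts(self, study):
        s = study["meta"].summary()
        assert s["n_bonferroni_dmps"] == len(study["meta"].dmp_probes)
        assert s["n_meta_analyzed"] == len(study["meta"].table)
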